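"""Microsatellite (SSR) mining: perfect tandem repeats of 1-6 nt motifs.

A locus is a maximal perfect tandem run of a primitive motif (one that is not
itself a repetition of a shorter motif), trimmed to whole repeats. Default
thresholds: mononucleotide runs of >= 10 bases; 2-6 nt motifs with >= 5
repeats. Runs are broken at ambiguous bases. When qualifying runs overlap, the
longer run wins, ties go to the shorter motif, then to the leftmost start, so
every genomic position belongs to at most one reported locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from ._util import ratio_percent, revcomp


@dataclass
class SSRConfig:
    min_mono_length: int = 10
    min_repeats_2_6: int = 5
    motif_lengths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def validate(self) -> None:
        if self.min_mono_length < 1 or self.min_repeats_2_6 < 1:
            raise ValueError("SSR thresholds must be >= 1")
        if any(m < 1 or m > 6 for m in self.motif_lengths):
            raise ValueError("motif lengths must be within 1..6")


@dataclass(frozen=True)
class SSRLocus:
    contig_id: str
    start: int  # 0-based half-open
    end: int
    motif: str
    repeat_count: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def motif_class(self) -> str:
        return canonical_motif(self.motif)


def is_primitive(motif: str) -> bool:
    """True unless the motif is a whole-number repetition of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical class label: smallest rotation of the motif or its revcomp."""
    if not 1 <= len(motif) <= 6 or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be 1-6 nt over ACGT: {motif!r}")
    rc = revcomp(motif)
    candidates = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(motif))]
    return min(candidates)


def _candidate_runs(seq: str, config: SSRConfig) -> list[tuple[int, int, str, int]]:
    """All qualifying maximal tandem runs as (start, end, motif, repeats)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    out = []
    for m in config.motif_lengths:
        if len(seq) < 2 * m:
            continue
        eq = (arr[m:] == arr[:-m]) & valid[m:] & valid[:-m]
        # runs of consecutive True in eq: eq[i..i+k-1] => seq[i:i+m+k] has period m
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for run_start, run_end in zip(idx[::2], idx[1::2]):
            span = (run_end - run_start) + m  # total periodic span in bases
            repeats = span // m
            if repeats < 2:
                continue
            motif = seq[run_start:run_start + m]
            if not is_primitive(motif):
                continue  # covered by the shorter-period run
            if m == 1:
                if span < config.min_mono_length:
                    continue
            elif repeats < config.min_repeats_2_6:
                continue
            out.append((int(run_start), int(run_start + m * repeats), motif, int(repeats)))
    return out


def find_ssrs(record: SeqRecord | str, config: SSRConfig | None = None) -> list[SSRLocus]:
    """Mine one sequence; loci are non-overlapping, sorted by start."""
    config = config or SSRConfig()
    config.validate()
    if isinstance(record, str):
        seq, contig_id = record.upper(), "seq"
    else:
        seq, contig_id = str(record.seq).upper(), record.id
    if not seq:
        raise ValueError("sequence is empty")
    candidates = _candidate_runs(seq, config)
    # precedence: longest run, then shorter motif, then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    taken: list[tuple[int, int]] = []
    accepted = []
    for start, end, motif, repeats in candidates:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        accepted.append(SSRLocus(contig_id, start, end, motif, repeats))
    accepted.sort(key=lambda l: l.start)
    return accepted


def find_ssrs_in_records(
    records: Iterable[SeqRecord], config: SSRConfig | None = None
) -> list[SSRLocus]:
    out: list[SSRLocus] = []
    for rec in records:
        out.extend(find_ssrs(rec, config))
    return out


@dataclass
class SSRSummary:
    counts_by_motif_length: dict[int, int]
    percent_by_motif_length: dict[int, float]
    counts_by_motif: dict[str, int] = field(default_factory=dict)
    total_loci: int = 0
    density_kb_per_locus: float | None = None

    def to_tsv(self) -> str:
        names = {1: "Mononucleotide", 2: "Dinucleotide", 3: "Trinucleotide",
                 4: "Tetranucleotide", 5: "Pentanucleotide", 6: "Hexanucleotide"}
        lines = ["Motif length\tNumber of occurences\tFrequency (%)"]
        for m in sorted(self.counts_by_motif_length):
            lines.append(f"{names[m]}\t{self.counts_by_motif_length[m]}\t"
                         f"{self.percent_by_motif_length[m]}")
        lines.append(f"Total\t{self.total_loci}\t100")
        density = "undefined" if self.density_kb_per_locus is None \
            else self.density_kb_per_locus
        lines.append(f"Density (kb/locus)\t{density}\t")
        return "\n".join(lines) + "\n"


def summary_from_counts(
    counts_by_motif_length: dict[int, int], assembly_total_length: int,
    counts_by_motif: dict[str, int] | None = None,
) -> SSRSummary:
    """Summaries from per-motif-length counts (2-decimal percentages, 1-decimal
    density in kb per locus)."""
    if assembly_total_length <= 0:
        raise ValueError("assembly_total_length must be positive")
    total = sum(counts_by_motif_length.values())
    if total == 0:
        return SSRSummary(dict(counts_by_motif_length), {}, counts_by_motif or {},
                          total_loci=0, density_kb_per_locus=None)
    percents = {m: ratio_percent(c, total, 2)
                for m, c in counts_by_motif_length.items()}
    density = round(assembly_total_length / 1000 / total, 1)
    return SSRSummary(dict(counts_by_motif_length), percents,
                      counts_by_motif or {}, total_loci=total,
                      density_kb_per_locus=density)


def ssr_summary(loci: Sequence[SSRLocus], assembly_total_length: int) -> SSRSummary:
    """Per-motif-length counts/percentages and overall density of mined loci."""
    counts_by_len: dict[int, int] = {}
    counts_by_motif: dict[str, int] = {}
    for locus in loci:
        m = len(locus.motif)
        counts_by_len[m] = counts_by_len.get(m, 0) + 1
        cls = locus.motif_class
        counts_by_motif[cls] = counts_by_motif.get(cls, 0) + 1
    return summary_from_counts(counts_by_len, assembly_total_length, counts_by_motif)


def loci_to_frame(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.contig_id, l.start, l.end, l.motif, l.repeat_count, l.motif_class)
         for l in loci],
        columns=["contig_id", "start", "end", "motif", "repeat_count", "motif_class"],
    )


def loci_to_bed(loci: Sequence[SSRLocus], path) -> None:
    """BED4 with name = motif:repeat_count (0-based half-open)."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.contig_id}\t{l.start}\t{l.end}\t{l.motif}:{l.repeat_count}\n")
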