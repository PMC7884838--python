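"""Seeded synthetic data: hairpin training sets, coding negatives, genomes.

The generator emulates the inputs of an ab initio pre-miRNA survey of a draft
plant genome assembly:

* positives are stem-loop (hairpin) sequences — ``stem + loop + revcomp(stem)``
  with per-base substitutions on the 3' arm, 70–300 nt, drawn as diverged
  members of a fixed set of hairpin families (emulating the strong family
  redundancy of curated pre-miRNA collections) at the AU-rich composition of
  non-coding sequence in an AT-rich plant genome (GC 0.36);
* negatives are codon-structured protein-coding fragments sampled from a codon
  usage table (uniform over the 61 sense codons by default, GC ≈ 0.52), with no
  in-frame stop codon;
* genomes are multi-contig i.i.d. backgrounds at a configurable GC (default
  38.7%, a typical pome-fruit genomic composition) with microsatellites and
  hairpin loci planted at recorded, non-overlapping coordinates.

A single integer seed drives everything; each generator derives its stream by
a fixed offset, so outputs are byte-identical across reruns.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import child_rng, revcomp

_BASES = np.array(list("ACGT"))

#: All 61 sense codons (the 64 triplets minus TAA/TAG/TGA), lexicographic.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)

# fixed stage offsets for child RNG streams
_FAMILY_STREAM = 10
_HAIRPIN_STREAM = 11
_CODING_STREAM = 12
_GENOME_STREAM = 13


class ParameterError(ValueError):
    """Infeasible or inconsistent simulation parameters."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the conditions every downstream test runs under: balanced
    1,000 + 1,000 training classes, 70–300 nt hairpins, genomic background at
    38.7% GC.
    """

    seed: int = 0
    n_positives: int = 1000
    n_negatives: int = 1000
    hairpin_length_range: tuple[int, int] = (70, 300)
    loop_length_range: tuple[int, int] = (4, 10)
    stem_mutation_rate: float = 0.05
    hairpin_gc: float = 0.36
    n_families: int = 100
    family_divergence: float = 0.08
    coding_length_range: tuple[int, int] = (70, 300)
    codon_weights: dict[str, float] | None = None
    n_contigs: int = 5
    contig_length_range: tuple[int, int] = (20_000, 60_000)
    background_gc: float = 0.387
    planted_ssrs: list[tuple[str, int]] = field(
        default_factory=lambda: [("A", 14), ("AT", 8), ("AAG", 6), ("ACAT", 5)]
    )
    planted_hairpins: int = 10
    #: optional (min, max) stem truncation for planted hairpins; None plants
    #: full-length family members, as pre-miRNA loci occur in real genomes
    planted_stem_range: tuple[int, int] | None = None

    def validate(self) -> None:
        for name in ("hairpin_length_range", "loop_length_range",
                     "coding_length_range", "contig_length_range",
                     "planted_stem_range"):
            rng_val = getattr(self, name)
            if rng_val is None:
                continue
            lo, hi = rng_val
            if lo > hi:
                raise ParameterError(f"{name}: min {lo} > max {hi}")
        for name in ("background_gc", "hairpin_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.stem_mutation_rate <= 1.0:
            raise ParameterError("stem_mutation_rate must be in [0, 1]")
        if not 0.0 <= self.family_divergence <= 1.0:
            raise ParameterError("family_divergence must be in [0, 1]")
        if self.n_families < 1:
            raise ParameterError("n_families must be >= 1")
        if self.n_positives < 1 or self.n_negatives < 1:
            raise ParameterError("n_positives and n_negatives must be >= 1")
        if self.hairpin_length_range[0] < 20:
            raise ParameterError("hairpins shorter than 20 nt are not supported")
        # a hairpin needs 2*stem + loop; stem >= 1
        if self.hairpin_length_range[1] < 2 + self.loop_length_range[0]:
            raise ParameterError("hairpin length range cannot fit stem + loop")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for name in ("hairpin_length_range", "loop_length_range",
                     "coding_length_range", "contig_length_range",
                     "planted_stem_range"):
            if d.get(name) is not None:
                d[name] = tuple(d[name])
        d["planted_ssrs"] = [tuple(x) for x in d["planted_ssrs"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def build_hairpin(stem: str, loop: str,
                  mutation_rate: float = 0.0,
                  rng: np.random.Generator | None = None) -> str:
    """``stem + loop + revcomp(stem)`` with per-base substitutions on the 3' arm."""
    arm2 = revcomp(stem)
    if mutation_rate > 0:
        if rng is None:
            raise ValueError("mutation_rate > 0 requires an rng")
        arm2 = _mutate(rng, arm2, mutation_rate)
    return stem + loop + arm2


def _hairpin_families(config: SimulationConfig) -> list[tuple[str, str]]:
    """Family archetypes (stem, loop), fixed by the seed alone so the training
    set and the planted genome loci share the same families."""
    rng = child_rng(config.seed, _FAMILY_STREAM)
    lo, hi = config.hairpin_length_range
    llo, lhi = config.loop_length_range
    fams = []
    for _ in range(config.n_families):
        total = int(rng.integers(lo, hi + 1))
        loop_len = int(rng.integers(llo, lhi + 1))
        if (total - loop_len) % 2:  # shrink by 1 nt so the arms match
            total -= 1
        stem_len = (total - loop_len) // 2
        if stem_len < 1:
            raise ParameterError(
                f"hairpin of {total} nt cannot fit a loop of {loop_len} nt"
            )
        fams.append((_random_bases(rng, stem_len, config.hairpin_gc),
                     _random_bases(rng, loop_len, config.hairpin_gc)))
    return fams


def _family_member(rng: np.random.Generator, stem: str, loop: str,
                   config: SimulationConfig, stem_len: int | None = None) -> str:
    if stem_len is not None:
        stem = stem[:stem_len]
    stem = _mutate(rng, stem, config.family_divergence)
    loop = _mutate(rng, loop, config.family_divergence)
    return build_hairpin(stem, loop, config.stem_mutation_rate, rng)


def make_hairpin_set(config: SimulationConfig) -> list[SeqRecord]:
    """Generate the positive class: pre-miRNA-like hairpin sequences.

    Records are diverged members of ``n_families`` archetype hairpins, the way
    curated pre-miRNA collections consist of conserved families rather than
    unrelated sequences.
    """
    config.validate()
    fams = _hairpin_families(config)
    rng = child_rng(config.seed, _HAIRPIN_STREAM)
    records = []
    for i in range(config.n_positives):
        stem, loop = fams[int(rng.integers(len(fams)))]
        seq = _family_member(rng, stem, loop, config)
        records.append(
            SeqRecord(Seq(seq), id=f"hairpin_{i:05d}",
                      description="synthetic pre-miRNA-like hairpin")
        )
    return records


def make_coding_set(config: SimulationConfig) -> list[SeqRecord]:
    """Generate the negative class: codon-structured coding fragments.

    Codons are drawn i.i.d. from the configured codon table (uniform over the
    61 sense codons by default), so sequences carry codon-level composition
    and stop-codon depletion but no in-frame stops; lengths are multiples of 3.
    """
    config.validate()
    rng = child_rng(config.seed, _CODING_STREAM)
    if config.codon_weights is None:
        codons = list(SENSE_CODONS)
        probs = np.full(len(codons), 1.0 / len(codons))
    else:
        codons = sorted(config.codon_weights)
        for c in codons:
            if len(c) != 3 or set(c) - set("ACGT") or c in ("TAA", "TAG", "TGA"):
                raise ParameterError(f"invalid sense codon in table: {c}")
        probs = np.array([config.codon_weights[c] for c in codons], dtype=float)
        probs /= probs.sum()
    lo, hi = config.coding_length_range
    records = []
    for i in range(config.n_negatives):
        n_codons = max(1, int(round(int(rng.integers(lo, hi + 1)) / 3)))
        idx = rng.choice(len(codons), size=n_codons, p=probs)
        seq = "".join(codons[j] for j in idx)
        records.append(
            SeqRecord(Seq(seq), id=f"cds_{i:05d}",
                      description="synthetic coding fragment")
        )
    return records


def crop_to_scan_windows(records: Sequence[SeqRecord], window_length: int = 70,
                         seed: int = 0) -> list[SeqRecord]:
    """Random fixed-length crop of each record (records shorter than the
    window pass through).

    Scanning classifies isolated windows, so the scan-stage model is trained
    on window-sized fragments of the training sequences; training on
    full-length sequences and deploying on 70-nt windows mixes two different
    feature distributions.
    """
    rng = child_rng(seed, 14)
    out = []
    for r in records:
        s = str(r.seq)
        if len(s) <= window_length:
            out.append(r)
            continue
        a = int(rng.integers(0, len(s) - window_length + 1))
        out.append(SeqRecord(Seq(s[a:a + window_length]), id=r.id,
                             description="scan-window crop"))
    return out


#: truth-table feature kinds
HAIRPIN = "hairpin"
SSR = "ssr"


def make_genome(config: SimulationConfig) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate a multi-contig genome with planted SSRs and hairpin loci.

    Returns the contigs and a truth table (``contig_id, start, end, kind,
    payload`` with 0-based half-open coordinates). Planted features never
    overlap; the base on either side of a planted SSR is forced to break the
    repeat period so the recorded interval is exactly the maximal run.
    """
    config.validate()
    rng = child_rng(config.seed, _GENOME_STREAM)
    lo, hi = config.contig_length_range

    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_contigs)]
    contigs = [list(_random_bases(rng, L, config.background_gc)) for L in lengths]

    features: list[tuple[str, str, str]] = []  # (kind, payload, sequence)
    for motif, count in config.planted_ssrs:
        motif = motif.upper()
        if set(motif) - set("ACGT") or not 1 <= len(motif) <= 6:
            raise ParameterError(f"planted SSR motif must be 1-6 nt ACGT: {motif}")
        features.append((SSR, f"{motif}x{count}", motif * count))
    fams = _hairpin_families(config) if config.planted_hairpins else []
    for i in range(config.planted_hairpins):
        stem, loop = fams[int(rng.integers(len(fams)))]
        if config.planted_stem_range is not None:
            slo, shi = config.planted_stem_range
            stem_len = min(int(rng.integers(slo, shi + 1)), len(stem))
        else:
            stem_len = None
        seq = _family_member(rng, stem, loop, config, stem_len=stem_len)
        features.append((HAIRPIN, f"planted_hairpin_{i:03d}", seq))

    margin = 5
    need = sum(len(s) + 2 * margin for _, _, s in features)
    if need > sum(lengths):
        raise ParameterError(
            f"planted features need {need} bp but contigs total {sum(lengths)} bp"
        )

    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(contigs))}
    rows = []
    for kind, payload, seq in features:
        placed = False
        for _ in range(1000):
            ci = int(rng.integers(len(contigs)))
            L = lengths[ci]
            if L < len(seq) + 2 * margin:
                continue
            start = int(rng.integers(margin, L - len(seq) - margin + 1))
            end = start + len(seq)
            if any(start - margin < e and s < end + margin for s, e in occupied[ci]):
                continue
            contigs[ci][start:end] = list(seq)
            if kind == SSR:
                motif = payload.split("x")[0]
                # break the tandem period on both flanks
                contigs[ci][start - 1] = _different_base(rng, motif[-1])
                contigs[ci][end] = _different_base(rng, motif[0])
            occupied[ci].append((start, end))
            rows.append((f"contig_{ci:03d}", start, end, kind, payload))
            placed = True
            break
        if not placed:
            raise ParameterError(
                f"could not place planted feature {payload!r} without overlap"
            )

    records = [
        SeqRecord(Seq("".join(contigs[i])), id=f"contig_{i:03d}",
                  description="synthetic contig")
        for i in range(len(contigs))
    ]
    truth = pd.DataFrame(rows, columns=["contig_id", "start", "end", "kind", "payload"])
    truth = truth.sort_values(["contig_id", "start"]).reset_index(drop=True)
    return records, truth


def _different_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid]
    return choices[int(rng.integers(3))]


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    """Truth table as BED4 (name column = ``kind:payload``), 0-based half-open."""
    with open(path, "w") as fh:
        for r in truth.itertuples(index=False):
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.kind}:{r.payload}\n")


def read_truth_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            kind, _, payload = name.partition(":")
            rows.append((chrom, int(start), int(end), kind, payload))
    return pd.DataFrame(rows, columns=["contig_id", "start", "end", "kind", "payload"])
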