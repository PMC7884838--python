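"""FASTA/BED input-output and assembly summary statistics.

Assembly statistics follow the usual draft-genome report conventions: N50 is
the length of the contig at which the cumulative sum over descending contig
lengths first reaches half of the total assembly length (inclusive at an exact
half), and GC% is computed over unambiguous bases only, so GC% + AT% = 100
whenever the assembly is N-free.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastaFormatError(ValueError):
    """Malformed FASTA input (message carries the offending line number)."""


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into a list of SeqRecord, order preserved.

    Sequences are uppercased and wrapped lines are joined. Structural problems
    (sequence before any header, empty record, duplicate id) raise
    :class:`FastaFormatError` with the line number.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(f"line {header_line}: record '{header}' has an empty sequence")
        rec_id, _, desc = header.partition(" ")
        if rec_id in seen:
            raise FastaFormatError(f"line {header_line}: duplicate record id '{rec_id}'")
        seen.add(rec_id)
        records.append(SeqRecord(Seq(seq.upper()), id=rec_id, description=desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(f"line {lineno}: sequence data before any '>' header")
                chunks.append(line)
    if header is None:
        raise FastaFormatError("line 1: no FASTA records found")
    flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    """Write records as multi-line FASTA (60-column wrap)."""
    SeqIO.write(list(records), str(path), "fasta")


def filter_min_length(
    records: Sequence[SeqRecord], min_len: int, inclusive: bool = True
) -> list[SeqRecord]:
    """Keep contigs at least (default) or strictly longer than ``min_len``."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    if inclusive:
        return [r for r in records if len(r.seq) >= min_len]
    return [r for r in records if len(r.seq) > min_len]


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    min_length: int
    max_length: int
    total_length: int
    n50: int
    gc_percent: float
    at_percent: float

    def to_tsv(self) -> str:
        rows = [
            ("Number of contigs", self.n_contigs),
            ("Min. contig length (bp)", self.min_length),
            ("Max. contig length (bp)", self.max_length),
            ("Total assembly length (bp)", self.total_length),
            ("N50 value (bp)", self.n50),
            ("GC content (%)", round(self.gc_percent, 2)),
            ("AT content (%)", round(self.at_percent, 2)),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def n50(lengths: Sequence[int]) -> int:
    """N50 of a multiset of contig lengths (cumulative-sum convention)."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def assembly_stats(records: Sequence[SeqRecord]) -> AssemblyStats:
    """Summary statistics for a set of assembly contigs."""
    if not records:
        raise ValueError("assembly_stats requires at least one record")
    lengths = [len(r.seq) for r in records]
    gc = at = 0
    for r in records:
        s = str(r.seq).upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in input")
    gc_percent = 100.0 * gc / (gc + at)
    return AssemblyStats(
        n_contigs=len(records),
        min_length=min(lengths),
        max_length=max(lengths),
        total_length=sum(lengths),
        n50=n50(lengths),
        gc_percent=gc_percent,
        at_percent=100.0 - gc_percent,
    )


def write_bed6(intervals, path: str | os.PathLike, header: str | None = None) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6 (0-based, half-open)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
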