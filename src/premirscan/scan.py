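"""Sliding-window genome scan with a trained hairpin classifier.

Contigs are scanned with a 70-nt window (step 7 by default); every window is
k-mer-featurized and scored by the trained model, windows at or above the call
threshold become hits, and overlapping same-strand hits are merged into
candidate pre-miRNA loci. The reverse strand is scanned on the reverse
complement with coordinates mapped back to the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .classify import TrainedModel
from .kmers import window_kmer_matrix


@dataclass
class ScanConfig:
    window_length: int = 70
    step: int = 7
    probability_threshold: float = 0.95
    both_strands: bool = True
    merge_gap: int = 0

    def validate(self) -> None:
        if not 1 <= self.step <= self.window_length:
            raise ValueError("step must satisfy 1 <= step <= window_length")
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must be in (0, 1)")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


HIT_COLUMNS = ["contig_id", "start", "end", "strand", "probability"]
LOCUS_COLUMNS = ["locus_id", "contig_id", "start", "end", "strand",
                 "max_probability", "n_supporting_windows"]


def windows(contig_length: int, config: ScanConfig) -> np.ndarray:
    """Window start positions 0, step, 2*step, ... fully inside the contig."""
    config.validate()
    if contig_length < config.window_length:
        return np.empty(0, dtype=int)
    return np.arange(0, contig_length - config.window_length + 1, config.step)


def scan(
    contigs: Sequence[SeqRecord], model: TrainedModel, config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Score every window on one or both strands; return hits >= threshold.

    Windows with zero unambiguous k-mers are skipped. Returned coordinates are
    0-based half-open on the forward strand.
    """
    config = config or ScanConfig()
    config.validate()
    if 4 ** model.k != len(model.feature_names):
        raise ValueError("model feature vocabulary is not a full k-mer alphabet")
    rows = []
    strands = ("+", "-") if config.both_strands else ("+",)
    for rec in contigs:
        seq = str(rec.seq).upper()
        L = len(seq)
        for strand in strands:
            s = seq if strand == "+" else revcomp(seq)
            starts, mat = window_kmer_matrix(s, model.k, config.window_length, config.step)
            if len(starts) == 0:
                continue
            keep = mat.sum(axis=1) > 0  # windows with at least one valid k-mer
            if not keep.any():
                continue
            proba = np.zeros(len(starts))
            proba[keep] = model.predict_proba_positive(mat[keep])
            called = keep & (proba >= config.probability_threshold)
            for idx in np.flatnonzero(called):
                w_start = int(starts[idx])
                if strand == "+":
                    fwd_start = w_start
                else:
                    fwd_start = L - (w_start + config.window_length)
                rows.append((rec.id, fwd_start, fwd_start + config.window_length,
                             strand, float(proba[idx])))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(["contig_id", "strand", "start"]).reset_index(drop=True)


def merge_hits(hits: pd.DataFrame, config: ScanConfig | None = None) -> pd.DataFrame:
    """Collapse same-strand hits that overlap or abut within ``merge_gap``.

    The number of supporting windows is conserved: summed over loci it equals
    the number of input hits.
    """
    config = config or ScanConfig()
    config.validate()
    if hits.empty:
        return pd.DataFrame(columns=LOCUS_COLUMNS)
    loci = []
    hits = hits.sort_values(["contig_id", "strand", "start"])
    for (contig, strand), grp in hits.groupby(["contig_id", "strand"], sort=True):
        cur = None
        for r in grp.itertuples(index=False):
            if cur is None or r.start > cur["end"] + config.merge_gap:
                if cur is not None:
                    loci.append(cur)
                cur = {"contig_id": contig, "start": int(r.start), "end": int(r.end),
                       "strand": strand, "max_probability": float(r.probability),
                       "n_supporting_windows": 1}
            else:
                cur["end"] = max(cur["end"], int(r.end))
                cur["max_probability"] = max(cur["max_probability"], float(r.probability))
                cur["n_supporting_windows"] += 1
        if cur is not None:
            loci.append(cur)
    loci.sort(key=lambda d: (d["contig_id"], d["start"], d["strand"]))
    df = pd.DataFrame(loci)
    df.insert(0, "locus_id", [f"locus_{i + 1:06d}" for i in range(len(df))])
    return df[LOCUS_COLUMNS]


def planted_recovery(loci: pd.DataFrame, truth: pd.DataFrame, kind: str = "hairpin") -> float:
    """Fraction of planted features of ``kind`` overlapped by >= 1 candidate locus."""
    planted = truth[truth["kind"] == kind]
    if planted.empty:
        raise ValueError(f"truth table has no features of kind {kind!r}")
    hit = 0
    for t in planted.itertuples(index=False):
        sub = loci[loci["contig_id"] == t.contig_id]
        if ((sub["start"] < t.end) & (sub["end"] > t.start)).any():
            hit += 1
    return hit / len(planted)


def loci_to_bed6(loci: pd.DataFrame, path) -> None:
    """Candidate loci as BED6; score = probability * 1000, capped at 1000."""
    with open(path, "w") as fh:
        for r in loci.itertuples(index=False):
            score = min(1000, int(round(r.max_probability * 1000)))
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.locus_id}\t{score}\t{r.strand}\n")


def loci_to_gff3(loci: pd.DataFrame, path) -> None:
    """Candidate loci as GFF3 ``pre_miRNA`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in loci.itertuples(index=False):
            attrs = (f"ID={r.locus_id};max_probability={r.max_probability:.6f};"
                     f"supporting_windows={r.n_supporting_windows}")
            fh.write(f"{r.contig_id}\tpremirscan\tpre_miRNA\t{r.start + 1}\t{r.end}\t"
                     f"{r.max_probability:.3f}\t{r.strand}\t.\t{attrs}\n")
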