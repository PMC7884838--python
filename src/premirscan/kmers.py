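"""k-mer frequency parameterization of nucleotide sequences.

A sequence is represented by the frequency vector of its overlapping k-mers
(k = 4 by default, 256 features, lexicographic over A < C < G < T). Windows
containing any ambiguous symbol (N, R, Y, ...) are discarded, and counts are
normalized by the number of retained windows, so vectors of sequences of
different lengths are comparable and rows sum to 1 for unambiguous input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def enumerate_kmers(k: int) -> list[str]:
    """All 4**k k-mers over {A,C,G,T}, lexicographic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Integer code of every k-window (base-4), -1 where the window is ambiguous."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} is shorter than k={k}")
    base = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = len(sequence) - k + 1
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        b = base[j:j + n]
        codes = codes * 4 + np.where(b < 0, 0, b)
        valid &= b >= 0
    codes[~valid] = -1
    return codes


def featurize(sequence: str, k: int = 4) -> np.ndarray:
    """Frequency vector of one sequence; zero vector if every window is ambiguous."""
    codes = kmer_codes(sequence, k)
    good = codes[codes >= 0]
    counts = np.bincount(good, minlength=4 ** k).astype(float)
    if good.size:
        counts /= good.size
    return counts


class KmerFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn transformer mapping sequences to k-mer frequency rows.

    Accepts an iterable of strings or Bio SeqRecords. Stateless apart from the
    fitted vocabulary; ``fit`` only validates ``k``.
    """

    def __init__(self, k: int = 4):
        self.k = k

    def fit(self, X: Iterable, y=None) -> "KmerFeaturizer":
        self.feature_names_ = np.array(enumerate_kmers(self.k))
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        check_is_fitted(self, "feature_names_")
        rows = [featurize(_as_str(x), self.k) for x in X]
        return np.vstack(rows) if rows else np.empty((0, 4 ** self.k))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "feature_names_")
        return self.feature_names_


def _as_str(x) -> str:
    return str(x.seq) if hasattr(x, "seq") else str(x)


@dataclass
class FeatureMatrix:
    """Labeled k-mer frequency matrix: positives (label 1) then negatives (0)."""

    X: np.ndarray
    labels: np.ndarray
    ids: list[str]
    feature_names: list[str]
    skipped: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.feature_names[0])

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[idx], labels=self.labels[idx],
            ids=[self.ids[i] for i in np.atleast_1d(idx)],
            feature_names=self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def featurize_dataset(positives: Sequence, negatives: Sequence, k: int = 4) -> FeatureMatrix:
    """Build the labeled matrix: positive rows first, input order preserved.

    Sequences shorter than k are recorded in ``skipped`` rather than silently
    dropped.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    rows, labels, ids, skipped = [], [], [], []
    for label, records in ((1, positives), (0, negatives)):
        for rec in records:
            seq = _as_str(rec)
            rec_id = getattr(rec, "id", None) or f"seq_{len(ids)}"
            if len(seq) < k:
                skipped.append(rec_id)
                continue
            rows.append(featurize(seq, k))
            labels.append(label)
            ids.append(rec_id)
    return FeatureMatrix(
        X=np.vstack(rows), labels=np.array(labels, dtype=int), ids=ids,
        feature_names=enumerate_kmers(k), skipped=skipped,
    )


def window_kmer_matrix(
    sequence: str, k: int, window_length: int, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency rows for every sliding window of a contig.

    Returns (starts, matrix). Windows whose k-mers are all ambiguous yield a
    zero row (callers may skip them). Contigs shorter than the window yield
    zero windows.
    """
    L = len(sequence)
    if L < window_length:
        return np.empty(0, dtype=int), np.empty((0, 4 ** k))
    starts = np.arange(0, L - window_length + 1, step)
    codes = kmer_codes(sequence, k)
    per_window = window_length - k + 1
    mat = np.zeros((len(starts), 4 ** k))
    for i, s in enumerate(starts):
        sub = codes[s:s + per_window]
        good = sub[sub >= 0]
        if good.size:
            mat[i] = np.bincount(good, minlength=4 ** k) / good.size
    return starts, mat
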