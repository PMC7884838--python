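"""Seed-and-extend nucleotide homology search with Karlin-Altschul E-values.

Candidate loci are confirmed against a reference pre-miRNA set using a
blastn-like strategy: exact word seeding (word size 7 by default), ungapped
X-drop extension in both directions, and significance via

    E = K * m' * n' * exp(-lambda * S)

with the standard length adjustment m' = m - l, n' = n - l,
l = ln(K*m*n) / H. Ungapped lambda/K/H constants are tabulated per score
scheme; the default +1/-2 scheme uses the published ungapped values
lambda = 1.33, K = 0.621, H = 1.12 (uniform base composition). References are
indexed on the forward strand and each query is searched on both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio.SeqRecord import SeqRecord

from ._util import revcomp

#: ungapped Karlin-Altschul parameters keyed by (match, mismatch) score scheme
KARLIN_ALTSCHUL_PARAMS: dict[tuple[int, int], tuple[float, float, float]] = {
    # (match, mismatch): (lambda, K, H)
    (1, -2): (1.33, 0.621, 1.12),
    (1, -3): (1.37, 0.711, 1.31),
    (2, -3): (0.62, 0.46, 0.85),
}


@dataclass
class HomologyConfig:
    word_size: int = 7
    evalue_threshold: float = 1e-10
    match_score: int = 1
    mismatch_score: int = -2
    x_drop: int = 20
    la_lambda: float | None = None  # override the tabulated lambda
    la_kappa: float | None = None
    la_entropy: float | None = None

    def validate(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.match_score <= 0 or self.mismatch_score >= 0:
            raise ValueError("expected match_score > 0 and mismatch_score < 0")

    def karlin_altschul(self) -> tuple[float, float, float]:
        scheme = (self.match_score, self.mismatch_score)
        if self.la_lambda is not None and self.la_kappa is not None:
            return (self.la_lambda, self.la_kappa, self.la_entropy or 1.12)
        if scheme not in KARLIN_ALTSCHUL_PARAMS:
            raise ValueError(
                f"no tabulated lambda/K for score scheme {scheme}; "
                "set la_lambda/la_kappa explicitly"
            )
        lam, kappa, ent = KARLIN_ALTSCHUL_PARAMS[scheme]
        return (self.la_lambda or lam, self.la_kappa or kappa, self.la_entropy or ent)


@dataclass(frozen=True)
class HomologyMatch:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    query_start: int  # 0-based half-open, on the forward query strand
    query_end: int
    subject_start: int
    subject_end: int
    strand: str  # strand of the query that aligned to the forward subject


def evalue(
    raw_score: float, query_length: int, database_length: int, config: HomologyConfig,
    n_sequences: int = 1,
) -> float:
    """Karlin-Altschul expectation for an ungapped score.

    ``database_length`` is the summed length of all subject sequences; the
    standard length adjustment subtracts l = ln(K*m*n)/H from the query and
    l per sequence from the database, floored at 1.
    """
    if query_length < 1 or database_length < 1:
        raise ValueError("sequence lengths must be >= 1")
    if not math.isfinite(raw_score):
        raise ValueError("raw_score must be finite")
    lam, kappa, entropy = config.karlin_altschul()
    l_adj = max(0.0, math.log(kappa * query_length * database_length) / entropy)
    m_eff = max(1.0, query_length - l_adj)
    n_eff = max(1.0, database_length - n_sequences * l_adj)
    return kappa * m_eff * n_eff * math.exp(-lam * raw_score)


def bit_score(raw_score: float, config: HomologyConfig) -> float:
    lam, kappa, _ = config.karlin_altschul()
    return (lam * raw_score - math.log(kappa)) / math.log(2)


def build_word_index(
    references: Sequence[SeqRecord], config: HomologyConfig | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Exact-match lookup: word -> [(reference index, offset), ...].

    References shorter than the word size are seedless (they can never be
    matched) and trigger a warning.
    """
    import warnings

    config = config or HomologyConfig()
    config.validate()
    if not references:
        raise ValueError("reference set is empty")
    ids = [r.id for r in references]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reference ids")
    w = config.word_size
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, rec in enumerate(references):
        seq = str(rec.seq).upper()
        if len(seq) < w:
            warnings.warn(f"reference {rec.id} shorter than word size; it can never match")
            continue
        for off in range(len(seq) - w + 1):
            word = seq[off:off + w]
            if set(word) - set("ACGT"):
                continue
            index.setdefault(word, []).append((ri, off))
    return index


def _extend(query: str, subject: str, q_off: int, s_off: int, w: int,
            match: int, mismatch: int, x_drop: int) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of an exact seed; returns
    (score, q_start, q_end, s_start, s_end)."""
    score = w * match
    best = score
    # right
    q, s = q_off + w, s_off + w
    bq, bs = q, s
    cur = score
    while q < len(query) and s < len(subject):
        cur += match if query[q] == subject[s] else mismatch
        q += 1
        s += 1
        if cur > best:
            best, bq, bs = cur, q, s
        elif best - cur > x_drop:
            break
    q_end, s_end = bq, bs
    # left
    score = best
    q, s = q_off, s_off
    bq, bs = q, s
    cur = score
    while q > 0 and s > 0:
        q -= 1
        s -= 1
        cur += match if query[q] == subject[s] else mismatch
        if cur > best:
            best, bq, bs = cur, q, s
        elif best - cur > x_drop:
            break
    return best, bq, q_end, bs, s_end


def search(
    queries: Sequence[SeqRecord], references: Sequence[SeqRecord],
    config: HomologyConfig | None = None,
    index: dict[str, list[tuple[int, int]]] | None = None,
) -> list[HomologyMatch]:
    """Best alignment per (query, subject) with E <= threshold, sorted by E.

    Queries shorter than the word size simply produce no hits. Each query is
    searched on both strands against the forward strand of the references.
    """
    config = config or HomologyConfig()
    config.validate()
    if index is None:
        index = build_word_index(references, config)
    w = config.word_size
    db_length = sum(len(r.seq) for r in references)
    n_seqs = len(references)
    best: dict[tuple[str, int], tuple[int, tuple]] = {}
    for q_rec in queries:
        fwd = str(q_rec.seq).upper()
        if len(fwd) < w:
            continue
        for strand, qseq in (("+", fwd), ("-", revcomp(fwd))):
            # extents already explored, per (subject, diagonal)
            covered: dict[tuple[int, int], list[tuple[int, int]]] = {}
            for q_off in range(len(qseq) - w + 1):
                word = qseq[q_off:q_off + w]
                for ri, s_off in index.get(word, ()):  # seeds
                    spans = covered.setdefault((ri, q_off - s_off), [])
                    if any(a <= q_off < b for a, b in spans):
                        continue
                    subject = str(references[ri].seq).upper()
                    score, q_s, q_e, s_s, s_e = _extend(
                        qseq, subject, q_off, s_off, w,
                        config.match_score, config.mismatch_score, config.x_drop,
                    )
                    spans.append((q_s, q_e))
                    key = (q_rec.id, ri)
                    if key not in best or score > best[key][0]:
                        if strand == "+":
                            fq_s, fq_e = q_s, q_e
                        else:  # map back to forward query coordinates
                            fq_s, fq_e = len(fwd) - q_e, len(fwd) - q_s
                        best[key] = (score, (strand, fq_s, fq_e, s_s, s_e, len(fwd)))
    matches = []
    for (query_id, ri), (score, (strand, q_s, q_e, s_s, s_e, q_len)) in best.items():
        e = evalue(score, q_len, db_length, config, n_sequences=n_seqs)
        if e <= config.evalue_threshold:
            matches.append(HomologyMatch(
                query_id=query_id, subject_id=references[ri].id,
                raw_score=score, bit_score=bit_score(score, config), e_value=e,
                query_start=q_s, query_end=q_e,
                subject_start=s_s, subject_end=s_e, strand=strand,
            ))
    matches.sort(key=lambda m: (m.e_value, m.query_id, m.subject_id))
    return matches


def matches_to_tsv(matches: Sequence[HomologyMatch], path,
                   probabilities: dict[str, float] | None = None) -> None:
    """TSV with subject id, (optional) scan probability, and E-value, plus
    alignment coordinates."""
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tprobability\te_value\tbit_score\traw_score\t"
                 "query_start\tquery_end\tsubject_start\tsubject_end\tstrand\n")
        for m in matches:
            p = probabilities.get(m.query_id, "") if probabilities else ""
            p_str = f"{p:.8f}" if isinstance(p, float) else ""
            fh.write(f"{m.query_id}\t{m.subject_id}\t{p_str}\t{m.e_value:.3e}\t"
                     f"{m.bit_score:.2f}\t{m.raw_score}\t{m.query_start}\t{m.query_end}\t"
                     f"{m.subject_start}\t{m.subject_end}\t{m.strand}\n")
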