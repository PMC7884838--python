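"""Microsatellite mining: thresholds, primitivity, precedence, oracle parity."""

import re

import numpy as np
import pytest

from premirscan._util import revcomp
from premirscan.simulate import SimulationConfig, make_genome
from premirscan.ssr import (SSRConfig, canonical_motif, find_ssrs, is_primitive,
                            ssr_summary, summary_from_counts)


def regex_ssr_oracle(seq, config=None):
    """Brute-force reference miner: overlapping backreference regex finds every
    start of >= 2 period-m repeats; each is normalized to its maximal periodic
    region, then the same qualification and precedence rules apply. Written
    independently of the production scanner."""
    config = config or SSRConfig()
    candidates = set()
    for m in range(1, 7):
        for match in re.finditer(rf"(?=(([ACGT]{{{m}}})\2+))", seq):
            start = match.start()
            # normalize to the maximal period-m region containing this start
            while start > 0 and seq[start - 1] == seq[start - 1 + m] \
                    and seq[start - 1] in "ACGT":
                start -= 1
            end_full = match.start() + len(match.group(1))
            while end_full < len(seq) and seq[end_full] == seq[end_full - m] \
                    and seq[end_full] in "ACGT":
                end_full += 1
            motif = seq[start:start + m]
            if not is_primitive(motif):
                continue
            repeats = (end_full - start) // m
            if m == 1:
                if end_full - start < config.min_mono_length:
                    continue
            elif repeats < config.min_repeats_2_6:
                continue
            candidates.add((start, start + m * repeats, motif, repeats))
    candidates = sorted(candidates)
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    taken, out = [], []
    for c in candidates:
        if any(c[0] < e and s < c[1] for s, e in taken):
            continue
        taken.append((c[0], c[1]))
        out.append(c)
    return sorted(out)


class TestThresholds:
    @pytest.mark.parametrize("seq,expected", [
        ("A" * 10, [(0, 10, "A", 10)]),
        ("A" * 9, []),
        ("AT" * 5, [(0, 10, "AT", 5)]),
        ("AT" * 4, []),
        ("ACG" * 5, [(0, 15, "ACG", 5)]),
        ("AAAA" + "N" + "AAAA", []),           # ambiguity breaks the run
        ("ACGT" * 5, [(0, 20, "ACGT", 5)]),
    ])
    def test_qualification_rules(self, seq, expected):
        got = [(l.start, l.end, l.motif, l.repeat_count) for l in find_ssrs(seq)]
        assert got == expected

    def test_mono_run_not_reported_as_dinucleotide(self):
        # A*10 is A x10, never AA x5 (primitive motifs only)
        loci = find_ssrs("A" * 10)
        assert [l.motif for l in loci] == ["A"]

    def test_flanked_locus_coordinates(self):
        loci = find_ssrs("GGC" + "AT" * 6 + "CGG")
        assert [(l.start, l.end, l.motif) for l in loci] == [(3, 15, "AT")]


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif,expected", [
        ("TA", "AT"), ("AT", "AT"), ("GAA", "AAG"), ("C", "C"),
    ])
    def test_examples(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_minimal_over_rotations_and_revcomp(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            m = "".join(bases[rng.integers(0, 4, rng.integers(1, 7))])
            cands = {m[i:] + m[:i] for i in range(len(m))}
            rc = revcomp(m)
            cands |= {rc[i:] + rc[:i] for i in range(len(rc))}
            assert canonical_motif(m) == min(cands)
            assert canonical_motif(canonical_motif(m)) == canonical_motif(m)

    def test_ambiguous_motif_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("AN")


class TestOracleParity:
    def test_matches_regex_oracle_on_random_sequences(self, rng):
        bases = np.array(list("ACGT"))
        for trial in range(20):
            seq = "".join(bases[rng.integers(0, 4, 3000)])
            # sprinkle repeats around threshold so the comparison is non-trivial
            inserts = ["A" * 11, "A" * 9, "AT" * 6, "AT" * 4, "CTT" * 5, "ACAT" * 5]
            for ins in inserts:
                pos = int(rng.integers(0, len(seq) - len(ins)))
                seq = seq[:pos] + ins + seq[pos + len(ins):]
            got = sorted((l.start, l.end, l.motif, l.repeat_count)
                         for l in find_ssrs(seq))
            assert got == regex_ssr_oracle(seq)

    def test_loci_disjoint_and_sorted(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 5000)]) + "A" * 12 + "AT" * 7
        loci = find_ssrs(seq)
        assert loci == sorted(loci, key=lambda l: l.start)
        assert all(a.end <= b.start for a, b in zip(loci, loci[1:]))


class TestPlantedRecovery:
    def test_planted_at_threshold_recovered_exactly(self):
        cfg = SimulationConfig(seed=8, n_contigs=2, contig_length_range=(20_000, 30_000),
                               planted_hairpins=0,
                               planted_ssrs=[("A", 10), ("AT", 5), ("ACG", 7),
                                             ("AACCGT", 5)])
        contigs, truth = make_genome(cfg)
        found = {(l.contig_id, l.start, l.end)
                 for c in contigs for l in find_ssrs(c)}
        for t in truth.itertuples(index=False):
            assert (t.contig_id, t.start, t.end) in found

    def test_subthreshold_plants_never_reported(self):
        cfg = SimulationConfig(seed=8, n_contigs=1, contig_length_range=(20_000, 20_000),
                               planted_hairpins=0,
                               planted_ssrs=[("A", 9), ("AT", 4), ("CTG", 4)])
        contigs, truth = make_genome(cfg)
        loci = find_ssrs(contigs[0])
        for t in truth.itertuples(index=False):
            assert not any(l.start < t.end and t.start < l.end for l in loci)


class TestSummary:
    def test_single_locus(self):
        loci = find_ssrs("A" * 10)
        s = ssr_summary(loci, 1000)
        assert s.total_loci == 1
        assert s.density_kb_per_locus == 1.0
        assert s.percent_by_motif_length == {1: 100.0}

    def test_percentages_sum_to_100(self):
        s = summary_from_counts({1: 3, 2: 5, 3: 2}, 100_000)
        assert sum(s.percent_by_motif_length.values()) == pytest.approx(100, abs=0.1)

    def test_zero_loci_density_undefined(self):
        s = ssr_summary([], 1000)
        assert s.density_kb_per_locus is None and s.total_loci == 0

    def test_invalid_assembly_length(self):
        with pytest.raises(ValueError):
            summary_from_counts({1: 1}, 0)
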