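"""Synthetic-data generator: construction identities, determinism, composition."""

import numpy as np
import pytest

from premirscan._util import revcomp
from premirscan.simulate import (
    SENSE_CODONS, ParameterError, SimulationConfig, build_hairpin,
    crop_to_scan_windows, make_coding_set, make_genome, make_hairpin_set,
)


class TestHairpins:
    def test_palindromic_stem_construction(self):
        assert build_hairpin("ACGT", "AAAA") == "ACGTAAAAACGT"

    def test_arms_are_reverse_complements_without_mutation(self):
        cfg = SimulationConfig(seed=3, n_positives=20, stem_mutation_rate=0.0)
        for rec in make_hairpin_set(cfg):
            seq = str(rec.seq)
            s = (len(seq) - 4) // 2  # loop is at least 4 nt
            # find the true stem length: longest s with prefix == revcomp(suffix)
            while s > 0 and seq[:s] != revcomp(seq[-s:]):
                s -= 1
            assert s >= 20, "no substantial paired stem found"

    def test_lengths_within_configured_range(self):
        cfg = SimulationConfig(seed=5, n_positives=100)
        lo, hi = cfg.hairpin_length_range
        assert all(lo - 1 <= len(r.seq) <= hi for r in make_hairpin_set(cfg))

    def test_deterministic_given_seed(self):
        a = make_hairpin_set(SimulationConfig(seed=1, n_positives=50))
        b = make_hairpin_set(SimulationConfig(seed=1, n_positives=50))
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]
        c = make_hairpin_set(SimulationConfig(seed=2, n_positives=50))
        assert [str(r.seq) for r in a] != [str(r.seq) for r in c]

    def test_infeasible_length_range_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(hairpin_length_range=(300, 70)).validate()


class TestCodingSet:
    def test_codon_structure(self):
        cfg = SimulationConfig(seed=2, n_negatives=50)
        stops = {"TAA", "TAG", "TGA"}
        for rec in make_coding_set(cfg):
            seq = str(rec.seq)
            assert len(seq) % 3 == 0
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not codons & stops

    def test_codon_frequencies_match_table(self):
        # uniform over 61 sense codons; check each within 3 multinomial SEs
        cfg = SimulationConfig(seed=9, n_negatives=1000)
        counts = {}
        total = 0
        for rec in make_coding_set(cfg):
            seq = str(rec.seq)
            for i in range(0, len(seq), 3):
                counts[seq[i:i + 3]] = counts.get(seq[i:i + 3], 0) + 1
                total += 1
        p = 1 / len(SENSE_CODONS)
        se = np.sqrt(p * (1 - p) / total)
        for codon in SENSE_CODONS:
            assert abs(counts.get(codon, 0) / total - p) < 3 * se

    def test_custom_codon_table(self):
        cfg = SimulationConfig(seed=2, n_negatives=10,
                               codon_weights={"GCT": 1.0, "AAG": 1.0})
        for rec in make_coding_set(cfg):
            seq = str(rec.seq)
            assert {seq[i:i + 3] for i in range(0, len(seq), 3)} <= {"GCT", "AAG"}


class TestGenome:
    def test_planted_ssr_inserted_verbatim(self, small_config):
        small_config.planted_ssrs = [("AT", 10)]
        small_config.planted_hairpins = 0
        contigs, truth = make_genome(small_config)
        assert len(truth) == 1
        row = truth.iloc[0]
        seq = {c.id: str(c.seq) for c in contigs}[row.contig_id]
        assert row.end - row.start == 20
        assert seq[row.start:row.end] == "AT" * 10

    def test_planted_hairpin_count_conserved(self, small_config):
        small_config.planted_hairpins = 5
        _, truth = make_genome(small_config)
        assert (truth.kind == "hairpin").sum() == 5

    def test_truth_intervals_valid_and_disjoint(self, small_config):
        contigs, truth = make_genome(small_config)
        lengths = {c.id: len(c.seq) for c in contigs}
        for r in truth.itertuples(index=False):
            assert 0 <= r.start < r.end <= lengths[r.contig_id]
        for cid, grp in truth.groupby("contig_id"):
            iv = sorted(zip(grp.start, grp.end))
            assert all(a[1] <= b[0] for a, b in zip(iv, iv[1:]))

    def test_background_gc_converges(self):
        cfg = SimulationConfig(seed=4, n_contigs=1, contig_length_range=(100_000, 100_000),
                               planted_ssrs=[], planted_hairpins=0)
        contigs, _ = make_genome(cfg)
        s = str(contigs[0].seq)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - cfg.background_gc) < 0.01

    def test_capacity_error(self):
        cfg = SimulationConfig(n_contigs=1, contig_length_range=(100, 100),
                               planted_hairpins=10)
        with pytest.raises(ParameterError):
            make_genome(cfg)

    def test_config_json_roundtrip(self, small_config):
        restored = SimulationConfig.from_json(small_config.to_json())
        assert restored == small_config


def test_crop_to_scan_windows_lengths():
    recs = make_hairpin_set(SimulationConfig(seed=1, n_positives=20))
    crops = crop_to_scan_windows(recs, 70, seed=1)
    assert all(len(c.seq) <= 70 for c in crops)
    assert [c.id for c in crops] == [r.id for r in recs]
    # crops are substrings of their sources
    for r, c in zip(recs, crops):
        assert str(c.seq) in str(r.seq)
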