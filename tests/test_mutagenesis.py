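"""Saturation mutagenesis analyses against additive oracles."""

import numpy as np
import pytest

from promdesign.design import Objective
from promdesign.mutagenesis import (
    frequency_matrix,
    find_longest_repeat,
    low_score_blocks,
    position_importance,
    repeat_differential,
    single_mutant_scan,
    site_extension_differential,
)
from promdesign.scaffold import sample_sequence
from promdesign.synthetic import (
    GroundTruthModel,
    OracleScorer,
    demo_scaffold,
    make_ground_truth,
)

from conftest import LinearScorer

OBJ = Objective("constitutive_activity", "mean", 0.0)


class TestSingleMutantScan:
    def test_differentials_equal_weight_differences_exactly(self):
        rng = np.random.default_rng(0)
        L = 30
        w = rng.normal(0, 0.1, (4, L))
        oracle = LinearScorer(w)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        prof = single_mutant_scan(seq, oracle, OBJ)
        for p, orig in enumerate(seq):
            oi = "ACGT".index(orig)
            for bi in range(4):
                if bi == oi:
                    assert np.isnan(prof.diffs[p, bi])
                else:
                    assert prof.diffs[p, bi] == pytest.approx(
                        w[bi, p] - w[oi, p], abs=1e-12
                    )

    def test_constant_oracle_gives_zero_scores(self):
        oracle = LinearScorer(np.zeros((4, 10)), bias=0.4)
        prof = single_mutant_scan("ACGTACGTAC", oracle, OBJ)
        assert np.nanmax(np.abs(prof.diffs)) == 0.0
        assert (prof.position_scores == 0).all()

    def test_position_score_is_greatest_loss(self):
        w = np.zeros((4, 3))
        w[:, 1] = [0.0, -0.3, 0.2, 0.1]  # original A at position 1
        oracle = LinearScorer(w)
        prof = single_mutant_scan("AAA", oracle, OBJ)
        # worst mutant at position 1 is C: differential -0.3
        assert prof.position_scores[1] == pytest.approx(0.3)
        assert prof.min_differential[1] == pytest.approx(-0.3)


class TestPositionImportance:
    def test_single_profile_normalized_copy(self):
        rng = np.random.default_rng(1)
        oracle = LinearScorer(rng.normal(0, 0.1, (4, 20)))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        prof = single_mutant_scan(seq, oracle, OBJ)
        imp = position_importance([prof])
        assert imp.scores.max() == pytest.approx(1.0)
        expected = prof.position_scores / prof.position_scores.max()
        assert np.allclose(imp.scores, expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.normal(0, 0.1, (4, 15))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 15))
        p1 = single_mutant_scan(seq, LinearScorer(w), OBJ)
        p2 = single_mutant_scan(seq, LinearScorer(w * 7.0), OBJ)
        assert np.allclose(
            position_importance([p1]).scores, position_importance([p2]).scores
        )

    def test_planted_high_weight_region_localized(self):
        w = np.zeros((4, 40))
        w[1, 10:16] = -0.5  # strong loss when mutating to C in 10..16
        seqs, profs = [], []
        rng = np.random.default_rng(3)
        for _ in range(5):
            seq = "".join("AGT"[i] for i in rng.integers(0, 3, 40))
            profs.append(single_mutant_scan(seq, LinearScorer(w), OBJ))
        imp = position_importance(profs)
        assert set(np.nonzero(imp.scores > 0.5)[0]) == set(range(10, 16))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            position_importance([])


class TestLowScoreBlocks:
    def test_flat_profile_has_no_blocks(self):
        oracle = LinearScorer(np.zeros((4, 50)))
        prof = single_mutant_scan("A" * 50, oracle, OBJ)
        blocks, _ = low_score_blocks([prof], min_len=6, select_fraction=0.05)
        assert blocks == [[]]

    def test_planted_block_found(self):
        w = np.zeros((4, 100))
        w[:, 40:50] = -1.0  # any mutation in 40..50 is very bad
        seq = "A" * 100
        w[0, :] = 0.0  # original base A keeps score 0
        prof = single_mutant_scan(seq, LinearScorer(w), OBJ)
        blocks, thr = low_score_blocks([prof], min_len=6, select_fraction=0.10)
        assert blocks[0] == [(40, 50)]

    def test_threshold_selects_requested_fraction(self):
        rng = np.random.default_rng(4)
        profs = []
        for _ in range(10):
            w = rng.normal(0, 0.1, (4, 80))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
            profs.append(single_mutant_scan(seq, LinearScorer(w), OBJ))
        _, thr = low_score_blocks(profs, select_fraction=0.05)
        pooled = np.concatenate([p.min_differential[p.mask] for p in profs])
        frac = (pooled < thr).mean()
        assert abs(frac - 0.05) <= 1.0 / 80 + 1e-9

    def test_agrees_with_brute_force_run_scan(self):
        rng = np.random.default_rng(5)
        profs = []
        for _ in range(30):
            w = rng.normal(0, 0.1, (4, 60))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            profs.append(single_mutant_scan(seq, LinearScorer(w), OBJ))
        blocks, thr = low_score_blocks(profs, min_len=4, select_fraction=0.08)
        for prof, got in zip(profs, blocks):
            below = (prof.min_differential < thr) & prof.mask
            brute = []
            i = 0
            while i < len(below):
                if below[i]:
                    j = i
                    while j < len(below) and below[j]:
                        j += 1
                    if j - i >= 4:
                        brute.append((i, j))
                    i = j
                else:
                    i += 1
            assert got == brute


class TestRepeatDifferential:
    def test_longest_repeat_matches_regex_oracle(self):
        import re

        rng = np.random.default_rng(6)
        for _ in range(200):
            seq = "".join("AT"[i] for i in rng.integers(0, 2, 40))
            got = find_longest_repeat(seq, "TA", 6)
            best = None
            for m in re.finditer(r"(?:TA)+", seq):
                ln = (m.end() - m.start()) // 2 * 2
                if ln >= 6 and (best is None or ln > best[1] - best[0]):
                    best = (m.start(), m.start() + ln)
            assert got == best

    def test_no_repeat_contributes_baseline_only(self):
        oracle = LinearScorer(np.zeros((4, 20)))
        seq = "ACGCACGCACGCACGCACGC"  # no TA repeat
        prof = single_mutant_scan(seq, oracle, OBJ)
        table = repeat_differential([seq], [prof])
        assert set(table.repeat_length) == {0}

    def test_planted_ta_bonus_makes_repeat_medians_negative(self):
        sc = demo_scaffold(inducible=True)
        truth = make_ground_truth(
            sc, np.random.default_rng(7), ta_repeat_bonus=0.15
        )
        oracle = OracleScorer(truth)
        rng = np.random.default_rng(8)
        region = (0, 24)  # 5' spacer of the demo inducible scaffold
        seqs, profs = [], []
        while len(seqs) < 15:
            s = sample_sequence(sc, rng)
            s = s[:6] + "TATATATA" + s[14:]  # ensure a repeat in the spacer
            seqs.append(s)
            profs.append(single_mutant_scan(s, oracle, Objective("induced_activity", "mean", 0.0), mask=sc.randomized_mask()))
        table = repeat_differential(seqs, profs, region=region)
        rep = table[table.repeat_length >= 6].median_differential
        base = table[table.repeat_length == 0].median_differential
        assert np.median(rep) < np.median(base)


class TestSiteExtension:
    def _setup(self, with_extension: bool):
        sc = demo_scaffold(inducible=True)
        truth = make_ground_truth(
            sc, np.random.default_rng(9), gcta_extension_bonus=0.2
        )
        oracle = OracleScorer(truth)
        rng = np.random.default_rng(10)
        sites = [m for m in range(len(sc.constant_backbone()))
                 if sc.constant_backbone()[m : m + 9] == "GCGTGGGCG"]
        seqs, profs = [], []
        for _ in range(10):
            s = sample_sequence(sc, rng)
            if with_extension:
                p = sites[0] + 9
                s = s[:p] + "GCTA" + s[p + 4 :]
            else:
                p = sites[0] + 9
                if s[p : p + 4] == "GCTA":
                    s = s[:p] + "CCCC" + s[p + 4 :]
            seqs.append(s)
            profs.append(
                single_mutant_scan(s, oracle, OBJ, mask=sc.randomized_mask())
            )
        return sc, sites, seqs, profs

    def test_extension_class_median_more_negative(self):
        sc, sites, seqs_e, profs_e = self._setup(True)
        _, _, seqs_n, profs_n = self._setup(False)
        table = site_extension_differential(
            seqs_e + seqs_n, profs_e + profs_n, site_positions=sites
        )
        t0 = table[table.site_index == 0]
        ext = t0[t0.is_extension].median_differential
        non = t0[~t0.is_extension].median_differential
        assert len(ext) and len(non)
        assert ext.median() < non.median()

    def test_classification_matches_string_comparison(self):
        sc, sites, seqs, profs = self._setup(True)
        table = site_extension_differential(seqs, profs, site_positions=sites)
        for _, row in table.iterrows():
            s = seqs[row.sequence_index]
            pos = sites[row.site_index] + 9
            assert row.is_extension == (s[pos : pos + 4] == "GCTA")

    def test_absent_site_warns_and_returns_empty(self):
        oracle = LinearScorer(np.zeros((4, 20)))
        seq = "A" * 20
        prof = single_mutant_scan(seq, oracle, OBJ)
        with pytest.warns(UserWarning):
            table = site_extension_differential([seq], [prof])
        assert table.empty


class TestFrequencyMatrix:
    def test_identical_sequences(self):
        counts = frequency_matrix(["ACGT"] * 7)
        assert counts.sum(axis=0).tolist() == [7, 7, 7, 7]
        assert counts[0, 0] == 7 and counts[3, 3] == 7

    def test_column_sums_always_n(self):
        rng = np.random.default_rng(11)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 25)) for _ in range(40)]
        counts = frequency_matrix(seqs, region=(5, 20))
        assert (counts.sum(axis=0) == 40).all()

    def test_uniform_input_near_uniform_counts(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(12)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 10)) for _ in range(2000)]
        counts = frequency_matrix(seqs)
        for j in range(10):
            _, p = chisquare(counts[:, j])
            assert p > 0.001
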