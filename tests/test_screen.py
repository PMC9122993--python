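"""Scanning-mutagenesis design and screen statistics."""

import numpy as np
import pytest

from _oracles import zscore_chain
from cutscan.errors import (DegeneratePlateError, MissingControlsError,
                            RangeError, UndefinedRatioError)
from cutscan.screen import (ProteinSequence, analyze_screen, call_hits,
                            depletion_ratio, enumerate_scan_variants,
                            plate_control_stats, qc_filter, variant_zscore,
                            DepletionResult)
from cutscan.simulate import gen_plate, random_protein


class TestEnumerateScanVariants:
    def test_two_constructs_per_position(self):
        prot = ProteinSequence(random_protein(1200, 0))
        variants = enumerate_scan_variants(prot, 575, 1054)
        assert len(variants) == 2 * (1054 - 575 + 1)
        assert len({v.position for v in variants}) == 1054 - 575 + 1

    def test_single_position(self):
        prot = ProteinSequence("MKVLRG")
        variants = enumerate_scan_variants(prot, 3, 3)
        assert len(variants) == 2
        assert {v.substituted_aa for v in variants} == {"R", "G"}

    def test_wt_controls_by_exhaustive_enumeration(self):
        # brute force: every position whose residue is R or G yields
        # exactly one construct that is a wild-type control
        seq = "MRGA"
        prot = ProteinSequence(seq)
        variants = enumerate_scan_variants(prot, 1, 4)
        assert len(variants) == 8
        expected_controls = sum(1 for aa in seq if aa in "RG")
        assert sum(v.is_wt_control for v in variants) == expected_controls

    def test_range_outside_sequence(self):
        prot = ProteinSequence("MKVL")
        with pytest.raises(RangeError):
            enumerate_scan_variants(prot, 2, 5)


class TestDepletionRatio:
    def test_identity_and_forced_cases(self):
        assert depletion_ratio(100, 100, 100, 100) == 1.0
        assert depletion_ratio(200, 100, 100, 100) == 2.0

    def test_matches_formula_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g_nt, r_nt, g_t, r_t = rng.uniform(10, 5000, size=4)
            expected = (g_nt / r_nt) / (g_t / r_t)
            assert depletion_ratio(g_nt, r_nt, g_t, r_t) == \
                pytest.approx(expected, rel=1e-12)

    def test_nonpositive_fluorescence_rejected(self):
        with pytest.raises(UndefinedRatioError):
            depletion_ratio(100, 0, 100, 100)


class TestPlateStats:
    def test_constant_controls(self):
        stats = plate_control_stats({"a": [1, 1], "b": [1, 1]})
        assert stats.mu_p == 1.0 and stats.sigma_p == 0.0

    def test_two_point_population_sd(self):
        stats = plate_control_stats({"a": [0.8], "b": [1.2]})
        assert stats.mu_p == pytest.approx(1.0)
        assert stats.sigma_p == pytest.approx(0.2)

    def test_parameter_recovery_on_synthetic_plate(self):
        rng = np.random.default_rng(1)
        controls = {f"w{i}": list(rng.normal(1.0, 0.1, size=3))
                    for i in range(40)}
        stats = plate_control_stats(controls)
        assert stats.mu_p == pytest.approx(1.0, abs=0.03)
        assert stats.sigma_p == pytest.approx(0.1, abs=0.03)

    def test_requires_controls(self):
        with pytest.raises(MissingControlsError):
            plate_control_stats({"a": [1.0]})


class TestZScore:
    def test_forced_values(self):
        stats = plate_control_stats({"a": [0.9] * 4, "b": [1.1] * 4})
        assert variant_zscore(stats.mu_p, stats) == 0.0
        # mean ratio = mu + sigma with 4 replicates -> Z = 2
        assert variant_zscore(stats.mu_p + stats.sigma_p, stats) == \
            pytest.approx(2.0)

    def test_matches_straight_line_chain_on_random_plates(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ctrl = rng.uniform(0.5, 1.5, size=(5, 3))
            var = rng.uniform(0.5, 3.0, size=3)
            stats = plate_control_stats(
                {f"w{i}": list(ctrl[i]) for i in range(5)})
            got = variant_zscore(float(np.mean(var)), stats)
            assert got == pytest.approx(zscore_chain(ctrl, var), rel=1e-9)

    def test_degenerate_plate(self):
        stats = plate_control_stats({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        with pytest.raises(DegeneratePlateError):
            variant_zscore(1.5, stats)


class TestQcAndHits:
    def test_clean_replicates_pass(self):
        ok, cv = qc_filter([1.0, 1.0, 1.0], [100, 100, 100])
        assert ok and cv == 0.0

    def test_rfu_floor(self):
        ok, _ = qc_filter([1.0, 1.0, 1.0], [100, 59, 100])
        assert not ok

    def test_cv_bound_against_hand_computed_cv(self):
        ratios = [1.0, 1.5]
        arr = np.array(ratios)
        cv_expected = 100 * arr.std(ddof=0) / arr.mean()   # ~28.3%
        ok, cv = qc_filter(ratios, [100, 100])
        assert cv == pytest.approx(cv_expected)
        assert not ok

    def test_hit_threshold(self):
        def res(vid, z):
            return DepletionResult(vid, "P", "GFP1", [1], 1, 0, True, z)
        assert call_hits([res("a", 1.9), res("a", 1.9)]) == set()
        assert call_hits([res("b", 2.1), res("b", 0.0)]) == {"b"}

    def test_planted_depleters_recovered_on_synthetic_plate(self):
        records, truth = gen_plate(n_variants=200, n_wt_controls=20,
                                   hit_fraction=0.05, hit_effect=3.0,
                                   noise_cv=5.0, seed=7)
        res = analyze_screen(records, set(truth.planted["wt_controls"]))
        called = set(res[res.hit].variant_id) - set(
            truth.planted["wt_controls"])
        planted = set(truth.planted["hits"])
        assert planted <= called                     # full recall
        nulls = set(res.variant_id) - planted - set(
            truth.planted["wt_controls"])
        fp = len(called - planted) / len(nulls)
        assert fp <= 0.10                            # near-nominal FPR


def test_control_zscores_center_on_zero():
    records, truth = gen_plate(n_variants=50, n_wt_controls=25,
                               hit_fraction=0.0, seed=11)
    res = analyze_screen(records, set(truth.planted["wt_controls"]))
    ctrl_z = res[res.is_wt_control & res.qc_pass].z_score
    assert abs(ctrl_z.mean()) < 3 / np.sqrt(25)
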