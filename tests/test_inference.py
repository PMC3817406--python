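from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import colsen as cs
from colsen.inference import (
    InferenceError,
    TestConfig,
    bootstrap_excess_deficit,
    bootstrap_group_test,
    fisher_combine,
    group_effect,
)


def enumeration_oracle(evolved, control, threshold, direction="sensitivity"):
    """Independent full enumeration of all joint with-replacement resamples."""
    evolved, control = list(evolved), list(control)
    hits = total = 0
    for ci in product(range(len(control)), repeat=len(control)):
        cm = float(np.mean([control[i] for i in ci]))
        for ei in product(range(len(evolved)), repeat=len(evolved)):
            em = float(np.mean([evolved[i] for i in ei]))
            d = (cm - em) / cm
            total += 1
            if direction == "sensitivity":
                hits += d < threshold
            else:
                hits += d > -threshold
    return hits / total


class TestGroupEffect:
    def test_identity_is_zero(self):
        assert group_effect([1.0, 1.0], [1.0, 1.0]) == 0.0

    def test_half_growth(self):
        assert group_effect([0.5, 0.5], [1.0, 1.0]) == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        assert group_effect([0.6, 0.6], [1.0, 0.8]) == pytest.approx((0.9 - 0.6) / 0.9)

    def test_zero_control_mean_untestable(self):
        assert np.isnan(group_effect([0.5, 0.5], [0.0, 0.0]))


class TestBootstrap:
    def test_exhaustive_forced_deficit(self):
        """Controls (1,1), evolved (0.8,0.6): every resampled deficit >= 0.2 > 0.1."""
        res = bootstrap_group_test(
            [0.8, 0.6], [1.0, 1.0], TestConfig(), "sensitivity", method="exhaustive"
        )
        assert res.pvalue == 0.0
        assert res.n_resamples == 16
        assert res.effect == pytest.approx(0.3)

    def test_null_identity_p_near_one(self):
        res = bootstrap_group_test(
            [1.0, 1.0, 1.0], [1.0, 1.0, 1.0], TestConfig(n_bootstrap=500, seed=1)
        )
        assert res.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", ["sensitivity", "resistance"])
    @pytest.mark.parametrize(
        "evolved,control",
        [
            ([0.6, 0.9, 0.8], [1.0, 1.1, 0.9]),
            ([1.2, 1.4, 1.0], [1.0, 0.9, 1.1]),
            ([0.95, 1.0, 1.05], [1.0, 1.0, 1.0]),
        ],
    )
    def test_monte_carlo_matches_enumeration(self, direction, evolved, control):
        """MC p within 3 binomial SE of the exhaustive p on size-3 groups."""
        cfg = TestConfig(n_bootstrap=20_000, seed=7)
        exact = enumeration_oracle(evolved, control, cfg.effect_threshold, direction)
        mc = bootstrap_group_test(evolved, control, cfg, direction).pvalue
        se = np.sqrt(max(exact * (1 - exact), 1e-6) / cfg.n_bootstrap)
        assert abs(mc - exact) <= 3 * se + 2 / cfg.n_bootstrap

    def test_exhaustive_agrees_with_independent_oracle(self):
        evolved, control = [0.7, 0.85, 1.0], [1.0, 0.95, 1.05]
        cfg = TestConfig()
        got = bootstrap_group_test(evolved, control, cfg, method="exhaustive").pvalue
        want = enumeration_oracle(evolved, control, cfg.effect_threshold)
        assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_in_evidence(self):
        """Scaling evolved down (same seed) never increases the sensitivity p."""
        control = [1.0, 0.95, 1.05, 1.0, 0.9, 1.1, 1.0, 1.02, 0.98, 1.0]
        rng_vals = np.linspace(0.95, 1.05, 10)
        last = 1.1
        for scale in (1.0, 0.9, 0.8, 0.6, 0.4):
            cfg = TestConfig(n_bootstrap=4000, seed=11)
            p = bootstrap_group_test(rng_vals * scale, control, cfg).pvalue
            assert p <= last + 1e-12
            last = p

    def test_symmetry_swapping_groups(self):
        """Swapping group labels turns a sensitivity call into resistance."""
        cfg = TestConfig(n_bootstrap=3000, seed=3)
        strong, weak = [1.0, 1.05, 0.95], [0.5, 0.55, 0.45]
        p_sens = bootstrap_group_test(weak, strong, cfg, "sensitivity").pvalue
        p_res = bootstrap_group_test(strong, weak, cfg, "resistance").pvalue
        assert p_sens < 0.05
        assert p_res < 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(InferenceError):
            bootstrap_group_test([1.0], [1.0, 1.0], TestConfig())

    def test_exhaustive_size_limit(self):
        with pytest.raises(InferenceError):
            bootstrap_group_test(np.ones(5), np.ones(5), TestConfig(), method="exhaustive")

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(0.05, 2.0), min_size=2, max_size=8),
        st.lists(st.floats(0.05, 2.0), min_size=2, max_size=8),
        st.integers(0, 10_000),
    )
    def test_pvalue_in_unit_interval(self, evolved, control, seed):
        cfg = TestConfig(n_bootstrap=200, seed=seed)
        for direction in ("sensitivity", "resistance"):
            p = bootstrap_group_test(evolved, control, cfg, direction).pvalue
            assert 0 < p <= 1


class TestFisherCombine:
    def test_no_evidence(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.5, 0.04, 0.9):
            assert fisher_combine([p]) == pytest.approx(p, abs=1e-12)

    def test_matches_chi_square_closed_form(self):
        """(0.05, 0.05): chi2 = -2(ln .05 + ln .05) = 11.983, df=4, p ~ 0.0175."""
        stat = -2 * (np.log(0.05) + np.log(0.05))
        expected = float(sps.chi2.sf(stat, 4))
        assert stat == pytest.approx(11.9829, abs=1e-3)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.0175, abs=5e-4)

    def test_zero_requires_floor(self):
        with pytest.raises(InferenceError):
            fisher_combine([0.0, 0.5])
        floored = fisher_combine([0.0, 0.5], zero_floor=1e-4)
        assert 0 < floored < 0.01

    def test_invalid_pvalues(self):
        with pytest.raises(InferenceError):
            fisher_combine([1.2])
        with pytest.raises(InferenceError):
            fisher_combine([])


class TestCostAdjustment:
    def test_no_cost_delta_equals_effect(self):
        ed, cd = np.full(4, 0.6), np.full(4, 1.0)
        ef, cf = np.full(4, 1.0), np.full(4, 1.0)
        res = bootstrap_excess_deficit(ed, cd, ef, cf, TestConfig(n_bootstrap=200, seed=0))
        assert res.effect == pytest.approx(0.4)
        assert res.pvalue < 0.01

    def test_pure_cost_yields_null(self):
        """Equal deficit with and without drug: excess deficit is zero."""
        ed, cd = np.full(4, 0.6), np.full(4, 1.0)
        res = bootstrap_excess_deficit(ed, cd, ed, cd, TestConfig(n_bootstrap=200, seed=0))
        assert res.effect == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_partial_cost_arithmetic(self):
        ed, cd = np.full(3, 0.5), np.full(3, 1.0)
        ef, cf = np.full(3, 0.8), np.full(3, 1.0)
        res = bootstrap_excess_deficit(ed, cd, ef, cf, TestConfig(n_bootstrap=100, seed=0))
        assert res.effect == pytest.approx(0.5 - 0.2)

    def test_misaligned_groups_rejected(self):
        with pytest.raises(InferenceError):
            bootstrap_excess_deficit([1, 1], [1, 1], [1, 1, 1], [1, 1], TestConfig())


class TestInferMatrix:
    def test_planted_effect_called(self, small_design, planted_pipeline):
        _, _, fitness, report = planted_pipeline
        calls = cs.infer_matrix(fitness, report, small_design, TestConfig(n_bootstrap=2000, seed=5))
        call = calls.set_index(["A", "B"])
        assert call.loc[("AMK", "TET"), "classification"] == "collateral_sensitivity"
        assert call.loc[("AMK", "TET"), "effect"] == pytest.approx(0.5, abs=0.12)
        assert (calls["classification"] != "untestable").all()

    def test_all_runs_excluded_untestable(self, small_design, planted_pipeline):
        _, _, fitness, report = planted_pipeline
        t = report.table.copy()
        t.loc[t["condition"] == "TET", "status"] = "excluded"
        t.loc[t["condition"] == "TET", "reasons"] = "overdose"
        calls = cs.infer_matrix(fitness, cs.QcReport(t), small_design, TestConfig(n_bootstrap=200, seed=5))
        sub = calls[calls["B"] == "TET"]
        assert (sub["classification"] == "untestable").all()

    def test_deterministic_given_seed(self, small_design, planted_pipeline):
        _, _, fitness, report = planted_pipeline
        cfg = TestConfig(n_bootstrap=500, seed=9)
        a = cs.infer_matrix(fitness, report, small_design, cfg)
        b = cs.infer_matrix(fitness, report, small_design, cfg)
        assert a.equals(b)

    def test_bh_correction_never_adds_calls(self, small_design, planted_pipeline):
        _, _, fitness, report = planted_pipeline
        raw = cs.infer_matrix(fitness, report, small_design, TestConfig(n_bootstrap=500, seed=9))
        adj = cs.infer_matrix(
            fitness, report, small_design, TestConfig(n_bootstrap=500, seed=9, mtc="bh_fdr")
        )
        raw_calls = set(map(tuple, raw[raw["classification"] == "collateral_sensitivity"][["A", "B"]].to_numpy()))
        adj_calls = set(map(tuple, adj[adj["classification"] == "collateral_sensitivity"][["A", "B"]].to_numpy()))
        assert adj_calls <= raw_calls
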