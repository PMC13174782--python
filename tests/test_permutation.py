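"""Tests for the hemisphere-swap permutation inference."""

import numpy as np
import pytest

from latvar import (compute_vi, exact_permutation_vi, permutation_test_vi,
                    permute_vi_once, vi_family_analysis, vi_results_frame)
from latvar.indices import FAMILY_SIZE


class _FixedRng:
    """Stub RNG returning a constant uniform value (forces swap patterns)."""

    def __init__(self, value):
        self.value = value

    def random(self, size):
        return np.full(size, self.value)


PAIRS = np.array([[1.0, 5.0], [2.0, 3.0], [7.0, 4.0], [2.5, 2.5]])


class TestPermuteOnce:
    def test_no_swap_reproduces_observed(self):
        obs = compute_vi(PAIRS[:, 0], PAIRS[:, 1]).vi
        assert permute_vi_once(PAIRS, _FixedRng(0.9)) == pytest.approx(obs)

    def test_full_swap_flips_sign(self):
        obs = compute_vi(PAIRS[:, 0], PAIRS[:, 1]).vi
        assert permute_vi_once(PAIRS, _FixedRng(0.1)) == pytest.approx(-obs)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            permute_vi_once(PAIRS[:1], _FixedRng(0.1))

    def test_null_symmetric_under_exchangeability(self, rng):
        pairs = rng.lognormal(0, 0.5, size=(40, 2))
        draws = np.array([permute_vi_once(pairs, rng) for _ in range(4000)])
        assert abs(draws.mean()) < 4 * draws.std() / np.sqrt(draws.size)


class TestExactEnumeration:
    def test_hand_enumeration_four_patterns(self):
        # pairs (1,5),(2,3): MADs per pattern give |VI| {1/3, .2, .2, 1/3};
        # observed 1/3 -> p = 2/4
        pairs = np.array([[1.0, 5.0], [2.0, 3.0]])
        assert exact_permutation_vi(pairs) == pytest.approx(0.5)

    def test_degenerate_symmetric_pairs_give_p_one(self):
        # pairs (1,3),(2,2): every swap pattern yields VI = 0 = observed
        pairs = np.array([[1.0, 3.0], [2.0, 2.0]])
        assert exact_permutation_vi(pairs) == pytest.approx(1.0)

    def test_single_pair_p_one(self):
        assert exact_permutation_vi(np.array([[1.0, 2.0]])) == 1.0

    def test_refuses_large_n(self):
        pairs = np.tile([[1.0, 2.0]], (17, 1))
        with pytest.raises(ValueError):
            exact_permutation_vi(pairs)

    def test_hemisphere_relabelling_preserves_p(self, rng):
        pairs = rng.lognormal(0, 0.7, size=(8, 2))
        assert exact_permutation_vi(pairs) == pytest.approx(
            exact_permutation_vi(pairs[:, ::-1]))


class TestMonteCarloTest:
    def test_identical_hemispheres_p_one(self):
        vals = np.array([1.0, 4.0, 2.0, 9.0, 3.0])
        res = permutation_test_vi(np.column_stack([vals, vals]), n_perm=500,
                                  seed=0)
        assert res.p_value == 1.0
        assert res.observation.vi == 0.0

    @pytest.mark.parametrize("n_pairs", range(3, 13))
    def test_matches_exact_enumeration(self, n_pairs, rng):
        pairs = rng.lognormal(0, 0.6, size=(n_pairs, 2))
        p_exact = exact_permutation_vi(pairs)
        res = permutation_test_vi(pairs, n_perm=5000, seed=7)
        p_mc = 0.0 if res.p_is_floor else res.p_value
        se = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(p_mc - p_exact) <= max(3 * se, 1e-12)

    def test_deterministic_for_fixed_seed(self, rng):
        pairs = rng.lognormal(0, 0.5, size=(30, 2))
        a = permutation_test_vi(pairs, n_perm=2000, seed=42)
        b = permutation_test_vi(pairs, n_perm=2000, seed=42)
        assert a.p_value == b.p_value
        assert a.null_quantiles == b.null_quantiles

    def test_floor_reported_when_no_permutation_as_extreme(self):
        left = 1000.0 + 0.001 * np.arange(40)   # nearly constant left
        right = 100.0 * (1.0 + np.arange(40))   # hugely dispersed right
        res = permutation_test_vi(np.column_stack([left, right]), n_perm=200,
                                  seed=3)
        assert res.p_is_floor
        assert res.p_value == pytest.approx(1 / 200)

    def test_smoothed_estimator(self):
        left = 1000.0 + 0.001 * np.arange(40)
        right = 100.0 * (1.0 + np.arange(40))
        res = permutation_test_vi(np.column_stack([left, right]), n_perm=200,
                                  seed=3, estimator="smoothed")
        assert res.p_value == pytest.approx(1 / 201)
        assert not res.p_is_floor


class TestFamilyAnalysis:
    def test_complete_cohort_yields_24_results(self, scenario_cohort):
        results = vi_family_analysis(scenario_cohort, n_perm=200, seed=5)
        assert len(results) == FAMILY_SIZE
        assert not any(r.missing for r in results)
        frame = vi_results_frame(results)
        assert frame["tract"].value_counts()["ALL"] == 3
        assert frame["p_value"].between(0, 1).all()

    def test_deterministic_and_order_independent(self, scenario_cohort):
        a = vi_results_frame(vi_family_analysis(scenario_cohort, n_perm=200,
                                                seed=5))
        b = vi_results_frame(vi_family_analysis(scenario_cohort, n_perm=200,
                                                seed=5))
        assert a.equals(b)

    def test_missing_tract_reported_not_fatal(self, scenario_cohort):
        table = scenario_cohort.copy()
        sel = (table["tract"] == "UF") & (table["hemisphere"] == "L")
        table.loc[sel, "value"] = np.nan
        results = vi_family_analysis(table, n_perm=100, seed=5)
        assert len(results) == FAMILY_SIZE
        missing = {(r.observation.tract, r.observation.metric)
                   for r in results if r.missing}
        # the three UF tests and the three global tests lose their data
        assert {("UF", m) for m in ("HMOA", "TC", "VC")} <= missing
        assert {("ALL", m) for m in ("HMOA", "TC", "VC")} <= missing

    def test_significance_uses_family_corrected_alpha(self, scenario_cohort):
        results = vi_family_analysis(scenario_cohort, n_perm=400, seed=5)
        for r in results:
            assert r.alpha == pytest.approx(0.05 / 24)
            assert r.significant_bonferroni == (r.p_value < r.alpha)
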