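"""Tests for the truncated-Cauchy one-sample Bayes machinery."""

import math

import numpy as np
import pytest

from latvar import (DegenerateSampleError, PriorSpec, bayes_log_bf_mc,
                    bayes_one_sample_li, bayes_table, frequentist_cross_check,
                    jzs_bf10, jzs_prior, prior_robustness_sweep,
                    sample_size_stability)


def li_sample(mu, sd, n, seed):
    rng = np.random.default_rng(seed)
    return np.clip(mu + sd * rng.standard_normal(n), -1, 1)


class TestResultInvariants:
    def test_structure(self):
        x = li_sample(0.2, 0.2, 80, 1)
        res = bayes_one_sample_li(x, hdi=True)
        assert res.ci95[0] <= res.post_mean <= res.ci95[1]
        assert res.hdi95[0] <= res.post_mean <= res.hdi95[1]
        assert res.bf10 == pytest.approx(math.exp(res.log_ml_h1 - res.log_ml_h0))
        assert -1 <= res.post_mean <= 1
        assert res.post_sd > 0
        assert res.numerical_error < 1e-4

    @pytest.mark.parametrize("mu", [-0.25, -0.05, 0.1, 0.3])
    def test_posterior_mean_tracks_sample_sign(self, mu):
        x = li_sample(mu, 0.15, 100, 2)
        res = bayes_one_sample_li(x)
        assert np.sign(res.post_mean) == np.sign(x.mean())

    def test_mirrored_sample_same_bf(self):
        x = li_sample(0.2, 0.2, 60, 3)
        a = bayes_one_sample_li(x)
        b = bayes_one_sample_li(-x)
        assert a.log_bf10 == pytest.approx(b.log_bf10, abs=1e-9)
        assert a.post_mean == pytest.approx(-b.post_mean, abs=1e-9)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            bayes_one_sample_li([0.1, 0.2])           # too few
        with pytest.raises(ValueError):
            bayes_one_sample_li([0.1, 0.2, 1.5])       # outside [-1, 1]
        with pytest.raises(DegenerateSampleError):
            bayes_one_sample_li([0.3, 0.3, 0.3, 0.3])  # constant


class TestEvidenceBehaviour:
    def test_symmetric_sample_favours_null(self):
        x = 0.2 * np.random.default_rng(4).standard_normal(60)
        x = np.clip(x - x.mean() + 0.0, -1, 1)
        assert bayes_one_sample_li(x).bf10 < 1

    def test_vanishing_prior_scale_collapses_onto_null(self):
        x = li_sample(0.05, 0.2, 40, 5)
        res = bayes_one_sample_li(x, PriorSpec(scale=1e-6))
        assert res.bf10 == pytest.approx(1.0, rel=0.01)

    def test_large_t_gives_strong_evidence(self):
        x = li_sample(0.3, 0.2, 164, 6)
        assert bayes_one_sample_li(x).log_bf10 > math.log(1e3)


class TestCrossChecks:
    def test_monte_carlo_agreement(self):
        x = li_sample(0.15, 0.2, 50, 7)
        quad = bayes_one_sample_li(x).log_bf10
        mc = bayes_log_bf_mc(x, n_draws=100_000, seed=0)
        assert abs(quad - mc) < 0.02

    @pytest.mark.parametrize("n,t", [(10, 1.0), (50, 2.5), (164, 4.0)])
    def test_jzs_limit_matches_oracle(self, n, t):
        rng = np.random.default_rng(8)
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
        x = t * 0.1 / math.sqrt(n) + 0.1 * z
        ours = bayes_one_sample_li(x, jzs_prior()).bf10
        assert ours == pytest.approx(jzs_bf10(t, n), rel=0.02)

    def test_frequentist_t(self):
        t, p = frequentist_cross_check([0.1, 0.2, 0.3])
        assert t == pytest.approx(3.464, abs=5e-4)
        t2, p2 = frequentist_cross_check([-0.1, -0.2, -0.3])
        assert t2 == pytest.approx(-t)
        assert p2 == pytest.approx(p)
        t0, p0 = frequentist_cross_check([-0.2, -0.1, 0.0, 0.1, 0.2])
        assert t0 == pytest.approx(0.0, abs=1e-12)
        assert p0 == pytest.approx(1.0)
        with pytest.raises(DegenerateSampleError):
            frequentist_cross_check([0.5, 0.5, 0.5])


class TestPriorSweep:
    def test_narrower_prior_pulls_bf_towards_one(self):
        x = li_sample(0.25, 0.2, 80, 9)
        sweep = prior_robustness_sweep(x, [0.01, 0.707])
        log_bf = dict(zip(sweep["scale"], sweep["log_bf10"]))
        assert abs(log_bf[0.01]) < abs(log_bf[0.707])

    def test_direction_stable_and_mean_robust_on_strong_sample(self):
        x = li_sample(0.2, 0.2, 164, 10)
        sweep = prior_robustness_sweep(x, np.geomspace(0.01, 1.0, 7))
        assert sweep["direction_stable"].all()
        assert sweep["post_mean"].max() - sweep["post_mean"].min() \
            < sweep["post_sd"].min()

    def test_deterministic(self):
        x = li_sample(0.1, 0.2, 30, 11)
        a = prior_robustness_sweep(x, [0.05, 0.5])
        b = prior_robustness_sweep(x, [0.05, 0.5])
        assert a.equals(b)


class TestStability:
    def test_reps_one_bit_identical(self):
        res1 = sample_size_stability((0.3, 0.2), [20], reps=1, seed=3)
        res2 = sample_size_stability((0.3, 0.2), [20], reps=1, seed=3)
        assert res1.log10_bf[0, 0] == res2.log10_bf[0, 0]

    def test_null_truth_accumulates_null_evidence(self):
        res = sample_size_stability((0.0, 0.2), [20, 164], reps=12, seed=4)
        assert (res.summary["prop_h1_conclusive"] <= 0.2).all()
        s = res.summary.set_index("n")
        assert s.loc[164, "prop_h0_conclusive"] >= s.loc[20, "prop_h0_conclusive"]

    def test_effect_truth_monotone_in_n(self):
        res = sample_size_stability((0.3, 0.2), [10, 40, 164], reps=10, seed=5)
        props = res.summary["prop_h1_conclusive"].to_numpy()
        assert (np.diff(props) >= 0).all()
        assert props[-1] >= 0.9

    def test_generator_spec_source(self):
        from latvar import TractMetricSpec

        spec = TractMetricSpec(target_li=0.3, base_location=1000.0,
                               base_scale=0.4, family="lognormal")
        res = sample_size_stability(spec, [40, 164], reps=6, seed=7)
        assert res.summary["prop_h1_conclusive"].iloc[-1] >= 0.9
        rerun = sample_size_stability(spec, [40, 164], reps=6, seed=7)
        assert np.array_equal(res.log10_bf, rerun.log10_bf)

    def test_subsampling_bounds_checked(self):
        with pytest.raises(ValueError):
            sample_size_stability(li_sample(0.1, 0.2, 30, 6), [50], reps=2)


def test_bayes_table_shapes(scenario_li):
    table = bayes_table(scenario_li)
    assert len(table) == 21
    assert {"tract", "metric", "est_mean", "est_error", "ci_low", "ci_high",
            "bf10"} <= set(table.columns)
    assert (table["est_error"] > 0).all()
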