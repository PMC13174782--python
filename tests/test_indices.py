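"""Unit and property tests for the deterministic asymmetry indices."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from latvar import (FEATURES, METRICS, TRACTS, UndefinedIndexError,
                    assemble_li_matrix, bonferroni_alpha, compute_li,
                    compute_mad, compute_vi, hemisphere_average,
                    li_matrix_to_long, success_percentage)


def brute_force_mad(values):
    """Independent oracle: sorted-list median of absolute deviations."""
    med = statistics.median(sorted(values))
    return statistics.median(sorted(abs(v - med) for v in values))


def make_cohort(values):
    """Long table from {(participant, tract, metric, hemisphere): value}."""
    rows = [{"participant_id": p, "tract": t, "metric": m, "hemisphere": h,
             "value": v} for (p, t, m, h), v in values.items()]
    return pd.DataFrame(rows)


def full_cohort(n, rng, missing=()):
    vals = {}
    for i in range(n):
        for t in TRACTS:
            for m in METRICS:
                for h in ("L", "R"):
                    key = (f"P{i:02d}", t, m, h)
                    vals[key] = (np.nan if (f"P{i:02d}", t, h) in missing
                                 else float(rng.uniform(1, 10)))
    return make_cohort(vals)


class TestComputeLi:
    @pytest.mark.parametrize("left,right,expected", [
        (5.0, 5.0, 0.0),
        (2.0, 0.0, -1.0),
        (0.0, 2.0, 1.0),
        (100.0, 150.0, 0.2),
    ])
    def test_examples(self, left, right, expected):
        assert compute_li(left, right) == pytest.approx(expected)

    def test_zero_pair_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_li(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_li(-1.0, 2.0)

    @given(a=st.floats(0.01, 1e6), b=st.floats(0.01, 1e6),
           c=st.floats(0.01, 1e3))
    def test_antisymmetry_scale_invariance_bounds(self, a, b, c):
        li = compute_li(a, b)
        assert -1.0 <= li <= 1.0
        assert compute_li(b, a) == pytest.approx(-li, abs=1e-12)
        assert compute_li(c * a, c * b) == pytest.approx(li, rel=1e-9)


class TestComputeMad:
    @pytest.mark.parametrize("values,expected", [
        ([7, 7, 7], 0.0),
        ([1, 2, 3, 4, 5], 1.0),
        ([1, 1, 1, 100], 0.0),  # even-length median of |devs| {0,0,0,99}
    ])
    def test_examples(self, values, expected):
        assert compute_mad(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_mad([])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=25))
    def test_matches_brute_force_oracle(self, values):
        assert compute_mad(values) == pytest.approx(brute_force_mad(values))

    @given(values=st.lists(st.floats(-100, 100), min_size=2, max_size=20),
           shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
    def test_translation_invariant_scale_equivariant(self, values, shift, scale):
        x = np.asarray(values)
        mad = compute_mad(x)
        assert compute_mad(x + shift) == pytest.approx(mad, abs=1e-8)
        assert compute_mad(scale * x) == pytest.approx(scale * mad, rel=1e-9, abs=1e-12)


class TestComputeVi:
    def test_identical_hemispheres_give_zero(self):
        vals = [1.0, 4.0, 2.0, 9.0]
        assert compute_vi(vals, vals).vi == 0.0

    def test_constructed_mad_ratio(self):
        # MAD_left = 1 ([0,1,2]), MAD_right = 2 ([0,2,4]) -> VI = 1/3
        obs = compute_vi([0, 1, 2], [0, 2, 4])
        assert obs.vi == pytest.approx(1 / 3)
        assert obs.mad_left == 1.0 and obs.mad_right == 2.0

    def test_more_dispersed_left_is_negative(self):
        obs = compute_vi([0, 10, 20, 30], [14, 15, 16, 17])
        assert obs.vi == pytest.approx((1 - 10) / 11)
        assert obs.vi < 0

    def test_both_constant_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_vi([3, 3, 3], [5, 5, 5])

    @given(st.lists(st.floats(0.1, 100), min_size=3, max_size=15),
           st.lists(st.floats(0.1, 100), min_size=3, max_size=15))
    def test_swap_antisymmetry_and_bounds(self, left, right):
        left, right = left[: len(right)], right[: len(left)]
        try:
            obs = compute_vi(left, right)
        except UndefinedIndexError:
            return
        assert -1.0 <= obs.vi <= 1.0
        assert compute_vi(right, left).vi == pytest.approx(-obs.vi, abs=1e-12)
        assert np.sign(obs.vi) == np.sign(obs.mad_right - obs.mad_left)

    @given(scale=st.floats(0.01, 1000))
    def test_scale_invariance(self, scale):
        left, right = [1.0, 3.0, 8.0, 2.0], [2.0, 2.5, 9.0, 1.0]
        base = compute_vi(left, right).vi
        scaled = compute_vi([scale * v for v in left],
                            [scale * v for v in right]).vi
        assert scaled == pytest.approx(base, abs=1e-10)


class TestScalars:
    def test_success_percentage(self):
        assert success_percentage(172, 172) == 100.0
        assert success_percentage(164, 172) == pytest.approx(95.35, abs=0.005)
        assert success_percentage(0, 10) == 0.0
        with pytest.raises(ValueError):
            success_percentage(1, 0)

    def test_bonferroni(self):
        assert round(bonferroni_alpha(0.05, 24), 4) == 0.0021
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.05, 21) == pytest.approx(0.00238, abs=5e-6)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestHemisphereAverage:
    def test_mean_across_tracts(self, rng):
        vals = {}
        for j, t in enumerate(TRACTS):
            for m in METRICS:
                vals[("P1", t, m, "L")] = float(j + 1)  # 1..7 -> mean 4
                vals[("P1", t, m, "R")] = 2.0 * (j + 1)
        left, right, ids = hemisphere_average(make_cohort(vals), "TC")
        assert ids == ["P1"]
        assert left[0] == pytest.approx(4.0)
        assert right[0] == pytest.approx(8.0)

    def test_incomplete_participants_dropped(self, rng):
        table = full_cohort(4, rng, missing={("P00", "UF", "L")})
        left, right, ids = hemisphere_average(table, "HMOA")
        assert ids == ["P01", "P02", "P03"]

    def test_no_complete_participants_errors(self, rng):
        table = full_cohort(2, rng, missing={("P00", "UF", "L"),
                                             ("P01", "ILF", "R")})
        with pytest.raises(ValueError):
            hemisphere_average(table, "VC")


class TestAssembleLiMatrix:
    def test_complete_cohort_shape(self, rng):
        mat = assemble_li_matrix(full_cohort(5, rng))
        assert mat.shape == (5, 21)
        assert list(mat.columns) == list(FEATURES)
        assert (mat.abs() <= 1).all().all()

    def test_listwise_versus_per_feature(self, rng):
        missing = {("P00", "UF", "L"), ("P01", "FAT", "R")}
        table = full_cohort(10, rng, missing=missing)
        listwise = assemble_li_matrix(table, "listwise")
        per_feature = assemble_li_matrix(table, "per_feature")
        assert listwise.shape[0] == 8
        assert per_feature.shape[0] == 10
        assert per_feature.isna().sum().sum() == 6  # 2 tracts x 3 metrics

    def test_zero_denominator_recorded_missing(self, rng):
        table = full_cohort(3, rng)
        sel = (table["participant_id"] == "P00") & (table["tract"] == "AFl") \
            & (table["metric"] == "TC")
        table.loc[sel, "value"] = 0.0
        with pytest.warns(RuntimeWarning, match="zero-denominator"):
            mat = assemble_li_matrix(table, "per_feature")
        assert np.isnan(mat.loc["P00", ("AFl", "TC")])

    def test_all_excluded_errors(self, rng):
        table = full_cohort(2, rng, missing={("P00", "UF", "L"),
                                             ("P01", "UF", "L")})
        with pytest.raises(ValueError):
            assemble_li_matrix(table, "listwise")

    def test_long_form_round_trip(self, rng):
        mat = assemble_li_matrix(full_cohort(4, rng))
        long = li_matrix_to_long(mat)
        assert set(long.columns) == {"participant_id", "tract", "metric", "li"}
        assert len(long) == 4 * 21
        back = long.pivot(index="participant_id", columns=["tract", "metric"],
                          values="li")[list(mat.columns)]
        assert np.allclose(back.to_numpy(), mat.to_numpy())
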