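import dataclasses

import numpy as np
import pandas as pd
import pytest

from wmtempo.bias import (
    attraction_test,
    compute_bias_curve,
    demean_signed_errors,
    equated_bias,
    integrate_auc,
)
from wmtempo.circular import signed_diff
from wmtempo.cohort import DesignSpec, GenerativeParams, generate_cohort
from wmtempo.errors import DegenerateVarianceError, InsufficientDataError


@pytest.fixture(scope="module")
def biased_cohort():
    spec = DesignSpec(n_participants=10, rng_seed=31)
    params = GenerativeParams(bias_amplitude=2.0, p_swap=0.0, p_guess=0.0, kappa_base=30.0,
                              contamination_rates={})
    return generate_cohort(spec, params)


class TestDemean:
    def test_constant_offset_removed(self, clean_cohort):
        shifted = clean_cohort.copy()
        from wmtempo.circular import wrap_orientation

        shifted["report_angle"] = wrap_orientation(shifted["target_angle"] + 3.0)
        out = demean_signed_errors(shifted)
        np.testing.assert_allclose(out["demeaned_error"], 0.0, atol=1e-9)

    def test_per_participant_sum_zero(self, small_cohort):
        out = demean_signed_errors(small_cohort)
        sums = out.groupby("participant_id")["demeaned_error"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_balanced_bias_demeaning_nearly_noop(self, biased_cohort):
        out = demean_signed_errors(biased_cohort)
        means = out.groupby("participant_id")["signed_error"].mean()
        assert means.abs().max() < 1.0  # balanced deltas: little to remove

    def test_delta_only_on_interference_trials(self, small_cohort):
        out = demean_signed_errors(small_cohort)
        assert np.isfinite(out["delta"]).sum() == small_cohort["interference_present"].sum()


class TestCurve:
    def test_constant_error_flat_curve(self):
        rng = np.random.default_rng(0)
        deltas = rng.uniform(-89, 90, 500)
        curve = compute_bias_curve(np.full(500, 2.5), deltas)
        np.testing.assert_allclose(curve.values, 2.5)
        assert len(curve.centers) == 36

    def test_window_counts_and_wrap(self):
        # single trial at delta = 88: windows centred near +90 AND near -90
        # (circular wrap) must contain it
        curve = compute_bias_curve([1.0], [88.0])
        assert set(curve.centers) >= {85.0, -90.0, 70.0}
        assert -65.0 not in curve.centers

    def test_smoothed_sine_oracle(self, biased_cohort):
        out = demean_signed_errors(biased_cohort)
        sub = out[np.isfinite(out["delta"])]
        curve = compute_bias_curve(sub["demeaned_error"], sub["delta"])
        # oracle: average the true bias A*sin(2d) over each 45-deg window of
        # the realised delta values
        d = sub["delta"].to_numpy()
        truth = []
        from wmtempo.circular import abs_dev

        for c in curve.centers:
            m = abs_dev(d, c) <= 22.5
            truth.append(2.0 * np.sin(2.0 * np.deg2rad(d[m])).mean())
        r = np.corrcoef(curve.values, truth)[0, 1]
        assert r > 0.95

    def test_null_generator_small_values(self):
        spec = DesignSpec(n_participants=10, rng_seed=32)
        params = GenerativeParams(bias_amplitude=0.0, p_swap=0.0, p_guess=0.0, kappa_base=30.0,
                                  contamination_rates={})
        cohort = generate_cohort(spec, params)
        out = demean_signed_errors(cohort)
        sub = out[np.isfinite(out["delta"])]
        curve = compute_bias_curve(sub["demeaned_error"], sub["delta"])
        assert np.abs(curve.values).max() < 1.0

    def test_degenerate_window_equals_raw_bins(self):
        rng = np.random.default_rng(1)
        deltas = rng.choice(np.arange(-90, 90, 5.0), size=400)
        errors = rng.normal(size=400)
        curve = compute_bias_curve(errors, deltas, step=5.0, width=5.0)
        for c, v in zip(curve.centers, curve.values):
            m = np.abs(signed_diff(deltas, c)) <= 2.5
            assert v == pytest.approx(errors[m].mean())

    def test_empty_input(self):
        with pytest.raises(InsufficientDataError):
            compute_bias_curve([], [])


class TestAuc:
    @staticmethod
    def _curve(values, centers=None):
        from wmtempo.bias import BiasCurve

        centers = np.arange(-90.0, 90.0, 5.0) if centers is None else np.asarray(centers)
        return BiasCurve(centers, np.asarray(values, dtype=float), np.ones(len(centers), dtype=int))

    def test_zero_curve(self):
        auc = integrate_auc(self._curve(np.zeros(36)))
        assert auc == (0.0, 0.0, 0.0)

    def test_odd_linear_curve(self):
        centers = np.arange(-85.0, 90.0, 5.0)  # symmetric grid
        auc = integrate_auc(self._curve(0.1 * centers, centers))
        assert auc.auc_pos > 0 > auc.auc_neg
        assert auc.auc_pos == pytest.approx(-auc.auc_neg)
        assert auc.attraction_stat > 0

    def test_one_sided_curve_rejected(self):
        centers = np.arange(-90.0, 0.0, 5.0)
        with pytest.raises(InsufficientDataError):
            integrate_auc(self._curve(np.ones(len(centers)), centers))

    def test_trapezoid_matches_oracle_smoothed_sine(self, biased_cohort):
        out = demean_signed_errors(biased_cohort)
        sub = out[np.isfinite(out["delta"])]
        curve = compute_bias_curve(sub["demeaned_error"], sub["delta"])
        auc = integrate_auc(curve)
        from wmtempo.circular import abs_dev

        d = sub["delta"].to_numpy()
        truth_vals = np.array(
            [2.0 * np.sin(2.0 * np.deg2rad(d[abs_dev(d, c) <= 22.5])).mean() for c in curve.centers]
        )
        neg, pos = curve.centers < 0, curve.centers > 0
        truth_stat = (
            np.trapezoid(truth_vals[pos], curve.centers[pos])
            - np.trapezoid(truth_vals[neg], curve.centers[neg])
        ) / 2.0
        assert auc.attraction_stat == pytest.approx(truth_stat, rel=0.10)


class TestEquatedBias:
    def test_null_generator_near_zero(self):
        spec = DesignSpec(n_participants=10, rng_seed=33)
        params = GenerativeParams(bias_amplitude=0.0, p_swap=0.0, p_guess=0.0, contamination_rates={})
        out = demean_signed_errors(generate_cohort(spec, params))
        eq = equated_bias(out)
        assert abs(eq["equated_bias"].mean()) < 0.3

    def test_positive_generator_matches_grid_average(self, biased_cohort):
        out = demean_signed_errors(biased_cohort)
        eq = equated_bias(out, cells=())
        d = out.loc[np.isfinite(out["delta"]), "delta"].to_numpy()
        truth = (
            2.0 * np.sin(2.0 * np.deg2rad(d[d > 0])).mean()
            - 2.0 * np.sin(2.0 * np.deg2rad(d[d < 0])).mean()
        ) / 2.0
        assert eq["equated_bias"].mean() == pytest.approx(truth, abs=0.4)

    def test_mirror_symmetry(self, biased_cohort):
        out = demean_signed_errors(biased_cohort)
        flipped = biased_cohort.copy()
        flipped["interference_angle"] = -flipped["interference_angle"]
        flipped["target_angle"] = -flipped["target_angle"]
        flipped["nonprobed_angle"] = -flipped["nonprobed_angle"]
        flipped["report_angle"] = -flipped["report_angle"]
        out2 = demean_signed_errors(flipped)
        a = equated_bias(out, cells=())["equated_bias"]
        b = equated_bias(out2, cells=())["equated_bias"]
        # exact up to the delta = +/-90 boundary atom, whose errors flip side
        assert abs(a.mean() - b.mean()) < 0.25
        np.testing.assert_allclose(a, b, atol=0.7)

    def test_negated_errors_flip_sign_exactly(self, biased_cohort):
        out = demean_signed_errors(biased_cohort).copy()
        a = equated_bias(out, cells=())["equated_bias"]
        flipped = out.copy()
        flipped["demeaned_error"] = -flipped["demeaned_error"]
        b = equated_bias(flipped, cells=())["equated_bias"]
        np.testing.assert_allclose(a, -b, atol=1e-12)
        sub = out[np.isfinite(out["delta"])]
        c1 = compute_bias_curve(sub["demeaned_error"], sub["delta"])
        c2 = compute_bias_curve(-sub["demeaned_error"], sub["delta"])
        assert integrate_auc(c1).attraction_stat == pytest.approx(-integrate_auc(c2).attraction_stat)

    def test_one_sided_cell_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": [0] * 5,
                "cond": ["a"] * 5,
                "demeaned_error": [1.0] * 5,
                "delta": [10.0, 20.0, 30.0, 40.0, 50.0],
            }
        )
        with pytest.raises(InsufficientDataError):
            equated_bias(df, cells=("cond",))


class TestAttractionTest:
    def test_all_zero(self):
        res = attraction_test([0.0, 1.0, -1.0, 0.0])
        assert res["t"] == pytest.approx(0.0)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            attraction_test([1.0, 1.0, 1.0, 1.0])

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            attraction_test([1.0])

    def test_power_under_positive_bias(self):
        # repeated small cohorts: a 2-degree attraction should be detected
        hits = 0
        for seed in range(5):
            spec = DesignSpec(n_participants=8, rng_seed=40 + seed)
            params = GenerativeParams(bias_amplitude=2.0, p_swap=0.0, p_guess=0.0, kappa_base=25.0,
                                      contamination_rates={})
            out = demean_signed_errors(generate_cohort(spec, params))
            eq = equated_bias(out, cells=())
            res = attraction_test(eq["equated_bias"])
            if res["t"] > 0 and res["p"] < 0.05:
                hits += 1
        assert hits >= 4
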