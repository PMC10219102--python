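"""Trace binning, normalization, double-logistic fitting and descriptors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import simpson

from fluxkin.fcs_io import KineticRecording
from fluxkin.kinetics import (
    KineticFit,
    PopulationTrace,
    bin_median_trace,
    derive_descriptors,
    descriptor_table,
    double_logistic,
    double_logistic_auc,
    fit_kinetic,
    normalize_trace,
)

TRUTH = (1.0, 2.0, 0.1, 30.0, 1.2, 0.02, 200.0)  # S H1 k1 m1 H2 k2 m2


def _recording(times, fluo):
    df = pd.DataFrame({"Time": times, "Fluo4": fluo})
    return KineticRecording(df, t_act=60.0, t_end=780.0, gap_seconds=0.0,
                            baseline_duration=60.0)


def _trace(t, y, counts=None, t_act=60.0):
    counts = np.full(len(t), 100) if counts is None else counts
    return PopulationTrace("p", np.asarray(t, float), np.asarray(y, float),
                           np.asarray(counts), t_act, 780.0,
                           medians_norm=np.asarray(y, float), baseline_stat=1.0)


class TestBinMedianTrace:
    def test_constant_signal(self):
        t = np.linspace(0, 780, 20_000)
        tr = bin_median_trace(_recording(t, np.full(len(t), 350.0)))
        assert np.allclose(tr.medians_raw, 350.0)
        assert np.all(np.diff(tr.bin_centers) > 0)

    def test_median_robust_to_outliers(self):
        # one 5 s bin holding values (1, 2, 100) plus dense later bins
        t = np.concatenate([[1.0, 2.0, 3.0], np.linspace(10, 780, 2000)])
        y = np.concatenate([[1.0, 2.0, 100.0], np.full(2000, 7.0)])
        tr = bin_median_trace(_recording(t, y), min_per_bin=3)
        assert tr.medians_raw[0] == pytest.approx(2.0)

    def test_medians_track_known_trajectory(self, rng):
        n_per_bin = 250
        edges = np.arange(0, 785, 5.0)
        times, values = [], []
        for lo in edges[:-1]:
            t = rng.uniform(lo, lo + 5, n_per_bin)
            f = double_logistic(t, *TRUTH)
            values.append(f * rng.lognormal(0.0, 0.05, n_per_bin))
            times.append(t)
        t = np.concatenate(times)
        tr = bin_median_trace(_recording(t, np.concatenate(values)))
        truth_at_centers = double_logistic(tr.bin_centers, *TRUTH)
        assert np.max(np.abs(tr.medians_raw / truth_at_centers - 1)) < 0.02

    def test_unfittable_when_all_bins_sparse(self):
        t = np.linspace(0, 780, 30)
        with pytest.raises(ValueError, match="unfittable"):
            bin_median_trace(_recording(t, np.ones(30)), min_per_bin=50)


class TestNormalizeTrace:
    def test_division_by_resting_level(self):
        t = np.array([10.0, 25, 40, 55, 100, 200])
        raw = np.array([200.0, 200, 200, 200, 400, 400])
        tr = PopulationTrace("p", t, raw, np.full(6, 50), 60.0, 780.0)
        out = normalize_trace(tr)
        assert out.baseline_stat == pytest.approx(200.0)
        np.testing.assert_allclose(out.medians_norm, [1, 1, 1, 1, 2, 2])

    def test_baseline_median_is_exactly_one(self, small_recording):
        rec, labels = small_recording
        tr = normalize_trace(bin_median_trace(rec, labels == "naive", name="naive"))
        base = tr.bin_centers < rec.t_act
        assert np.median(tr.medians_norm[base]) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        t = np.linspace(2.5, 777.5, 156)
        raw = double_logistic(t, *TRUTH) * 321.0
        tr = PopulationTrace("p", t, raw, np.full(156, 80), 60.0, 780.0)
        a = normalize_trace(tr).medians_norm
        tr7 = PopulationTrace("p", t, raw * 7.0, np.full(156, 80), 60.0, 780.0)
        b = normalize_trace(tr7).medians_norm
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_too_few_baseline_bins(self):
        t = np.array([55.0, 100, 200, 300])
        tr = PopulationTrace("p", t, np.ones(4), np.full(4, 50), 60.0, 780.0)
        with pytest.raises(ValueError, match="baseline bins"):
            normalize_trace(tr)


class TestFitKinetic:
    def test_constant_trace(self):
        t = np.linspace(2.5, 777.5, 156)
        fit = fit_kinetic(_trace(t, np.ones(156)), model="auto")
        assert fit.model == "constant"
        assert fit.S == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_zero_noise_recovery(self):
        t = np.arange(2.5, 780, 5.0)
        y = double_logistic(t, *TRUTH)
        fit = fit_kinetic(_trace(t, y), model="dlogist")
        rel = np.abs(np.array(fit.params) / np.array(TRUTH) - 1.0)
        assert rel.max() < 1e-3
        assert fit.converged

    def test_auto_prefers_single_logistic_for_monotone_rise(self):
        t = np.arange(2.5, 780, 5.0)
        y = double_logistic(t, 1.0, 1.5, 0.05, 120.0)
        fit = fit_kinetic(_trace(t, y), model="auto")
        assert fit.model == "logistic"
        assert fit.H2 == 0.0

    def test_noisy_recovery_max_ending_midpoints(self):
        t = np.arange(2.5, 780, 5.0)
        clean = double_logistic(t, *TRUTH)
        errs_max, errs_end, errs_m1, errs_m2 = [], [], [], []
        true_d = derive_descriptors(
            KineticFit("dlogist", *TRUTH), t_act=60.0)
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            y = clean * rng.lognormal(0.0, 0.05, len(t))
            fit = fit_kinetic(_trace(t, y), model="dlogist")
            d = derive_descriptors(fit, t_act=60.0)
            errs_max.append(abs(d.max / true_d.max - 1))
            errs_end.append(abs(d.ending / true_d.ending - 1))
            errs_m1.append(abs(fit.m1 - TRUTH[3]))
            errs_m2.append(abs(fit.m2 - TRUTH[6]))
        assert np.median(errs_max) <= 0.05
        assert np.median(errs_end) <= 0.05
        assert np.median(errs_m1) <= 10.0
        assert np.median(errs_m2) <= 10.0

    @pytest.mark.parametrize("bin_width", [2.0, 10.0])
    def test_recovery_insensitive_to_bin_width(self, bin_width):
        t = np.arange(bin_width / 2, 780, bin_width)
        y = double_logistic(t, *TRUTH)
        fit = fit_kinetic(_trace(t, y), model="dlogist")
        rel = np.abs(np.array(fit.params) / np.array(TRUTH) - 1.0)
        assert rel.max() < 1e-3

    def test_determinism(self):
        t = np.arange(2.5, 780, 5.0)
        rng = np.random.default_rng(5)
        y = double_logistic(t, *TRUTH) * rng.lognormal(0, 0.05, len(t))
        f1 = fit_kinetic(_trace(t, y))
        f2 = fit_kinetic(_trace(t, y))
        assert f1.params == f2.params

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="too few"):
            fit_kinetic(_trace([1.0, 2, 3], [1.0, 1, 1]), model="dlogist")


class TestDescriptors:
    def test_constant_fit(self):
        d = derive_descriptors(KineticFit("constant", S=1.0), 60.0, 780.0)
        assert d.start == d.max == d.ending == 1.0
        assert d.auc == pytest.approx(0.0)
        assert all(math.isnan(v) for v in (d.t_to_max, d.t_to_50, d.t_50_to_max,
                                           d.slope_at_50, d.t_max_to_2nd50,
                                           d.slope_at_2nd50))

    def test_ending_is_sum_of_amplitudes(self):
        fit = KineticFit("dlogist", *TRUTH)
        d = derive_descriptors(fit, 0.0, 780.0)
        assert d.ending == pytest.approx(1.8)

    def test_limits_match_descriptors(self):
        fit = KineticFit("dlogist", *TRUTH)
        d = derive_descriptors(fit, 0.0, 780.0)
        assert abs(fit(-1e6) - d.start) < 1e-9
        assert abs(fit(1e6) - d.ending) < 1e-9

    def test_auc_matches_simpson_and_max_matches_grid(self):
        fit = KineticFit("dlogist", *TRUTH)
        d = derive_descriptors(fit, 0.0, 780.0)
        gs = np.linspace(0.0, 780.0, 100_001)
        num = simpson(fit(gs) - fit.S, x=gs)
        assert abs(d.auc - num) / abs(num) < 1e-6
        grid = np.arange(0.0, 780.0 + 1e-9, 0.01)
        vals = fit(grid)
        assert abs(d.t_to_max - grid[np.argmax(vals)]) < 0.02
        assert d.max == pytest.approx(vals.max(), abs=1e-9)

    def test_auc_zero_baseline_option(self):
        fit = KineticFit("dlogist", *TRUTH)
        d0 = derive_descriptors(fit, 0.0, 780.0, auc_baseline="zero")
        d1 = derive_descriptors(fit, 0.0, 780.0, auc_baseline="start")
        assert d0.auc - d1.auc == pytest.approx(fit.S * 780.0, rel=1e-12)

    def test_times_measured_from_activation(self):
        fit = KineticFit("dlogist", *TRUTH)
        d0 = derive_descriptors(fit, 0.0, 780.0)
        d60 = derive_descriptors(fit, 60.0, 780.0)
        # same absolute peak location, shifted reference
        assert d0.t_to_max - d60.t_to_max == pytest.approx(60.0, abs=0.05)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            derive_descriptors(KineticFit("constant", S=1.0), 780.0, 60.0)

    def test_monotonic_effects_of_amplitudes(self):
        base = dict(S=1.0, H1=2.0, k1=0.1, m1=30.0, H2=1.2, k2=0.02, m2=200.0)
        d = derive_descriptors(KineticFit("dlogist", **base), 0.0)
        up = derive_descriptors(
            KineticFit("dlogist", **{**base, "H1": 2.5}), 0.0)
        assert up.max > d.max and up.auc > d.auc
        down = derive_descriptors(
            KineticFit("dlogist", **{**base, "H2": 1.5}), 0.0)
        assert down.ending < d.ending


# Parameter draws whose peak falls inside the 780 s observation window
peaked_params = st.tuples(
    st.floats(0.5, 2.0),      # S
    st.floats(0.3, 5.0),      # H1
    st.floats(0.03, 0.5),     # k1
    st.floats(10.0, 150.0),   # m1
    st.floats(0.2, 3.0),      # H2
    st.floats(0.005, 0.05),   # k2
    st.floats(200.0, 500.0),  # m2
).filter(lambda p: p[1] > p[4] * 0.15 and p[3] + 30 < p[6])


class TestDescriptorProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(peaked_params)
    def test_sign_and_order_invariants(self, params):
        S, H1, k1, m1, H2, k2, m2 = params
        fit = KineticFit("dlogist", S, H1, k1, m1, H2, k2, m2)
        d = derive_descriptors(fit, 0.0, 780.0)
        if not math.isnan(d.t_to_50):
            assert d.t_to_50 <= d.t_to_max + 1e-9
            assert d.t_to_max == pytest.approx(d.t_to_50 + d.t_50_to_max)
            assert d.slope_at_50 > 0
        if not math.isnan(d.slope_at_2nd50):
            assert d.slope_at_2nd50 < 0
            assert d.t_max_to_2nd50 > 0
        peak_inside = d.t_to_max < 779.0 - 0.5
        if peak_inside:
            assert d.max >= max(d.start, d.ending) - 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(peaked_params, st.floats(0.1, 50.0))
    def test_auc_closed_form_vs_quadrature(self, params, span_scale):
        a, b = 0.0, 780.0 / span_scale if span_scale < 1 else 780.0
        gs = np.linspace(a, b, 20_001)
        f = double_logistic(gs, *params)
        num = simpson(f - params[0], x=gs)
        closed = double_logistic_auc(a, b, *params)
        assert closed == pytest.approx(num, rel=1e-5, abs=1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 40.0))
    def test_raw_scale_invariance_of_descriptors(self, scale):
        t = np.arange(2.5, 780, 5.0)
        raw = double_logistic(t, *TRUTH) * 250.0
        out = []
        for c in (1.0, scale):
            tr = PopulationTrace("p", t, raw * c, np.full(len(t), 60), 60.0,
                                 780.0)
            fit = fit_kinetic(normalize_trace(tr), model="dlogist")
            out.append(derive_descriptors(fit, 60.0).to_dict())
        for k, v in out[0].items():
            assert v == pytest.approx(out[1][k], rel=1e-6, abs=1e-9) or (
                math.isnan(v) and math.isnan(out[1][k])
            )


class TestDescriptorTable:
    def test_single_fit_ten_rows(self):
        d = derive_descriptors(KineticFit("dlogist", *TRUTH), 60.0)
        long, pivot = descriptor_table({("s0", "naive", "IgG+M"): d})
        assert len(long) == 10
        assert pivot.loc[("IgG+M", "max"), "naive"] == pytest.approx(d.max)

    def test_pivot_median_of_two_samples(self):
        d1 = derive_descriptors(KineticFit("dlogist", *TRUTH), 60.0)
        d2 = derive_descriptors(
            KineticFit("dlogist", 1.0, 2.4, 0.1, 30.0, 1.2, 0.02, 200.0), 60.0)
        long, pivot = descriptor_table(
            {("s0", "naive", "IgG+M"): d1, ("s1", "naive", "IgG+M"): d2})
        assert pivot.loc[("IgG+M", "max"), "naive"] == pytest.approx(
            (d1.max + d2.max) / 2)

    def test_na_cells_propagate(self):
        d = derive_descriptors(KineticFit("constant", S=1.0), 60.0)
        long, pivot = descriptor_table({("s0", "naive", "NA"): d})
        assert math.isnan(pivot.loc[("NA", "t_to_max"), "naive"])
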