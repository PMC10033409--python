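"""Tests for binding/dose-response fits and assay signal processing."""

import numpy as np
import pytest

from icl3kit.pharmacology import (
    _one_site,
    _two_site,
    cheng_prusoff,
    delta_metric,
    fit_competition,
    fit_hill,
    fit_saturation,
    fret_ratio,
    percent_bound,
    process_kinetic_trace,
    zscore_outlier_filter,
)
from icl3kit.synthetic_data import gen_dose_response, gen_kinetic_trace


class TestFitSaturation:
    L = np.array([5, 15, 50, 150, 500, 1500], dtype=float)  # pM

    def test_noiseless_round_trip(self):
        bound = 100 * self.L / (50 + self.L)
        fit = fit_saturation(self.L, bound)
        assert fit.Bmax == pytest.approx(100, rel=1e-6)
        assert fit.Kd == pytest.approx(50, rel=1e-6)

    def test_half_maximal_at_kd(self):
        fit = fit_saturation(self.L, 100 * self.L / (50 + self.L))
        assert fit.Bmax * fit.Kd / (fit.Kd + fit.Kd) == pytest.approx(fit.Bmax / 2)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(21)
        bound = 100 * self.L / (50 + self.L) * (1 + rng.normal(0, 0.05, self.L.size))
        fit = fit_saturation(self.L, bound)
        assert fit.Kd == pytest.approx(50, rel=0.15)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_saturation([1, 2, 3], [1, 2, 3])


class TestFitCompetition:
    A = np.linspace(-10, -4, 13)  # log10 molar competitor

    def test_noiseless_one_site_round_trip(self):
        y = _one_site(self.A, 100.0, 0.0, np.log10(300e-9))
        fit = fit_competition(self.A, y, sites=1)
        assert fit.ic50 == pytest.approx(300e-9, rel=1e-6)
        assert fit.Bmax == pytest.approx(100, rel=1e-6)

    def test_midpoint_property(self):
        y = _one_site(np.array([np.log10(300e-9)]), 100.0, 10.0, np.log10(300e-9))
        assert y[0] == pytest.approx(55.0)  # (Bmax + Bmin) / 2

    def test_two_site_nests_one_site(self):
        one = _one_site(self.A, 100.0, 0.0, -7.0)
        for f1 in (0.0, 1.0):
            two = _two_site(self.A, 100.0, 0.0, f1, -7.0, -7.0)
            assert two == pytest.approx(one, abs=1e-10)

    def test_two_site_recovery_and_weighted_average(self):
        y = _two_site(self.A, 100.0, 0.0, 0.4, -8.5, -5.5)
        fit = fit_competition(self.A, y, sites=2)
        assert fit.F1 == pytest.approx(0.4, abs=0.01)
        assert fit.ic50_1 == pytest.approx(10**-8.5, rel=0.02)
        assert fit.ic50_2 == pytest.approx(10**-5.5, rel=0.02)
        assert fit.ic50 == pytest.approx(0.4 * 10**-8.5 + 0.6 * 10**-5.5, rel=0.02)

    def test_log_scale_weighted_average_option(self):
        y = _two_site(self.A, 100.0, 0.0, 0.5, -8.0, -6.0)
        fit = fit_competition(self.A, y, sites=2, weighted_average="log")
        assert fit.ic50 == pytest.approx(1e-7, rel=0.02)

    def test_pinned_f1_flagged(self):
        y = _one_site(self.A, 100.0, 0.0, -7.0)
        fit = fit_competition(self.A, y, sites=2)
        if fit.F1 < 0.01 or fit.F1 > 0.99:
            assert fit.flags

    def test_ki_attached_when_tracer_given(self):
        y = _one_site(self.A, 100.0, 0.0, np.log10(300e-9))
        fit = fit_competition(
            self.A, y, sites=1, tracer_L=50e-12, tracer_KD=25e-12
        )
        assert fit.Ki == pytest.approx(100e-9, rel=1e-5)


class TestChengPrusoff:
    def test_limit_of_vanishing_tracer(self):
        assert cheng_prusoff(300e-9, 1e-18, 25e-12) == pytest.approx(300e-9)

    def test_tracer_at_kd_halves_ic50(self):
        assert cheng_prusoff(300e-9, 25e-12, 25e-12) == pytest.approx(150e-9)

    def test_worked_example(self):
        # IC50 300 nM, L 50 pM, KD 25 pM: Ki = 300/(1+2) = 100 nM
        assert cheng_prusoff(300e-9, 50e-12, 25e-12) == pytest.approx(100e-9)

    def test_monotonicity_and_bound(self):
        kis = [cheng_prusoff(1e-7, L, 25e-12) for L in (1e-12, 25e-12, 1e-10)]
        assert all(a > b for a, b in zip(kis, kis[1:]))
        assert all(k <= 1e-7 for k in kis)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            cheng_prusoff(0.0, 1e-12, 1e-12)


class TestFitHill:
    conc = np.logspace(-11, -4, 15)

    def test_noiseless_round_trip_at_10_nM(self):
        e = 1.0 / (1.0 + 10.0 ** (np.log10(10e-9) - np.log10(self.conc)))
        fit = fit_hill(self.conc, e)
        assert fit.ec50 == pytest.approx(10e-9, rel=1e-4)
        assert fit.hill == pytest.approx(1.0, rel=1e-4)

    def test_half_maximal_response_at_ec50(self):
        e = 2.0 / (1.0 + 10.0 ** (np.log10(10e-9) - np.log10(self.conc))) + 0.5
        fit = fit_hill(self.conc, e)
        at_ec50 = (fit.Emax - fit.Emin) / 2 + fit.Emin
        assert at_ec50 == pytest.approx((fit.Emax + fit.Emin) / 2)

    def test_doubling_emax_adds_log10_2_to_efficacy(self):
        e = 1.0 / (1.0 + 10.0 ** (np.log10(10e-9) - np.log10(self.conc)))
        f1 = fit_hill(self.conc, e)
        f2 = fit_hill(self.conc, 2 * e)
        assert f2.efficacy - f1.efficacy == pytest.approx(np.log10(2), abs=1e-6)

    def test_extrapolated_ec50_flagged(self):
        e = 1.0 / (1.0 + 10.0 ** (np.log10(1e-1) - np.log10(self.conc)) * 0.4)
        fit = fit_hill(self.conc, e + 0.4)
        if not (self.conc.min() / 100 <= fit.ec50 <= self.conc.max() * 100):
            assert fit.flags

    def test_noisy_preset_recovery_across_seeds(self):
        # 5% noise, 4 replicates: EC50 within 25%, Hill slope within 30%
        for seed in range(10):
            df, _ = gen_dose_response(preset="fig4c-wt", seed=seed)
            mean = df.groupby("concentration")["response"].mean()
            fit = fit_hill(mean.index.to_numpy(), mean.to_numpy())
            assert fit.ec50 == pytest.approx(10e-9, rel=0.25)
            assert fit.hill == pytest.approx(1.0, rel=0.30)


class TestDeltaMetric:
    def test_identical_arms_give_zero(self):
        assert delta_metric([0.3, 0.4], [0.3, 0.4]) == 0.0

    def test_worked_example(self):
        assert delta_metric([0.30, 0.32], [0.25, 0.27]) == pytest.approx(0.05)

    def test_antisymmetric_under_arm_swap(self):
        a, b = [0.31, 0.29, 0.35], [0.22, 0.24]
        assert delta_metric(a, b) == pytest.approx(-delta_metric(b, a))

    def test_built_from_fret_ratios(self):
        treated = [fret_ratio(100, 30), fret_ratio(100, 32)]
        ref = [fret_ratio(100, 25), fret_ratio(100, 27)]
        assert delta_metric(treated, ref) == pytest.approx(0.05)

    def test_empty_arm_raises(self):
        with pytest.raises(ValueError):
            delta_metric([], [0.3])


class TestPercentBound:
    def test_worked_examples(self):
        assert percent_bound(1000, [250]) == pytest.approx(75.0)
        assert percent_bound(1000, [1000]) == pytest.approx(0.0)
        assert percent_bound(1000, [400, 420]) == pytest.approx(59.0)

    def test_bound_plus_free_is_total(self):
        pct = percent_bound(800, [300, 340])
        free = 100 * np.mean([300, 340]) / 800
        assert pct + free == pytest.approx(100.0)

    def test_out_of_range_warned_not_clamped(self):
        with pytest.warns(UserWarning):
            assert percent_bound(100, [150]) == pytest.approx(-50.0)

    def test_nonpositive_total_raises(self):
        with pytest.raises(ValueError):
            percent_bound(0, [10])


class TestProcessKineticTrace:
    def test_constant_trace(self):
        t = np.arange(0.0, 600.0)
        res = process_kinetic_trace(t, np.full(t.size, 5.0), 300, control_value=1.0)
        assert res.normalized == pytest.approx(np.ones(t.size))
        assert res.plateau == pytest.approx(1.0)
        assert res.specific_signal == pytest.approx(0.0)

    def test_noiseless_step_reaches_fold_change(self):
        t = np.arange(0.0, 600.0)
        y = np.where(t < 300, 1.0, 2.4)
        res = process_kinetic_trace(t, y, 300, control_value=1.0)
        assert res.plateau == pytest.approx(2.4)
        assert res.specific_signal == pytest.approx(1.4)

    def test_invariant_to_overall_scale(self):
        t, y, idx, _ = gen_kinetic_trace(fold_change=2.0, noise_sd=0.0)
        r1 = process_kinetic_trace(t, y, idx, control_value=1.0)
        r2 = process_kinetic_trace(t, 7.3 * y, idx, control_value=1.0)
        assert r2.plateau == pytest.approx(r1.plateau)

    def test_window_sizes_reported(self):
        t, y, idx, _ = gen_kinetic_trace(noise_sd=0.0)
        res = process_kinetic_trace(t, y, idx, control_value=0.0)
        assert res.windows == (3, 8)

    def test_short_post_drug_trace_raises(self):
        with pytest.raises(ValueError):
            process_kinetic_trace(np.arange(10.0), np.ones(10), 6, 0.0)


class TestZscoreOutlierFilter:
    def test_all_equal_removes_nothing(self):
        with pytest.warns(UserWarning):  # zero variance among comparators
            vals, keep = zscore_outlier_filter([5.0] * 6, [True] + [False] * 5)
        assert keep.all()

    def test_flagged_outlier_removed_unflagged_retained(self):
        base = np.array([10.0, 11.0, 10.5, 9.5, 10.2])
        mean, sd = base.mean(), base.std(ddof=1)
        outlier = mean + 3.5 * sd
        vals = np.append(base, outlier)
        _, keep_flagged = zscore_outlier_filter(vals, [False] * 5 + [True])
        assert not keep_flagged[-1]
        _, keep_unflagged = zscore_outlier_filter(vals, [False] * 6)
        assert keep_unflagged.all()

    def test_mild_flagged_deviation_retained(self):
        base = np.array([10.0, 11.0, 10.5, 9.5, 10.2])
        mild = base.mean() + 2.9 * base.std(ddof=1)
        _, keep = zscore_outlier_filter(np.append(base, mild), [False] * 5 + [True])
        assert keep.all()

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            zscore_outlier_filter([1.0, 2.0], [True])
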