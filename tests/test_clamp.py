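"""Clamp analysis: survival estimation, model selection, slip fits, steps."""

import numpy as np
import pytest

from tipbond import clamp as C
from tipbond import kinetics as K
from tipbond.params import (
    COMPLEX_SLIP1,
    COMPLEX_SLIP2,
    INTERFACE_WT,
    STEP_HEIGHT_MEANS,
    UnfoldingClassParams,
)
from tipbond.synth import TraceRecipe, generate_trace


class TestEmpiricalSurvival:
    def test_counting_estimator_without_censoring(self):
        ds = C.ClampDataset(50.0, np.array([1.0, 2.0, 4.0]))
        s = C.empirical_survival(ds)
        idx = np.searchsorted(s.times, 1.5, side="right") - 1
        assert s.survival[idx] == pytest.approx(2 / 3)
        assert s.survival[0] == 1.0

    def test_proper_survival_function(self):
        rng = np.random.default_rng(2)
        lifetimes = np.minimum(rng.exponential(3.0, 200), 10.0)
        ds = C.ClampDataset(50.0, lifetimes, censored=lifetimes >= 10.0)
        s = C.empirical_survival(ds)
        assert np.all(np.diff(s.survival) <= 1e-12)
        assert np.all((s.survival >= 0) & (s.survival <= 1))

    def test_product_limit_equals_naive_fraction_uncensored(self):
        rng = np.random.default_rng(3)
        lifetimes = rng.exponential(2.0, 100)
        ds = C.ClampDataset(50.0, lifetimes, max_duration=np.inf)
        s = C.empirical_survival(ds)
        for t in (0.5, 1.0, 3.0):
            idx = np.searchsorted(s.times, t, side="right") - 1
            assert s.survival[idx] == pytest.approx((lifetimes > t).mean(), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            C.empirical_survival(C.ClampDataset(50.0, np.array([])))
        with pytest.raises(ValueError):
            C.empirical_survival(
                C.ClampDataset(50.0, np.array([10.0, 10.0]),
                               censored=np.array([True, True]))
            )


class TestExponentialFits:
    def test_mono_recovery(self):
        t = np.linspace(0, 15, 100)
        fit = C.fit_exponential(K.SurvivalCurve(t, np.exp(-t / 3.0)), 1)
        assert fit.taus[0] == pytest.approx(3.0, abs=1e-6)

    def test_bi_recovery(self):
        t = np.linspace(0, 40, 300)
        s = 0.4 * np.exp(-t / 1.0) + 0.6 * np.exp(-t / 8.0)
        fit = C.fit_exponential(K.SurvivalCurve(t, s), 2)
        assert fit.taus[0] == pytest.approx(1.0, abs=1e-4)
        assert fit.taus[1] == pytest.approx(8.0, abs=1e-4)
        assert fit.amplitudes[0] == pytest.approx(0.4, abs=1e-4)

    def test_nested_models_rss_ordering(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 10, 60)
        s = np.exp(-t / 2.0) + rng.normal(0, 0.03, t.size)
        curve = K.SurvivalCurve(t, s)
        f1 = C.fit_exponential(curve, 1)
        f2 = C.fit_exponential(curve, 2)
        assert f2.rss <= f1.rss + 1e-12


class TestFTest:
    def test_identical_rss_keeps_simpler_model(self):
        f1 = C.ExpFit(1, np.array([2.0]), np.array([1.0]), rss=0.5, dof=49)
        f2 = C.ExpFit(2, np.array([1.0, 3.0]), np.array([0.5, 0.5]),
                      rss=0.5, dof=47)
        assert C.select_model_ftest(f1, f2) == 1

    def test_null_mono_exponential_rarely_rejected(self):
        """Under mono-exponential truth the F-test keeps order 1 in >= 90%
        of noisy replicates."""
        rng = np.random.default_rng(7)
        t = np.linspace(0, 10, 50)
        kept = 0
        n_rep = 200
        for _ in range(n_rep):
            s = np.exp(-t / 3.0) + rng.normal(0, 0.02, t.size)
            curve = K.SurvivalCurve(t, s)
            f1 = C.fit_exponential(curve, 1)
            f2 = C.fit_exponential(curve, 2)
            kept += C.select_model_ftest(f1, f2, 0.05) == 1
        assert kept / n_rep >= 0.90

    def test_strong_bi_exponential_detected(self):
        t = np.linspace(0, 30, 120)
        s = 0.5 * np.exp(-t / 0.5) + 0.5 * np.exp(-t / 10.0)
        curve = K.SurvivalCurve(t, s)
        f1 = C.fit_exponential(curve, 1)
        f2 = C.fit_exponential(curve, 2)
        assert C.select_model_ftest(f1, f2, 0.05) == 2

    def test_perfect_order2_fit(self):
        f1 = C.ExpFit(1, np.array([2.0]), np.array([1.0]), rss=0.4, dof=49)
        f2 = C.ExpFit(2, np.array([1.0, 3.0]), np.array([0.5, 0.5]),
                      rss=0.0, dof=47)
        assert C.select_model_ftest(f1, f2) == 2


class TestBellSlipFit:
    def test_first_slip_region_parameters(self):
        tau0, fstar = COMPLEX_SLIP1["tau0"], COMPLEX_SLIP1["f_star"]
        forces = np.arange(10.0, 36.0, 5.0)
        curve = K.LifetimeForceCurve(forces, tau0 * np.exp(-forces / fstar))
        fit = C.fit_bell_slip(curve, (10, 35))
        assert fit.tau0 == pytest.approx(tau0, rel=1e-6)
        assert fit.f_star == pytest.approx(fstar, rel=1e-6)
        assert fit.fit_error_percent < 1e-6

    def test_second_slip_region_parameters(self):
        tau0, fstar = COMPLEX_SLIP2["tau0"], COMPLEX_SLIP2["f_star"]
        forces = np.arange(80.0, 151.0, 10.0)
        curve = K.LifetimeForceCurve(forces, tau0 * np.exp(-forces / fstar))
        fit = C.fit_bell_slip(curve, (80, 150))
        assert fit.tau0 == pytest.approx(tau0, rel=1e-6)
        assert fit.f_star == pytest.approx(fstar, rel=1e-6)

    def test_constant_curve(self):
        forces = np.arange(36.0, 71.0, 8.0)
        curve = K.LifetimeForceCurve(forces, np.full(forces.size, 6.3))
        ideal = C.fit_bell_slip(curve, (36, 70), model="ideal")
        assert ideal.tau0 == pytest.approx(6.3)
        slip = C.fit_bell_slip(curve, (36, 70), model="slip")
        assert np.isinf(slip.f_star)

    def test_narrow_window_rejected(self):
        curve = K.LifetimeForceCurve(np.array([10.0, 20, 30]), np.ones(3))
        with pytest.raises(ValueError):
            C.fit_bell_slip(curve, (25, 35))


CLASS_5NM = (5.3, 0.3, UnfoldingClassParams(k_u0=0.17, x_beta_u=2.3))
CLASS_12NM = (11.5, 0.2, UnfoldingClassParams(k_u0=0.45, x_beta_u=1.0))


class TestStepDetection:
    def test_single_step_round_trip_zero_noise(self):
        recipe = TraceRecipe(
            clamp_force=58.0, kinetic_params=INTERFACE_WT,
            step_classes=[CLASS_5NM], force_noise_sd=1e-6,
            height_noise_sd=1e-9,
        )
        for seed in range(30):
            trace, truth = generate_trace(recipe, seed=seed, return_events=True)
            if len(truth) != 1:
                continue
            events = C.detect_steps(trace)
            assert len(events) == 1
            assert events[0].height_gain == pytest.approx(truth[0][1], abs=0.5)
            return
        pytest.fail("no trace with exactly one injected event")

    def test_two_separated_steps_in_order(self):
        recipe = TraceRecipe(
            clamp_force=58.0, kinetic_params=INTERFACE_WT,
            step_classes=[CLASS_5NM, CLASS_12NM], force_noise_sd=1e-6,
            height_noise_sd=1e-9, max_duration=30.0,
        )
        for seed in range(200):
            trace, truth = generate_trace(recipe, seed=seed, return_events=True)
            if len(truth) != 2:
                continue
            if truth[1][0] - truth[0][0] < recipe.spike_duration + 0.1:
                continue  # overlapping feedback transients are unresolvable
            events = C.detect_steps(trace)
            assert len(events) == 2
            assert events[0].time < events[1].time
            for ev, (t_true, gain_true) in zip(events, truth):
                assert ev.height_gain == pytest.approx(gain_true, abs=0.5)
            return
        pytest.fail("no trace with two well-separated events")

    def test_sensitivity_at_default_noise(self):
        """>= 95% of injected ~5 nm steps are recovered at the 3-sigma
        threshold under realistic noise."""
        hits = total = 0
        for seed in range(500):
            recipe = TraceRecipe(
                clamp_force=58.0, kinetic_params=INTERFACE_WT,
                step_classes=[CLASS_5NM],
            )
            trace, truth = generate_trace(recipe, seed=seed, return_events=True)
            try:
                events = C.detect_steps(trace)
            except ValueError:
                continue  # trace too short to hold a plateau
            total += len(truth)
            hits += min(len(events), len(truth))
        assert total > 200
        assert hits / total >= 0.95

    def test_false_positive_rate_on_flat_traces(self):
        """Flat noisy plateaus produce no events in >= 99% of traces."""
        false_pos = 0
        n_rep = 1000
        for seed in range(n_rep):
            recipe = TraceRecipe(
                clamp_force=58.0, kinetic_params=INTERFACE_WT, step_classes=[]
            )
            trace = generate_trace(recipe, seed=seed)
            false_pos += len(C.detect_steps(trace)) > 0
        assert false_pos / n_rep <= 0.01

    def test_plateauless_trace_rejected(self):
        trace = C.ClampTrace(
            time=np.linspace(0, 1, 1000),
            force=np.linspace(0, 100, 1000),  # a ramp, not a clamp
            height=np.zeros(1000),
            setpoint=120.0,
            sampling_rate=1000.0,
        )
        with pytest.raises(ValueError):
            C.detect_steps(trace)


class TestStepHeightMixture:
    def test_single_component(self):
        rng = np.random.default_rng(8)
        heights = rng.normal(5.2, 0.4, 400)
        fit = C.fit_step_height_mixture(heights, 1)
        assert fit.means[0] == pytest.approx(5.2, abs=0.1)

    def test_four_component_recovery_at_published_means(self):
        """n = 1788 draws at the full-length construct's step-height means
        are recovered within 1 nm per component."""
        means = STEP_HEIGHT_MEANS["EC1-27"]
        weights = (0.45, 0.30, 0.15, 0.10)
        rng = np.random.default_rng(5)
        comps = rng.choice(4, size=1788, p=weights)
        heights = rng.normal(np.array(means)[comps], 1.5)
        fit = C.fit_step_height_mixture(heights, 4)
        assert np.all(np.abs(fit.means - np.array(means)) < 1.0)
        assert not fit.collapsed

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        heights = np.concatenate([
            rng.normal(5.0, 0.5, 300), rng.normal(12.0, 0.5, 300)
        ])
        fit_a = C.fit_step_height_mixture(heights, 2)
        fit_b = C.fit_step_height_mixture(rng.permutation(heights), 2)
        np.testing.assert_allclose(fit_a.means, fit_b.means, atol=0.05)
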