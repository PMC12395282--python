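"""Kinetic simulation: AIF construction/fitting, the implicit-Euler
two-tissue solver, frame averaging, and Patlak analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpetkit.kinetics import (ArterialInput, BiexpResponse, FramedTac,
                              InfusionSchedule, KineticParams, frame_average,
                              frame_tac, fit_aif, make_aif, patlak_ki,
                              reference_tac_ode, simulate_tac,
                              simulate_tac_matrix)


class TestInfusionSchedule:
    def test_kbol_rejected_for_ci(self):
        with pytest.raises(ValueError, match="kbol"):
            InfusionSchedule("CI", duration=95.0, kbol=19.3)

    def test_bolus_width_must_be_small(self):
        with pytest.raises(ValueError):
            InfusionSchedule("B+CI", duration=95.0, kbol=1.0, bolus_width=2.0)


class TestMakeAif:
    def test_single_exponential_closed_form(self, ci_schedule):
        """CI with one response component matches (rate/lam)(1 - e^-lam t)."""
        lam = 0.1
        aif = make_aif(ci_schedule, BiexpResponse(1.0, 0.0, lam, lam / 2), dt=0.01)
        exact = (1.0 / lam) * (1.0 - np.exp(-lam * aif.times))
        err = np.max(np.abs(aif.values - exact)) / exact.max()
        assert err < 1e-3

    def test_starts_at_zero_and_nonnegative(self, ci_aif, bci_aif):
        for aif in (ci_aif, bci_aif):
            assert aif.values[0] == 0.0
            assert np.all(aif.values >= 0)

    def test_ci_values_nondecreasing(self, ci_aif):
        assert np.all(np.diff(ci_aif.values) >= -1e-12)

    def test_bolus_raises_early_aif(self, ci_schedule):
        """A bolus strictly raises the input everywhere in the first 10 min."""
        resp = BiexpResponse(1.0, 0.05, 0.25, 0.012)
        ci = make_aif(ci_schedule, resp)
        bci = make_aif(
            InfusionSchedule("B+CI", duration=95.0, kbol=19.3), resp)
        early = (ci.times > 0) & (ci.times <= 10.0)
        assert np.all(bci.values[early] > ci.values[early])

    def test_nonpositive_dt_rejected(self, ci_schedule):
        with pytest.raises(ValueError):
            make_aif(ci_schedule, BiexpResponse(1.0, 0.0, 1.0, 0.5), dt=0.0)


class TestFitAif:
    def test_exact_recovery(self, ci_schedule):
        true = BiexpResponse(1.0, 0.05, 0.25, 0.012)
        aif = make_aif(ci_schedule, true, 0.05)
        t = np.arange(0.0, 95.1, 2.0)
        v = np.interp(t, aif.times, aif.values)
        fit = fit_aif(t, v, ci_schedule)
        for name in ("a1", "a2", "lam1", "lam2"):
            assert abs(getattr(fit, name) - getattr(true, name)) \
                <= 0.01 * getattr(true, name)

    def test_all_zero_samples(self, ci_schedule):
        t = np.arange(0.0, 95.1, 2.0)
        fit = fit_aif(t, np.zeros_like(t), ci_schedule)
        model = make_aif(ci_schedule, fit)
        assert np.max(np.abs(model.values)) < 1e-9

    def test_monte_carlo_recovery_bci(self):
        """5% sample noise: median parameter error below 10% relative.

        The B+CI schedule is used because the bolus excites the fast
        response component, making all four parameters identifiable.
        """
        sch = InfusionSchedule("B+CI", duration=95.0, kbol=19.3)
        true = BiexpResponse(1.0, 0.3, 0.5, 0.02)
        aif = make_aif(sch, true, 0.05)
        t = np.unique(np.concatenate([np.arange(0, 10, 0.25),
                                      np.arange(10.0, 95.1, 1.0)]))
        v = np.interp(t, aif.times, aif.values)
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(30):
            noisy = np.maximum(
                v + 0.05 * v.max() * rng.standard_normal(len(v)), 0.0)
            fit = fit_aif(t, noisy, sch)
            errs.append([abs(getattr(fit, n) - getattr(true, n))
                         / getattr(true, n)
                         for n in ("a1", "a2", "lam1", "lam2")])
        assert np.all(np.median(errs, axis=0) < 0.10)

    def test_too_few_samples_rejected(self, ci_schedule):
        with pytest.raises(ValueError):
            fit_aif([0, 1, 2], [0, 1, 2], ci_schedule)


class TestSimulateTac:
    def test_zero_input_gives_zero(self, ci_aif, lit_params):
        zero = ArterialInput(times=ci_aif.times,
                             values=np.zeros_like(ci_aif.values),
                             response=ci_aif.response, schedule=ci_aif.schedule)
        tac = simulate_tac(zero, lit_params)
        assert np.all(tac.total == 0)

    def test_pure_integrator_limit(self, ci_aif):
        """With k2 = k3 = k4 = 0 the tissue integrates K1 * Ca."""
        params = KineticParams(K1=0.1, k2=0.0, k3=0.0, k4=0.0)
        tac = simulate_tac(ci_aif, params)
        expected = 0.1 * ci_aif.cumulative()
        scale = expected.max()
        assert np.max(np.abs(tac.total - expected)) < 2 * ci_aif.dt * scale

    def test_matches_adaptive_ode_oracle(self, ci_aif, lit_params):
        ref = reference_tac_ode(ci_aif, lit_params)
        tac = simulate_tac(ci_aif, lit_params)
        assert np.max(np.abs(tac.total - ref)) / ref.max() < 0.01

    def test_linear_in_the_input(self, ci_aif, lit_params):
        tac1 = simulate_tac(ci_aif, lit_params)
        scaled = ArterialInput(times=ci_aif.times, values=3.5 * ci_aif.values,
                               response=ci_aif.response,
                               schedule=ci_aif.schedule)
        tac2 = simulate_tac(scaled, lit_params)
        np.testing.assert_allclose(tac2.total, 3.5 * tac1.total, rtol=1e-12)

    def test_negative_rate_rejected(self, ci_aif):
        with pytest.raises(ValueError):
            simulate_tac_matrix(ci_aif, -0.1, 0.1, 0.1, 0.0)

    def test_nonuniform_grid_rejected(self, ci_aif, lit_params):
        warped = ArterialInput(times=ci_aif.times ** 1.01,
                               values=ci_aif.values,
                               response=ci_aif.response,
                               schedule=ci_aif.schedule)
        with pytest.raises(ValueError):
            simulate_tac(warped, lit_params)

    def test_matrix_solver_matches_scalar(self, ci_aif, lit_params):
        totals = simulate_tac_matrix(ci_aif, lit_params.K1, lit_params.k2,
                                     lit_params.k3, lit_params.k4)
        tac = simulate_tac(ci_aif, lit_params)
        np.testing.assert_allclose(totals[:, 0], tac.total, rtol=1e-12)


class TestFrameTac:
    def test_constant_series(self):
        dt = 1.0 / 60.0
        n = int(20 / dt) + 1
        mid, vals = frame_average(np.full(n, 7.0), dt, 0.5, 20.0)
        np.testing.assert_allclose(vals, 7.0, atol=1e-12)

    def test_linear_series_exact_at_midpoint(self):
        dt = 1.0 / 60.0
        t = np.arange(int(20 / dt) + 1) * dt
        mid, vals = frame_average(3.0 * t, dt, 0.5, 20.0)
        np.testing.assert_allclose(vals, 3.0 * mid, atol=1e-9)

    def test_frame_count_ci(self, ci_framed):
        assert ci_framed.n_frames == 356

    def test_monotone_ci_accumulation(self, ci_framed):
        """Decay-corrected CI TACs rise strictly through the whole scan."""
        assert np.all(np.diff(ci_framed.series(0)) > 0)

    def test_scan_beyond_grid_rejected(self, ci_aif, lit_params):
        tac = simulate_tac(ci_aif, lit_params)
        with pytest.raises(ValueError):
            frame_tac(tac, 16.0 / 60.0, 200.0)


class TestPatlak:
    def test_exact_linear_form(self, ci_aif):
        """A TAC built as Ki * int(Ca) + V * Ca recovers slope and
        intercept to machine precision."""
        ki, vol = 0.03, 0.05
        mid = (np.arange(356) + 0.5) * 16.0 / 60.0
        ca = np.interp(mid, ci_aif.times, ci_aif.values)
        intca = np.interp(mid, ci_aif.times, ci_aif.cumulative())
        tac = FramedTac(frame_mid=mid, frame_dur=16.0 / 60.0,
                        values=ki * intca + vol * ca)
        res = patlak_ki(tac, ci_aif, t_star=30.0)
        assert abs(res.ki - ki) < 1e-12
        assert abs(res.intercept - vol) < 1e-10

    def test_irreversible_analytic_limit(self, ci_aif):
        params = KineticParams(0.102, 0.13, 0.062, 0.0)
        framed = frame_tac(simulate_tac(ci_aif, params), 16.0 / 60.0, 95.0)
        analytic = params.ki_irreversible()
        for t_star in (30.0, 45.0, 60.0):
            res = patlak_ki(framed, ci_aif, t_star=t_star)
            assert abs(res.ki - analytic) / analytic < 0.02

    def test_dephosphorylation_lowers_slope(self, ci_aif, ci_framed):
        """k4 > 0 biases the Patlak slope below the irreversible value."""
        params0 = KineticParams(0.102, 0.13, 0.062, 0.0)
        framed0 = frame_tac(simulate_tac(ci_aif, params0), 16.0 / 60.0, 95.0)
        ki0 = patlak_ki(framed0, ci_aif, 30.0).ki
        ki4 = patlak_ki(ci_framed, ci_aif, 30.0).ki
        assert ki4 < ki0

    def test_t_star_outside_scan_rejected(self, ci_framed, ci_aif):
        with pytest.raises(ValueError):
            patlak_ki(ci_framed, ci_aif, t_star=200.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(k1=st.floats(0.01, 0.5), k2=st.floats(0.0, 0.5),
       k3=st.floats(0.0, 0.3), k4=st.floats(0.0, 0.05))
def test_simulated_tacs_nonnegative(k1, k2, k3, k4):
    """Non-negative rates and inputs always give non-negative TACs."""
    sch = InfusionSchedule("CI", duration=20.0)
    aif = make_aif(sch, BiexpResponse(1.0, 0.05, 0.3, 0.01), dt=0.05)
    totals = simulate_tac_matrix(aif, k1, k2, k3, k4)
    assert np.all(totals >= 0)
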