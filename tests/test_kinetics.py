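"""Kinetics: 2TC simulation against closed forms, Logan transform, t* search."""

import numpy as np
import pytest

from pbifpet.cohort_types import TriExpParams, TwoTCParams, true_aif
from pbifpet.input_function import InputFunction
from pbifpet.kinetics import (
    FrameSchedule,
    LoganModel,
    RegionTAC,
    blood_volume_correct,
    find_tstar,
    fit_logan,
    logan_points,
    simulate_2tc,
)

GRID = np.arange(0.0, 5401.0)


def _cp_triexp():
    aif = TriExpParams(0.5, (50.0, 8.0, 3.0), (4.0, 0.35, 0.012))
    return InputFunction(GRID, true_aif(aif, GRID / 60.0))


class TestFrameSchedule:
    def test_default_schedule_layout(self):
        s = FrameSchedule.default_32()
        assert len(s) == 32
        assert s.total_s == 5400.0
        assert s.starts_s[0] == 0.0 and s.ends_s[-1] == 5400.0

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule((0.0, 20.0), (10.0, 30.0))


class TestSimulate2TC:
    def test_zero_input_gives_zero_tac(self):
        cp = InputFunction(GRID, np.zeros_like(GRID))
        tac = simulate_2tc(cp, TwoTCParams(0.3, 0.2, 0.05, 0.03), FrameSchedule.default_32())
        assert np.allclose(tac.values, 0.0)

    def test_one_tissue_limit_matches_convolution_closed_form(self):
        """With k3 negligible the model collapses to one tissue:
        C1(t) = K1 (e^{-k2 t} - e^{-l t})/(l - k2) for Cp = e^{-l t}."""
        K1, k2, lam = 0.5, 0.1, 0.3
        cp = InputFunction(GRID, np.exp(-lam * GRID / 60.0))
        params = TwoTCParams(K1, k2, 1e-10, 1e-4, vB=0.0)
        sched = FrameSchedule.from_durations([(90, 60)])
        tac = simulate_2tc(cp, params, sched)
        t = GRID / 60.0
        closed = K1 * (np.exp(-k2 * t) - np.exp(-lam * t)) / (lam - k2)
        expected = np.array(
            [
                np.trapezoid(closed[int(s) : int(e) + 1], t[int(s) : int(e) + 1]) / ((e - s) / 60.0)
                for s, e in zip(sched.starts_s, sched.ends_s)
            ]
        )
        assert np.allclose(tac.values, expected, rtol=1e-3)

    def test_slow_input_equilibrium_ratio(self):
        """For Cp = e^{-lam t} the late tissue/plasma ratio approaches the
        Laplace transform of the impulse response at -lam (analytic)."""
        params = TwoTCParams(0.4, 0.25, 0.06, 0.04, vB=0.0)
        lam = 0.01
        grid = np.arange(0.0, 18001.0)
        cp = InputFunction(grid, np.exp(-lam * grid / 60.0))
        sched = FrameSchedule.from_durations([(300, 60)])
        tac = simulate_2tc(cp, params, sched)
        s = params.k2 + params.k3 + params.k4
        root = np.sqrt(s * s - 4 * params.k2 * params.k4)
        a1, a2 = (s - root) / 2, (s + root) / 2
        c1 = (params.k3 + params.k4 - a1) / (a2 - a1)
        c2 = (a2 - params.k3 - params.k4) / (a2 - a1)
        limit = params.K1 * (c1 / (a1 - lam) + c2 / (a2 - lam))
        t_mid = sched.mid_times_min[-1]
        cp_mid = np.exp(-lam * t_mid)
        assert tac.values[-1] / cp_mid == pytest.approx(limit, rel=0.01)

    def test_unstable_parameters_rejected(self):
        with pytest.raises(ValueError):
            TwoTCParams(0.3, -0.2, 0.05, 0.03)


class TestBloodVolumeCorrect:
    def test_zero_vb_is_identity(self):
        sched = FrameSchedule.default_32()
        tac = RegionTAC("r", sched, np.linspace(1, 2, 32))
        out = blood_volume_correct(tac, _cp_triexp(), 0.0)
        assert np.allclose(out.values, tac.values)

    def test_inverts_the_simulators_composition(self):
        cp = _cp_triexp()
        params = TwoTCParams(0.4, 0.25, 0.06, 0.04, vB=0.05)
        sched = FrameSchedule.default_32()
        mixed = simulate_2tc(cp, params, sched)
        pure = simulate_2tc(cp, TwoTCParams(0.4, 0.25, 0.06, 0.04, vB=0.0), sched)
        out = blood_volume_correct(mixed, cp, 0.05)
        assert np.allclose(out.values, pure.values, rtol=1e-10)

    def test_negative_values_clipped_with_warning(self, caplog):
        sched = FrameSchedule.from_durations([(3, 60)])
        tac = RegionTAC("r", sched, np.array([0.0, 0.0, 0.0]))
        wb = InputFunction(np.arange(0.0, 181.0), np.full(181, 10.0))
        with caplog.at_level("WARNING", logger="pbifpet.kinetics"):
            out = blood_volume_correct(tac, wb, 0.05)
        assert np.all(out.values == 0.0)
        assert any("clipped" in r.message for r in caplog.records)

    def test_vb_out_of_range_rejected(self):
        sched = FrameSchedule.from_durations([(3, 60)])
        tac = RegionTAC("r", sched, np.ones(3))
        with pytest.raises(ValueError):
            blood_volume_correct(tac, _cp_triexp(), 1.0)


class TestLoganPoints:
    def test_identity_tracer_gives_unit_slope_zero_intercept(self):
        # Cp a ramp from zero: both integrals are exact for linear curves,
        # so the tissue curve C = Cp makes y = x point for point
        cp = InputFunction(GRID, GRID / 60.0)
        sched = FrameSchedule.default_32()
        tac = RegionTAC("r", sched, sched.mid_times_min.copy())
        x, y, _ = logan_points(tac, cp)
        assert np.allclose(y, x, rtol=1e-12)
        ols = fit_logan(x, y, 0)
        assert ols["slope"] == pytest.approx(1.0, rel=1e-12)
        assert ols["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_one_tissue_late_slope_is_k1_over_k2(self):
        cp = _cp_triexp()
        params = TwoTCParams(0.5, 0.1, 1e-10, 1e-4, vB=0.0)
        tac = simulate_2tc(cp, params, FrameSchedule.default_32())
        x, y, _ = logan_points(tac, cp)
        start, warn = find_tstar(x, y, 0.10)
        assert not warn
        assert fit_logan(x, y, start)["slope"] == pytest.approx(5.0, rel=0.01)

    def test_abscissa_strictly_increasing(self):
        cp = _cp_triexp()
        tac = simulate_2tc(cp, TwoTCParams(0.4, 0.25, 0.06, 0.04), FrameSchedule.default_32())
        x, _, _ = logan_points(tac, cp)
        assert np.all(np.diff(x) > 0)

    def test_all_zero_frames_rejected(self):
        sched = FrameSchedule.from_durations([(4, 60)])
        tac = RegionTAC("r", sched, np.zeros(4))
        with pytest.raises(ValueError):
            logan_points(tac, _cp_triexp())


def _bruteforce_tstar(x, y, threshold, measure="fitted"):
    """Independent enumeration over all start indices with polyfit lines."""
    n = len(x)
    for s in range(n - 2):
        coef = np.polyfit(x[s:], y[s:], 1)
        yhat = np.polyval(coef, x[s:])
        denom = np.abs(yhat) if measure == "fitted" else np.abs(y[s:])
        rel = np.abs(y[s:] - yhat) / np.where(denom > 0, denom, np.inf)
        if np.max(rel) <= threshold:
            return s, False
    return n - 3, True


class TestFindTstar:
    def test_collinear_points_start_at_first_frame(self):
        x = np.linspace(1, 30, 20)
        y = 5 * x + 1
        assert find_tstar(x, y) == (0, False)

    def test_curved_head_then_linear_tail(self):
        x = np.linspace(1, 30, 20)
        y = 5 * x + 1 - 40 * np.exp(-x)  # deviation dies off quickly
        s, warn = find_tstar(x, y, 0.02)
        assert (s, warn) == _bruteforce_tstar(x, y, 0.02)
        assert s > 0 and not warn

    def test_zero_threshold_falls_back_to_last_three(self):
        rng = np.random.default_rng(4)
        x = np.linspace(1, 30, 12)
        y = 5 * x + 1 + rng.normal(0, 0.5, 12)
        s, warn = find_tstar(x, y, 0.0)
        assert warn and s == 9

    @pytest.mark.parametrize("seed", range(5))
    def test_loosening_threshold_never_delays_tstar(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(1, 40, 25))
        y = 3 * x + 2 + rng.normal(0, 0.3, 25) + 5 * np.exp(-x / 3)
        starts = [find_tstar(x, y, thr)[0] for thr in (0.01, 0.03, 0.10, 0.30)]
        assert all(a >= b for a, b in zip(starts, starts[1:]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            find_tstar(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestFitLogan:
    def test_exact_line(self):
        x = np.linspace(1, 30, 15)
        res = fit_logan(x, 5 * x + 1, 0)
        assert res["slope"] == pytest.approx(5.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["rsquared"] == pytest.approx(1.0)

    def test_two_tissue_vt_recovery(self):
        # K1/k2 (1 + k3/k4) = 2 * 3 = 6; these rate constants equilibrate
        # with a ~80 min half-time, so the plot is sampled to 300 min
        grid = np.arange(0.0, 18001.0)
        aif = TriExpParams(0.5, (50.0, 8.0, 3.0), (4.0, 0.35, 0.012))
        cp = InputFunction(grid, true_aif(aif, grid / 60.0))
        sched = FrameSchedule.from_durations([(100, 180)])
        params = TwoTCParams(0.1, 0.05, 0.03, 0.015, vB=0.0)
        res = LoganModel(simulate_2tc(cp, params, sched), cp).fit()
        assert res.vt == pytest.approx(6.0, rel=0.02)
        assert res.rsquared > 0.999

    def test_input_scaling_inverts_slope(self):
        cp = _cp_triexp()
        tac = simulate_2tc(cp, TwoTCParams(0.4, 0.25, 0.06, 0.04), FrameSchedule.default_32())
        wb = cp
        base = LoganModel(tac, cp, whole_blood=wb).fit()
        cp2 = cp.scaled(2.0)
        doubled = LoganModel(tac, cp2, whole_blood=wb).fit()
        assert doubled.vt == pytest.approx(base.vt / 2.0, rel=1e-6)

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError):
            fit_logan(np.ones(5), np.linspace(1, 2, 5), 0)


class TestNoiseBias:
    def test_multiplicative_noise_biases_vt_downward(self):
        """Known property of the Logan transform: TAC noise enters both
        coordinates through 1/C(t) and biases the slope low."""
        cp = _cp_triexp()
        sched = FrameSchedule.default_32()
        clean = simulate_2tc(cp, TwoTCParams(0.4, 0.25, 0.06, 0.04, vB=0.0), sched)
        clean_vt = LoganModel(clean, cp).fit().vt
        rng = np.random.default_rng(123)
        vts = []
        for _ in range(200):
            noisy = RegionTAC(
                "r", sched, clean.values * (1.0 + rng.normal(0.0, 0.10, len(sched)))
            )
            noisy.values[noisy.values <= 0] = 1e-9
            vts.append(LoganModel(noisy, cp).fit().vt)
        assert np.median(vts) <= clean_vt
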