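"""Arterial input-function processing.

Raw arterial blood data for a dynamic PET session consist of densely sampled
early activity (automated withdrawal, every 15 s for the first 10 min) plus a
handful of late manual samples, together with parent-fraction measurements
from metabolite analysis.  This module turns those tables into a
patient-specific arterial input function (PSAIF): the total-blood curve is
fitted with a tri-exponential (linear rise from zero to the peak, three
decaying exponentials after it), the parent fraction is fitted with a
monotone Hill-type curve anchored at f(0)=1, the product of the two fits is
the metabolite-corrected plasma curve, and that curve is resampled onto a
uniform 1-s grid with its peak aligned to the 30-s time point so curves from
different subjects can be averaged.

The two fitting entry points follow the Model/Results convention:
``TriExpModel(samples).fit()`` and ``ParentFractionModel(samples).fit()``
return results objects carrying parameter estimates, residuals and a
``summary()``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .cohort_types import ParentFractionParams, TriExpParams, parent_fraction, true_aif

GRID_STEP_S = 1.0
#: default span of an input function, seconds (90-min dynamic scan)
GRID_END_S = 5400.0
#: target peak position after alignment, seconds
PEAK_ALIGN_S = 30.0

__all__ = [
    "TimeSeries",
    "InputFunction",
    "FitReport",
    "TriExpModel",
    "TriExpResults",
    "ParentFractionModel",
    "ParentFractionResults",
    "merge_blood_samples",
    "fit_triexp",
    "fit_parent_fraction",
    "metabolite_correct",
    "resample_and_align",
    "auc",
]


@dataclass
class TimeSeries:
    """Sampled activity (or fraction) curve: strictly increasing times in
    minutes, non-negative values, optional per-point durations (minutes)."""

    times_min: np.ndarray
    values: np.ndarray
    durations_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times_min.size == 0:
            raise ValueError("empty time series")
        if np.any(~np.isfinite(self.times_min)) or np.any(~np.isfinite(self.values)):
            raise ValueError("NaN/inf in time series")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times_min < 0):
            raise ValueError("negative times")
        if self.durations_min is not None:
            self.durations_min = np.asarray(self.durations_min, dtype=float)
            if self.durations_min.shape != self.times_min.shape:
                raise ValueError("durations length mismatch")

    def __len__(self) -> int:
        return self.times_min.size


@dataclass
class InputFunction:
    """Metabolite-corrected plasma curve on a uniform 1-s grid.

    ``provenance`` records whether the curve came from the subject's own
    blood data ("PSAIF") or from a rescaled population curve ("PBIF_scaled").
    """

    times_s: np.ndarray
    values: np.ndarray
    provenance: str = "PSAIF"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("grid/value length mismatch")
        steps = np.diff(self.times_s)
        if self.times_s.size < 2 or not np.allclose(steps, GRID_STEP_S):
            raise ValueError("input function requires a uniform 1-s grid")
        if np.any(self.values < -1e-9):
            raise ValueError("negative activity values")
        self.values = np.clip(self.values, 0.0, None)

    @property
    def times_min(self) -> np.ndarray:
        return self.times_s / 60.0

    @property
    def peak_time_s(self) -> float:
        return float(self.times_s[int(np.argmax(self.values))])

    def value_at(self, t_min) -> np.ndarray:
        """Linear interpolation at ``t_min`` (minutes)."""
        return np.interp(np.asarray(t_min, dtype=float) * 60.0, self.times_s, self.values)

    def auc(self, t_lo_min: float = 0.0, t_hi_min: float | None = None) -> float:
        if t_hi_min is None:
            t_hi_min = float(self.times_s[-1]) / 60.0
        return auc(self, t_lo_min, t_hi_min)

    def scaled(self, factor: float, provenance: str | None = None) -> "InputFunction":
        return InputFunction(
            self.times_s.copy(),
            self.values * factor,
            provenance or self.provenance,
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times_min, self.values, **kwargs)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity (kBq/mL)")
        return ax


@dataclass
class FitReport:
    """Nonlinear least-squares fit diagnostics."""

    params: dict
    rss: float
    residuals: np.ndarray
    n_starts: int
    converged: bool
    start_results: list = field(default_factory=list)


def merge_blood_samples(auto: TimeSeries, manual: TimeSeries | None) -> TimeSeries:
    """Merge automated early samples with late manual samples, time sorted.

    Duplicate times across the two series are an error: the same nominal
    draw must not enter the fit twice.
    """
    if manual is None or len(manual) == 0:
        return auto
    times = np.concatenate([auto.times_min, manual.times_min])
    values = np.concatenate([auto.values, manual.values])
    order = np.argsort(times)
    times, values = times[order], values[order]
    if np.any(np.diff(times) <= 0):
        raise ValueError("duplicate time points between automated and manual samples")
    return TimeSeries(times, values)


def _triexp_eval(t, t_peak, amps, rates):
    return true_aif(TriExpParams(t_peak, tuple(amps), tuple(rates)), t)


def _initial_amplitudes(samples: TimeSeries, t_peak0: float, rates) -> np.ndarray:
    """Non-negative linear least squares for amplitudes at fixed rates."""
    post = samples.times_min >= t_peak0
    if post.sum() < 3:
        post = np.ones(len(samples), dtype=bool)
    dt = np.clip(samples.times_min[post] - t_peak0, 0.0, None)
    design = np.exp(-np.outer(dt, np.asarray(rates)))
    try:
        amps, _ = optimize.nnls(design, samples.values[post])
    except RuntimeError:
        amps = np.full(3, samples.values.max() / 3.0)
    return np.clip(amps, 1e-9, None)


class TriExpModel:
    """Tri-exponential model of the total-blood activity curve.

    The curve rises linearly from zero at t=0 to the exponential sum at the
    peak time, then decays as ``sum_i A_i exp(-lambda_i (t - t_peak))``.
    Fitting is multi-start nonlinear least squares over a deterministic,
    log-spaced list of rate starts (tri-exponential fits are notoriously
    initialization sensitive).
    """

    RATE_STARTS = (
        tuple(itertools.product((1.0, 3.0, 8.0), (0.1, 0.3, 0.8), (0.003, 0.012, 0.05)))
    )

    def __init__(self, samples: TimeSeries):
        if len(samples) < 7:
            raise ValueError("need at least 7 blood samples to fit a tri-exponential")
        if samples.values.max() <= 0:
            raise ValueError("all-zero samples: no peak to fit")
        # the rise is anchored at (0, 0), so an early argmax is fine; a peak at
        # the final sample leaves the decay unconstrained
        if int(np.argmax(samples.values)) == len(samples) - 1:
            raise ValueError("samples must span pre- and post-peak times")
        self.samples = samples

    def _residuals(self, theta, times, values):
        t_peak = theta[0]
        amps = theta[1:4]
        rates = theta[4:7]
        return _triexp_eval(times, t_peak, amps, rates) - values

    def fit(self, rss_early_stop: float | None = None) -> "TriExpResults":
        s = self.samples
        t_peak0 = float(s.times_min[int(np.argmax(s.values))])
        t_peak0 = min(max(t_peak0, 0.05), 5.0)
        scale = float(np.sum(s.values**2))
        if rss_early_stop is None:
            rss_early_stop = 1e-16 * max(scale, 1.0)
        lb = [1e-3] + [0.0] * 3 + [1e-6] * 3
        ub = [10.0] + [np.inf] * 3 + [200.0] * 3
        best = None
        starts = []
        for rates in self.RATE_STARTS:
            amps0 = _initial_amplitudes(s, t_peak0, rates)
            x0 = np.concatenate([[t_peak0], amps0, rates])
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    x0,
                    bounds=(lb, ub),
                    args=(s.times_min, s.values),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                    max_nfev=2000,
                )
            except Exception:  # pragma: no cover - scipy failures are rare
                continue
            rss = float(np.sum(sol.fun**2))
            starts.append({"rates0": rates, "rss": rss, "success": bool(sol.success)})
            if best is None or rss < best[0]:
                best = (rss, sol)
            if rss <= rss_early_stop:
                break
        if best is None:
            raise RuntimeError(
                f"tri-exponential fit failed to converge from {len(starts)} starts: {starts}"
            )
        rss, sol = best
        order = np.argsort(sol.x[4:7])[::-1]  # convention: lambda1 > lambda2 > lambda3
        params = TriExpParams(
            t_peak_min=float(sol.x[0]),
            amplitudes=tuple(float(a) for a in sol.x[1:4][order]),
            rates=tuple(float(r) for r in sol.x[4:7][order]),
        )
        report = FitReport(
            params={"t_peak_min": params.t_peak_min, "amplitudes": params.amplitudes, "rates": params.rates},
            rss=rss,
            residuals=self._residuals(sol.x, s.times_min, s.values),
            n_starts=len(starts),
            converged=bool(sol.success),
            start_results=starts,
        )
        return TriExpResults(self, params, report)


@dataclass
class TriExpResults:
    model: TriExpModel
    params: TriExpParams
    report: FitReport

    @property
    def rss(self) -> float:
        return self.report.rss

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.samples.times_min)

    def predict(self, t_min) -> np.ndarray:
        return true_aif(self.params, t_min)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Tri-exponential blood-curve fit",
            f"  t_peak      {p.t_peak_min:10.4f} min",
        ]
        for i, (a, r) in enumerate(zip(p.amplitudes, p.rates), 1):
            lines.append(f"  A{i}, lambda{i}  {a:10.4f} kBq/mL, {r:10.5f} /min")
        lines.append(f"  RSS         {self.rss:10.4g}   ({self.report.n_starts} starts)")
        return "\n".join(lines)


class ParentFractionModel:
    """Hill-type parent-fraction model ``f(t) = a + (1-a) c^b / (c^b + t^b)``.

    Monotone non-increasing from f(0)=1 toward the plateau ``a``; the form
    stands in for the metabolite-fraction curve shape used for this tracer.
    """

    STARTS = tuple(itertools.product((0.5, 1.0, 2.0), (5.0, 20.0, 60.0)))

    def __init__(self, fractions: TimeSeries):
        if len(fractions) < 3:
            raise ValueError("need at least 3 parent-fraction points")
        if np.any(fractions.values < 0) or np.any(fractions.values > 1):
            raise ValueError("parent fractions must lie in [0, 1]")
        self.fractions = fractions

    @staticmethod
    def _curve(t, a, b, c):
        return parent_fraction(ParentFractionParams(a, b, c), t)

    def fit(self) -> "ParentFractionResults":
        s = self.fractions
        a0 = float(np.clip(s.values.min(), 1e-6, 1 - 1e-6))
        best = None
        starts = []
        for b0, c0 in self.STARTS:
            try:
                popt, _ = optimize.curve_fit(
                    self._curve,
                    s.times_min,
                    s.values,
                    p0=[a0, b0, c0],
                    bounds=([0.0, 0.01, 0.01], [1.0, 20.0, 1e4]),
                    xtol=1e-12,
                    ftol=1e-12,
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            resid = self._curve(s.times_min, *popt) - s.values
            rss = float(np.sum(resid**2))
            starts.append({"b0": b0, "c0": c0, "rss": rss})
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is None:
            raise RuntimeError(f"parent-fraction fit failed from {len(starts)} starts")
        rss, popt = best
        params = ParentFractionParams(float(popt[0]), float(popt[1]), float(popt[2]))
        report = FitReport(
            params={"a": params.a, "b": params.b, "c": params.c},
            rss=rss,
            residuals=self._curve(s.times_min, *popt) - s.values,
            n_starts=len(starts),
            converged=True,
            start_results=starts,
        )
        return ParentFractionResults(self, params, report)


@dataclass
class ParentFractionResults:
    model: ParentFractionModel
    params: ParentFractionParams
    report: FitReport

    @property
    def rss(self) -> float:
        return self.report.rss

    def predict(self, t_min) -> np.ndarray:
        return parent_fraction(self.params, t_min)

    def summary(self) -> str:
        p = self.params
        return (
            "Parent-fraction (Hill-type) fit\n"
            f"  plateau a   {p.a:8.4f}\n"
            f"  shape b     {p.b:8.4f}\n"
            f"  half-pt c   {p.c:8.4f} min\n"
            f"  RSS         {self.rss:10.4g}"
        )


def fit_triexp(samples: TimeSeries) -> tuple[TriExpParams, FitReport]:
    """Functional wrapper around :class:`TriExpModel`."""
    res = TriExpModel(samples).fit()
    return res.params, res.report


def fit_parent_fraction(fractions: TimeSeries) -> tuple[ParentFractionParams, FitReport]:
    """Functional wrapper around :class:`ParentFractionModel`."""
    res = ParentFractionModel(fractions).fit()
    return res.params, res.report


def metabolite_correct(total, pf: ParentFractionParams):
    """Multiply a total-activity curve by the fitted parent fraction.

    ``total`` may be a :class:`TimeSeries`, an :class:`InputFunction`, or a
    callable of time in minutes; the corrected object has the same type.
    """
    if callable(total):
        return lambda t_min: np.asarray(total(t_min)) * parent_fraction(pf, t_min)
    if isinstance(total, InputFunction):
        f = parent_fraction(pf, total.times_min)
        return InputFunction(total.times_s.copy(), total.values * f, total.provenance)
    f = parent_fraction(pf, total.times_min)
    return TimeSeries(total.times_min.copy(), total.values * f, total.durations_min)


def _exp_tail_extrapolator(times_s: np.ndarray, values: np.ndarray):
    """Mono-exponential extrapolation fitted to the last 10 min of a curve."""
    mask = times_s >= times_s[-1] - 600.0
    t, v = times_s[mask], values[mask]
    pos = v > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(v[pos]), 1)
        return lambda ts: np.exp(intercept + slope * np.asarray(ts, dtype=float))
    last = values[-1]
    return lambda ts: np.full(np.shape(ts), last, dtype=float)


def resample_and_align(
    curve,
    end_min: float = 90.0,
    peak_target_s: float = PEAK_ALIGN_S,
    provenance: str = "PSAIF",
) -> InputFunction:
    """Resample a fitted curve to the shared 1-s grid and rigidly shift it so
    its maximum sits at the 30-s point.

    ``curve`` is either a callable of time in minutes (the fitted,
    metabolite-corrected model — preferred, since it can be evaluated exactly
    at shifted times and extrapolated past 90 min) or an already sampled
    :class:`InputFunction`.  The left gap created by a right shift is
    zero-padded; a left shift extends the right end by evaluating the
    callable (or by mono-exponential extrapolation of the sampled tail) so
    the 90-min span is preserved.
    """
    grid_s = np.arange(0.0, end_min * 60.0 + GRID_STEP_S / 2, GRID_STEP_S)
    if callable(curve):
        raw = np.asarray(curve(grid_s / 60.0), dtype=float)
        if np.ptp(raw) <= 0:
            raise ValueError("flat curve: no unique peak to align")
        shift = peak_target_s - grid_s[int(np.argmax(raw))]
        src_t = (grid_s - shift) / 60.0
        values = np.where(src_t < 0, 0.0, np.asarray(curve(np.clip(src_t, 0, None)), dtype=float))
        return InputFunction(grid_s, np.clip(values, 0.0, None), provenance)

    times_s = np.asarray(curve.times_s, dtype=float)
    vals = np.asarray(curve.values, dtype=float)
    if np.ptp(vals) <= 0:
        raise ValueError("flat curve: no unique peak to align")
    shift = peak_target_s - times_s[int(np.argmax(vals))]
    src = grid_s - shift
    out = np.interp(src, times_s, vals, left=0.0)
    beyond = src > times_s[-1]
    if np.any(beyond):
        out[beyond] = _exp_tail_extrapolator(times_s, vals)(src[beyond])
    return InputFunction(grid_s, np.clip(out, 0.0, None), provenance)


def auc(curve, t_lo_min: float, t_hi_min: float) -> float:
    """Trapezoidal area under a sampled curve, in kBq*min/mL.

    Bounds must lie inside the curve's domain; values at the bounds are
    obtained by linear interpolation on the stored grid.
    """
    if t_lo_min >= t_hi_min:
        raise ValueError("t_lo must be < t_hi")
    if isinstance(curve, InputFunction):
        times = curve.times_min
        values = curve.values
    else:
        times = np.asarray(curve.times_min, dtype=float)
        values = np.asarray(curve.values, dtype=float)
    if t_lo_min < times[0] - 1e-9 or t_hi_min > times[-1] + 1e-9:
        raise ValueError("integration bounds outside the curve domain")
    t_lo = max(t_lo_min, times[0])
    t_hi = min(t_hi_min, times[-1])
    inner = (times > t_lo) & (times < t_hi)
    ts = np.concatenate([[t_lo], times[inner], [t_hi]])
    vs = np.concatenate([[np.interp(t_lo, times, values)], values[inner], [np.interp(t_hi, times, values)]])
    return float(np.trapezoid(vs, ts))
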