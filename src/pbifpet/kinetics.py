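"""Tissue kinetics: 2-tissue-compartment simulation and Logan V_T analysis.

The forward model is the standard reversible two-tissue compartment system

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

driven by the metabolite-corrected plasma curve Cp, with the measured PET
signal composed as (1 - vB)*(C1 + C2) + vB*C_blood and averaged over the
acquisition frames.  Its total volume of distribution is
V_T = (K1/k2)(1 + k3/k4).

Estimation is by the Logan graphical method: after the linearity onset t*,
the plot of  int_0^t C dT / C(t)  against  int_0^t Cp dT / C(t)  is a line
whose slope is V_T.  t* is chosen automatically by the maximum-admissible-
error criterion: the earliest frame after which every point's relative
deviation from the fitted line stays below a threshold (10% by default).

``LoganModel(tac, cp, whole_blood=...).fit()`` returns a
:class:`LoganResults` with V_T, intercept, t*, R^2, AIC and the percent
standard error of the slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal, stats

from .cohort_types import TwoTCParams
from .input_function import InputFunction

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSchedule",
    "RegionTAC",
    "LoganModel",
    "LoganResults",
    "simulate_2tc",
    "blood_volume_correct",
    "logan_points",
    "find_tstar",
    "fit_logan",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames (seconds)."""

    starts_s: tuple
    ends_s: tuple

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        ends = np.asarray(self.ends_s, dtype=float)
        if starts.shape != ends.shape or starts.size == 0:
            raise ValueError("frame starts/ends length mismatch")
        if np.any(ends <= starts):
            raise ValueError("frame end must exceed start")
        if not np.allclose(starts[1:], ends[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "starts_s", tuple(float(s) for s in starts))
        object.__setattr__(self, "ends_s", tuple(float(e) for e in ends))

    @classmethod
    def from_durations(cls, spec: list[tuple[int, float]]) -> "FrameSchedule":
        """Build from ``[(count, duration_s), ...]`` blocks."""
        durations = np.repeat([d for _, d in spec], [n for n, _ in spec]).astype(float)
        ends = np.cumsum(durations)
        starts = ends - durations
        return cls(tuple(starts), tuple(ends))

    @classmethod
    def default_32(cls) -> "FrameSchedule":
        """The 32-frame dynamic schedule used throughout: 6x10 s, 4x30 s,
        3x60 s, 2x120 s, 5x240 s, 12x300 s (90 min total)."""
        return cls.from_durations([(6, 10), (4, 30), (3, 60), (2, 120), (5, 240), (12, 300)])

    def __len__(self) -> int:
        return len(self.starts_s)

    @property
    def durations_s(self) -> np.ndarray:
        return np.asarray(self.ends_s) - np.asarray(self.starts_s)

    @property
    def mid_times_s(self) -> np.ndarray:
        return (np.asarray(self.starts_s) + np.asarray(self.ends_s)) / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_s(self) -> float:
        return float(self.ends_s[-1] - self.starts_s[0])


@dataclass
class RegionTAC:
    """Frame-averaged activity for one brain region."""

    region: str
    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schedule),):
            raise ValueError("activity length must equal frame count")


def _impulse_response(params: TwoTCParams, t_min: np.ndarray) -> np.ndarray:
    """Analytic 2TC impulse response for total tissue C1+C2 (per minute)."""
    s = params.k2 + params.k3 + params.k4
    disc = s * s - 4.0 * params.k2 * params.k4
    disc = max(disc, 0.0)
    root = np.sqrt(disc)
    a1 = (s - root) / 2.0
    a2 = (s + root) / 2.0
    if a2 - a1 < 1e-12:  # repeated-root edge: perturb to keep the formula stable
        a2 = a1 + 1e-12
    c1 = (params.k3 + params.k4 - a1) / (a2 - a1)
    c2 = (a2 - params.k3 - params.k4) / (a2 - a1)
    return params.K1 * (c1 * np.exp(-a1 * t_min) + c2 * np.exp(-a2 * t_min))


def _frame_average(times_s: np.ndarray, values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    out = np.empty(len(schedule))
    for i, (s, e) in enumerate(zip(schedule.starts_s, schedule.ends_s)):
        m = (times_s >= s - 1e-9) & (times_s <= e + 1e-9)
        out[i] = np.trapezoid(values[m], times_s[m]) / (e - s)
    return out


def simulate_2tc(
    cp: InputFunction,
    params: TwoTCParams,
    schedule: FrameSchedule,
    whole_blood: InputFunction | None = None,
) -> RegionTAC:
    """Simulate a frame-averaged regional TAC from the 2TC model.

    ``cp`` is the metabolite-corrected plasma curve on the 1-s grid; the
    blood-volume term uses ``whole_blood`` (total blood) when given, else
    ``cp``.  Tissue concentration is the exact convolution of Cp with the
    analytic impulse response, evaluated on the 1-s grid (trapezoid-corrected
    discrete convolution).
    """
    if cp.times_s[-1] < schedule.ends_s[-1] - 1e-9:
        raise ValueError("input function grid must cover the frame schedule")
    dt_min = (cp.times_s[1] - cp.times_s[0]) / 60.0
    t_min = cp.times_s / 60.0
    irf = _impulse_response(params, t_min)
    conv = signal.fftconvolve(cp.values, irf)[: cp.values.size]
    # trapezoid end-point correction (Cp[0] is 0 by construction but keep both)
    conv = conv - 0.5 * (cp.values[0] * irf + cp.values * irf[0])
    tissue = np.clip(conv * dt_min, 0.0, None)
    blood = whole_blood.values if whole_blood is not None else cp.values
    pet = (1.0 - params.vB) * tissue + params.vB * blood
    return RegionTAC("simulated", schedule, _frame_average(cp.times_s, pet, schedule))


def blood_volume_correct(
    tac: RegionTAC, whole_blood: InputFunction, vb: float = 0.05
) -> RegionTAC:
    """Remove the intravascular contribution from a measured TAC.

    C_tissue = (C_pet - vB * C_blood) / (1 - vB), clipped at zero (a warning
    is logged when clipping occurs).  The blood term is frame-averaged from
    the whole-blood curve.
    """
    if not (0.0 <= vb < 1.0):
        raise ValueError("vb must lie in [0, 1)")
    if vb == 0.0:
        return RegionTAC(tac.region, tac.schedule, tac.values.copy())
    wb = _frame_average(whole_blood.times_s, whole_blood.values, tac.schedule)
    corrected = (tac.values - vb * wb) / (1.0 - vb)
    if np.any(corrected < 0):
        logger.warning(
            "blood-volume correction clipped %d negative frame(s) in %s",
            int(np.sum(corrected < 0)),
            tac.region,
        )
        corrected = np.clip(corrected, 0.0, None)
    return RegionTAC(tac.region, tac.schedule, corrected)


def logan_points(tissue: RegionTAC, cp: InputFunction):
    """Logan-transformed coordinates at frame mid-times.

    y_k = int_0^{t_k} C dT / C(t_k),  x_k = int_0^{t_k} Cp dT / C(t_k).
    The tissue integral anchors a straight segment at (0, 0) before the
    first mid-time; the plasma integral is trapezoidal on the 1-s grid.
    Frames with non-positive tissue activity are excluded.
    """
    t_mid = tissue.schedule.mid_times_min
    c = tissue.values
    keep = c > 0
    if not np.any(keep):
        raise ValueError("all frames excluded: tissue activity is non-positive")
    t_anchor = np.concatenate([[0.0], t_mid])
    c_anchor = np.concatenate([[0.0], c])
    int_c = integrate.cumulative_trapezoid(c_anchor, t_anchor)[keep]
    cum_cp = integrate.cumulative_trapezoid(cp.values, cp.times_min, initial=0.0)
    int_cp = np.interp(t_mid[keep] * 60.0, cp.times_s, cum_cp)
    y = int_c / c[keep]
    x = int_cp / c[keep]
    return x, y, t_mid[keep]


def _ols_line(x: np.ndarray, y: np.ndarray):
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate Logan abscissa (zero variance)")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return slope, ym - slope * xm


def find_tstar(
    x: np.ndarray,
    y: np.ndarray,
    max_rel_error: float = 0.10,
    measure_against: str = "fitted",
):
    """Earliest start index after which the Logan plot is linear.

    For each candidate start, a line is fitted to the remaining points; the
    start qualifies when every point's relative deviation (measured against
    the fitted value by default, or against the observed value with
    ``measure_against='observed'``) is at or below ``max_rel_error``.  If no
    start qualifies the last three points are used and a warning flag is
    returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 Logan points")
    for s in range(n - 2):
        slope, intercept = _ols_line(x[s:], y[s:])
        yhat = slope * x[s:] + intercept
        denom = np.abs(yhat) if measure_against == "fitted" else np.abs(y[s:])
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(denom > 0, np.abs(y[s:] - yhat) / denom, np.inf)
        if np.max(rel) <= max_rel_error:
            return s, False
    return n - 3, True


def fit_logan(x: np.ndarray, y: np.ndarray, start: int):
    """OLS line through the Logan points from ``start`` onward."""
    xs, ys = np.asarray(x[start:], dtype=float), np.asarray(y[start:], dtype=float)
    if xs.size < 3:
        raise ValueError("need at least 3 points at/after t*")
    if np.ptp(xs) <= 0:
        raise ValueError("degenerate Logan abscissa (zero variance)")
    res = stats.linregress(xs, ys)
    n = xs.size
    resid = ys - (res.slope * xs + res.intercept)
    rss = float(np.sum(resid**2))
    with np.errstate(divide="ignore"):
        aic = n * np.log(rss / n) + 2 * 2 if rss > 0 else -np.inf
    pct_se = 100.0 * res.stderr / abs(res.slope) if res.slope != 0 else np.inf
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "rsquared": float(res.rvalue**2),
        "aic": float(aic),
        "pct_se": float(pct_se),
        "n": n,
        "rss": rss,
    }


class LoganModel:
    """Logan graphical V_T model for one regional TAC and an input function.

    Parameters
    ----------
    tac : RegionTAC
        Measured (frame-averaged) PET activity for the region.
    cp : InputFunction
        Metabolite-corrected plasma input function on the 1-s grid.
    whole_blood : InputFunction, optional
        Total-blood curve for the vascular correction; when omitted the
        TAC is taken as already blood-volume corrected.
    vb : float
        Fractional blood volume, fixed to 5% by default.
    """

    def __init__(
        self,
        tac: RegionTAC,
        cp: InputFunction,
        whole_blood: InputFunction | None = None,
        vb: float = 0.05,
    ):
        self.tac = tac
        self.cp = cp
        tissue = blood_volume_correct(tac, whole_blood, vb) if whole_blood is not None else tac
        self.x, self.y, self.t_mid_min = logan_points(tissue, cp)

    def fit(self, max_rel_error: float = 0.10, measure_against: str = "fitted") -> "LoganResults":
        start, warn = find_tstar(self.x, self.y, max_rel_error, measure_against)
        ols = fit_logan(self.x, self.y, start)
        return LoganResults(
            model=self,
            vt=ols["slope"],
            intercept=ols["intercept"],
            t_star_min=float(self.t_mid_min[start]),
            t_star_index=start,
            n_points=ols["n"],
            rsquared=ols["rsquared"],
            aic=ols["aic"],
            pct_se=ols["pct_se"],
            tstar_warning=warn,
            max_rel_error=max_rel_error,
        )


@dataclass
class LoganResults:
    """Logan fit: V_T (slope), intercept, linearity onset and diagnostics."""

    model: LoganModel = field(repr=False)
    vt: float
    intercept: float
    t_star_min: float
    t_star_index: int
    n_points: int
    rsquared: float
    aic: float
    pct_se: float
    tstar_warning: bool
    max_rel_error: float

    def to_dict(self) -> dict:
        return {
            "VT": self.vt,
            "intercept": self.intercept,
            "t_star_min": self.t_star_min,
            "n_points": self.n_points,
            "R2": self.rsquared,
            "AIC": self.aic,
            "pct_SE": self.pct_se,
            "tstar_warning": self.tstar_warning,
        }

    def summary(self) -> str:
        flag = "  [t* fallback: last 3 points]" if self.tstar_warning else ""
        return (
            f"Logan V_T fit ({self.model.tac.region})\n"
            f"  V_T        {self.vt:10.4f} mL/cm^3\n"
            f"  intercept  {self.intercept:10.4f} min\n"
            f"  t*         {self.t_star_min:10.2f} min "
            f"({self.n_points} points, {self.max_rel_error:.0%} criterion){flag}\n"
            f"  R^2        {self.rsquared:10.6f}\n"
            f"  AIC        {self.aic:10.2f}\n"
            f"  %SE(slope) {self.pct_se:10.3f}"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x, self.model.y, "o", label="Logan points")
        xs = self.model.x[self.t_star_index :]
        ax.plot(xs, self.vt * xs + self.intercept, "-", label=f"fit (V_T={self.vt:.2f})")
        ax.axvline(self.model.x[self.t_star_index], ls=":", color="gray")
        ax.set_xlabel(r"$\int_0^t C_p\,dT / C(t)$")
        ax.set_ylabel(r"$\int_0^t C\,dT / C(t)$")
        ax.legend()
        return ax
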