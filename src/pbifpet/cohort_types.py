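"""Domain types for subjects, input-function shapes and tissue kinetics.

These dataclasses carry the ground-truth parameterization used by the
synthetic cohort generator and the estimates produced by the fitting code:

* :class:`SubjectRecord` — demographics/scan metadata that drive the
  population-curve normalization factors (weight, injected dose, session).
* :class:`TriExpParams` — total-blood curve: linear rise from zero to the
  peak, then a sum of three decaying exponentials.
* :class:`ParentFractionParams` — Hill-type monotone parent-fraction curve
  with f(0)=1 and plateau ``a``.
* :class:`TwoTCParams` — two-tissue-compartment rate constants; the total
  volume of distribution is V_T = (K1/k2)(1 + k3/k4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubjectRecord",
    "TriExpParams",
    "ParentFractionParams",
    "TwoTCParams",
    "true_aif",
    "parent_fraction",
    "GROUPS",
    "GENOTYPES",
    "SESSIONS",
]

GROUPS = ("HV", "PD")
GENOTYPES = ("HAB", "MAB")
SESSIONS = ("single", "test", "retest")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    genotype: str
    weight_kg: float
    injected_dose_mbq: float
    session: str = "single"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if not (self.weight_kg > 0):
            raise ValueError("weight must be strictly positive")
        if not (self.injected_dose_mbq > 0):
            raise ValueError("injected dose must be strictly positive")


@dataclass(frozen=True)
class TriExpParams:
    """Tri-exponential blood curve: linear rise on [0, t_peak], then
    ``sum_i A_i exp(-lambda_i (t - t_peak))``; continuous at the peak."""

    t_peak_min: float
    amplitudes: tuple[float, float, float]
    rates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.t_peak_min < 0:
            raise ValueError("t_peak must be >= 0")
        if len(self.amplitudes) != 3 or len(self.rates) != 3:
            raise ValueError("exactly three exponential terms")
        if any(a < 0 for a in self.amplitudes) or not any(a > 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0 with at least one > 0")
        if any(not np.isfinite(r) or r <= 0 for r in self.rates):
            raise ValueError("rates must be finite and > 0")
        # convention: lambda1 > lambda2 > lambda3
        order = np.argsort(self.rates)[::-1]
        object.__setattr__(self, "amplitudes", tuple(float(self.amplitudes[i]) for i in order))
        object.__setattr__(self, "rates", tuple(float(self.rates[i]) for i in order))

    @property
    def peak_value(self) -> float:
        return float(sum(self.amplitudes))

    def __call__(self, t_min):
        return true_aif(self, t_min)


@dataclass(frozen=True)
class ParentFractionParams:
    """Hill-type parent fraction ``f(t) = a + (1-a) c^b / (c^b + t^b)``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("plateau a must lie in [0, 1]")
        if self.b <= 0 or self.c <= 0:
            raise ValueError("shape b and half-point c must be > 0")

    def __call__(self, t_min):
        return parent_fraction(self, t_min)


@dataclass(frozen=True)
class TwoTCParams:
    """Two-tissue-compartment rate constants (plus fractional blood volume)."""

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.05

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.vB < 1.0):
            raise ValueError("vB must lie in [0, 1)")

    @property
    def vt(self) -> float:
        """Total volume of distribution (K1/k2)(1 + k3/k4)."""
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)


def true_aif(params: TriExpParams, t_min):
    """Evaluate the tri-exponential blood curve at ``t_min`` (minutes).

    Zero at t=0, linear rise to the exponential sum at the peak, then the
    sum of exponentials; continuous at the peak.  Negative times are an
    error.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    scalar = t.ndim == 0
    t1 = np.atleast_1d(t)
    amps = np.asarray(params.amplitudes)
    rates = np.asarray(params.rates)
    peak = amps.sum()
    decay = np.exp(-np.outer(np.clip(t1 - params.t_peak_min, 0.0, None), rates)) @ amps
    if params.t_peak_min > 0:
        rise = peak * np.clip(t1 / params.t_peak_min, 0.0, 1.0)
        out = np.where(t1 < params.t_peak_min, rise, decay)
    else:
        out = decay
    return float(out[0]) if scalar else out.reshape(t.shape)


def parent_fraction(params: ParentFractionParams, t_min):
    """Evaluate the Hill-type parent fraction at ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    cb = params.c**params.b
    out = params.a + (1.0 - params.a) * cb / (cb + t**params.b)
    return out if out.ndim else float(out)
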