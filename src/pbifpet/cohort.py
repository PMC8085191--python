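"""Synthetic dynamic-PET cohort generator.

Emulates the data products of a TSPO brain PET study with arterial
sampling: a subject manifest (healthy volunteers and Parkinson disease
subjects, high- and mixed-affinity TSPO binders), per-session blood tables
(automated sampling every 15 s for 10 min plus manual draws at 20/30/45/60/
90 min, parent fractions at 5/10/20/30/45/60/90 min), nine regional
time-activity curves on the 32-frame schedule, and a ground-truth table.

Composition conventions:

* The TOTAL blood curve is tri-exponential (linear rise to a peak near
  30 s); the unmetabolized parent curve is total x parent-fraction, so the
  measured total equals parent / f as the blood-table contract requires.
* Whole blood and plasma are treated as identical and all activities are
  decay-corrected to injection time by construction.
* Regional TACs are exact 2TC solutions driven by the true corrected curve,
  mixed with 5% whole blood, frame-averaged, plus optional additive noise
  with SD = noise_scale * sqrt(C / duration) (count-statistics-like
  heteroscedasticity that vanishes at noise_scale = 0).
* The MAB genotype scales every regional V_T by ``genotype_vt_ratio``
  (default 0.60, a ~40% reduction); the PD group by ``pd_vt_ratio``; retest
  sessions get an extra multiplicative V_T factor emulating the systematic
  same-day retest increase reported for this tracer class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_types import (
    ParentFractionParams,
    SubjectRecord,
    TriExpParams,
    TwoTCParams,
    parent_fraction,
    true_aif,
)
from .input_function import GRID_STEP_S, InputFunction
from .kinetics import FrameSchedule, simulate_2tc

__all__ = [
    "REGIONS",
    "REGION_VT_HAB",
    "BloodSampleSchedule",
    "CohortConfig",
    "Cohort",
    "SessionTruth",
    "measured_blood",
    "generate_cohort",
]

#: the nine regions quantified in the study
REGIONS = (
    "white matter",
    "cerebellum",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "brainstem",
    "hippocampus",
    "amygdala",
)

#: baseline total volume of distribution for a healthy high-affinity binder,
#: matched to the range reported for this tracer (≈3–5 mL/cm^3)
REGION_VT_HAB = {
    "white matter": 3.7,
    "cerebellum": 3.6,
    "thalamus": 4.5,
    "caudate": 3.2,
    "putamen": 3.8,
    "pallidum": 4.1,
    "brainstem": 4.9,
    "hippocampus": 4.1,
    "amygdala": 4.0,
}

# shared 2TC rate constants; K1 is region/subject specific so that
# V_T = (K1/k2)(1 + k3/k4) hits the target
_K2, _K3, _K4 = 0.25, 0.06, 0.04
_VT_PER_K1 = (1.0 / _K2) * (1.0 + _K3 / _K4)

# base tri-exponential total-blood curve at the reference dose/weight
_BASE_AMPLITUDES = (60.0, 8.0, 3.0)  # kBq/mL
_BASE_RATES = (4.0, 0.35, 0.012)  # /min
_REF_DOSE_MBQ = 526.4
_REF_WEIGHT_KG = 75.0


@dataclass(frozen=True)
class BloodSampleSchedule:
    """Sampling times (minutes) for automated/manual draws and metabolites."""

    auto_times_min: tuple
    manual_times_min: tuple
    pf_times_min: tuple
    auto_duration_min: float = 0.25
    manual_duration_min: float = 1.0

    @classmethod
    def default(cls) -> "BloodSampleSchedule":
        return cls(
            auto_times_min=tuple(np.round(np.arange(0.25, 10.0 + 1e-9, 0.25), 4)),
            manual_times_min=(20.0, 30.0, 45.0, 60.0, 90.0),
            pf_times_min=(5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0),
        )


@dataclass
class CohortConfig:
    """Study-design and variability knobs for the generator.

    The seed is mandatory: the generator draws no implicit entropy.
    """

    seed: int
    n_subjects: int = 18
    fraction_pd: float = 12 / 18
    fraction_hab: float = 0.5
    n_test_retest: int = 5
    weight_cv: float = 0.15
    dose_cv: float = 0.14
    aif_amplitude_cv: float = 0.20
    aif_rate_cv: float = 0.15
    t_peak_mean_min: float = 0.5
    t_peak_sd_min: float = 0.05
    genotype_vt_ratio: float = 0.60
    pd_vt_ratio: float = 1.15
    subject_vt_cv: float = 0.25
    region_vt_cv: float = 0.05
    retest_vt_ratio: float = 1.25
    retest_ratio_cv: float = 0.15
    parent_a: float = 0.15
    parent_b: float = 1.5
    parent_c: float = 15.0
    parent_cv: float = 0.10
    noise_scale: float = 0.10
    vb: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in ("fraction_pd", "fraction_hab"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "weight_cv", "dose_cv", "aif_amplitude_cv", "aif_rate_cv",
            "subject_vt_cv", "region_vt_cv", "retest_ratio_cv", "parent_cv",
            "noise_scale", "t_peak_sd_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_test_retest < 0 or self.n_test_retest > self.n_subjects:
            raise ValueError("n_test_retest out of range")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionTruth:
    """Ground-truth curves and kinetics for one scan session."""

    subject: SubjectRecord
    aif: TriExpParams
    pf: ParentFractionParams
    kinetics: dict  # region -> TwoTCParams

    def corrected_cp(self) -> InputFunction:
        """True metabolite-corrected plasma curve on the 1-s grid."""
        grid = np.arange(0.0, 5400.0 + GRID_STEP_S / 2, GRID_STEP_S)
        t = grid / 60.0
        return InputFunction(grid, true_aif(self.aif, t) * parent_fraction(self.pf, t))

    def whole_blood(self) -> InputFunction:
        grid = np.arange(0.0, 5400.0 + GRID_STEP_S / 2, GRID_STEP_S)
        return InputFunction(grid, true_aif(self.aif, grid / 60.0))


@dataclass
class Cohort:
    """Generated cohort bundle: tidy tables plus ground-truth objects."""

    config: CohortConfig
    subjects: pd.DataFrame
    blood: pd.DataFrame
    tacs: pd.DataFrame
    truth: pd.DataFrame
    sessions: dict = field(default_factory=dict)  # (subject_id, session) -> SessionTruth

    def to_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "subjects.csv", index=False)
        self.blood.to_csv(outdir / "blood.csv", index=False)
        self.tacs.to_csv(outdir / "tacs.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)

    def session_keys(self) -> list[tuple[str, str]]:
        return list(self.sessions.keys())


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size)


def measured_blood(
    parent_curve,
    parent_fraction_curve,
    schedule: BloodSampleSchedule | None = None,
    noise_scale: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a blood-sample table from a parent curve and parent fraction.

    Total-blood activity at each draw is parent / f plus zero-mean Gaussian
    noise with SD = noise_scale * sqrt(C / duration); the parent-fraction
    column is populated only at the metabolite-assay times.
    """
    schedule = schedule or BloodSampleSchedule.default()
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    pf_times = set(schedule.pf_times_min)
    for times, dur, stype in (
        (schedule.auto_times_min, schedule.auto_duration_min, "auto"),
        (schedule.manual_times_min, schedule.manual_duration_min, "manual"),
    ):
        for t in times:
            f = float(parent_fraction_curve(t))
            if f <= 0:
                raise ValueError(f"parent fraction is zero at t={t} min")
            total = float(parent_curve(t)) / f
            if noise_scale > 0:
                total += rng.normal(0.0, noise_scale * np.sqrt(max(total, 0.0) / dur))
                total = max(total, 0.0)
            pf_val = np.nan
            if t in pf_times:
                pf_val = f
                if noise_scale > 0:
                    pf_val = float(np.clip(f + rng.normal(0.0, 0.1 * noise_scale), 1e-3, 1.0))
            rows.append((t, total, stype, pf_val))
    df = pd.DataFrame(rows, columns=["time_min", "activity_kBq_mL", "sample_type", "parent_fraction"])
    return df.sort_values("time_min", kind="stable").reset_index(drop=True)


def _draw_aif(cfg: CohortConfig, rng: np.random.Generator, dose: float, weight: float) -> TriExpParams:
    physio = (dose / _REF_DOSE_MBQ) * (_REF_WEIGHT_KG / weight)
    amps = tuple(
        float(a * physio * m)
        for a, m in zip(_BASE_AMPLITUDES, _lognormal(rng, cfg.aif_amplitude_cv, 3))
    )
    rates = tuple(float(r * m) for r, m in zip(_BASE_RATES, _lognormal(rng, cfg.aif_rate_cv, 3)))
    t_peak = float(np.clip(cfg.t_peak_mean_min + rng.normal(0.0, cfg.t_peak_sd_min)
                           if cfg.t_peak_sd_min > 0 else cfg.t_peak_mean_min, 0.1, 2.0))
    return TriExpParams(t_peak, amps, rates)


def _draw_pf(cfg: CohortConfig, rng: np.random.Generator) -> ParentFractionParams:
    a = float(np.clip(cfg.parent_a * _lognormal(rng, cfg.parent_cv), 0.01, 0.95))
    b = float(np.clip(cfg.parent_b * _lognormal(rng, cfg.parent_cv), 0.2, 10.0))
    c = float(np.clip(cfg.parent_c * _lognormal(rng, cfg.parent_cv), 1.0, 200.0))
    return ParentFractionParams(a, b, c)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort bundle (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    n_pd = int(round(config.fraction_pd * n))
    n_hab = int(round(config.fraction_hab * n))
    if config.n_test_retest > n - n_pd:
        raise ValueError("more test-retest pairs than healthy volunteers")

    groups = ["HV"] * (n - n_pd) + ["PD"] * n_pd
    genotypes = np.array(["MAB"] * n)
    genotypes[rng.permutation(n)[:n_hab]] = "HAB"

    schedule = BloodSampleSchedule.default()
    frames = FrameSchedule.default_32()
    subjects_rows, blood_frames, tac_frames, truth_rows = [], [], [], []
    sessions: dict = {}

    for i in range(n):
        sid = f"S{i + 1:02d}"
        weight = float(_REF_WEIGHT_KG * _lognormal(rng, config.weight_cv))
        subj_factor = float(_lognormal(rng, config.subject_vt_cv))
        if genotypes[i] == "MAB":
            subj_factor *= config.genotype_vt_ratio
        if groups[i] == "PD":
            subj_factor *= config.pd_vt_ratio
        region_factors = {r: float(_lognormal(rng, config.region_vt_cv)) for r in REGIONS}

        session_names = (
            ("test", "retest") if (groups[i] == "HV" and i < config.n_test_retest) else ("single",)
        )
        retest_factor = 1.0
        for session in session_names:
            if session == "retest":
                retest_factor = float(config.retest_vt_ratio * _lognormal(rng, config.retest_ratio_cv))
            dose = float(_REF_DOSE_MBQ * _lognormal(rng, config.dose_cv))
            subject = SubjectRecord(sid, groups[i], str(genotypes[i]), weight, dose, session)
            aif = _draw_aif(config, rng, dose, weight)
            pf = _draw_pf(config, rng)
            kin = {
                r: TwoTCParams(
                    K1=(REGION_VT_HAB[r] / _VT_PER_K1)
                    * subj_factor
                    * region_factors[r]
                    * (retest_factor if session == "retest" else 1.0),
                    k2=_K2,
                    k3=_K3,
                    k4=_K4,
                    vB=config.vb,
                )
                for r in REGIONS
            }
            truth_obj = SessionTruth(subject, aif, pf, kin)
            sessions[(sid, session)] = truth_obj

            subjects_rows.append(
                (sid, session, groups[i], genotypes[i], weight, dose)
            )

            parent = lambda t, _a=aif, _p=pf: true_aif(_a, t) * parent_fraction(_p, t)
            btab = measured_blood(parent, pf, schedule, config.noise_scale, rng)
            btab.insert(0, "session", session)
            btab.insert(0, "subject_id", sid)
            blood_frames.append(btab)

            cp = truth_obj.corrected_cp()
            wb = truth_obj.whole_blood()
            for r in REGIONS:
                tac = simulate_2tc(cp, kin[r], frames, whole_blood=wb)
                vals = tac.values.copy()
                if config.noise_scale > 0:
                    dur_min = frames.durations_s / 60.0
                    vals += rng.normal(
                        0.0, config.noise_scale * np.sqrt(np.clip(vals, 0.0, None) / dur_min)
                    )
                    vals = np.clip(vals, 0.0, None)
                tac_frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "session": session,
                            "region": r,
                            "frame_start_s": np.asarray(frames.starts_s),
                            "frame_end_s": np.asarray(frames.ends_s),
                            "activity_kBq_mL": vals,
                        }
                    )
                )
                p = kin[r]
                truth_rows.append((sid, session, r, p.K1, p.k2, p.k3, p.k4, p.vB, p.vt))

    subjects = pd.DataFrame(
        subjects_rows,
        columns=["subject_id", "session", "group", "genotype", "weight_kg", "dose_MBq"],
    )
    blood = pd.concat(blood_frames, ignore_index=True)
    tacs = pd.concat(tac_frames, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "session", "region", "K1", "k2", "k3", "k4", "vB", "true_VT"],
    )
    return Cohort(config, subjects, blood, tacs, truth, sessions)
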