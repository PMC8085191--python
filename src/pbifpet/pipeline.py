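"""End-to-end study replica: simulate -> PSAIF -> PBIF -> Logan -> agreement.

``run_full`` reproduces the whole workflow on a synthetic cohort:

1. generate the cohort bundle (subjects, blood tables, TACs, ground truth);
2. process every session's blood data into a fitted, metabolite-corrected,
   peak-aligned PSAIF;
3. build leave-one-out PBIFs under the requested normalization schemes and
   individualize them (weight x dose rescaling, or tail scaling on the
   60-90 min window);
4. estimate Logan V_T for every region from the PSAIF and from each
   PBIF-derived input function;
5. compute the agreement statistics: test-retest Bland-Altman + ICC,
   PBIF-vs-PSAIF Bland-Altman per scheme, ANOVA across schemes, genotype /
   disease-group contrasts, and the single-sample tail-time-point screen.

Every stage is a pure function of the run configuration; rerunning a
manifest reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import agreement as agr
from .cohort import Cohort, CohortConfig, REGIONS, generate_cohort
from .cohort_types import SubjectRecord
from .input_function import (
    InputFunction,
    ParentFractionModel,
    TimeSeries,
    TriExpModel,
    merge_blood_samples,
    metabolite_correct,
    resample_and_align,
)
from .kinetics import FrameSchedule, LoganModel, RegionTAC
from .pbif import (
    NormScheme,
    PBIFModel,
    build_pbif,
    evaluate_tail_timepoints,
    normalize_psaif,
    rescale_weight_dose,
    tail_scale,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "StageError", "process_session", "run_full", "validate_inputs"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Full-run configuration; serialized verbatim into the run manifest."""

    cohort: CohortConfig
    schemes: tuple = ("weight-dose", "auc", "weight-auc")
    tail_window: tuple = (60.0, 90.0)
    logan_max_rel_error: float = 0.10
    vb: float = 0.05
    loa_factor: float = 1.96
    outdir: str | None = None
    write_curves: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = CohortConfig(**d.pop("cohort"))
        if "schemes" in d:
            d["schemes"] = tuple(d["schemes"])
        if "tail_window" in d:
            d["tail_window"] = tuple(d["tail_window"])
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes)
        d["tail_window"] = list(self.tail_window)
        return d


@dataclass
class SessionPSAIF:
    """Fitted input-function products for one scan session."""

    subject: SubjectRecord
    psaif: InputFunction  # metabolite-corrected, peak-aligned, 1-s grid
    whole_blood: InputFunction  # fitted total-blood curve, unshifted
    triexp_report: dict
    pf_report: dict


def process_session(blood: pd.DataFrame, subject: SubjectRecord) -> SessionPSAIF:
    """Blood table -> PSAIF for one session.

    Fits the tri-exponential to the merged total-blood samples, the
    Hill-type curve to the parent fractions, multiplies the two fits
    (metabolite correction), and resamples/aligns onto the shared grid.
    The unshifted fitted total curve is kept for the blood-volume term.
    """
    auto = blood[blood.sample_type == "auto"]
    manual = blood[blood.sample_type == "manual"]
    auto_ts = TimeSeries(auto.time_min.to_numpy(), auto.activity_kBq_mL.to_numpy())
    manual_ts = (
        TimeSeries(manual.time_min.to_numpy(), manual.activity_kBq_mL.to_numpy())
        if len(manual)
        else None
    )
    merged = merge_blood_samples(auto_ts, manual_ts)
    tri = TriExpModel(merged).fit()

    pf_rows = blood.dropna(subset=["parent_fraction"]).sort_values("time_min")
    pf_ts = TimeSeries(pf_rows.time_min.to_numpy(), pf_rows.parent_fraction.to_numpy())
    pf = ParentFractionModel(pf_ts).fit()

    corrected = metabolite_correct(lambda t: tri.predict(t), pf.params)
    psaif = resample_and_align(corrected, provenance="PSAIF")
    grid = psaif.times_s
    whole_blood = InputFunction(grid.copy(), tri.predict(grid / 60.0), "PSAIF")
    return SessionPSAIF(
        subject=subject,
        psaif=psaif,
        whole_blood=whole_blood,
        triexp_report={"params": tri.report.params, "rss": tri.rss, "n_starts": tri.report.n_starts},
        pf_report={"params": pf.report.params, "rss": pf.rss},
    )


@dataclass
class RunResult:
    config: RunConfig
    cohort: Cohort
    psaifs: dict  # (subject_id, session) -> SessionPSAIF
    pbifs: dict  # scheme -> subject_id -> PBIFModel
    scaled_ifs: dict  # (scheme, subject_id, session) -> (InputFunction, factor)
    logan: pd.DataFrame
    testretest: pd.DataFrame
    pbif_agreement: dict  # scheme -> DataFrame
    scheme_tests: pd.DataFrame
    group_contrasts: pd.DataFrame
    tail_timepoints: pd.DataFrame
    outdir: Path | None = None


def _subject_records(cohort: Cohort) -> dict:
    recs = {}
    for row in cohort.subjects.itertuples():
        recs[(row.subject_id, row.session)] = SubjectRecord(
            row.subject_id, row.group, row.genotype, row.weight_kg, row.dose_MBq, row.session
        )
    return recs


def _primary_session(cohort: Cohort, sid: str) -> str:
    sess = set(cohort.subjects.loc[cohort.subjects.subject_id == sid, "session"])
    return "test" if "test" in sess else "single"


def _session_tacs(cohort: Cohort) -> dict:
    """(sid, session) -> {region: RegionTAC} built once from the tidy table."""
    out: dict = {}
    for (sid, session, region), g in cohort.tacs.groupby(
        ["subject_id", "session", "region"], sort=False
    ):
        g = g.sort_values("frame_start_s")
        sched = FrameSchedule(tuple(g.frame_start_s), tuple(g.frame_end_s))
        out.setdefault((sid, session), {})[region] = RegionTAC(
            region, sched, g.activity_kBq_mL.to_numpy()
        )
    return out


def run_full(config: RunConfig) -> RunResult:
    """Execute the full study replica; optionally write all outputs."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- simulate -----------------------------------------------------
    name = stage("simulate")
    try:
        cohort = generate_cohort(config.cohort)
        if outdir:
            cohort.to_csv(outdir)
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError(name, e) from e

    records = _subject_records(cohort)
    schemes = [NormScheme.from_string(s) for s in config.schemes]

    # --- PSAIF processing ----------------------------------------------
    name = stage("fit-aif")
    try:
        psaifs: dict = {}
        for key, rec in records.items():
            sid, session = key
            blood = cohort.blood[
                (cohort.blood.subject_id == sid) & (cohort.blood.session == session)
            ]
            psaifs[key] = process_session(blood, rec)
        if outdir:
            rows = []
            for (sid, session), sp in psaifs.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "session": session,
                            "time_s": sp.psaif.times_s,
                            "activity_kBq_mL": sp.psaif.values,
                        }
                    )
                )
            pd.concat(rows, ignore_index=True).to_csv(outdir / "psaif.csv", index=False)
            reports = {
                f"{sid}:{session}": {"triexp": sp.triexp_report, "parent_fraction": sp.pf_report}
                for (sid, session), sp in psaifs.items()
            }
            (outdir / "psaif_fits.json").write_text(json.dumps(reports, indent=2, default=list))
    except StageError:
        raise
    except Exception as e:
        raise StageError(name, e) from e

    # --- PBIF construction ----------------------------------------------
    name = stage("build-pbif")
    try:
        subject_ids = sorted(cohort.subjects.subject_id.unique())
        primary = {sid: _primary_session(cohort, sid) for sid in subject_ids}
        pbifs: dict = {}
        scaled_ifs: dict = {}
        for scheme in schemes:
            normalized = {
                sid: normalize_psaif(psaifs[(sid, primary[sid])].psaif, records[(sid, primary[sid])], scheme)
                for sid in subject_ids
            }
            pbifs[scheme.value] = {
                sid: build_pbif(normalized, exclude=sid, scheme=scheme) for sid in subject_ids
            }
            for key, rec in records.items():
                sid, session = key
                model = pbifs[scheme.value][sid]
                if scheme is NormScheme.WEIGHT_DOSE:
                    scaled = rescale_weight_dose(model, rec)
                    factor = rec.weight_kg * rec.injected_dose_mbq
                else:
                    psaif = psaifs[key].psaif
                    lo, hi = config.tail_window
                    late = TimeSeries(
                        np.array([lo, hi]),
                        np.array([float(psaif.value_at(lo)), float(psaif.value_at(hi))]),
                    )
                    weight = rec.weight_kg if scheme is NormScheme.WEIGHT_AUC else None
                    scaled, factor = tail_scale(model, late, config.tail_window, weight)
                scaled_ifs[(scheme.value, sid, session)] = (scaled, factor)
        if outdir and config.write_curves:
            for scheme in schemes:
                for sid, model in pbifs[scheme.value].items():
                    pd.DataFrame(
                        {"time_s": model.times_s, "mean": model.mean, "sd": model.sd}
                    ).to_csv(outdir / f"pbif_{scheme.value}_{sid}.csv", index=False)
        if outdir:
            scale_report = {
                f"{scheme}:{sid}:{session}": {"factor": factor, "window": list(config.tail_window)}
                for (scheme, sid, session), (_, factor) in scaled_ifs.items()
            }
            (outdir / "pbif_scale_report.json").write_text(json.dumps(scale_report, indent=2))
    except StageError:
        raise
    except Exception as e:
        raise StageError(name, e) from e

    # --- Logan kinetics ---------------------------------------------------
    name = stage("logan")
    try:
        tacs = _session_tacs(cohort)
        rows = []
        for key in records:
            sid, session = key
            wb = psaifs[key].whole_blood
            sources = [("PSAIF", "", psaifs[key].psaif)] + [
                ("PBIF", scheme.value, scaled_ifs[(scheme.value, sid, session)][0])
                for scheme in schemes
            ]
            for region in REGIONS:
                tac = tacs[key][region]
                for if_source, scheme_name, cp in sources:
                    res = LoganModel(tac, cp, whole_blood=wb, vb=config.vb).fit(
                        config.logan_max_rel_error
                    )
                    rows.append(
                        {
                            "subject_id": sid,
                            "session": session,
                            "region": region,
                            "if_source": if_source,
                            "scheme": scheme_name,
                            "VT": res.vt,
                            "intercept": res.intercept,
                            "t_star_min": res.t_star_min,
                            "n_points": res.n_points,
                            "R2": res.rsquared,
                            "AIC": res.aic,
                            "pct_SE": res.pct_se,
                            "tstar_warning": res.tstar_warning,
                        }
                    )
        logan = pd.DataFrame(rows)
        if outdir:
            logan.to_csv(outdir / "logan_results.csv", index=False)
    except StageError:
        raise
    except Exception as e:
        raise StageError(name, e) from e

    # --- agreement statistics ----------------------------------------------
    name = stage("agree")
    try:
        testretest = _testretest_table(cohort, logan, config.loa_factor)
        pbif_agreement = {}
        scheme_rows = []
        for scheme in schemes:
            pbif_agreement[scheme.value] = _pbif_agreement_table(
                logan, scheme.value, config.loa_factor
            )
        for region in REGIONS:
            diffs = {
                scheme.value: _pbif_diffs(logan, scheme.value, region) for scheme in schemes
            }
            if len(diffs) >= 2:
                comp = agr.compare_schemes(diffs)
                row = {"region": region, "anova_F": comp.anova_f, "anova_p": comp.anova_p}
                for _, r in comp.pairwise.iterrows():
                    row[f"p_bonf[{r.scheme_a} vs {r.scheme_b}]"] = r.p_bonferroni
                for k, v in comp.shapiro_p.items():
                    row[f"shapiro_p[{k}]"] = v
                scheme_rows.append(row)
        scheme_tests = pd.DataFrame(scheme_rows)
        contrasts = _group_contrasts(cohort, logan, schemes)
        tail = _tail_screen(cohort, psaifs, pbifs, records, primary)
        if outdir:
            testretest.to_csv(outdir / "agreement_testretest.csv", index=False)
            for scheme_name, df in pbif_agreement.items():
                df.to_csv(outdir / f"agreement_pbif_{scheme_name}.csv", index=False)
            scheme_tests.to_csv(outdir / "scheme_tests.csv", index=False)
            contrasts.to_csv(outdir / "group_contrasts.csv", index=False)
            tail.to_csv(outdir / "tail_timepoints.csv", index=False)
    except StageError:
        raise
    except Exception as e:
        raise StageError(name, e) from e

    if outdir:
        # the output path itself is not part of the scientific configuration
        manifest_cfg = config.to_dict()
        manifest_cfg.pop("outdir", None)
        (outdir / "manifest.json").write_text(json.dumps({"config": manifest_cfg}, indent=2))

    return RunResult(
        config=config,
        cohort=cohort,
        psaifs=psaifs,
        pbifs=pbifs,
        scaled_ifs=scaled_ifs,
        logan=logan,
        testretest=testretest,
        pbif_agreement=pbif_agreement,
        scheme_tests=scheme_tests,
        group_contrasts=contrasts,
        tail_timepoints=tail,
        outdir=outdir,
    )


def _psaif_vt(logan: pd.DataFrame, sid: str, session: str, region: str) -> float:
    m = logan[
        (logan.subject_id == sid)
        & (logan.session == session)
        & (logan.region == region)
        & (logan.if_source == "PSAIF")
    ]
    return float(m.VT.iloc[0])


def _testretest_table(cohort: Cohort, logan: pd.DataFrame, factor: float) -> pd.DataFrame:
    pairs = [
        sid
        for sid in cohort.subjects.subject_id.unique()
        if {"test", "retest"}
        <= set(cohort.subjects.loc[cohort.subjects.subject_id == sid, "session"])
    ]
    rows = []
    for region in REGIONS:
        if len(pairs) < 2:
            break
        test = np.array([_psaif_vt(logan, sid, "test", region) for sid in pairs])
        retest = np.array([_psaif_vt(logan, sid, "retest", region) for sid in pairs])
        diffs = agr.rel_diff_symmetric(test, retest)
        icc_val = (
            agr.icc(agr.PairedEstimates(pairs, test, retest)) if len(pairs) >= 3 else None
        )
        res = agr.bland_altman(diffs, factor, icc_value=icc_val)
        rows.append({"region": region, "test_mean": test.mean(), "retest_mean": retest.mean(),
                     **res.to_dict()})
    return pd.DataFrame(rows)


def _pbif_diffs(logan: pd.DataFrame, scheme: str, region: str) -> np.ndarray:
    pb = logan[(logan.if_source == "PBIF") & (logan.scheme == scheme) & (logan.region == region)]
    pb = pb.sort_values(["subject_id", "session"])
    ref = np.array(
        [_psaif_vt(logan, r.subject_id, r.session, region) for r in pb.itertuples()]
    )
    return agr.rel_diff_reference(ref, pb.VT.to_numpy())


def _pbif_agreement_table(logan: pd.DataFrame, scheme: str, factor: float) -> pd.DataFrame:
    rows = []
    for region in REGIONS:
        diffs = _pbif_diffs(logan, scheme, region)
        res = agr.bland_altman(diffs, factor)
        rows.append({"region": region, **res.to_dict()})
    return pd.DataFrame(rows)


def _group_contrasts(cohort: Cohort, logan: pd.DataFrame, schemes) -> pd.DataFrame:
    """Genotype and disease-group mean-V_T contrasts (region-averaged).

    Three families, mirroring how surrogate-input studies report them:
    MAB vs HAB per route; PD vs HV within each genotype per route; and
    PBIF vs PSAIF within each genotype (paired across subjects).
    """
    meta = cohort.subjects.set_index(["subject_id", "session"])
    lg = logan.copy()
    lg["genotype"] = [meta.loc[(r.subject_id, r.session), "genotype"] for r in lg.itertuples()]
    lg["group"] = [meta.loc[(r.subject_id, r.session), "group"] for r in lg.itertuples()]
    lg = lg[lg.session != "retest"]
    routes = [("PSAIF", "")] + [("PBIF", s.value) for s in schemes]
    per_subj = {
        (ifs, sch): lg[(lg.if_source == ifs) & (lg.scheme == sch)]
        .groupby(["subject_id", "genotype", "group"])
        .VT.mean()
        .reset_index()
        .sort_values("subject_id")
        for ifs, sch in routes
    }
    rows = []

    def add(if_source, scheme, contrast, va, vb_, paired):
        if va.size < 2 or vb_.size < 2:
            return
        _, p = sps.ttest_rel(va, vb_) if paired else sps.ttest_ind(va, vb_)
        rows.append(
            {
                "if_source": if_source,
                "scheme": scheme,
                "contrast": contrast,
                "mean_VT_a": float(va.mean()),
                "mean_VT_b": float(vb_.mean()),
                "pct_difference": float((va.mean() - vb_.mean()) / vb_.mean() * 100.0),
                "p_value": float(p),
                "n_a": int(va.size),
                "n_b": int(vb_.size),
            }
        )

    for ifs, sch in routes:
        ps = per_subj[(ifs, sch)]
        add(ifs, sch, "MAB vs HAB",
            ps.loc[ps.genotype == "MAB", "VT"].to_numpy(),
            ps.loc[ps.genotype == "HAB", "VT"].to_numpy(), paired=False)
        for geno in ("HAB", "MAB"):
            sub = ps[ps.genotype == geno]
            add(ifs, sch, f"PD vs HV ({geno})",
                sub.loc[sub.group == "PD", "VT"].to_numpy(),
                sub.loc[sub.group == "HV", "VT"].to_numpy(), paired=False)
    # PBIF vs PSAIF within genotype, paired on subjects
    ref = per_subj[("PSAIF", "")]
    for ifs, sch in routes[1:]:
        ps = per_subj[(ifs, sch)]
        for geno in ("HAB", "MAB"):
            a = ps[ps.genotype == geno].set_index("subject_id").VT
            b = ref[ref.genotype == geno].set_index("subject_id").VT
            common = a.index.intersection(b.index)
            add(ifs, sch, f"PBIF vs PSAIF ({geno})",
                a.loc[common].to_numpy(), b.loc[common].to_numpy(), paired=True)
    return pd.DataFrame(rows)


def _tail_screen(cohort, psaifs, pbifs, records, primary) -> pd.DataFrame:
    """Single-sample scaling screen (real + pseudo times), AUC scheme."""
    if "auc" not in pbifs:
        return pd.DataFrame()
    frames = []
    for sid, model in pbifs["auc"].items():
        key = (sid, primary[sid])
        df = evaluate_tail_timepoints(model, psaifs[key].psaif)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    all_rows = pd.concat(frames, ignore_index=True)
    summary = (
        all_rows.groupby(["time_min", "pseudo"])
        .auc_pct_error.agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "auc_pct_error_mean", "std": "auc_pct_error_sd"})
    )
    return summary


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(directory) -> list[dict]:
    """Schema/unit/invariant checks for a cohort CSV bundle.

    Returns a machine-readable list of issues (empty when the bundle is
    well formed); never raises on bad data.
    """
    directory = Path(directory)
    issues: list[dict] = []

    def issue(file, problem, **ctx):
        issues.append({"file": file, "problem": problem, **ctx})

    subjects_path = directory / "subjects.csv"
    if not subjects_path.exists():
        issue("subjects.csv", "missing file")
        subjects = None
    else:
        subjects = pd.read_csv(subjects_path)
        required = {"subject_id", "session", "group", "genotype", "weight_kg", "dose_MBq"}
        missing = required - set(subjects.columns)
        if missing:
            issue("subjects.csv", f"missing columns {sorted(missing)}")
            subjects = None
        else:
            dup = subjects.duplicated(["subject_id", "session"])
            if dup.any():
                issue("subjects.csv", "duplicate (subject_id, session)", rows=list(subjects[dup].index))
            if (subjects.weight_kg <= 0).any() or (subjects.dose_MBq <= 0).any():
                issue("subjects.csv", "non-positive weight or dose")

    blood_path = directory / "blood.csv"
    if not blood_path.exists():
        issue("blood.csv", "missing file")
    else:
        blood = pd.read_csv(blood_path)
        required = {"subject_id", "session", "time_min", "activity_kBq_mL", "sample_type"}
        missing = required - set(blood.columns)
        if missing:
            issue("blood.csv", f"missing columns {sorted(missing)}")
        else:
            for (sid, session), g in blood.groupby(["subject_id", "session"]):
                t = g.time_min.to_numpy()
                if np.any(np.diff(t) <= 0):
                    bad = int(np.argmax(np.diff(t) <= 0)) + 1
                    issue("blood.csv", "non-increasing times", subject=sid, session=session, row=bad)
                if (g.activity_kBq_mL < 0).any():
                    issue("blood.csv", "negative activity", subject=sid, session=session)
            if "parent_fraction" in blood.columns:
                pf = blood.parent_fraction.dropna()
                if ((pf < 0) | (pf > 1)).any():
                    issue("blood.csv", "parent fraction outside [0, 1]")

    tacs_path = directory / "tacs.csv"
    if not tacs_path.exists():
        issue("tacs.csv", "missing file")
    else:
        tacs = pd.read_csv(tacs_path)
        required = {"subject_id", "session", "region", "frame_start_s", "frame_end_s", "activity_kBq_mL"}
        missing = required - set(tacs.columns)
        if missing:
            issue("tacs.csv", f"missing columns {sorted(missing)}")
        else:
            for (sid, session, region), g in tacs.groupby(["subject_id", "session", "region"]):
                g = g.sort_values("frame_start_s")
                starts = g.frame_start_s.to_numpy()
                ends = g.frame_end_s.to_numpy()
                if not np.allclose(starts[1:], ends[:-1]):
                    issue("tacs.csv", "gap or overlap between frames", subject=sid,
                          session=session, region=region)
                if (g.activity_kBq_mL < 0).any():
                    issue("tacs.csv", "negative activity", subject=sid, session=session, region=region)

    truth_path = directory / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        needed = {"K1", "k2", "k3", "k4", "true_VT"}
        if needed <= set(truth.columns):
            implied = (truth.K1 / truth.k2) * (1 + truth.k3 / truth.k4)
            if not np.allclose(implied, truth.true_VT, rtol=1e-6):
                issue("truth.csv", "true_VT inconsistent with rate constants")
    return issues
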