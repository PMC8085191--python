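"""Agreement and inference statistics for paired V_T estimates.

Two percent-difference conventions are used, matching how PET test-retest
and surrogate-method studies report them:

* test-retest (symmetric):  D = (retest - test) / ((retest + test)/2) x 100
* reference-based:          D = (P_PBIF - P_PSAIF) / P_PSAIF x 100

Bland-Altman mean bias and limits of agreement (bias ± factor x SD, sample
SD, factor 1.96 by default but configurable), a coefficient of
repeatability in the study's printed form CR = 1.96 sqrt(var(D)/(N-1))
(the conventional 1.96 x SD form is available behind a flag), ICC
(two-way mixed, single measure, consistency by default), and the
scheme-comparison battery (one-way ANOVA, Bonferroni-corrected pairwise
t-tests, per-group Shapiro-Wilk) round out the module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedEstimates",
    "AgreementResult",
    "SchemeComparison",
    "rel_diff_symmetric",
    "rel_diff_reference",
    "bland_altman",
    "coefficient_repeatability",
    "icc",
    "compare_schemes",
    "gm_normalize",
    "DEFAULT_GM_REGIONS",
]

#: gray-matter structures among the nine quantified regions
DEFAULT_GM_REGIONS = (
    "cerebellum",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
)


@dataclass
class PairedEstimates:
    """Paired series (test/retest, or PSAIF/PBIF) with row labels."""

    labels: list
    first: np.ndarray
    second: np.ndarray

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        if len(self.labels) != self.first.size or self.first.size != self.second.size:
            raise ValueError("labels/first/second must have equal length")
        if self.first.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(self.first <= 0) or np.any(self.second <= 0):
            raise ValueError("paired estimates must be strictly positive")


@dataclass
class AgreementResult:
    """Bland-Altman summary of a set of percent differences."""

    mean_bias: float
    sd: float
    loa_low: float
    loa_high: float
    cr: float
    icc: float | None
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_bias <= self.loa_high):
            raise ValueError("LOA must bracket the mean bias")
        if self.cr < 0:
            raise ValueError("CR must be non-negative")

    def to_dict(self) -> dict:
        return {
            "mean_bias": self.mean_bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "cr": self.cr,
            "icc": self.icc,
            "n": self.n,
        }

    def summary(self) -> str:
        icc_s = f"{self.icc:.3f}" if self.icc is not None else "-"
        return (
            f"mean bias {self.mean_bias:+.2f}% ± {self.sd:.2f} (SD), "
            f"95% LOA [{self.loa_low:.2f}, {self.loa_high:.2f}], "
            f"CR {self.cr:.2f}%, ICC {icc_s}, N={self.n}"
        )


def rel_diff_symmetric(test, retest):
    """Percent difference normalized by the pair mean (antisymmetric)."""
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    mean = (test + retest) / 2.0
    if np.any(mean <= 0):
        raise ValueError("pair mean must be positive")
    out = (retest - test) / mean * 100.0
    return out if out.ndim else float(out)


def rel_diff_reference(p_psaif, p_pbif):
    """Percent difference referenced to the PSAIF (gold standard) value.

    Not antisymmetric: D(a->b) = -D(b->a) / (1 + D(b->a)/100).
    """
    p_psaif = np.asarray(p_psaif, dtype=float)
    p_pbif = np.asarray(p_pbif, dtype=float)
    if np.any(p_psaif <= 0):
        raise ValueError("reference values must be positive")
    out = (p_pbif - p_psaif) / p_psaif * 100.0
    return out if out.ndim else float(out)


def bland_altman(
    diffs, factor: float = 1.96, icc_value: float | None = None
) -> AgreementResult:
    """Mean bias and limits of agreement for a vector of % differences.

    LOA = bias ± factor x SD with the sample (n-1) SD; the coverage factor
    defaults to 1.96 but is configurable (published tables sometimes use
    2.0).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        mean_bias=bias,
        sd=sd,
        loa_low=bias - factor * sd,
        loa_high=bias + factor * sd,
        cr=coefficient_repeatability(d),
        icc=icc_value,
        n=int(d.size),
    )


def coefficient_repeatability(diffs, form: str = "printed") -> float:
    """Coefficient of repeatability of a difference vector.

    ``form='printed'`` implements CR = 1.96 sqrt(var(D)/(N-1)) — the form
    the study prints, which divides the variance by N-1 a second time and
    therefore behaves like a standard error.  ``form='conventional'`` gives
    the textbook 1.96 x SD(D).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    var = float(d.var(ddof=1))
    if form == "printed":
        return 1.96 * np.sqrt(var / (d.size - 1))
    if form == "conventional":
        return 1.96 * np.sqrt(var)
    raise ValueError("form must be 'printed' or 'conventional'")


def icc(pairs: PairedEstimates, form: str = "ICC3") -> float:
    """Intraclass correlation coefficient of the paired series.

    Default ICC(3,1): two-way mixed, single measure, consistency.  Any form
    label understood by :func:`pingouin.intraclass_corr` ("ICC1" ...
    "ICC3k") may be requested.
    """
    import pingouin as pg

    n = pairs.first.size
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    data = pd.DataFrame(
        {
            "target": list(range(n)) * 2,
            "rater": ["first"] * n + ["second"] * n,
            "rating": np.concatenate([pairs.first, pairs.second]),
        }
    )
    table = pg.intraclass_corr(data, targets="target", raters="rater", ratings="rating")
    # map the conventional Shrout-Fleiss names onto pingouin's labels
    aliases = {
        "ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
        "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)",
    }
    label = aliases.get(form, form)
    row = table.loc[table["Type"] == label]
    if row.empty:
        raise ValueError(f"unknown ICC form {form!r}")
    value = float(row["ICC"].iloc[0])
    if not np.isfinite(value):
        raise ValueError("ICC undefined (zero total variance)")
    return value


@dataclass
class SchemeComparison:
    """ANOVA + pairwise t-tests across normalization schemes."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: scheme_a, scheme_b, t, p_raw, p_bonferroni
    shapiro_p: dict

    def summary(self) -> str:
        lines = [f"one-way ANOVA: F={self.anova_f:.3f}, p={self.anova_p:.4g}"]
        for _, r in self.pairwise.iterrows():
            lines.append(
                f"  {r.scheme_a} vs {r.scheme_b}: t={r.t:.3f}, "
                f"p={r.p_raw:.4g} (Bonferroni {r.p_bonferroni:.4g})"
            )
        for k, v in self.shapiro_p.items():
            lines.append(f"  Shapiro-Wilk {k}: p={v:.4g}")
        return "\n".join(lines)


def compare_schemes(diffs_by_scheme: dict, paired: bool = True) -> SchemeComparison:
    """Compare % difference vectors across normalization schemes.

    One-way ANOVA over the groups, all pairwise two-sided t-tests (paired
    across the same subjects by default) with Bonferroni correction
    (p multiplied by the number of pairs, capped at 1), and per-group
    Shapiro-Wilk normality p-values.
    """
    names = list(diffs_by_scheme)
    if len(names) < 2:
        raise ValueError("need at least 2 schemes")
    groups = [np.asarray(diffs_by_scheme[k], dtype=float) for k in names]
    if any(g.size < 3 for g in groups):
        raise ValueError("each scheme needs at least 3 values")
    if all(np.allclose(g, groups[0]) for g in groups[1:]):
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*groups)
    pairs = list(itertools.combinations(range(len(names)), 2))
    n_tests = len(pairs)
    rows = []
    for i, j in pairs:
        if np.allclose(groups[i], groups[j]):
            t, p = 0.0, 1.0
        elif paired:
            if groups[i].size != groups[j].size:
                raise ValueError("paired tests require equal group sizes")
            t, p = stats.ttest_rel(groups[i], groups[j])
        else:
            t, p = stats.ttest_ind(groups[i], groups[j])
        rows.append((names[i], names[j], float(t), float(p), min(1.0, n_tests * float(p))))
    pairwise = pd.DataFrame(rows, columns=["scheme_a", "scheme_b", "t", "p_raw", "p_bonferroni"])
    shapiro = {}
    for name, g in zip(names, groups):
        shapiro[name] = float(stats.shapiro(g).pvalue) if np.ptp(g) > 0 else np.nan
    return SchemeComparison(float(f_stat), float(p_val), pairwise, shapiro)


def gm_normalize(
    vt_table: pd.DataFrame,
    gm_regions=DEFAULT_GM_REGIONS,
    volumes: dict | None = None,
) -> pd.DataFrame:
    """Divide each regional V_T by the session's gray-matter composite.

    The composite is the volume-weighted mean V_T of the designated
    gray-matter regions (equal weights unless ``volumes`` is given).
    Expects columns subject_id, session, region, VT; extra columns are kept.
    """
    required = {"subject_id", "session", "region", "VT"}
    if not required.issubset(vt_table.columns):
        raise ValueError(f"vt_table must have columns {sorted(required)}")
    out = vt_table.copy()
    weights = {r: (volumes or {}).get(r, 1.0) for r in gm_regions}

    def composite(group: pd.DataFrame) -> float:
        gm = group[group["region"].isin(gm_regions)]
        if gm.empty:
            raise ValueError("missing gray-matter regions for a session")
        w = gm["region"].map(weights).to_numpy(dtype=float)
        return float(np.average(gm["VT"].to_numpy(dtype=float), weights=w))

    keys = [c for c in ("subject_id", "session", "if_source", "scheme") if c in out.columns]
    comp = out.groupby(keys, dropna=False).apply(composite, include_groups=False)
    comp.name = "gm_composite"
    out = out.merge(comp.reset_index(), on=keys)
    if np.any(out["gm_composite"] <= 0):
        raise ValueError("gray-matter composite must be positive")
    out["VT"] = out["VT"] / out["gm_composite"]
    return out.drop(columns="gm_composite")
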