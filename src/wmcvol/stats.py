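"""The study's statistical battery on a scored cohort table.

Radiological volumes (and CSF biomarkers) are log2-transformed before any
model, so regression coefficients read "change in outcome per doubling of
volume".  Three frozen covariate sets are used: delta-score models adjust
for age, sex, waiting time, preoperative total score, Evans' index and DESH;
baseline-score and biomarker models adjust for age, sex, Evans' index and
DESH.  One ordinary-least-squares model is fitted per (dependent, volume)
pair; complete cases only; no multiple-testing correction anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "COVARIATE_SETS",
    "VOLUME_COLUMNS",
    "ModelSpec",
    "ModelResult",
    "GroupComparison",
    "log2_volumes",
    "fit_outcome_model",
    "compare_groups",
    "spearman_corr",
    "paired_t",
    "wilcoxon_signed",
    "paired_change_tests",
    "build_report",
]

logger = logging.getLogger(__name__)

VOLUME_COLUMNS = ("pvh_ml", "dwmh_ml", "ventricles_ml")

COVARIATE_SETS: dict[str, list[str]] = {
    "delta": ["age", "sex_male", "waiting_time_months", "pre_total", "evans_index", "desh"],
    "baseline": ["age", "sex_male", "evans_index", "desh"],
    "biomarker": ["age", "sex_male", "evans_index", "desh"],
    "none": [],
}


@dataclass(frozen=True)
class ModelSpec:
    """One regression: a dependent outcome against one log2 volume term."""

    dependent: str
    volume: str  # pvh_ml | dwmh_ml | ventricles_ml
    covariate_set: str = "delta"
    adjusted: bool = True

    def __post_init__(self) -> None:
        if self.volume not in VOLUME_COLUMNS and self.volume != "total_wmc_ml":
            raise ValueError(f"unknown volume term {self.volume!r}")
        if self.covariate_set not in COVARIATE_SETS:
            raise ValueError(
                f"covariate_set must be one of {sorted(COVARIATE_SETS)}, "
                f"got {self.covariate_set!r}"
            )

    @property
    def covariates(self) -> list[str]:
        return COVARIATE_SETS[self.covariate_set] if self.adjusted else []


@dataclass
class ModelResult:
    """Unstandardized coefficient B for the log2(volume) term, its two-sided
    p-value and the complete-case n."""

    dependent: str
    volume: str
    B: float
    p_value: float
    n: int
    adjusted: bool
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class GroupComparison:
    variable: str
    group_stats: dict[str, dict[str, float]]
    u_statistic: float
    p_value: float
    test: str
    method: str  # exact | asymptotic

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def log2_volumes(
    cohort: pd.DataFrame,
    columns: tuple[str, ...] = VOLUME_COLUMNS + ("total_wmc_ml",),
) -> pd.DataFrame:
    """Add log2-transformed volume columns (originals retained).

    Non-positive volumes cannot be log-transformed: they are set missing in
    the transformed column (hence excluded from complete-case model fits)
    and logged as a warning.
    """
    out = cohort.copy()
    for col in columns:
        if col not in out:
            continue
        vals = out[col].astype(float)
        bad = vals <= 0
        if bad.any():
            logger.warning(
                "%d record(s) with non-positive %s flagged and excluded from "
                "log2 transform", int(bad.sum()), col,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"log2_{col}"] = np.where(bad | vals.isna(), np.nan, np.log2(vals))
    return out


def _design_frame(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = cohort.copy()
    if "sex_male" in spec.covariates and "sex_male" not in df and "sex" in df:
        df["sex_male"] = (
            df["sex"].astype(str).str.upper().isin(["M", "MALE", "1"]).astype(float)
        )
    volcol = f"log2_{spec.volume}"
    if volcol not in df:
        df = log2_volumes(df, columns=(spec.volume,))
    cols = [spec.dependent, volcol, *spec.covariates]
    missing = [c for c in cols if c not in df]
    if missing:
        raise KeyError(f"cohort table lacks columns {missing}")
    return df[cols].dropna().astype(float)


def fit_outcome_model(cohort: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS of the dependent on log2(volume) plus the frozen covariate set."""
    data = _design_frame(cohort, spec)
    volcol = f"log2_{spec.volume}"
    y = data[spec.dependent]
    X = data[[volcol, *spec.covariates]]
    if len(data) < X.shape[1] + 2:
        raise ValueError(
            f"only {len(data)} complete cases for {spec.dependent} ~ {volcol}; "
            f"need at least {X.shape[1] + 2}"
        )
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        collinear = _collinear_columns(Xc)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, Xc).fit()
    return ModelResult(
        dependent=spec.dependent,
        volume=spec.volume,
        B=float(fit.params[volcol]),
        p_value=float(fit.pvalues[volcol]),
        n=int(fit.nobs),
        adjusted=spec.adjusted,
        covariates=list(spec.covariates),
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    names = [c for c in X.columns if c != "const"]
    bad = []
    arr = X.to_numpy()
    for j, name in enumerate(X.columns):
        if name == "const":
            continue
        others = np.delete(arr, j, axis=1)
        resid = arr[:, j] - others @ np.linalg.lstsq(others, arr[:, j], rcond=None)[0]
        denom = np.var(arr[:, j]) if np.var(arr[:, j]) > 0 else 1.0
        if np.sum(resid**2) / (len(resid) * denom) < 1e-10:
            bad.append(name)
    return bad or names


def compare_groups(
    cohort: pd.DataFrame, variable: str, grouping: str = "responder"
) -> GroupComparison:
    """Two-sided Mann-Whitney U between the two groups of ``grouping``.

    Exact null distribution for combined n <= 20 without ties; otherwise the
    normal approximation with tie correction.  Group medians (IQR) reported.
    """
    df = cohort[[variable, grouping]].dropna()
    groups = df[grouping].astype(bool)
    x = df.loc[groups, variable].astype(float).to_numpy()
    y = df.loc[~groups, variable].astype(float).to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError(f"empty group when splitting {variable} by {grouping}")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    def gstats(v: np.ndarray) -> dict[str, float]:
        return {
            "n": int(v.size),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        }
    return GroupComparison(
        variable=variable,
        group_stats={"group_true": gstats(x), "group_false": gstats(y)},
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        test="mann-whitney-u",
        method=method,
    )


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input; rank correlation undefined")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def paired_t(pre, post) -> tuple[float, float, int]:
    """Two-sided paired t-test (used for the total iNPH score)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    mask = np.isfinite(pre) & np.isfinite(post)
    d = post[mask] - pre[mask]
    if d.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.allclose(d, d[0]):
        raise ValueError("zero-variance differences; paired t-test degenerate")
    t, p = sps.ttest_rel(post[mask], pre[mask])
    return float(t), float(p), int(d.size)


def wilcoxon_signed(pre, post, exact_max_n: int = 25) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test (MMSE and the separate domains).

    Zero differences are dropped; exact distribution up to ``exact_max_n``
    nonzero differences, normal approximation beyond.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    mask = np.isfinite(pre) & np.isfinite(post)
    d = post[mask] - pre[mask]
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences zero; signed-rank test undefined")
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= exact_max_n and not has_ties:
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue), int(d.size)


def paired_change_tests(cohort: pd.DataFrame, variable: str) -> dict:
    """Pre/post change test for one variable.

    ``"total"`` uses the paired t-test on the total iNPH score; MMSE and the
    separate domains use Wilcoxon's signed-rank test.
    """
    if variable == "total":
        t, p, n = paired_t(cohort["pre_total"], cohort["post_total"])
        return {"variable": variable, "test": "paired-t", "statistic": t,
                "p_value": p, "n": n}
    if variable == "mmse":
        pre, post = cohort["mmse_pre"], cohort["mmse_post"]
    else:
        pre, post = cohort[f"pre_{variable}"], cohort[f"post_{variable}"]
    w, p, n = wilcoxon_signed(pre, post)
    return {"variable": variable, "test": "wilcoxon-signed-rank", "statistic": w,
            "p_value": p, "n": n}


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


DELTA_OUTCOMES = (
    "delta_total",
    "delta_balance",
    "delta_continence",
    "delta_gait",
    "delta_cognitive",
    "delta_mmse",
)
BASELINE_OUTCOMES = (
    "pre_total",
    "pre_balance",
    "pre_continence",
    "pre_gait",
    "pre_cognition",
    "mmse_pre",
)
BIOMARKERS = ("t_tau", "p_tau", "abeta42", "nfl")


def build_report(
    cohort: pd.DataFrame, log2_biomarkers: bool = True
) -> dict[str, pd.DataFrame | str]:
    """Assemble the four result tables on a scored cohort.

    volumes_by_response: group medians/IQR (mean/SD for ventricles) with the
    Mann-Whitney p; delta_models: per-outcome unadjusted and adjusted B and p
    for each volume; baseline_models and biomarker_models: adjusted B and p.
    Significance flagged * (<0.05) / ** (<0.01).  Biomarker dependents are
    log2-transformed by default, matching the volumes.
    """
    df = log2_volumes(cohort)
    if "sex_male" not in df and "sex" in df:
        df["sex_male"] = (
            df["sex"].astype(str).str.upper().isin(["M", "MALE", "1"]).astype(float)
        )

    rows = []
    for var in VOLUME_COLUMNS:
        if var not in df or "responder" not in df:
            continue
        gc = compare_groups(df, var, "responder")
        r, nr = gc.group_stats["group_true"], gc.group_stats["group_false"]
        if var == "ventricles_ml":
            desc_r = f"{r['mean']:.1f} ({r['sd']:.1f})"
            desc_n = f"{nr['mean']:.1f} ({nr['sd']:.1f})"
        else:
            desc_r = f"{r['median']:.1f} ({r['q1']:.1f}-{r['q3']:.1f})"
            desc_n = f"{nr['median']:.1f} ({nr['q1']:.1f}-{nr['q3']:.1f})"
        rows.append(
            {
                "volume": var,
                "responders": desc_r,
                "non_responders": desc_n,
                "U": gc.u_statistic,
                "p_value": gc.p_value,
                "sig": _stars(gc.p_value),
            }
        )
    table2 = pd.DataFrame(rows)

    rows = []
    for dep in DELTA_OUTCOMES:
        if dep not in df:
            continue
        for vol in VOLUME_COLUMNS:
            try:
                un = fit_outcome_model(
                    df, ModelSpec(dep, vol, covariate_set="none", adjusted=False)
                )
                ad = fit_outcome_model(df, ModelSpec(dep, vol, covariate_set="delta"))
            except (ValueError, KeyError):
                continue
            rows.append(
                {
                    "delta_score": dep,
                    "volume": vol,
                    "B_unadjusted": un.B,
                    "p_unadjusted": un.p_value,
                    "sig_unadjusted": _stars(un.p_value),
                    "B_adjusted": ad.B,
                    "p_adjusted": ad.p_value,
                    "sig_adjusted": _stars(ad.p_value),
                    "n": ad.n,
                }
            )
    table3 = pd.DataFrame(rows)

    rows = []
    for dep in BASELINE_OUTCOMES:
        if dep not in df:
            continue
        for vol in VOLUME_COLUMNS:
            try:
                res = fit_outcome_model(df, ModelSpec(dep, vol, covariate_set="baseline"))
            except (ValueError, KeyError):
                continue
            rows.append(
                {
                    "baseline_score": dep,
                    "volume": vol,
                    "B": res.B,
                    "p_value": res.p_value,
                    "sig": _stars(res.p_value),
                    "n": res.n,
                }
            )
    table4 = pd.DataFrame(rows)

    rows = []
    note_bio = ""
    for marker in BIOMARKERS:
        if marker not in df:
            continue
        dep = marker
        if log2_biomarkers:
            dep = f"log2_{marker}"
            vals = df[marker].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                df[dep] = np.where(vals > 0, np.log2(vals), np.nan)
        for vol in VOLUME_COLUMNS:
            try:
                res = fit_outcome_model(df, ModelSpec(dep, vol, covariate_set="biomarker"))
            except (ValueError, KeyError):
                continue
            rows.append(
                {
                    "biomarker": marker,
                    "volume": vol,
                    "B": res.B,
                    "p_value": res.p_value,
                    "sig": _stars(res.p_value),
                    "n": res.n,
                }
            )
    table5 = pd.DataFrame(rows)
    if table5.empty:
        note_bio = " No biomarker columns present; biomarker table empty."

    note = (
        "Volumes (and biomarkers) log2-transformed; one OLS per (outcome, volume) "
        "pair on complete cases; * p<0.05, ** p<0.01; no correction for multiple "
        "analyses was applied." + note_bio
    )
    return {
        "volumes_by_response": table2,
        "delta_models": table3,
        "baseline_models": table4,
        "biomarker_models": table5,
        "note": note,
    }
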