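"""iNPH-scale scoring, outcome deltas, responder classification, exclusions.

The iNPH scale has four domains (gait, balance, continence, cognition), each
0-100 with 0 the most severe symptoms.  The total score is the weighted mean
of the available domains with gait counted twice.  Shunt outcome is the
post- minus preoperative total ("delta total"); a delta of at least 5 points
defines a shunt responder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "DOMAIN_WEIGHTS",
    "DomainScores",
    "DeltaScores",
    "total_inph_score",
    "delta_scores",
    "classify_responder",
    "mmse_change_category",
    "apply_stroop_conversion",
    "apply_exclusions",
    "score_cohort",
    "cohort_summary",
    "proportion_pct",
    "paired_median_change",
]

DOMAIN_WEIGHTS = {"gait": 2.0, "balance": 1.0, "continence": 1.0, "cognition": 1.0}
RESPONDER_THRESHOLD = 5.0
# Scores are recorded to at most one decimal; the epsilon keeps the inclusive
# >= 5 cut stable against float rounding in computed totals.
_EPS = 1e-9


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class DomainScores:
    gait: float | None = None
    balance: float | None = None
    continence: float | None = None
    cognition: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not _missing(v) and not (0.0 <= float(v) <= 100.0):
                raise ValueError(f"{f.name} score {v} outside [0, 100]")

    def available(self) -> dict[str, float]:
        return {
            f.name: float(getattr(self, f.name))
            for f in fields(self)
            if not _missing(getattr(self, f.name))
        }


@dataclass
class DeltaScores:
    delta_total: float | None = None
    delta_gait: float | None = None
    delta_balance: float | None = None
    delta_continence: float | None = None
    delta_cognitive: float | None = None
    delta_mmse: float | None = None


def total_inph_score(domains: DomainScores) -> float:
    """Weighted mean of the available domains, gait weighted double.

    The denominator is the sum of the weights of the domains actually
    present, so the total always stays on the 0-100 scale.
    """
    avail = domains.available()
    if not avail:
        raise ValueError("no iNPH domain scores present")
    wsum = sum(DOMAIN_WEIGHTS[k] for k in avail)
    return sum(DOMAIN_WEIGHTS[k] * v for k, v in avail.items()) / wsum


def delta_scores(
    pre: DomainScores,
    post: DomainScores,
    mmse_pre: float | None = None,
    mmse_post: float | None = None,
    strict: bool = False,
) -> DeltaScores:
    """Componentwise post minus pre; totals are computed before differencing.

    Each time point's total uses its own available domains.  In ``strict``
    mode (sensitivity analysis) the delta total is reported missing when the
    two time points were scored on different domain sets.
    """
    pre_avail, post_avail = pre.available(), post.available()
    delta_total: float | None = None
    if pre_avail and post_avail:
        if strict and set(pre_avail) != set(post_avail):
            delta_total = None
        else:
            delta_total = total_inph_score(post) - total_inph_score(pre)

    def comp(name: str) -> float | None:
        if name in pre_avail and name in post_avail:
            return post_avail[name] - pre_avail[name]
        return None

    delta_mmse = None
    if not _missing(mmse_pre) and not _missing(mmse_post):
        delta_mmse = float(mmse_post) - float(mmse_pre)
    return DeltaScores(
        delta_total=delta_total,
        delta_gait=comp("gait"),
        delta_balance=comp("balance"),
        delta_continence=comp("continence"),
        delta_cognitive=comp("cognition"),
        delta_mmse=delta_mmse,
    )


def classify_responder(delta_total: float) -> bool:
    """Shunt responder iff the delta total score is at least 5 (inclusive)."""
    if _missing(delta_total):
        raise ValueError("delta total score is missing")
    return float(delta_total) >= RESPONDER_THRESHOLD - _EPS


def mmse_change_category(pre: float, post: float) -> str | None:
    """'improved' / 'unchanged' / 'reduced' by the sign of post - pre."""
    if _missing(pre) or _missing(post):
        return None
    if post > pre:
        return "improved"
    if post < pre:
        return "reduced"
    return "unchanged"


def apply_stroop_conversion(raw: float, table: dict[float, float]) -> float:
    """Convert an abbreviated (24-item) Stroop result to the 0-100 cognitive
    domain via an injected lookup table; no default table is shipped."""
    if raw not in table:
        raise KeyError(f"raw Stroop value {raw} not in conversion table")
    return float(table[raw])


def apply_exclusions(registry: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records flagged for exclusion; report counts per reason.

    ``exclusion_reason`` of "none" (or missing) keeps the record.  Retained
    records are returned unaltered (pure filter).
    """
    if len(registry) == 0:
        raise ValueError("empty registry")
    reasons = registry.get("exclusion_reason")
    if reasons is None:
        reasons = pd.Series("none", index=registry.index)
    reasons = reasons.fillna("none")
    excluded = reasons[reasons != "none"]
    report = {
        "registry_n": int(len(registry)),
        "retained_n": int((reasons == "none").sum()),
        "excluded_total": int(len(excluded)),
        "excluded_by_reason": {
            str(k): int(v) for k, v in excluded.value_counts().sort_index().items()
        },
    }
    return registry.loc[reasons == "none"].copy(), report


_DOMAIN_COLS = ("gait", "balance", "continence", "cognition")


def _row_domains(row: pd.Series, prefix: str) -> DomainScores:
    vals = {}
    for d in _DOMAIN_COLS:
        v = row.get(f"{prefix}_{d}", np.nan)
        vals[d] = None if pd.isna(v) else float(v)
    return DomainScores(**vals)


def score_cohort(cohort: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Add totals, deltas, responder flags and change categories per patient.

    Expects per-domain columns ``pre_<domain>`` / ``post_<domain>`` and
    optionally ``mmse_pre`` / ``mmse_post``.
    """
    out = cohort.copy()
    pre_tot, post_tot = [], []
    deltas: dict[str, list] = {f.name: [] for f in fields(DeltaScores)}
    for _, row in cohort.iterrows():
        pre = _row_domains(row, "pre")
        post = _row_domains(row, "post")
        pre_tot.append(total_inph_score(pre) if pre.available() else np.nan)
        post_tot.append(total_inph_score(post) if post.available() else np.nan)
        d = delta_scores(
            pre, post, row.get("mmse_pre", np.nan), row.get("mmse_post", np.nan),
            strict=strict,
        )
        for f in fields(DeltaScores):
            v = getattr(d, f.name)
            deltas[f.name].append(np.nan if v is None else v)
    out["pre_total"] = pre_tot
    out["post_total"] = post_tot
    for name, col in deltas.items():
        out[name] = col
    out["responder"] = np.where(
        out["delta_total"].isna(),
        np.nan,
        (out["delta_total"] >= RESPONDER_THRESHOLD - _EPS).astype(float),
    )
    out["inph_change"] = [
        mmse_change_category(0.0, d) if not pd.isna(d) else None
        for d in out["delta_total"]
    ]
    nan_col = pd.Series(np.nan, index=out.index)
    mpre = out["mmse_pre"] if "mmse_pre" in out else nan_col
    mpost = out["mmse_post"] if "mmse_post" in out else nan_col
    out["mmse_change"] = [mmse_change_category(a, b) for a, b in zip(mpre, mpost)]
    return out


def proportion_pct(count: int, total: int) -> int:
    """Proportion as a whole percent (nearest integer)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * count / total))


def paired_median_change(pre: np.ndarray, post: np.ndarray) -> dict[str, float]:
    """Paired medians and their decline (pre median minus post median)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise ValueError("pre and post must be non-empty and paired")
    m_pre, m_post = float(np.median(pre)), float(np.median(post))
    return {"median_pre": m_pre, "median_post": m_post, "decline": m_pre - m_post}


def _mean_sd(s: pd.Series) -> dict[str, float]:
    s = s.dropna()
    return {
        "n": int(len(s)),
        "mean": float(s.mean()) if len(s) else float("nan"),
        "sd": float(s.std(ddof=1)) if len(s) > 1 else float("nan"),
    }


def _median_iqr(s: pd.Series) -> dict[str, float]:
    s = s.dropna()
    if not len(s):
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    return {
        "n": int(len(s)),
        "median": float(s.median()),
        "q1": float(s.quantile(0.25)),
        "q3": float(s.quantile(0.75)),
    }


def _count_pct(flags: pd.Series) -> dict[str, float]:
    flags = flags.dropna().astype(bool)
    n = int(len(flags))
    k = int(flags.sum())
    return {"n": n, "count": k, "pct": proportion_pct(k, n) if n else float("nan")}


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Descriptive summary mirroring the study's baseline/outcome reporting:
    mean (SD) or median (IQR) per variable, counts (%) for flags, responder
    and improvement proportions, and paired gait-velocity medians when
    present."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out: dict = {"n": int(len(cohort))}
    if "age" in cohort:
        a = cohort["age"].dropna()
        out["age"] = {
            "n": int(len(a)),
            "mean": float(a.mean()),
            "min": float(a.min()),
            "max": float(a.max()),
        }
    if "sex" in cohort:
        male = cohort["sex"].astype(str).str.upper().isin(["M", "MALE", "1"])
        out["male"] = _count_pct(male)
    for flag in (
        "diabetes",
        "hyperlipidemia",
        "hypertension",
        "prior_ami",
        "prior_stroke",
        "aspirin",
        "anticoagulant",
        "desh",
    ):
        if flag in cohort:
            out[flag] = _count_pct(cohort[flag])
    if "pre_total" in cohort:
        out["pre_total"] = _mean_sd(cohort["pre_total"])
    for d in _DOMAIN_COLS:
        col = f"pre_{d}"
        if col in cohort:
            out[col] = _mean_sd(cohort[col])
    if "mmse_pre" in cohort:
        out["mmse_pre"] = _median_iqr(cohort["mmse_pre"])
    if "waiting_time_months" in cohort:
        out["waiting_time_months"] = _median_iqr(cohort["waiting_time_months"])
    for col in ("t_tau", "p_tau", "abeta42", "nfl", "pvh_ml", "dwmh_ml"):
        if col in cohort:
            out[col] = _median_iqr(cohort[col])
    if "ventricles_ml" in cohort:
        out["ventricles_ml"] = _mean_sd(cohort["ventricles_ml"])
    if "responder" in cohort:
        out["responder"] = _count_pct(cohort["responder"])
    for cat_col, key in (("inph_change", "inph"), ("mmse_change", "mmse")):
        if cat_col in cohort:
            cats = cohort[cat_col].dropna()
            n = int(len(cats))
            out[key + "_change"] = {
                "n": n,
                **{
                    c: {
                        "count": int((cats == c).sum()),
                        "pct": proportion_pct(int((cats == c).sum()), n) if n else None,
                    }
                    for c in ("improved", "unchanged", "reduced")
                },
            }
    if {"gait_velocity_baseline", "gait_velocity_presurgery"} <= set(cohort.columns):
        sub = cohort[["gait_velocity_baseline", "gait_velocity_presurgery"]].dropna()
        if len(sub):
            out["gait_velocity"] = {
                "n": int(len(sub)),
                **paired_median_change(
                    sub["gait_velocity_baseline"].to_numpy(),
                    sub["gait_velocity_presurgery"].to_numpy(),
                ),
            }
    return out
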