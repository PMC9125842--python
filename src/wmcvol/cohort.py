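"""Simulated shunt-surgery cohorts with known outcome-model coefficients.

The generator emulates the population structure the analyses assume: an
elderly iNPH cohort (age ~75, 56% male), right-skewed log-normal lesion and
ventricle volumes (periventricular median ~15 ml, deep ~2 ml, ventricles
mean ~129 ml, log-volume correlation ~0.75 between the two lesion
compartments), a baseline total symptom score of mean 49.8 SD 19.0
decomposed into four correlated domains with realistic per-domain
missingness, waiting times with median 6 months (IQR 4-8), comorbidity
prevalences, CSF biomarkers, and a configurable linear model for the
postoperative change in the total score ("delta total") with an explicit
coefficient per doubling of a chosen volume.

Only population-level structure is emulated: every anchor is a cohort
summary, not per-patient data.  Scores are truncated (not resampled) at
[0, 100], so the generating linear-model coefficient stays recoverable away
from the bounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LinearModel", "LogNormalSpec", "CohortSpec", "generate_cohort",
           "COLUMN_DICTIONARY"]

_Z_IQR = 1.3489795003921634  # standard-normal distance between the quartiles


@dataclass(frozen=True)
class LogNormalSpec:
    """Natural-log parameters of a log-normal volume/biomarker distribution."""

    mu: float
    sigma: float

    @classmethod
    def from_median_iqr(cls, median: float, q1: float, q3: float) -> "LogNormalSpec":
        """Moment matching from a printed median (IQR)."""
        return cls(math.log(median), (math.log(q3) - math.log(q1)) / _Z_IQR)

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float) -> "LogNormalSpec":
        s2 = math.log(1.0 + (sd / mean) ** 2)
        return cls(math.log(mean) - s2 / 2.0, math.sqrt(s2))


@dataclass(frozen=True)
class LinearModel:
    """intercept + sum(coefficients x columns) + Normal(0, residual_sd).

    Coefficient keys name cohort columns; ``log2_pvh_ml`` etc. refer to the
    log2-transformed volumes, matching how the analysis models are fit.
    """

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.intercept, self.residual_sd, *self.coefficients.values()]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite linear-model parameter")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.intercept, dtype=float)
        for col, beta in self.coefficients.items():
            if col not in table:
                raise KeyError(f"linear model refers to unknown column {col!r}")
            out += beta * table[col].to_numpy(dtype=float)
        return out


# Per-domain offsets from the total score and availability, anchored to the
# published per-domain means and per-row n of the study population.
_DOMAIN_OFFSETS = {"gait": -10.9, "balance": 14.5, "continence": 9.7, "cognition": -0.9}
_DOMAIN_MISSING = {"gait": 0.0, "balance": 9 / 253, "continence": 7 / 253,
                   "cognition": 155 / 253}
_DOMAIN_WEIGHTS = {"gait": 2.0, "balance": 1.0, "continence": 1.0, "cognition": 1.0}
_DOMAIN_DEV_SD = 12.0

_COMORBIDITY_PREVALENCE = {
    "diabetes": 63 / 253,
    "hyperlipidemia": 96 / 253,
    "hypertension": 162 / 253,
    "prior_ami": 37 / 253,
    "prior_stroke": 32 / 253,
    "aspirin": 102 / 253,
    "anticoagulant": 18 / 253,
}

_COMPLICATION_PREVALENCE = {
    "compl_subdural": 20 / 253,
    "compl_catheter": 27 / 253,
    "compl_ich": 2 / 253,
    "compl_infection": 5 / 253,
}

_BIOMARKER_MISSING = {"t_tau": 13 / 253, "p_tau": 17 / 253, "abeta42": 16 / 253,
                      "nfl": 178 / 253}


def _default_volumes() -> dict[str, LogNormalSpec]:
    return {
        "pvh_ml": LogNormalSpec.from_median_iqr(14.7, 5.8, 28.7),
        "dwmh_ml": LogNormalSpec.from_median_iqr(1.85, 0.75, 3.8),
        "ventricles_ml": LogNormalSpec.from_mean_sd(129.0, 42.0),
    }


def _default_biomarkers() -> dict[str, LinearModel]:
    # log2-scale linear predictors; T-tau carries the ventricular dilution
    # effect (lower tau with larger ventricles), the rest are null models.
    def iso(spec: LogNormalSpec) -> tuple[float, float]:
        return spec.mu / math.log(2), spec.sigma / math.log(2)

    t_tau = LogNormalSpec.from_median_iqr(211, 150, 326)
    p_tau = LogNormalSpec.from_median_iqr(30, 23, 39)
    abeta = LogNormalSpec.from_median_iqr(540, 378, 708)
    nfl = LogNormalSpec.from_median_iqr(1200, 790, 1730)
    vent_mean_log2 = LogNormalSpec.from_mean_sd(129.0, 42.0).mu / math.log(2)
    tt_mu, tt_sd = iso(t_tau)
    resid = math.sqrt(max(tt_sd**2 - (0.474 * 0.459) ** 2, 0.01))
    models = {
        "t_tau": LinearModel(
            tt_mu + 0.474 * vent_mean_log2, {"log2_ventricles_ml": -0.474}, resid
        ),
        "p_tau": LinearModel(iso(p_tau)[0], {}, iso(p_tau)[1]),
        "abeta42": LinearModel(iso(abeta)[0], {}, iso(abeta)[1]),
        "nfl": LinearModel(iso(nfl)[0], {}, iso(nfl)[1]),
    }
    return models


def _default_delta_model() -> LinearModel:
    # Mean delta ~5.3 (51% responders at the >=5 cut, ~60% improved) with a
    # negative effect per doubling of periventricular volume.
    mean_log2_pvh = math.log(14.7) / math.log(2)
    return LinearModel(5.3 + 1.2 * mean_log2_pvh, {"log2_pvh_ml": -1.2}, 20.9)


@dataclass
class CohortSpec:
    """Distributional description of one simulated registry."""

    n: int = 253
    seed: int = 0
    age_mean: float = 74.8
    age_sd: float = 6.5
    age_range: tuple[float, float] = (50.0, 89.0)
    male_fraction: float = 141 / 253
    waiting_time: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec.from_median_iqr(6.0, 4.0, 8.0)
    )
    volume_distributions: dict[str, LogNormalSpec] = field(
        default_factory=_default_volumes
    )
    # Pearson correlations on the log scale; 0.767 on log-volumes yields a
    # Spearman rank correlation of ~0.752 between the two lesion compartments
    # (r = 2 sin(pi r_s / 6) for bivariate normals).
    volume_log_corr: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.767, 0.30),
        (0.767, 1.0, 0.30),
        (0.30, 0.30, 1.0),
    )
    evans_mean: float = 0.38
    evans_sd: float = 0.035
    evans_bounds: tuple[float, float] = (0.2, 0.5)
    desh_prevalence: float = 0.55
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_COMORBIDITY_PREVALENCE)
    )
    complication_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_COMPLICATION_PREVALENCE)
    )
    baseline_score_model: LinearModel = field(
        default_factory=lambda: LinearModel(49.8, {}, 19.0)
    )
    delta_score_model: LinearModel = field(default_factory=_default_delta_model)
    biomarker_models: dict[str, LinearModel] = field(
        default_factory=_default_biomarkers
    )
    biomarker_missing: dict[str, float] = field(
        default_factory=lambda: dict(_BIOMARKER_MISSING)
    )
    domain_missing: dict[str, float] = field(
        default_factory=lambda: dict(_DOMAIN_MISSING)
    )
    domain_deviation_sd: float = _DOMAIN_DEV_SD
    mmse_mean: float = 24.7
    mmse_sd: float = 4.0
    mmse_missing: float = 4 / 253
    mmse_delta_mean: float = 0.28
    mmse_delta_sd: float = 2.2
    n_event_excluded: int = 0
    n_artifact_excluded: int = 0
    gait_velocity_subgroup_n: int = 11

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_event_excluded + self.n_artifact_excluded > self.n:
            raise ValueError("more exclusions than records")
        for m in (self.baseline_score_model, self.delta_score_model,
                  *self.biomarker_models.values()):
            if not np.isfinite(m.intercept):  # pragma: no cover - LinearModel validates
                raise ValueError("non-finite model parameter")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


def _decompose_domains(
    rng: np.random.Generator, total: np.ndarray, sd: float
) -> dict[str, np.ndarray]:
    """Split a total score into four clipped domain scores whose
    gait-double-weighted mean reproduces the total exactly.

    Raw domains are total + offset + deviation; a per-patient shift c is then
    found by bisection so that the weighted mean of clip(raw + c, 0, 100)
    equals the total, keeping the generated total recoverable from the
    domains despite the [0, 100] bounds."""
    names = list(_DOMAIN_WEIGHTS)
    w = np.array([_DOMAIN_WEIGHTS[k] for k in names])
    w = w / w.sum()
    n = total.size
    dev = rng.normal(0.0, sd, size=(n, len(names)))
    dev += np.array([_DOMAIN_OFFSETS[k] for k in names])
    dev -= dev @ w[:, None]
    raw = total[:, None] + dev
    lo = np.full(n, -250.0)
    hi = np.full(n, 250.0)
    for _ in range(50):
        mid = (lo + hi) / 2.0
        m = np.clip(raw + mid[:, None], 0.0, 100.0) @ w
        lo = np.where(m < total, mid, lo)
        hi = np.where(m < total, hi, mid)
    c = (lo + hi) / 2.0
    out = np.clip(raw + c[:, None], 0.0, 100.0)
    return {k: out[:, i] for i, k in enumerate(names)}


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one registry table; same spec and seed give identical output.

    The delta total score is generated as intercept + sum(coefficients x
    covariates) + noise; the responder label is derivable downstream (it is
    deliberately not stored).  Exclusion flags are assigned to the first
    records so the exclusion filter can be exercised.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    df = pd.DataFrame({"id": [f"P{i + 1:04d}" for i in range(n)]})
    df["age"] = np.clip(
        rng.normal(spec.age_mean, spec.age_sd, n), *spec.age_range
    ).round(0)
    df["sex"] = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    df["sex_male"] = (df["sex"] == "M").astype(int)
    wt = spec.waiting_time
    df["waiting_time_months"] = np.exp(rng.normal(wt.mu, wt.sigma, n)).round(1)
    df["evans_index"] = np.clip(
        rng.normal(spec.evans_mean, spec.evans_sd, n), *spec.evans_bounds
    ).round(3)
    df["desh"] = (rng.random(n) < spec.desh_prevalence).astype(int)
    for name, prev in spec.comorbidity_prevalences.items():
        df[name] = (rng.random(n) < prev).astype(int)
    for name, prev in spec.complication_prevalences.items():
        df[name] = (rng.random(n) < prev).astype(int)

    # Correlated log-normal volumes.
    vol_names = list(spec.volume_distributions)
    corr = np.asarray(spec.volume_log_corr, dtype=float)[: len(vol_names), : len(vol_names)]
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(vol_names))) @ chol.T
    for i, name in enumerate(vol_names):
        d = spec.volume_distributions[name]
        df[name] = np.exp(d.mu + d.sigma * z[:, i])
    if {"pvh_ml", "dwmh_ml"} <= set(df.columns):
        df["total_wmc_ml"] = df["pvh_ml"] + df["dwmh_ml"]
    for name in vol_names + (["total_wmc_ml"] if "total_wmc_ml" in df else []):
        df[f"log2_{name}"] = np.log2(df[name])

    # Baseline total and its decomposition into domains.
    base = spec.baseline_score_model
    pre_total = base.predict(df) + rng.normal(0.0, base.residual_sd, n)
    pre_total = np.clip(pre_total, 0.0, 100.0)
    df["pre_total_generated"] = pre_total
    pre_domains = _decompose_domains(rng, pre_total, spec.domain_deviation_sd)

    # Delta total and the postoperative decomposition.
    delta_model = spec.delta_score_model
    delta = delta_model.predict(df) + rng.normal(0.0, delta_model.residual_sd, n)
    post_total = np.clip(pre_total + delta, 0.0, 100.0)
    post_domains = _decompose_domains(rng, post_total, spec.domain_deviation_sd)

    avail = {
        d: rng.random(n) >= spec.domain_missing.get(d, 0.0) for d in _DOMAIN_WEIGHTS
    }
    for d in _DOMAIN_WEIGHTS:
        df[f"pre_{d}"] = np.where(avail[d], pre_domains[d], np.nan)
        df[f"post_{d}"] = np.where(avail[d], post_domains[d], np.nan)

    mmse_avail = rng.random(n) >= spec.mmse_missing
    mmse_pre = np.clip(
        np.round(rng.normal(spec.mmse_mean, spec.mmse_sd, n)), 0, 30
    )
    mmse_delta = np.round(rng.normal(spec.mmse_delta_mean, spec.mmse_delta_sd, n))
    mmse_post = np.clip(mmse_pre + mmse_delta, 0, 30)
    df["mmse_pre"] = np.where(mmse_avail, mmse_pre, np.nan)
    df["mmse_post"] = np.where(mmse_avail, mmse_post, np.nan)

    for name, model in spec.biomarker_models.items():
        log2_val = model.predict(df) + rng.normal(0.0, model.residual_sd, n)
        vals = np.power(2.0, log2_val).round(0)
        miss = rng.random(n) < spec.biomarker_missing.get(name, 0.0)
        df[name] = np.where(miss, np.nan, vals)

    # Gait-velocity waiting-period subgroup (baseline vs day before surgery).
    k = min(spec.gait_velocity_subgroup_n, n)
    gv_pre = np.full(n, np.nan)
    gv_post = np.full(n, np.nan)
    if k:
        base_v = np.exp(rng.normal(math.log(0.66), 0.45, k))
        decline = rng.normal(0.08, 0.06, k)
        gv_pre[:k] = np.clip(base_v, 0.05, 2.0).round(2)
        gv_post[:k] = np.clip(base_v - decline, 0.05, 2.0).round(2)
    df["gait_velocity_baseline"] = gv_pre
    df["gait_velocity_presurgery"] = gv_post

    reasons = np.array(["none"] * n, dtype=object)
    reasons[: spec.n_event_excluded] = "non-shunt event"
    reasons[spec.n_event_excluded : spec.n_event_excluded + spec.n_artifact_excluded] = (
        "artifact"
    )
    df["exclusion_reason"] = reasons
    return df.drop(columns=["pre_total_generated"])


COLUMN_DICTIONARY: dict[str, str] = {
    "id": "patient identifier",
    "age": "age at preoperative evaluation, years",
    "sex": "M/F",
    "sex_male": "1 if male",
    "waiting_time_months": "preoperative evaluation to surgery, months",
    "evans_index": "frontal-horn to inner-skull width ratio",
    "desh": "disproportionately enlarged subarachnoid-space hydrocephalus flag",
    "diabetes": "comorbidity flag", "hyperlipidemia": "comorbidity flag",
    "hypertension": "comorbidity flag", "prior_ami": "comorbidity flag",
    "prior_stroke": "comorbidity flag", "aspirin": "medication flag",
    "anticoagulant": "medication flag",
    "compl_subdural": "postoperative subdural hematoma/hygroma flag",
    "compl_catheter": "displaced/migrated shunt catheter flag",
    "compl_ich": "intracerebral hematoma flag",
    "compl_infection": "shunt infection flag",
    "pvh_ml": "periventricular hyperintensity volume, ml",
    "dwmh_ml": "deep white-matter hyperintensity volume, ml",
    "ventricles_ml": "lateral-ventricle volume, ml",
    "total_wmc_ml": "total white-matter-change volume, ml",
    "log2_pvh_ml": "log2 of pvh_ml (analysis scale)",
    "log2_dwmh_ml": "log2 of dwmh_ml",
    "log2_ventricles_ml": "log2 of ventricles_ml",
    "log2_total_wmc_ml": "log2 of total_wmc_ml",
    "pre_gait": "baseline gait domain score 0-100 (100 = no symptoms)",
    "pre_balance": "baseline balance domain score",
    "pre_continence": "baseline continence domain score",
    "pre_cognition": "baseline cognitive domain score",
    "post_gait": "12-month gait domain score",
    "post_balance": "12-month balance domain score",
    "post_continence": "12-month continence domain score",
    "post_cognition": "12-month cognitive domain score",
    "mmse_pre": "baseline MMSE 0-30", "mmse_post": "12-month MMSE 0-30",
    "t_tau": "CSF total tau, ng/L", "p_tau": "CSF phosphorylated tau, ng/L",
    "abeta42": "CSF amyloid beta 1-42, ng/L",
    "nfl": "CSF neurofilament light, ng/L",
    "gait_velocity_baseline": "gait velocity at first evaluation, m/s (subgroup)",
    "gait_velocity_presurgery": "gait velocity the day before surgery, m/s (subgroup)",
    "exclusion_reason": "none | non-shunt event | artifact",
}
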