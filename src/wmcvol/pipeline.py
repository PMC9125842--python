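"""End-to-end orchestration: phantoms -> segmentation -> partition -> scoring
-> statistics -> report, under a single JSON config and one master seed.

Every stochastic stage draws its seed from a named substream of the master
seed, so re-running the same config reproduces identical outputs; the run
manifest records parameters, seeds and SHA-256 hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman_plot, icc_absolute_agreement
from .cohort import COLUMN_DICTIONARY, CohortSpec, generate_cohort
from .partition import build_pvh_mask, measure_volumes, partition_wmc, volume_of
from .phantom import PhantomSpec, generate_phantom, random_phantom_spec
from .scores import apply_exclusions, cohort_summary, score_cohort
from .segmentation import (
    ThresholdRange,
    auto_min_percent,
    clean_mask,
    denoise,
    intensity_to_percent,
    normalize_intensity,
    remove_pencil_thin_lining,
    segment_ventricles,
    threshold_segment,
)
from .stats import build_report, log2_volumes, spearman_corr
from .types import BinaryMask, LesionVolumes, VolumeImage

__all__ = ["RunConfig", "measure_subject", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage substream seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def measure_subject(
    image: VolumeImage,
    brain_mask: BinaryMask,
    ventricle_seeds: list[tuple[int, int, int]],
    pvh_mask_width_mm: float,
    min_percent: float | None = None,
    raw_min_intensity: float | None = None,
    denoise_method: str | None = None,
    rim_max_thickness_mm: float = 2.0,
    ventricle_tolerance: float = 20.0,
    min_object_vox: int = 10,
    max_hole_vox: int = 64,
) -> dict:
    """Run the full per-subject volumetry: normalize, threshold, clean,
    strip the ependymal rim, grow the ventricles, build the periventricular
    mask and partition.

    The minimum threshold is per-subject: pass ``min_percent`` directly, or
    ``raw_min_intensity`` on the raw scale (converted through the same
    normalization), or neither to fall back to the Otsu default.  Returns
    masks, volumes under the mask rule and under the continuity rule.
    """
    work = denoise(image, method=denoise_method) if denoise_method else image
    norm = normalize_intensity(work, brain_mask)
    if min_percent is None:
        if raw_min_intensity is not None:
            min_percent = intensity_to_percent(raw_min_intensity, work, brain_mask)
        else:
            min_percent = auto_min_percent(norm, brain_mask)
    wmc_raw = threshold_segment(norm, brain_mask, ThresholdRange(min_percent, 100.0))
    wmc_clean = clean_mask(wmc_raw, min_size_vox=min_object_vox, max_hole_vox=max_hole_vox)
    ventricles = segment_ventricles(
        norm, ventricle_seeds, brain_mask=brain_mask, tolerance=ventricle_tolerance
    )
    wmc = remove_pencil_thin_lining(
        wmc_clean - ventricles, ventricles, rim_max_thickness_mm
    )
    pvh_mask = build_pvh_mask(ventricles, brain_mask, pvh_mask_width_mm)
    pvh, dwmh = partition_wmc(wmc, pvh_mask)
    volumes = LesionVolumes(
        total_wmc_ml=volume_of(pvh) + volume_of(dwmh),
        pvh_ml=volume_of(pvh),
        dwmh_ml=volume_of(dwmh),
        ventricles_ml=volume_of(ventricles),
    )
    volumes_continuity = measure_volumes(wmc, ventricles, rule="continuity")
    return {
        "min_percent": float(min_percent),
        "wmc": wmc,
        "ventricles": ventricles,
        "pvh": pvh,
        "dwmh": dwmh,
        "pvh_mask": pvh_mask,
        "volumes": volumes,
        "volumes_continuity": volumes_continuity,
    }


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str
    seed: int = 0
    n_phantoms: int = 3
    phantom_size: str = "compact"  # compact | default
    phantom_noise_sd: float = 0.0
    denoise_method: str | None = None  # set to "median" for noisy phantoms
    rim_max_thickness_mm: float = 2.0
    cohort_n: int = 250
    cohort_overrides: dict = field(default_factory=dict)
    write_nifti: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def as_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "n_phantoms": self.n_phantoms,
            "phantom_size": self.phantom_size,
            "phantom_noise_sd": self.phantom_noise_sd,
            "denoise_method": self.denoise_method,
            "rim_max_thickness_mm": self.rim_max_thickness_mm,
            "cohort_n": self.cohort_n,
            "cohort_overrides": self.cohort_overrides,
            "write_nifti": self.write_nifti,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict = {
        "tool": "wmcvol",
        "version": __version__,
        "config": config.as_dict(),
        "stage_seeds": {},
    }

    # Stage 1: phantoms -> segmentation -> partition.
    phantom_rows = []
    mask_pvh, cont_pvh = [], []
    for i in range(config.n_phantoms):
        sub = stage_seed(config.seed, "phantom", i)
        manifest["stage_seeds"][f"phantom_{i}"] = sub
        try:
            spec = random_phantom_spec(
                sub, noise_sd=config.phantom_noise_sd, size=config.phantom_size
            )
            image, truth = generate_phantom(spec)
            wm = spec.intensity_means["white_matter"]
            wmc_mean = spec.intensity_means["wmc"]
            result = measure_subject(
                image,
                truth.brain_mask,
                truth.ventricle_seeds,
                pvh_mask_width_mm=truth.suggested_mask_width_mm,
                raw_min_intensity=(wm + wmc_mean) / 2.0,
                denoise_method=config.denoise_method,
                rim_max_thickness_mm=config.rim_max_thickness_mm,
            )
        except Exception as exc:
            raise RuntimeError(f"stage phantom failed for subject phantom_{i}: {exc}") from exc
        if config.write_nifti:
            pdir = out / "phantoms"
            pdir.mkdir(exist_ok=True)
            image.save(pdir / f"phantom_{i}.nii.gz")
            truth.save(pdir, stem=f"phantom_{i}")
            result["wmc"].save(pdir / f"phantom_{i}_wmc_seg.nii.gz")
            artifacts += sorted(pdir.glob(f"phantom_{i}*.nii.gz"))
        vols, tv = result["volumes"], truth.true_volumes
        phantom_rows.append(
            {
                "subject": f"phantom_{i}",
                "noise_sd": config.phantom_noise_sd,
                "min_percent": result["min_percent"],
                **{f"true_{k}": v for k, v in tv.as_dict().items()},
                **{f"measured_{k}": v for k, v in vols.as_dict().items()},
                **{
                    f"continuity_{k}": v
                    for k, v in result["volumes_continuity"].as_dict().items()
                },
            }
        )
        mask_pvh.append(vols.pvh_ml)
        cont_pvh.append(result["volumes_continuity"].pvh_ml)
    phantom_table = pd.DataFrame(phantom_rows)
    phantom_csv = out / "phantom_volumes.csv"
    phantom_table.to_csv(phantom_csv, index=False)
    artifacts.append(phantom_csv)

    # Stage 2: method agreement between the two partition rules.
    agreement: dict = {}
    if config.n_phantoms >= 3:
        icc = icc_absolute_agreement(mask_pvh, cont_pvh)
        ba = bland_altman_plot(mask_pvh, cont_pvh, out / "bland_altman.png")
        agreement = {
            "icc": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
            "mean_diff_ml": ba.mean_diff, "loa_low_ml": ba.loa_low,
            "loa_high_ml": ba.loa_high, "n": icc.n,
        }
        agr_path = out / "agreement.json"
        agr_path.write_text(json.dumps(agreement, indent=2))
        artifacts.append(agr_path)

    # Stage 3: cohort simulation, scoring, exclusions, statistics.
    cohort_seed = stage_seed(config.seed, "cohort")
    manifest["stage_seeds"]["cohort"] = cohort_seed
    cspec = CohortSpec(n=config.cohort_n, seed=cohort_seed, **config.cohort_overrides)
    registry = generate_cohort(cspec)
    registry_csv = out / "registry.csv"
    registry.to_csv(registry_csv, index=False)
    artifacts.append(registry_csv)
    cohort, exclusion_report = apply_exclusions(registry)
    scored = score_cohort(cohort)
    scored = log2_volumes(scored)
    scored_csv = out / "scored_cohort.csv"
    scored.to_csv(scored_csv, index=False)
    artifacts.append(scored_csv)

    summary = cohort_summary(scored)
    rs, rp = spearman_corr(scored["pvh_ml"], scored["dwmh_ml"])
    summary["pvh_dwmh_spearman"] = {"r_s": rs, "p_value": rp}
    summary["exclusions"] = exclusion_report
    summary_path = out / "cohort_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    artifacts.append(summary_path)

    report = build_report(scored)
    for name, table in report.items():
        if isinstance(table, pd.DataFrame):
            p = out / f"report_{name}.csv"
            table.to_csv(p, index=False)
            artifacts.append(p)
    (out / "report_note.txt").write_text(str(report["note"]) + "\n")
    artifacts.append(out / "report_note.txt")
    (out / "column_dictionary.json").write_text(json.dumps(COLUMN_DICTIONARY, indent=2))
    artifacts.append(out / "column_dictionary.json")

    manifest["phantom_recovery"] = {
        "max_abs_rel_error": _max_rel_error(phantom_table),
    }
    manifest["agreement"] = agreement
    manifest["artifacts"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", manifest_path)
    return manifest


def _max_rel_error(table: pd.DataFrame) -> float:
    worst = 0.0
    for comp in ("pvh_ml", "dwmh_ml", "ventricles_ml"):
        t = table[f"true_{comp}"].to_numpy()
        m = table[f"measured_{comp}"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(m - t) / np.where(t > 0, t, np.nan)
        worst = max(worst, float(np.nanmax(rel)) if np.isfinite(rel).any() else 0.0)
    return worst
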