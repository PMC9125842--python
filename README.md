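# wmcvol

White-matter-change (WMC) volumetry and shunt-outcome analysis for idiopathic
normal pressure hydrocephalus (iNPH) imaging studies.

On FLAIR MRI, WMC appear as hyperintense white-matter lesions and are
conventionally split into **periventricular hyperintensities (PVH)** —
adjacent to the lateral ventricles — and **deep white-matter hyperintensities
(DWMH)** — separated from the ventricles by normal-appearing white matter.
Whether the preoperative burden of either compartment predicts the outcome of
CSF shunt surgery is a recurring clinical question. `wmcvol` implements a
semi-automatic volumetry pipeline for this setting, the agreement statistics
used to validate it, and the outcome-analysis battery applied downstream —
all exercisable on synthetic phantoms and simulated cohorts with known ground
truth, so every stage can be tested against exact answers.

It is aimed at researchers in neuroimaging methods and clinical outcome
analysis who need a scriptable, reproducible reference implementation of this
workflow rather than an interactive segmentation GUI.

## What it computes

**Segmentation.** Per-subject intensity normalization maps the in-brain range
to a 0–100% scale; WMC are the voxels of a brain search mask whose intensity
lies in a closed threshold interval `[min%, 100%]`, the minimum customized per
subject. Scripted 3D brush strokes (weights decreasing in both spatial and
intensity distance) replace interactive editing; the lateral ventricles are
grown from seed points as a connected CSF-intensity region; the pencil-thin
ependymal rim — a normal ageing finding — is stripped from the lesion mask.

**Partition and volumes.** The default rule intersects the WMC mask with a
periventricular search mask (ventricles dilated by an operator-chosen width
*w*): PVH = WMC ∩ mask, DWMH = WMC ∖ mask. The alternative
continuity-to-ventricle rule assigns whole connected lesions touching the
ventricular surface to PVH. Volumes are voxel counts × voxel volume (ml), and
by construction V(WMC) = V(PVH) + V(DWMH) exactly.

**Clinical scoring.** The iNPH scale total is the gait-double-weighted mean
of the available domain scores (gait, balance, continence, cognition; each
0–100). Shunt outcome is Δtotal = post − pre; Δtotal ≥ 5 defines a responder.

**Statistics.** Volumes and CSF biomarkers are log2-transformed, so a
regression coefficient *B* is the change in outcome per doubling of volume.
One OLS model is fitted per (outcome, volume) pair with frozen covariate
sets; group contrasts use the Mann–Whitney U test, paired change the paired
t-test (total score) or Wilcoxon signed-rank (MMSE, domains), correlation
Spearman's r_s. Method agreement uses ICC(A,1) (two-way random effects,
absolute agreement, single rater) with an F-based 95% CI, plus Bland–Altman
limits of agreement.

**Synthetic ground truth.** A phantom generator renders FLAIR-like brains
(ellipsoidal ventricles, periventricular caps, isolated deep spheres, a
1-voxel ependymal rim, Gaussian noise) with voxel-exact truth masks; a cohort
generator simulates registries with the demographic, volumetric and
outcome-model structure the analyses assume, including a configurable
per-doubling volume effect on Δtotal.

## Worked example

```python
from wmcvol.phantom import PhantomSpec, generate_phantom
from wmcvol.pipeline import measure_subject

spec = PhantomSpec(noise_sd=8.0, seed=42)        # noise at 20% of the WM-WMC gap
image, truth = generate_phantom(spec)
res = measure_subject(
    image, truth.brain_mask, truth.ventricle_seeds,
    pvh_mask_width_mm=truth.suggested_mask_width_mm,
    raw_min_intensity=70.0,                      # midpoint of WM (50) and WMC (90)
    denoise_method="median",
)
print("true:    ", truth.true_volumes.as_dict())
print("measured:", res["volumes"].as_dict())
```

prints

```
true:     {'total_wmc_ml': 16.09, 'pvh_ml': 14.16, 'dwmh_ml': 1.93, 'ventricles_ml': 14.75}
measured: {'total_wmc_ml': 16.0,  'pvh_ml': 14.11, 'dwmh_ml': 1.9,  'ventricles_ml': 14.73}
```

i.e. despite heavy noise every compartment is recovered within a fraction of
a millilitre (all well under 5% relative error); with `noise_sd=0` the
recovery is voxel-exact. The cohort side works the same way:

```bash
wmcvol simulate-cohort --out cohort.csv --n 262 --seed 1
wmcvol score --cohort cohort.csv --out scored.csv
wmcvol analyze --cohort scored.csv --out report/
```

`report/` then contains the responder/non-responder volume contrasts, the
Δ-score regressions (unadjusted and covariate-adjusted *B* and *p* per
volume), the baseline-score and biomarker models, and a cohort summary. A
full phantom-plus-cohort run with a manifest is `wmcvol run --config run.json`.

## Layout

| module | contents |
|---|---|
| `wmcvol.types` | `VolumeImage`, `BinaryMask`, `LesionVolumes`, NIfTI I/O |
| `wmcvol.phantom` / `wmcvol.cohort` | synthetic ground-truth generators |
| `wmcvol.segmentation` | normalization, thresholding, brush strokes, ventricle growing, rim removal |
| `wmcvol.partition` | PVH mask, both partition rules, volume conversion |
| `wmcvol.scores` | iNPH-scale scoring, deltas, responders, exclusions, summaries |
| `wmcvol.agreement` | ICC(A,1) with CI, Bland–Altman |
| `wmcvol.stats` | log2 transforms, OLS battery, rank tests, report tables |
| `wmcvol.pipeline` / `wmcvol.cli` | orchestration, manifest, `wmcvol` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
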