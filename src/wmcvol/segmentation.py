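"""Threshold segmentation of white-matter changes with scripted brush editing.

The operators here mirror a semi-automatic FLAIR workflow: per-subject
intensity normalization to a 0-100 percent scale, closed-interval threshold
segmentation inside a search mask, 3D brush strokes that add or remove voxels
weighted by spatial and intensity (range) distance, seeded region growing for
the lateral ventricles, and removal of the thin ependymal rim ("pencil-thin
lining") that is a normal finding and must not count as lesion volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .types import BinaryMask, VolumeImage, check_aligned

__all__ = [
    "ThresholdRange",
    "Stroke",
    "normalize_intensity",
    "intensity_to_percent",
    "auto_min_percent",
    "denoise",
    "threshold_segment",
    "clean_mask",
    "paint",
    "segment_ventricles",
    "remove_pencil_thin_lining",
]


def _structure(connectivity: int) -> np.ndarray:
    """3D structuring element: 26-neighbourhood by default, 6 optional."""
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass(frozen=True)
class ThresholdRange:
    """Closed intensity interval on the normalized 0-100 percent scale.

    The maximum is conventionally kept at 100 for every subject while the
    minimum is customized per subject so that all lesions are included.
    """

    min_percent: float
    max_percent: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_percent <= 100.0 and 0.0 <= self.max_percent <= 100.0):
            raise ValueError("threshold percents must lie in [0, 100]")
        if self.min_percent > self.max_percent:
            raise ValueError(
                f"min_percent {self.min_percent} > max_percent {self.max_percent}"
            )


@dataclass
class Stroke:
    """One scripted brush stroke.

    label: "add" or "remove"; voxels: 0-based voxel coordinates painted over;
    spatial_radius in mm bounds the spatial reach, range_width (intensity
    units) bounds how far in intensity from the stroke's mean a voxel may be
    and still be affected.
    """

    label: str
    voxels: list[tuple[int, int, int]]
    spatial_radius: float
    range_width: float

    def __post_init__(self) -> None:
        if self.label not in ("add", "remove"):
            raise ValueError(f"stroke label must be 'add' or 'remove', got {self.label!r}")
        if len(self.voxels) == 0:
            raise ValueError("stroke has no voxels")
        if self.spatial_radius <= 0 or self.range_width <= 0:
            raise ValueError("spatial_radius and range_width must be > 0")


def normalize_intensity(
    image: VolumeImage,
    brain_mask: BinaryMask,
    ceiling_percentile: float | None = None,
) -> VolumeImage:
    """Rescale so the in-brain minimum maps to 0 and the maximum to 100.

    Outside-mask voxels are carried through the same linear transform.  With
    ``ceiling_percentile`` set (e.g. 99.9), that percentile of in-brain
    intensities defines 100 instead of the maximum and the result is clipped
    to [0, 100] - a robust variant for noisy inputs.
    """
    check_aligned(image, brain_mask)
    if brain_mask.is_empty():
        raise ValueError("brain mask is empty")
    inside = image.values[brain_mask.values]
    vmin = float(inside.min())
    if ceiling_percentile is None:
        vmax = float(inside.max())
    else:
        vmax = float(np.percentile(inside, ceiling_percentile))
    if vmax <= vmin:
        raise ValueError("constant image within brain mask; cannot normalize")
    scaled = (image.values - vmin) / (vmax - vmin) * 100.0
    if ceiling_percentile is not None:
        scaled = np.clip(scaled, 0.0, 100.0)
    return image.with_values(scaled)


def intensity_to_percent(
    raw_value: float, image: VolumeImage, brain_mask: BinaryMask
) -> float:
    """Map a raw intensity to the percent scale normalize_intensity produces."""
    check_aligned(image, brain_mask)
    inside = image.values[brain_mask.values]
    vmin, vmax = float(inside.min()), float(inside.max())
    if vmax <= vmin:
        raise ValueError("constant image within brain mask")
    return (raw_value - vmin) / (vmax - vmin) * 100.0


def auto_min_percent(
    image: VolumeImage, brain_mask: BinaryMask, floor_percent: float = 40.0
) -> float:
    """Automatic default for the per-subject minimum threshold.

    Otsu's threshold over in-brain normalized intensities above
    ``floor_percent`` (the white-matter window, excluding CSF).  Always
    overridable: the interactive procedure it stands in for chose the minimum
    per subject.
    """
    check_aligned(image, brain_mask)
    vals = image.values[brain_mask.values]
    vals = vals[vals >= floor_percent]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("too little intensity spread above floor for Otsu")
    return float(threshold_otsu(vals))


def denoise(image: VolumeImage, method: str = "median", size_mm: float = 1.0) -> VolumeImage:
    """Edge-preserving pre-filter for noisy images.

    "median" uses a 6-neighbourhood-plus-centre median (edge preserving and
    unbiased at intensity steps); "gaussian" uses a Gaussian of ``size_mm``.
    """
    if method == "median":
        footprint = ndimage.generate_binary_structure(3, 1)
        out = ndimage.median_filter(image.values, footprint=footprint)
    elif method == "gaussian":
        sigma_vox = [size_mm / v for v in image.voxel_size]
        out = ndimage.gaussian_filter(image.values, sigma=sigma_vox)
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return image.with_values(out)


def threshold_segment(
    image: VolumeImage, search_mask: BinaryMask, trange: ThresholdRange
) -> BinaryMask:
    """Voxels of the search mask whose intensity lies in the closed range."""
    check_aligned(image, search_mask)
    if search_mask.is_empty():
        warnings.warn("empty search mask; returning empty segmentation", stacklevel=2)
        return search_mask.with_values(np.zeros(search_mask.shape, dtype=bool))
    sel = (
        search_mask.values
        & (image.values >= trange.min_percent)
        & (image.values <= trange.max_percent)
    )
    return search_mask.with_values(sel)


def clean_mask(
    mask: BinaryMask, min_size_vox: int = 10, max_hole_vox: int = 64
) -> BinaryMask:
    """Remove speckle components and fill small holes.

    Identity on noise-free segmentations (no components below ``min_size_vox``
    and no enclosed holes below ``max_hole_vox``).
    """
    out = remove_small_objects(mask.values, max_size=min_size_vox - 1)
    out = remove_small_holes(out, max_size=max_hole_vox - 1)
    return mask.with_values(out)


def _stroke_weights(
    image: VolumeImage, stroke: Stroke
) -> np.ndarray:
    """Per-voxel membership weight: linear spatial falloff x linear range falloff.

    Strictly decreasing in the Euclidean distance to the nearest stroke voxel
    and in the absolute intensity difference from the stroke's mean intensity;
    exactly zero beyond spatial_radius or range_width.
    """
    idx = np.asarray(stroke.voxels, dtype=np.intp)
    if idx.ndim != 2 or idx.shape[1] != 3:
        raise ValueError("stroke voxels must be (i, j, k) triples")
    shape = np.asarray(image.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        bad = idx[np.any((idx < 0) | (idx >= shape), axis=1)][0]
        raise ValueError(f"stroke voxel {tuple(int(v) for v in bad)} outside grid")
    seed = np.zeros(image.shape, dtype=bool)
    seed[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~seed, sampling=image.voxel_size)
    mean_intensity = float(image.values[seed].mean())
    w_spatial = np.clip(1.0 - dist / stroke.spatial_radius, 0.0, 1.0)
    w_range = np.clip(
        1.0 - np.abs(image.values - mean_intensity) / stroke.range_width, 0.0, 1.0
    )
    return w_spatial * w_range


def paint(image: VolumeImage, mask: BinaryMask, stroke: Stroke) -> BinaryMask:
    """Apply one brush stroke in 3D: voxels with membership weight >= 0.5 are
    added (label "add") or removed (label "remove"); all other voxels keep
    their prior state."""
    check_aligned(image, mask)
    weights = _stroke_weights(image, stroke)
    affected = weights >= 0.5
    out = mask.values.copy()
    if stroke.label == "add":
        out[affected] = True
    else:
        out[affected] = False
    return mask.with_values(out)


def segment_ventricles(
    image: VolumeImage,
    seeds: list[tuple[int, int, int]],
    brain_mask: BinaryMask | None = None,
    tolerance: float = 20.0,
    csf_ceiling: float = 35.0,
    connectivity: int = 26,
) -> BinaryMask:
    """Seeded region growing for the lateral ventricles.

    Grows the connected low-intensity (CSF) region containing each seed:
    candidate voxels differ from the mean seed intensity by at most
    ``tolerance`` (normalized percent units); connected components not
    containing a seed are discarded.  Restricted to ``brain_mask`` if given.
    Seeds brighter than ``csf_ceiling`` are rejected as non-CSF.
    """
    if not seeds:
        raise ValueError("at least one seed voxel is required")
    shape = np.asarray(image.shape)
    vals = image.values
    for s in seeds:
        si = np.asarray(s, dtype=np.intp)
        if np.any(si < 0) or np.any(si >= shape):
            raise ValueError(f"seed {tuple(s)} outside grid")
        if vals[tuple(si)] > csf_ceiling:
            raise ValueError(
                f"seed {tuple(s)} lies in non-CSF intensity "
                f"({vals[tuple(si)]:.1f} > ceiling {csf_ceiling})"
            )
    ref = float(np.mean([vals[tuple(s)] for s in seeds]))
    candidate = np.abs(vals - ref) <= tolerance
    if brain_mask is not None:
        check_aligned(image, brain_mask)
        candidate &= brain_mask.values
    labels, _ = ndimage.label(candidate, structure=_structure(connectivity))
    keep = {int(labels[tuple(s)]) for s in seeds} - {0}
    out = np.isin(labels, sorted(keep))
    vs, aff = image.voxel_size, image.affine
    return BinaryMask(out, vs, aff)


def remove_pencil_thin_lining(
    wmc: BinaryMask,
    ventricles: BinaryMask,
    max_thickness: float,
    connectivity: int = 26,
) -> BinaryMask:
    """Strip the thin ependymal rim from a WMC segmentation.

    A candidate voxel lies within ``max_thickness`` mm of the ventricle
    surface (Euclidean distance transform).  Connected candidate components
    are removed when they (a) touch the ventricle surface and (b) have no
    adjacency to WMC deeper than ``max_thickness`` - so a genuinely thin rim
    disappears entirely while thick ventricle-adjacent lesions (caps, halos)
    are retained in full, including their tapered margins.
    """
    if max_thickness <= 0:
        raise ValueError(f"max_thickness must be > 0, got {max_thickness}")
    check_aligned(wmc, ventricles)
    struct = _structure(connectivity)
    dist = ndimage.distance_transform_edt(~ventricles.values, sampling=wmc.voxel_size)
    lesion = wmc.values & ~ventricles.values
    candidate = lesion & (dist <= max_thickness)
    if not candidate.any():
        return wmc.with_values(wmc.values.copy())
    deep = lesion & (dist > max_thickness)
    vent_adjacent = ndimage.binary_dilation(ventricles.values, structure=struct)
    deep_adjacent = ndimage.binary_dilation(deep, structure=struct)
    labels, n = ndimage.label(candidate, structure=struct)
    if n:
        touches_vent = ndimage.labeled_comprehension(
            vent_adjacent, labels, np.arange(1, n + 1), np.any, bool, False
        )
        supported = ndimage.labeled_comprehension(
            deep_adjacent, labels, np.arange(1, n + 1), np.any, bool, False
        )
        drop = np.flatnonzero(touches_vent & ~supported) + 1
        remove = np.isin(labels, drop)
    else:
        remove = np.zeros_like(candidate)
    return wmc.with_values(wmc.values & ~remove)
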