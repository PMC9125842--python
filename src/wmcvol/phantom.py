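"""FLAIR-like 3D phantoms with exact ground-truth compartment volumes.

A phantom emulates the geometry the volumetry pipeline must handle: an
ellipsoidal brain with a thin cortical shell, two ellipsoidal lateral
ventricles filled with CSF, hyperintense periventricular lesions (ellipsoid
caps at the ventricle poles, optionally a full halo shell), isolated deep
spherical lesions separated from the periventricular zone by normal white
matter, a pencil-thin ependymal rim around the ventricles, and additive
Gaussian noise.  Truth masks are voxelized analytically, so true volumes are
exact integer multiples of the voxel volume.

What the phantom does not emulate: bias fields, partial-volume mixing,
multi-sequence contrast, anatomical ventricle shape.  Tests passing on
phantoms show that the geometric operators are correct, not that the
pipeline handles real-scanner artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
from scipy import ndimage

from .partition import volume_of
from .types import BinaryMask, LesionVolumes, VolumeImage

__all__ = [
    "CapSpec",
    "SphereSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "random_phantom_spec",
]

# Grey matter defaults to the white-matter mean so that any threshold strictly
# between WM and WMC recovers the lesion compartment exactly on noise-free
# phantoms; override intensity_means["grey_matter"] (e.g. 60) to emulate the
# hyperintense cortex that brush editing must then clean up.
DEFAULT_INTENSITIES = {
    "background": 0.0,
    "csf": 10.0,
    "white_matter": 50.0,
    "grey_matter": 50.0,
    "wmc": 90.0,
}


@dataclass(frozen=True)
class CapSpec:
    """Ellipsoidal periventricular cap attached to a ventricle pole.

    ventricle: 0 (left) or 1 (right); pole: -1 (posterior) or +1 (anterior);
    axes: semi-axes in mm.  The cap is centred on the pole, so roughly half
    of it protrudes into white matter.
    """

    ventricle: int
    pole: int
    axes: tuple[float, float, float]


@dataclass(frozen=True)
class SphereSpec:
    """Isolated deep lesion: centre in mm grid coordinates, radius in mm."""

    center: tuple[float, float, float]
    radius: float


@dataclass
class PhantomSpec:
    """Full geometric and intensity description of one phantom."""

    grid_shape: tuple[int, int, int] = (96, 112, 96)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes: tuple[float, float, float] = (40.0, 52.0, 40.0)
    cortex_thickness: float = 3.0
    ventricle_axes: tuple[float, float, float] = (8.0, 22.0, 10.0)
    ventricle_offset: float = 12.0  # lateral shift of each ventricle centre, mm
    pvh_halo_width: float = 0.0  # 0 disables the halo shell
    cap_specs: list[CapSpec] = field(
        default_factory=lambda: [
            CapSpec(v, p, (11.0, 8.0, 11.0)) for v in (0, 1) for p in (-1, 1)
        ]
    )
    dwmh_specs: list[SphereSpec] = field(
        default_factory=lambda: [
            SphereSpec((48.0, 94.0, 52.0), 7.0),
            SphereSpec((48.0, 18.0, 52.0), 5.0),
        ]
    )
    rim_thickness: int = 1  # voxels
    rim_cap_gap: float = 3.0  # mm kept clear between rim and thick lesions
    deep_clearance: float = 10.0  # min distance (mm) ventricle surface -> deep lesion
    intensity_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_size", "brain_axes", "ventricle_axes"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} entries must be > 0")
        if self.cortex_thickness < 0 or self.rim_thickness < 0:
            raise ValueError("thicknesses must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        im = self.intensity_means
        if not (im["wmc"] > im["white_matter"] > im["csf"]):
            raise ValueError(
                "intensity ordering must satisfy wmc > white_matter > csf"
            )
        if self.pvh_halo_width >= self.deep_clearance:
            raise ValueError("deep_clearance must exceed pvh_halo_width")

    @property
    def wm_wmc_gap(self) -> float:
        return self.intensity_means["wmc"] - self.intensity_means["white_matter"]

    def to_json(self, path: str | Path) -> None:
        d = {
            **{
                k: getattr(self, k)
                for k in (
                    "grid_shape",
                    "voxel_size",
                    "brain_axes",
                    "cortex_thickness",
                    "ventricle_axes",
                    "ventricle_offset",
                    "pvh_halo_width",
                    "rim_thickness",
                    "rim_cap_gap",
                    "deep_clearance",
                    "intensity_means",
                    "noise_sd",
                    "seed",
                )
            },
            "cap_specs": [
                {"ventricle": c.ventricle, "pole": c.pole, "axes": c.axes}
                for c in self.cap_specs
            ],
            "dwmh_specs": [
                {"center": s.center, "radius": s.radius} for s in self.dwmh_specs
            ],
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        d["cap_specs"] = [
            CapSpec(c["ventricle"], c["pole"], tuple(c["axes"]))
            for c in d["cap_specs"]
        ]
        d["dwmh_specs"] = [
            SphereSpec(tuple(s["center"]), s["radius"]) for s in d["dwmh_specs"]
        ]
        for k in ("grid_shape", "voxel_size", "brain_axes", "ventricle_axes"):
            d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def compact(cls, seed: int = 0, noise_sd: float = 0.0) -> "PhantomSpec":
        """Small, fast variant with the same structure (for tests/demos)."""
        return cls(
            grid_shape=(48, 60, 48),
            brain_axes=(20.0, 26.0, 20.0),
            cortex_thickness=2.0,
            ventricle_axes=(4.0, 11.0, 5.0),
            ventricle_offset=6.0,
            cap_specs=[CapSpec(v, p, (5.0, 4.0, 5.0)) for v in (0, 1) for p in (-1, 1)],
            dwmh_specs=[
                SphereSpec((24.0, 48.0, 26.0), 3.0),
                SphereSpec((24.0, 12.0, 22.0), 2.5),
            ],
            rim_cap_gap=2.0,
            deep_clearance=6.0,
            noise_sd=noise_sd,
            seed=seed,
        )


@dataclass
class PhantomTruth:
    """Ground-truth masks and exact volumes for one phantom."""

    ventricle_mask: BinaryMask
    pvh_mask_true: BinaryMask
    dwmh_mask_true: BinaryMask
    rim_mask_true: BinaryMask
    brain_mask: BinaryMask
    true_volumes: LesionVolumes
    ventricle_seeds: list[tuple[int, int, int]]
    pvh_extent_mm: float  # max distance of a true PVH voxel from the ventricle surface
    dwmh_clearance_mm: float  # min distance of a true DWMH voxel from the ventricle surface

    @property
    def suggested_mask_width_mm(self) -> float:
        """Operator-style periventricular mask width: halfway between the PVH
        extent and the deep-lesion clearance (the phantom analogue of
        adjusting the mask to the width of the periventricular changes)."""
        return 0.5 * (self.pvh_extent_mm + self.dwmh_clearance_mm)

    def save(self, directory: str | Path, stem: str = "phantom") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.ventricle_mask.save(directory / f"{stem}_ventricles.nii.gz")
        self.pvh_mask_true.save(directory / f"{stem}_pvh_true.nii.gz")
        self.dwmh_mask_true.save(directory / f"{stem}_dwmh_true.nii.gz")
        self.rim_mask_true.save(directory / f"{stem}_rim_true.nii.gz")
        self.brain_mask.save(directory / f"{stem}_brain.nii.gz")


def _mm_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        np.arange(n, dtype=np.float64) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(
    grids: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[float, float, float],
    axes: tuple[float, float, float],
) -> np.ndarray:
    acc = np.zeros(grids[0].shape, dtype=np.float64)
    for g, c, a in zip(grids, center, axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Render a phantom image and its ground truth.

    Image intensities are the tissue-class means plus seeded Gaussian noise;
    identical specs (including seed) give bit-identical output.  Geometry is
    validated: deep lesions must keep ``deep_clearance`` mm of normal white
    matter between themselves and the ventricle surface and must fit inside
    the white matter; the brain must fit inside the grid.
    """
    grids = _mm_grids(spec)
    extent = [
        (n - 1) * v for n, v in zip(spec.grid_shape, spec.voxel_size)
    ]
    center = tuple(e / 2.0 for e in extent)
    for c, a, e in zip(center, spec.brain_axes, extent):
        if c - a < 0 or c + a > e:
            raise ValueError(
                f"grid too small to contain the brain ellipsoid (axes {spec.brain_axes})"
            )

    brain = _ellipsoid(grids, center, spec.brain_axes)
    inner_axes = tuple(max(a - spec.cortex_thickness, 1e-6) for a in spec.brain_axes)
    wm_region = _ellipsoid(grids, center, inner_axes)
    cortex = brain & ~wm_region

    vent_centers = []
    vent = np.zeros(spec.grid_shape, dtype=bool)
    for side in (-1, 1):
        vc = (center[0] + side * spec.ventricle_offset, center[1], center[2])
        vent_centers.append(vc)
        vent |= _ellipsoid(grids, vc, spec.ventricle_axes)
    if not (vent & wm_region).any():
        raise ValueError("ventricles fall outside the white-matter region")
    vent &= wm_region

    d_vent = ndimage.distance_transform_edt(~vent, sampling=spec.voxel_size)

    pvh = np.zeros(spec.grid_shape, dtype=bool)
    if spec.pvh_halo_width > 0:
        pvh |= (d_vent > 0) & (d_vent <= spec.pvh_halo_width)
    for cap in spec.cap_specs:
        vc = vent_centers[cap.ventricle]
        pole = (vc[0], vc[1] + cap.pole * spec.ventricle_axes[1], vc[2])
        pvh |= _ellipsoid(grids, pole, cap.axes)
    pvh &= wm_region & ~vent

    min_vox = min(spec.voxel_size)
    rim = (d_vent > 0) & (d_vent <= spec.rim_thickness * min_vox + 1e-9)
    rim &= wm_region & ~pvh
    if pvh.any():
        d_pvh = ndimage.distance_transform_edt(~pvh, sampling=spec.voxel_size)
        rim &= d_pvh > spec.rim_cap_gap

    dwmh = np.zeros(spec.grid_shape, dtype=bool)
    for sph in spec.dwmh_specs:
        ball = _ellipsoid(grids, sph.center, (sph.radius,) * 3)
        if not ball.any():
            raise ValueError(f"deep lesion at {sph.center} lies outside the grid")
        if (ball & ~wm_region).any():
            raise ValueError(
                f"deep lesion at {sph.center} (r={sph.radius}) extends outside "
                "the white-matter region"
            )
        min_clear = float(d_vent[ball].min())
        if min_clear <= max(spec.deep_clearance, spec.pvh_halo_width):
            raise ValueError(
                f"deep lesion at {sph.center} (r={sph.radius}) is only "
                f"{min_clear:.1f} mm from the ventricle surface; it would overlap "
                "the periventricular zone (required clearance "
                f"{max(spec.deep_clearance, spec.pvh_halo_width):.1f} mm)"
            )
        dwmh |= ball
    if (dwmh & (pvh | rim)).any():  # pragma: no cover - excluded by clearance
        raise ValueError("deep lesions intersect the periventricular compartment")

    im = spec.intensity_means
    values = np.full(spec.grid_shape, im["background"], dtype=np.float64)
    values[brain] = im["white_matter"]
    values[cortex] = im["grey_matter"]
    values[vent] = im["csf"]
    values[pvh | rim | dwmh] = im["wmc"]
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vs, aff = spec.voxel_size, None
    image = VolumeImage(values, vs, aff)
    vent_mask = BinaryMask(vent, vs, image.affine)
    pvh_mask = BinaryMask(pvh, vs, image.affine)
    dwmh_mask = BinaryMask(dwmh, vs, image.affine)
    rim_mask = BinaryMask(rim, vs, image.affine)
    brain_mask = BinaryMask(brain, vs, image.affine)

    volumes = LesionVolumes(
        total_wmc_ml=volume_of(pvh_mask) + volume_of(dwmh_mask),
        pvh_ml=volume_of(pvh_mask),
        dwmh_ml=volume_of(dwmh_mask),
        ventricles_ml=volume_of(vent_mask),
    )
    seeds = [
        tuple(int(round(c / v)) for c, v in zip(vc, spec.voxel_size))
        for vc in vent_centers
    ]
    truth = PhantomTruth(
        ventricle_mask=vent_mask,
        pvh_mask_true=pvh_mask,
        dwmh_mask_true=dwmh_mask,
        rim_mask_true=rim_mask,
        brain_mask=brain_mask,
        true_volumes=volumes,
        ventricle_seeds=seeds,
        pvh_extent_mm=float(d_vent[pvh].max()) if pvh.any() else spec.pvh_halo_width,
        dwmh_clearance_mm=float(d_vent[dwmh].min()) if dwmh.any() else float("inf"),
    )
    return image, truth


def random_phantom_spec(
    seed: int,
    noise_sd: float = 0.0,
    size: str = "default",
    max_tries: int = 10,
) -> PhantomSpec:
    """Seeded geometric jitter around the default (or compact) phantom.

    Ventricle and cap axes and deep-lesion radii/positions are perturbed a
    few percent / mm; candidates violating the clearance or containment
    invariants are rejected and redrawn.
    """
    base = PhantomSpec.compact() if size == "compact" else PhantomSpec()
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_tries):
        rng = np.random.default_rng(child)
        scale = 0.5 if size == "compact" else 1.0
        vent_axes = tuple(
            float(a * rng.uniform(0.92, 1.08)) for a in base.ventricle_axes
        )
        caps = [
            CapSpec(
                c.ventricle,
                c.pole,
                tuple(float(a * rng.uniform(0.88, 1.08)) for a in c.axes),
            )
            for c in base.cap_specs
        ]
        spheres = [
            SphereSpec(
                tuple(
                    float(x + rng.uniform(-1.5, 1.5) * scale) for x in s.center
                ),
                float(s.radius * rng.uniform(0.9, 1.05)),
            )
            for s in base.dwmh_specs
        ]
        spec = PhantomSpec(
            grid_shape=base.grid_shape,
            brain_axes=base.brain_axes,
            cortex_thickness=base.cortex_thickness,
            ventricle_axes=vent_axes,
            ventricle_offset=base.ventricle_offset,
            pvh_halo_width=base.pvh_halo_width,
            cap_specs=caps,
            dwmh_specs=spheres,
            rim_thickness=base.rim_thickness,
            rim_cap_gap=base.rim_cap_gap,
            deep_clearance=base.deep_clearance,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            generate_phantom(spec)
        except ValueError:
            continue
        return spec
    raise RuntimeError(f"no valid phantom geometry found after {max_tries} tries")
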