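"""Synthetic activity phantoms for single-photon (SPECT-like) volumetry studies.

This module builds 3-D voxelized activity distributions that emulate the
physical phantoms used to validate isocontour volumetry — a large cylindrical
quality-control phantom (Jaszczak type) with hot spheres at known
sphere-to-background concentration ratios, standalone cylinders mimicking a
liver, and a clinical-like liver-plus-tumor configuration — together with the
binary reference masks that play the role of the anatomical (CT) boundary in
fused SPECT/CT reading.

The acquisition/reconstruction chain is represented in the image domain: an
isotropic Gaussian point-spread function of stated FWHM followed by a global
rescale to an expected total count and optional voxel-wise Poisson noise.
Projection-domain physics (attenuation, scatter, OSEM reconstruction) is
deliberately out of scope.

Coordinates are world millimetres; grids are indexed 0-based; a voxel belongs
to an object iff the voxel *center* lies inside the analytic shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

__all__ = [
    "GeometricObject",
    "PhantomSpec",
    "AcquisitionModel",
    "ActivityImage",
    "ReferenceMask",
    "rasterize",
    "degrade",
    "make_clinical_phantom",
    "jaszczak_spec",
    "cylinder_spec",
    "JASZCZAK_VOLUME_ML",
    "SPHERE_VOLUMES_ML",
    "SPHERE_RATIOS_BY_LEVEL",
]

#: Analytic volumes of the reference test objects, mL.
JASZCZAK_VOLUME_ML = 6716.0
CYLINDER2_VOLUME_ML = 774.0
CYLINDER3_VOLUME_ML = 473.0
SPHERE_VOLUMES_ML = {"Sphere 1": 55.0, "Sphere 2": 20.5, "Sphere 3": 16.0, "Sphere 4": 8.0}

#: True sphere/background concentration ratios per activity level
#: (four levels: 18.5, 37, 55.5 and 74 MBq loaded per sphere).
SPHERE_RATIOS_BY_LEVEL = {
    "18.5 MBq/sphere": {"Sphere 1": 2.8, "Sphere 2": 7.6, "Sphere 3": 9.6, "Sphere 4": 19.6},
    "37 MBq/sphere": {"Sphere 1": 6.0, "Sphere 2": 17.0, "Sphere 3": 23.4, "Sphere 4": 43.8},
    "55.5 MBq/sphere": {"Sphere 1": 9.9, "Sphere 2": 29.6, "Sphere 3": 38.6, "Sphere 4": 73.1},
    "74 MBq/sphere": {"Sphere 1": 16.0, "Sphere 2": 45.0, "Sphere 3": 57.0, "Sphere 4": 114.0},
}


def sphere_radius_mm(volume_mL: float) -> float:
    """Radius of a sphere of the given volume (mL -> mm)."""
    return (3.0 * volume_mL * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class GeometricObject:
    """An analytic shape carrying a uniform activity concentration.

    Parameters
    ----------
    shape : {"sphere", "cylinder", "ellipsoid"}
    center : world coordinates of the shape center, mm.
    dimensions : radius (sphere); (radius, height) (cylinder, axis along z);
        semi-axes (ellipsoid), mm.
    activity_concentration : relative activity per mL (arbitrary units).
    label : identifier used in masks and error messages.
    """

    shape: str
    center: tuple[float, float, float]
    dimensions: tuple[float, ...]
    activity_concentration: float
    label: str

    def __post_init__(self):
        if self.shape not in ("sphere", "cylinder", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")
        ndim = {"sphere": 1, "cylinder": 2, "ellipsoid": 3}[self.shape]
        if len(self.dimensions) != ndim:
            raise ValueError(f"{self.shape} takes {ndim} dimension(s), got {len(self.dimensions)}")
        if any(d <= 0 for d in self.dimensions):
            raise ValueError(f"object {self.label!r}: dimensions must be strictly positive")

    @property
    def analytic_volume_mL(self) -> float:
        if self.shape == "sphere":
            (r,) = self.dimensions
            return 4.0 / 3.0 * math.pi * r**3 / 1000.0
        if self.shape == "cylinder":
            r, h = self.dimensions
            return math.pi * r**2 * h / 1000.0
        a, b, c = self.dimensions
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world-coordinate corners of the axis-aligned bbox, mm."""
        c = np.asarray(self.center, dtype=float)
        if self.shape == "sphere":
            half = np.full(3, self.dimensions[0])
        elif self.shape == "cylinder":
            r, h = self.dimensions
            half = np.array([r, r, h / 2.0])
        else:
            half = np.asarray(self.dimensions, dtype=float)
        return c - half, c + half

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Boolean membership of world points (broadcastable arrays, mm)."""
        cx, cy, cz = self.center
        if self.shape == "sphere":
            (r,) = self.dimensions
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        if self.shape == "cylinder":
            r, h = self.dimensions
            return ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (np.abs(z - cz) <= h / 2.0)
        a, b, c = self.dimensions
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """A phantom: nested analytic objects on a voxel grid.

    Objects later in the list are treated as *inner* — a voxel center covered
    by several objects takes the concentration of the last one listed.
    ``background_concentration`` applies outside all objects.
    """

    objects: tuple[GeometricObject, ...]
    background_concentration: float = 0.0
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self):
        object.__setattr__(self, "objects", tuple(self.objects))
        if any(n <= 0 for n in self.grid_shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("grid_shape and voxel_size must be strictly positive")

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def grid_extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * np.asarray(self.voxel_size, float)


@dataclass(frozen=True)
class AcquisitionModel:
    """Image-domain surrogate of the acquisition/reconstruction chain.

    psf_fwhm : isotropic Gaussian PSF full width at half maximum, mm.
    total_counts : expected whole-image count sum after rescaling.
    noise : apply voxel-wise Poisson noise when True.
    seed : RNG seed for the Poisson draw (ignored when noise is False).
    """

    psf_fwhm: float = 15.0
    total_counts: float = 1.0e7
    noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.total_counts <= 0:
            raise ValueError("total_counts must be > 0")


@dataclass
class ActivityImage:
    """A 3-D non-negative scalar field of counts with physical voxel spacing."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ActivityImage requires a 3-D array")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())


@dataclass
class ReferenceMask:
    """Binary mask of an object's true extent, on the same grid as its image."""

    values: np.ndarray
    object_label: str
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("ReferenceMask requires a 3-D array")
        if not self.values.any():
            raise ValueError(f"reference mask {self.object_label!r} is empty")

    @property
    def volume_mL(self) -> float:
        return float(self.values.sum()) * float(np.prod(self.voxel_size)) / 1000.0

    def centroid_index(self) -> tuple[int, int, int]:
        idx = np.argwhere(self.values)
        return tuple(int(round(v)) for v in idx.mean(axis=0))


def _voxel_center_axes(spec: PhantomSpec):
    return [
        (np.arange(n, dtype=float) + 0.5) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size)
    ]


def rasterize(spec: PhantomSpec) -> tuple[ActivityImage, dict[str, ReferenceMask]]:
    """Voxelize a phantom: activity image plus one reference mask per object.

    Each voxel takes the concentration of the innermost (last-listed) object
    whose analytic shape contains the voxel center, else the background
    concentration.  Masks are purely geometric (nesting does not carve them).

    Raises
    ------
    ValueError
        If an object's bounding box extends outside the grid (named).
    """
    extent = spec.grid_extent_mm()
    for obj in spec.objects:
        lo, hi = obj.bounding_box()
        if np.any(lo < 0) or np.any(hi > extent):
            raise ValueError(
                f"object {obj.label!r} extends outside the grid "
                f"(bbox {lo.round(1)}..{hi.round(1)} mm, grid {extent} mm)"
            )

    ax = _voxel_center_axes(spec)
    X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
    values = np.full(spec.grid_shape, float(spec.background_concentration))
    masks: dict[str, ReferenceMask] = {}
    for obj in spec.objects:  # later objects override: list order = nesting order
        inside = obj.contains(X, Y, Z)
        values[inside] = obj.activity_concentration
        masks[obj.label] = ReferenceMask(inside, obj.label, spec.voxel_size)
    image = ActivityImage(values, spec.voxel_size, metadata={"source": "rasterize"})
    return image, masks


def degrade(image: ActivityImage, acq: AcquisitionModel) -> ActivityImage:
    """Apply the image-domain acquisition model.

    The input is convolved with an isotropic Gaussian PSF of ``acq.psf_fwhm``,
    rescaled so that the expected whole-image sum equals ``acq.total_counts``,
    then (if ``acq.noise``) replaced voxel-wise by Poisson draws seeded with
    ``acq.seed``.  Total counts are conserved in expectation.
    """
    vals = image.values
    if acq.psf_fwhm > 0:
        sigma_vox = [acq.psf_fwhm * FWHM_TO_SIGMA / v for v in image.voxel_size]
        vals = gaussian_filter(vals, sigma=sigma_vox, mode="constant")
    s = vals.sum()
    if s <= 0:
        raise ValueError("cannot rescale an all-zero image to a positive total count")
    vals = vals * (acq.total_counts / s)
    if acq.noise:
        rng = np.random.default_rng(acq.seed)
        vals = rng.poisson(vals).astype(float)
    meta = dict(image.metadata)
    meta.update(psf_fwhm_mm=acq.psf_fwhm, total_counts=acq.total_counts,
                noise=acq.noise, seed=acq.seed)
    return ActivityImage(vals, image.voxel_size, metadata=meta)


def jaszczak_spec(
    level: str = "37 MBq/sphere",
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> PhantomSpec:
    """The large-cylinder phantom with four hot spheres at a given activity level.

    The cylinder (6716 mL) holds the warm background (concentration 1); each
    sphere's concentration is the tabulated sphere/background ratio for the
    requested activity level.
    """
    if level not in SPHERE_RATIOS_BY_LEVEL:
        raise KeyError(f"unknown activity level {level!r}")
    ratios = SPHERE_RATIOS_BY_LEVEL[level]
    extent = np.asarray(grid_shape, float) * np.asarray(voxel_size, float)
    cx, cy, cz = extent / 2.0
    cyl_r = 108.0  # 21.6 cm diameter; height chosen to give 6716 mL exactly
    cyl_h = JASZCZAK_VOLUME_ML * 1000.0 / (math.pi * cyl_r**2)
    objects = [
        GeometricObject("cylinder", (cx, cy, cz), (cyl_r, cyl_h), 1.0, "Cylinder 1")
    ]
    # Spheres on a ring at mid-height, well separated from each other and the wall.
    ring_r = 50.0
    for k, (label, vol) in enumerate(SPHERE_VOLUMES_ML.items()):
        ang = 2.0 * math.pi * k / 4.0 + math.pi / 4.0
        center = (cx + ring_r * math.cos(ang), cy + ring_r * math.sin(ang), cz)
        objects.append(
            GeometricObject("sphere", center, (sphere_radius_mm(vol),), ratios[label], label)
        )
    return PhantomSpec(tuple(objects), background_concentration=0.0,
                       grid_shape=grid_shape, voxel_size=voxel_size)


def cylinder_spec(
    volume_mL: float,
    label: str,
    radius_mm: float = 50.0,
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> PhantomSpec:
    """A standalone uniform hot cylinder of the stated volume in a cold field."""
    extent = np.asarray(grid_shape, float) * np.asarray(voxel_size, float)
    cx, cy, cz = extent / 2.0
    h = volume_mL * 1000.0 / (math.pi * radius_mm**2)
    obj = GeometricObject("cylinder", (cx, cy, cz), (radius_mm, h), 1.0, label)
    return PhantomSpec((obj,), background_concentration=0.0,
                       grid_shape=grid_shape, voxel_size=voxel_size)


def make_clinical_phantom(
    liver_volume_mL: float,
    tumor_volume_mL: float,
    tumor_count_fraction: float,
    acq: AcquisitionModel | None = None,
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> tuple[ActivityImage, ReferenceMask, ReferenceMask]:
    """A liver-like ellipsoid with an internal tumor ellipsoid.

    Compartment concentrations are solved so that, before degradation, the
    tumor holds ``tumor_count_fraction`` of the total hepatic counts.  The
    healthy-liver concentration is fixed at 1; the implied tumor concentration
    is ``f/(1-f) * (V_L - V_t)/V_t``.

    Returns the (optionally degraded) activity image plus the liver and tumor
    reference masks.  Raises ``ValueError`` for infeasible inputs.
    """
    if not 0 < tumor_volume_mL < liver_volume_mL:
        raise ValueError("require 0 < tumor volume < liver volume")
    if not 0 < tumor_count_fraction < 1:
        raise ValueError("tumor_count_fraction must lie in (0, 1)")
    f = tumor_count_fraction
    healthy_volume = liver_volume_mL - tumor_volume_mL
    tumor_conc = f / (1.0 - f) * healthy_volume / tumor_volume_mL
    if tumor_conc <= 0:
        raise ValueError("infeasible compartment concentrations")

    extent = np.asarray(grid_shape, float) * np.asarray(voxel_size, float)
    cx, cy, cz = extent / 2.0
    # Liver-like proportions (wider than tall); scaled to the requested volume.
    # Large tumors adopt the liver's proportions so they still fit inside.
    w = tumor_volume_mL / liver_volume_mL
    liver_prop = np.array([1.4, 1.0, 0.7])
    tumor_prop = (1.0 - w) * np.array([1.1, 1.0, 0.9]) + w * liver_prop
    liver_axes = _ellipsoid_axes(liver_volume_mL, tuple(liver_prop))
    tumor_axes = _ellipsoid_axes(tumor_volume_mL, tuple(tumor_prop))
    # Tumor sits off-center toward the "left lobe"; shrink the offset until
    # the tumor surface stays inside the liver.
    offset = np.array([0.35 * liver_axes[0], 0.0, 0.0])
    for _ in range(40):
        if _ellipsoid_inside(offset, tumor_axes, liver_axes):
            break
        offset *= 0.85
    else:
        raise ValueError("could not place tumor inside liver")
    liver = GeometricObject("ellipsoid", (cx, cy, cz), liver_axes, 1.0, "liver")
    tumor = GeometricObject(
        "ellipsoid", (cx + offset[0], cy + offset[1], cz + offset[2]),
        tumor_axes, tumor_conc, "tumor",
    )
    spec = PhantomSpec((liver, tumor), background_concentration=0.0,
                       grid_shape=grid_shape, voxel_size=voxel_size)
    image, masks = rasterize(spec)
    if acq is not None:
        image = degrade(image, acq)
    return image, masks["liver"], masks["tumor"]


def _ellipsoid_axes(volume_mL: float, proportions: tuple[float, float, float]):
    p = np.asarray(proportions, float)
    scale = (volume_mL * 1000.0 * 3.0 / (4.0 * math.pi * np.prod(p))) ** (1.0 / 3.0)
    return tuple(p * scale)


def _ellipsoid_inside(offset, inner_axes, outer_axes, n=2000) -> bool:
    """Check an inner ellipsoid (offset from the outer's center) is contained."""
    rng = np.random.default_rng(12345)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = offset + u * np.asarray(inner_axes)
    return bool(np.all(np.sum((pts / np.asarray(outer_axes)) ** 2, axis=1) <= 1.0))
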