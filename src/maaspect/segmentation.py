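"""Isocontour-threshold VOI extraction and threshold fitting.

A VOI is the connected component — containing a seed voxel — of the set of
voxels whose activity reaches or exceeds a stated percentage of a reference
maximum.  Two fitting strategies produce the threshold:

* **anatomical** (``fit_threshold_anatomical``): the threshold whose VOI best
  overlaps (Dice) a binary reference mask, emulating fitting the isocontour to
  the organ wall seen on fused anatomical images;
* **hot-spot** (``fit_threshold_hotspot``): no anatomical truth — a surrogate
  human observer who contours the apparent edge of the display-transformed
  emission image.  Rays are cast from the hot-spot peak, the steepest-descent
  point of each display profile marks the perceived edge, and the activity
  level there becomes the threshold.  ``display_gamma`` parametrizes the
  display window (observer variability): gamma < 1 brightens faint activity
  and pushes the perceived edge outward.

The superlevel set is always taken over the full image; a ``search_region``
(or a ball of ``max_search_radius_mm`` around the seed) only restricts where
the reference maximum is read, which matters in multi-object phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantoms import FWHM_TO_SIGMA, ActivityImage, ReferenceMask

__all__ = [
    "VOI",
    "ThresholdFit",
    "EmptyVOIError",
    "ThresholdFitError",
    "isocontour_voi",
    "measure_volume",
    "measure_counts",
    "fit_threshold_anatomical",
    "fit_threshold_hotspot",
    "default_threshold_grid",
    "dice_coefficient",
]


class EmptyVOIError(ValueError):
    """The seed voxel falls below the requested isocontour threshold."""


class ThresholdFitError(RuntimeError):
    """No candidate threshold produced a usable VOI / no edge was detected."""


def default_threshold_grid() -> np.ndarray:
    """Integer percentages 1–99, as fractions."""
    return np.arange(1, 100) / 100.0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class VOI:
    """A connected voxel set produced by an isocontour threshold."""

    mask: np.ndarray
    threshold_fraction: float
    seed_point: tuple[int, int, int]
    image_id: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptyVOIError("VOI is empty")
        if not self.mask[tuple(self.seed_point)]:
            raise ValueError("VOI does not contain its seed point")

    @property
    def indices(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def is_connected(self, connectivity: int = 26) -> bool:
        _, n = ndimage.label(self.mask, structure=_structure(connectivity))
        return n == 1


@dataclass
class ThresholdFit:
    """Result of a threshold search.

    ``trace`` holds one row per evaluated candidate (columns ``threshold``,
    ``volume_mL``, ``objective``); hot-spot fits, which do not scan the grid,
    record the single chosen threshold.
    """

    best_threshold_fraction: float
    objective: float
    trace: pd.DataFrame = field(repr=False, default=None)


def _ball_mask(shape, voxel_size, center_index, radius_mm) -> np.ndarray:
    ax = [
        ((np.arange(n, dtype=float) - c) * v)
        for n, v, c in zip(shape, voxel_size, center_index)
    ]
    X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
    return X**2 + Y**2 + Z**2 <= radius_mm**2


def _reference_max(image, seed_point, search_region, max_search_radius_mm):
    if search_region is not None:
        region = search_region.values
        if not region[tuple(seed_point)]:
            raise ValueError("seed_point lies outside the search region")
    elif max_search_radius_mm is not None:
        region = _ball_mask(image.values.shape, image.voxel_size, seed_point,
                            max_search_radius_mm)
    else:
        region = None
    return float(image.values.max() if region is None else image.values[region].max())


def isocontour_voi(
    image: ActivityImage,
    threshold_fraction: float,
    seed_point: tuple[int, int, int],
    search_region: ReferenceMask | None = None,
    max_search_radius_mm: float | None = None,
    connectivity: int = 26,
    reference_max: float | None = None,
) -> VOI:
    """Extract the isocontour VOI at a fractional threshold.

    The reference maximum is the largest voxel value inside ``search_region``
    if given, else inside a ball of ``max_search_radius_mm`` around the seed,
    else the whole image; ``reference_max`` overrides it explicitly.  The VOI
    is the connected component containing ``seed_point`` of all voxels with
    value >= threshold_fraction * maximum (ties included).
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    if reference_max is not None:
        refmax = float(reference_max)
    else:
        refmax = _reference_max(image, seed_point, search_region, max_search_radius_mm)
    level = threshold_fraction * refmax
    above = image.values >= level
    if not above[tuple(seed_point)]:
        raise EmptyVOIError(
            f"seed voxel value {image.values[tuple(seed_point)]:g} is below the "
            f"{threshold_fraction:.0%} isocontour level {level:g}"
        )
    labels, _ = ndimage.label(above, structure=_structure(connectivity))
    comp = labels[tuple(seed_point)]
    return VOI(labels == comp, threshold_fraction, tuple(seed_point),
               image_id=image.metadata.get("id", ""))


def measure_volume(voi: VOI, image: ActivityImage) -> float:
    """VOI volume in mL: member count times voxel volume."""
    if voi.mask.shape != image.values.shape:
        raise ValueError("VOI and image are on different grids")
    return voi.n_voxels * image.voxel_volume_mL


def measure_counts(voi: VOI, image: ActivityImage) -> float:
    """Total counts inside the VOI."""
    if voi.mask.shape != image.values.shape:
        raise ValueError("VOI and image are on different grids")
    return float(image.values[voi.mask].sum())


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def _crop_slices(mask: np.ndarray, voxel_size, margin_mm: float):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    out = []
    for axis in range(3):
        pad = int(np.ceil(margin_mm / voxel_size[axis]))
        out.append(slice(max(0, lo[axis] - pad), min(mask.shape[axis], hi[axis] + pad)))
    return tuple(out)


def fit_threshold_anatomical(
    image: ActivityImage,
    reference: ReferenceMask,
    seed_point: tuple[int, int, int] | None = None,
    threshold_grid: np.ndarray | None = None,
    connectivity: int = 26,
    crop_margin_mm: float = 32.0,
) -> ThresholdFit:
    """Fit the isocontour threshold to an anatomical reference mask.

    Every candidate threshold's VOI is scored by Dice overlap with the
    reference; the best (ties broken toward the smallest threshold, i.e. the
    largest VOI) is returned together with the full search trace.

    For speed the candidate components are evaluated on a subgrid cropped
    ``crop_margin_mm`` beyond the reference bounding box; components flooding
    past the crop are truncated there, which only affects thresholds already
    far from the optimum.
    """
    if threshold_grid is None:
        threshold_grid = default_threshold_grid()
    threshold_grid = np.sort(np.asarray(threshold_grid, float))
    if np.any(threshold_grid <= 0) or np.any(threshold_grid > 1):
        raise ValueError("threshold grid must lie within (0, 1]")
    if seed_point is None:
        seed_point = reference.centroid_index()
        if not reference.values[seed_point]:
            # centroid of a non-convex mask may fall outside; snap to the
            # member voxel with the highest activity
            members = np.argwhere(reference.values)
            seed_point = tuple(members[np.argmax(image.values[reference.values])])
    refmax = float(image.values[reference.values].max())
    if refmax <= 0:
        raise ThresholdFitError("reference region contains no activity")

    sl = _crop_slices(reference.values, image.voxel_size, crop_margin_mm)
    sub = image.values[sl]
    subref = reference.values[sl]
    seed_local = tuple(int(s) - s_.start for s, s_ in zip(seed_point, sl))
    structure = _structure(connectivity)
    vox_mL = image.voxel_volume_mL

    rows = []
    for t in threshold_grid:
        above = sub >= t * refmax
        if not above[seed_local]:
            rows.append((t, 0.0, np.nan))
            continue
        labels, _ = ndimage.label(above, structure=structure)
        comp = labels == labels[seed_local]
        rows.append((t, comp.sum() * vox_mL, dice_coefficient(comp, subref)))
    trace = pd.DataFrame(rows, columns=["threshold", "volume_mL", "objective"])
    if trace["objective"].isna().all():
        raise ThresholdFitError("all candidate VOIs were empty")
    best_i = int(np.nanargmax(trace["objective"].to_numpy()))  # first max = smallest t
    return ThresholdFit(float(trace.loc[best_i, "threshold"]),
                        float(trace.loc[best_i, "objective"]), trace)


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def fit_threshold_hotspot(
    image: ActivityImage,
    seed_point: tuple[int, int, int],
    threshold_grid: np.ndarray | None = None,
    display_gamma: float = 1.0,
    max_search_radius_mm: float = 60.0,
    peak_search_radius_mm: float = 30.0,
    edge_sensitivity: float = 0.3,
    display_smoothing_mm: float = 8.0,
    n_rays: int = 64,
    connectivity: int = 26,
) -> ThresholdFit:
    """Emulate visual hot-spot contouring without anatomical truth.

    The observer's display is modeled as the emission image lightly smoothed
    (``display_smoothing_mm`` — screens interpolate and viewers do not
    perceive single-voxel noise spikes), windowed to saturate at the local
    reference maximum and gamma-transformed (``display_gamma``).  Rays of
    length ``max_search_radius_mm`` are cast from the hot-spot peak (the
    display maximum within ``peak_search_radius_mm`` of the seed).  On each
    ray profile the perceived object edge is the steepest point of the
    *outermost* descent run reaching ``edge_sensitivity`` times the strongest
    descent on that ray — the outer boundary an observer would contour, even
    when the object encloses hotter structures.  The median display-image
    activity fraction at those edge points, snapped to the threshold grid, is
    the fitted threshold; the VOI is flooded on the display image at that
    level.  The objective is the fraction of rays with a detectable edge.

    Fully deterministic for fixed inputs.
    """
    if display_gamma <= 0:
        raise ValueError("display_gamma must be positive")
    if not 0 < edge_sensitivity <= 1:
        raise ValueError("edge_sensitivity must lie in (0, 1]")
    if threshold_grid is None:
        threshold_grid = default_threshold_grid()
    threshold_grid = np.sort(np.asarray(threshold_grid, float))

    vox = np.asarray(image.voxel_size, float)
    # the observer's field of view: crop to the reachable neighborhood of the
    # seed (ray extent plus smoothing support) before building the display
    fov_mm = max_search_radius_mm + 2.0 * display_smoothing_mm + 8.0
    sl = tuple(
        slice(max(0, int(seed_point[a] - np.ceil(fov_mm / vox[a]))),
              min(image.values.shape[a], int(seed_point[a] + np.ceil(fov_mm / vox[a])) + 1))
        for a in range(3)
    )
    sub = image.values[sl]
    seed_local = tuple(int(seed_point[a]) - sl[a].start for a in range(3))
    if display_smoothing_mm > 0:
        sigma_vox = [display_smoothing_mm * FWHM_TO_SIGMA / v for v in vox]
        shown = ndimage.gaussian_filter(sub, sigma=sigma_vox)
    else:
        shown = sub
    ball = _ball_mask(shown.shape, image.voxel_size, seed_local,
                      peak_search_radius_mm)
    ball[seed_local] = True
    vals_in_ball = np.where(ball, shown, -np.inf)
    peak = tuple(int(v) for v in
                 np.unravel_index(int(np.argmax(vals_in_ball)), shown.shape))
    refmax = float(shown[peak])
    if refmax <= 0:
        raise ThresholdFitError("no activity near the seed")

    step_mm = 0.5 * float(vox.min())
    n_steps = max(4, int(np.ceil(max_search_radius_mm / step_mm)))
    s = np.arange(n_steps + 1) * step_mm
    dirs = _fibonacci_directions(n_rays)
    peak_mm = (np.asarray(peak, float) + 0.5) * vox
    # sample points for all rays at once: (3, n_rays, n_steps+1) world coords
    pts_mm = peak_mm[:, None, None] + dirs.T[:, :, None] * s[None, None, :]
    coords = pts_mm / vox[:, None, None] - 0.5
    raw = ndimage.map_coordinates(shown, coords.reshape(3, -1), order=1,
                                  mode="nearest").reshape(n_rays, n_steps + 1)
    # display window saturates at the reference level ("windowed to the target")
    disp = np.clip(raw / refmax, 0.0, 1.0) ** display_gamma
    grad = np.gradient(disp, step_mm, axis=1)

    skip = max(2, int(np.ceil(vox.min() / step_mm)))  # ignore the peak voxel itself
    edge_thresholds = []
    for i in range(n_rays):
        g = grad[i, skip:]
        strongest = float(g.min())
        if strongest >= -1e-12:
            continue  # flat ray: no edge
        significant = np.flatnonzero(g <= edge_sensitivity * strongest)
        # outermost contiguous descent run; its steepest point marks the edge
        breaks = np.flatnonzero(np.diff(significant) > 1)
        run = significant[breaks[-1] + 1:] if breaks.size else significant
        j = int(run[np.argmin(g[run])])
        frac = raw[i, skip + j] / refmax
        if 0 < frac <= 1:
            edge_thresholds.append(frac)
    if not edge_thresholds:
        raise ThresholdFitError("no detectable edge along any ray")
    t = float(np.median(edge_thresholds))
    t_snapped = float(threshold_grid[np.argmin(np.abs(threshold_grid - t))])
    shown_img = ActivityImage(shown, image.voxel_size,
                              metadata=dict(image.metadata, display="smoothed"))
    voi = isocontour_voi(shown_img, t_snapped, peak, connectivity=connectivity,
                         reference_max=refmax)
    trace = pd.DataFrame(
        {"threshold": [t_snapped],
         "volume_mL": [measure_volume(voi, shown_img)],
         "objective": [len(edge_thresholds) / n_rays]}
    )
    return ThresholdFit(t_snapped, len(edge_thresholds) / n_rays, trace)
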