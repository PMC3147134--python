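"""Isocontour VOI extraction and threshold fitting."""

import numpy as np
import pytest

from maaspect.phantoms import (
    AcquisitionModel,
    ActivityImage,
    GeometricObject,
    PhantomSpec,
    ReferenceMask,
    degrade,
    rasterize,
    sphere_radius_mm,
)
from maaspect.segmentation import (
    EmptyVOIError,
    ThresholdFitError,
    dice_coefficient,
    fit_threshold_anatomical,
    fit_threshold_hotspot,
    isocontour_voi,
    measure_counts,
    measure_volume,
)


def brute_force_voi(values, threshold_fraction, seed_point, refmax=None):
    """Independent oracle: exhaustive threshold + flood fill (26-neighborhood)."""
    refmax = values.max() if refmax is None else refmax
    above = values >= threshold_fraction * refmax
    if not above[seed_point]:
        return None
    member = np.zeros_like(above)
    stack = [tuple(seed_point)]
    member[tuple(seed_point)] = True
    while stack:
        i, j, k = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    p = (i + di, j + dj, k + dk)
                    if all(0 <= p[a] < above.shape[a] for a in range(3)):
                        if above[p] and not member[p]:
                            member[p] = True
                            stack.append(p)
    return member


class TestIsocontourVOI:
    def test_matches_brute_force_oracle_on_random_images(self, rng):
        """100 random <=8^3 images: component equals exhaustive flood fill."""
        for trial in range(100):
            shape = tuple(rng.integers(3, 9, size=3))
            values = rng.integers(0, 10, size=shape).astype(float)
            seed = tuple(rng.integers(0, s) for s in shape)
            t = float(rng.uniform(0.1, 1.0))
            image = ActivityImage(values, (1, 1, 1))
            expected = brute_force_voi(values, t, seed)
            if expected is None:
                with pytest.raises(EmptyVOIError):
                    isocontour_voi(image, t, seed)
            else:
                voi = isocontour_voi(image, t, seed)
                assert np.array_equal(voi.mask, expected), f"trial {trial}"

    def test_uniform_image_gives_whole_region(self):
        image = ActivityImage(np.full((6, 6, 6), 7.0), (2, 2, 2))
        voi = isocontour_voi(image, 0.5, (0, 0, 0))
        assert voi.n_voxels == 6**3

    def test_threshold_one_keeps_maximal_component(self):
        values = np.zeros((5, 5, 5))
        values[1, 1, 1] = values[1, 1, 2] = 9.0
        values[4, 4, 4] = 9.0  # disconnected maximal voxel
        voi = isocontour_voi(ActivityImage(values, (1, 1, 1)), 1.0, (1, 1, 1))
        assert voi.n_voxels == 2

    def test_seed_below_threshold_raises_named_error(self):
        values = np.zeros((4, 4, 4))
        values[0, 0, 0] = 10.0
        with pytest.raises(EmptyVOIError, match="50%"):
            isocontour_voi(ActivityImage(values, (1, 1, 1)), 0.5, (3, 3, 3))

    def test_nestedness_in_threshold(self, rng):
        """VOI(t2) is a subset of VOI(t1) for t1 <= t2; volume non-increasing."""
        values = rng.random((10, 10, 10)) + 0.1
        values[5, 5, 5] = 2.0
        image = ActivityImage(values, (1, 1, 1))
        prev = None
        for t in np.linspace(0.05, 1.0, 12):
            try:
                voi = isocontour_voi(image, float(t), (5, 5, 5))
            except EmptyVOIError:
                break
            if prev is not None:
                assert np.all(prev.mask | ~voi.mask)  # voi ⊆ prev
                assert voi.n_voxels <= prev.n_voxels
            prev = voi

    def test_search_region_sets_reference_maximum(self):
        values = np.ones((6, 6, 6))
        values[0, 0, 0] = 100.0
        values[3:, 3:, 3:] = 2.0
        image = ActivityImage(values, (1, 1, 1))
        region = ReferenceMask(values == 2.0, "hot", (1, 1, 1))
        voi = isocontour_voi(image, 0.9, (4, 4, 4), search_region=region)
        # reference max is 2 (inside region), not the global 100
        assert voi.n_voxels == 3 * 3 * 3


class TestMeasurement:
    def test_volume_is_count_times_voxel_volume(self):
        values = np.zeros((12, 12, 12))
        values[:10, :10, :10] = 1.0
        image = ActivityImage(values, (4, 4, 4))
        voi = isocontour_voi(image, 0.5, (0, 0, 0))
        assert voi.n_voxels == 1000
        assert measure_volume(voi, image) == pytest.approx(64.0)

    def test_volume_of_rasterized_cylinder(self):
        """A VOI equal to a 473 mL cylinder mask measures 473 mL within 2%."""
        obj = GeometricObject("cylinder", (60, 60, 60), (38.0, 473e3 / (np.pi * 38**2)),
                              1.0, "cyl")
        spec = PhantomSpec((obj,), grid_shape=(120, 120, 120), voxel_size=(1, 1, 1))
        image, masks = rasterize(spec)
        voi = isocontour_voi(image, 0.5, masks["cyl"].centroid_index())
        assert measure_volume(voi, image) == pytest.approx(473.0, rel=0.02)

    def test_counts_equal_exhaustive_sum(self, rng):
        values = rng.random((8, 8, 8)) + 0.05
        image = ActivityImage(values, (2, 2, 2))
        voi = isocontour_voi(image, 0.3, tuple(np.unravel_index(values.argmax(), values.shape)))
        expected = sum(values[tuple(idx)] for idx in np.argwhere(voi.mask))
        assert measure_counts(voi, image) == pytest.approx(expected, rel=1e-12)

    def test_nested_vois_have_ordered_counts(self, rng):
        values = rng.random((9, 9, 9))
        values[4, 4, 4] = 2.0
        image = ActivityImage(values, (1, 1, 1))
        a = isocontour_voi(image, 0.8, (4, 4, 4))
        b = isocontour_voi(image, 0.3, (4, 4, 4))
        assert measure_counts(a, image) <= measure_counts(b, image)


class TestAnatomicalFit:
    def test_constructed_fixed_point_recovers_threshold(self):
        """Reference equal to the 40% superlevel set is matched at 0.40, Dice 1."""
        rng = np.random.default_rng(5)
        values = rng.random((12, 12, 12))
        values[6, 6, 6] = 1.0  # ensure a unique interior maximum
        image = ActivityImage(values, (1, 1, 1))
        voi40 = isocontour_voi(image, 0.40, (6, 6, 6))
        ref = ReferenceMask(voi40.mask, "level40", (1, 1, 1))
        fit = fit_threshold_anatomical(image, ref, seed_point=(6, 6, 6))
        assert fit.best_threshold_fraction == pytest.approx(0.40)
        assert fit.objective == pytest.approx(1.0)

    def test_dice_ties_break_to_smallest_threshold(self):
        """On a binary object every threshold gives Dice 1; the smallest is kept."""
        values = np.zeros((10, 10, 10))
        values[3:7, 3:7, 3:7] = 5.0
        image = ActivityImage(values, (1, 1, 1))
        ref = ReferenceMask(values > 0, "cube", (1, 1, 1))
        fit = fit_threshold_anatomical(image, ref, seed_point=(4, 4, 4))
        assert fit.best_threshold_fraction == pytest.approx(0.01)
        assert fit.objective == pytest.approx(1.0)

    def test_pristine_phantom_reaches_dice_one(self, jaszczak_low_contrast):
        """Noise-free unblurred objects are recovered exactly (Dice >= 0.99)."""
        _, image, masks = jaszczak_low_contrast
        for label in ("Cylinder 1", "Sphere 1", "Sphere 4"):
            fit = fit_threshold_anatomical(image, masks[label])
            assert fit.objective >= 0.99, label

    def test_noise_free_blurred_spheres_recovered_within_10pct(self,
                                                               jaszczak_low_contrast):
        """With 15 mm PSF (no noise) spheres >= 16 mL are measured within 10%."""
        spec, pristine, masks = jaszczak_low_contrast
        image = degrade(pristine, AcquisitionModel(psf_fwhm=15, total_counts=1e7,
                                                   noise=False))
        for label, true_mL in [("Sphere 1", 55.0), ("Sphere 2", 20.5),
                               ("Sphere 3", 16.0)]:
            mask = masks[label]
            fit = fit_threshold_anatomical(image, mask)
            seed = np.unravel_index(
                int(np.argmax(np.where(mask.values, image.values, -np.inf))),
                image.values.shape)
            voi = isocontour_voi(image, fit.best_threshold_fraction, seed,
                                 search_region=mask)
            err = abs(measure_volume(voi, image) - true_mL) / true_mL
            assert err <= 0.10, (label, err)

    def test_trace_records_every_candidate(self):
        values = np.zeros((8, 8, 8))
        values[2:6, 2:6, 2:6] = 1.0
        image = ActivityImage(values, (1, 1, 1))
        ref = ReferenceMask(values > 0, "cube", (1, 1, 1))
        grid = np.array([0.2, 0.5, 0.9])
        fit = fit_threshold_anatomical(image, ref, seed_point=(3, 3, 3),
                                       threshold_grid=grid)
        assert list(fit.trace["threshold"]) == [0.2, 0.5, 0.9]

    def test_all_empty_candidates_fail(self):
        values = np.zeros((6, 6, 6))
        values[0, 0, 0] = 1.0
        image = ActivityImage(values, (1, 1, 1))
        ref = ReferenceMask(np.pad(np.ones((2, 2, 2), bool), (2, 2))[:6, :6, :6],
                            "far", (1, 1, 1))
        with pytest.raises((ThresholdFitError, EmptyVOIError, ValueError)):
            fit_threshold_anatomical(image, ref, seed_point=(3, 3, 3))


class TestHotspotFit:
    @staticmethod
    def _blurred_sphere(ratio=6.0, seed=None):
        ext = 192.0
        bg = GeometricObject("cylinder", (ext / 2,) * 3, (80.0, 170.0), 1.0, "bg")
        sph = GeometricObject("sphere", (ext / 2,) * 3, (sphere_radius_mm(55.0),),
                              ratio, "s")
        spec = PhantomSpec((bg, sph), grid_shape=(48, 48, 48), voxel_size=(4, 4, 4))
        pristine, masks = rasterize(spec)
        acq = AcquisitionModel(psf_fwhm=15, total_counts=5e6,
                               noise=seed is not None, seed=seed or 0)
        return degrade(pristine, acq), masks

    def test_step_edge_object_recovered_exactly(self):
        """A binary object with no blur or noise is measured exactly."""
        values = np.zeros((24, 24, 24))
        values[8:16, 8:16, 8:16] = 4.0
        image = ActivityImage(values, (4, 4, 4))
        fit = fit_threshold_hotspot(image, (11, 11, 11), display_smoothing_mm=0.0)
        assert float(fit.trace["volume_mL"].iloc[0]) == pytest.approx(512 * 0.064)

    def test_two_gammas_give_two_volumes(self):
        image, masks = self._blurred_sphere(seed=9)
        seed_idx = tuple(np.argwhere(masks["s"].values)[0])
        v = {}
        for g in (1.0, 0.4):
            fit = fit_threshold_hotspot(image, seed_idx, display_gamma=g,
                                        max_search_radius_mm=50.0)
            v[g] = float(fit.trace["volume_mL"].iloc[0])
        assert v[1.0] != v[0.4]
        assert v[0.4] > v[1.0]  # brighter window pushes the edge outward

    def test_deterministic_for_fixed_inputs(self):
        image, masks = self._blurred_sphere(seed=9)
        seed_idx = tuple(np.argwhere(masks["s"].values)[0])
        fits = [fit_threshold_hotspot(image, seed_idx, display_gamma=0.7)
                for _ in range(2)]
        assert fits[0].best_threshold_fraction == fits[1].best_threshold_fraction
        assert fits[0].trace.equals(fits[1].trace)

    def test_flat_image_has_no_edge(self):
        image = ActivityImage(np.full((16, 16, 16), 3.0), (4, 4, 4))
        with pytest.raises(ThresholdFitError):
            fit_threshold_hotspot(image, (8, 8, 8))


def test_dice_coefficient_basics():
    a = np.zeros((4, 4, 4), bool)
    a[:2] = True
    assert dice_coefficient(a, a) == 1.0
    assert dice_coefficient(a, ~a) == 0.0
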