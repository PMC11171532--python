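"""Phantom generator: determinism, geometry, covariate fidelity."""

import numpy as np
import pytest
from scipy import ndimage

from mammosub.image_io import MammogramImage
from mammosub.phantom import (
    PhantomSpec,
    generate_bilateral_case,
    generate_cohort,
    insert_lesion,
    smooth_random_field,
)


class TestSmoothRandomField:
    def test_zero_magnitude_gives_zero_field(self):
        f = smooth_random_field((32, 32), 0.0, 8.0, seed=1)
        assert f.shape == (2, 32, 32)
        assert np.all(f == 0)

    def test_deterministic_under_seed(self):
        a = smooth_random_field((32, 48), 2.0, 8.0, seed=5)
        b = smooth_random_field((32, 48), 2.0, 8.0, seed=5)
        np.testing.assert_array_equal(a, b)
        c = smooth_random_field((32, 48), 2.0, 8.0, seed=6)
        assert not np.array_equal(a, c)

    def test_rms_close_to_requested_magnitude(self):
        rmss = []
        for seed in range(10):
            f = smooth_random_field((64, 64), 3.0, 12.0, seed=seed)
            rmss.append(np.sqrt((f**2).sum(axis=0).mean()))
        assert abs(np.mean(rmss) - 3.0) < 0.6  # within 20 %

    def test_zero_mean_components(self):
        f = smooth_random_field((64, 64), 3.0, 12.0, seed=3)
        assert abs(f[0].mean()) < 1e-5
        assert abs(f[1].mean()) < 1e-5

    @pytest.mark.parametrize("shape", [(0, 10), (10, -1)])
    def test_rejects_nonpositive_shape(self, shape):
        with pytest.raises(ValueError):
            smooth_random_field(shape, 1.0, 4.0, seed=0)


class TestGenerateBilateralCase:
    def test_symmetric_case_mirrors_exactly(self, symmetric_case):
        left_flipped = symmetric_case.left_image.pixels[:, ::-1]
        np.testing.assert_array_equal(left_flipped, symmetric_case.right_image.pixels)

    def test_deterministic_under_seed(self):
        spec = PhantomSpec(image_height=96, image_width=96, seed=11)
        a = generate_bilateral_case(spec)
        b = generate_bilateral_case(spec)
        np.testing.assert_array_equal(a.right_image.pixels, b.right_image.pixels)
        np.testing.assert_array_equal(a.left_image.pixels, b.left_image.pixels)
        np.testing.assert_array_equal(a.true_field, b.true_field)

    @pytest.mark.parametrize("density", [0.25, 0.65])
    def test_glandular_coverage_matches_request(self, density):
        spec = PhantomSpec(
            image_height=128, image_width=128, density_fraction=density, seed=2
        )
        case = generate_bilateral_case(spec)
        assert abs(case.density_pct / 100.0 - density) < 0.05

    def test_breast_area_fidelity_over_random_specs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            frac = rng.uniform(0.12, 0.75)
            spec = PhantomSpec(
                image_height=96,
                image_width=96,
                breast_area_fraction=frac,
                seed=int(rng.integers(2**31)),
            )
            case = generate_bilateral_case(spec)
            assert abs(case.breast_area_pct / 100.0 - frac) < 0.03

    def test_mask_single_component_touching_chest_wall(self, phantom_case):
        mask = phantom_case.right_mask
        _, n = ndimage.label(mask)
        assert n == 1
        assert mask[:, 0].any()  # chest wall at column 0
        assert not mask[:, -1].any()

    def test_infeasible_area_raises(self):
        with pytest.raises(ValueError, match="not attainable"):
            spec = PhantomSpec(
                image_height=64, image_width=64, breast_area_fraction=0.999
            )
            generate_bilateral_case(spec)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(breast_area_fraction=1.2)
        with pytest.raises(ValueError):
            PhantomSpec(density_fraction=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(deform_magnitude=-1.0)


class TestGenerateCohort:
    def test_count_and_manifest_rows(self):
        cases, manifest = generate_cohort(8, seed=1, image_size=(64, 64))
        assert len(cases) == 8
        assert len(manifest) == 8
        assert manifest.case_id.is_unique

    def test_covariates_within_study_ranges(self):
        cases, manifest = generate_cohort(12, seed=3, image_size=(64, 64))
        assert manifest.breast_area_pct.between(11.1, 79.8).all()
        assert manifest.thickness_mm.between(12.0, 84.0).all()

    def test_same_seed_identical_manifest(self):
        _, a = generate_cohort(5, seed=9, image_size=(64, 64))
        _, b = generate_cohort(5, seed=9, image_size=(64, 64))
        assert a.equals(b)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty range"):
            generate_cohort(
                3, covariate_ranges={"thickness_mm": (50.0, 50.0)}, seed=0
            )


class TestInsertLesion:
    def test_zero_radius_leaves_image_unchanged(self, phantom_case):
        center = tuple(np.argwhere(phantom_case.right_mask)[0])
        out = insert_lesion(
            phantom_case.right_image, phantom_case.right_mask, center, 0.0, 0.3
        )
        np.testing.assert_array_equal(out.pixels, phantom_case.right_image.pixels)

    def test_center_amplitude_and_support(self, phantom_case):
        mask = phantom_case.right_mask
        interior = ndimage.binary_erosion(mask, iterations=10)
        r0, c0 = np.argwhere(interior)[len(np.argwhere(interior)) // 2]
        out = insert_lesion(
            phantom_case.right_image, mask, (r0, c0), 6.0, 0.2
        )
        delta = out.pixels - phantom_case.right_image.pixels
        assert delta[r0, c0] == pytest.approx(0.2, abs=1e-6)
        rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        outside = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) >= 6.0
        assert np.all(delta[outside] == 0)

    def test_difference_image_highlights_unilateral_lesion(self, phantom_case):
        mask = phantom_case.right_mask
        interior = ndimage.binary_erosion(mask, iterations=10)
        r0, c0 = np.argwhere(interior)[0]
        out = insert_lesion(phantom_case.right_image, mask, (r0, c0), 8.0, 0.3)
        diff = np.abs(out.pixels - phantom_case.right_image.pixels)
        rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        inside = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) < 8.0
        assert diff[inside].mean() > diff[mask & ~inside].mean()

    def test_center_outside_mask_rejected(self, phantom_case):
        bg = tuple(np.argwhere(~phantom_case.right_mask)[-1])
        with pytest.raises(ValueError, match="outside"):
            insert_lesion(
                phantom_case.right_image, phantom_case.right_mask, bg, 5.0, 0.1
            )
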