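"""Deformation operator: draws, fields, warping, composition, sessions."""

import numpy as np
import pytest

from fracaug import (
    DeformParams,
    DisplacementField,
    PhiDraw,
    ValidationError,
    compose_fields,
    dice,
    generate_label_field,
    jacobian_min,
    sample_phi_draw,
    simulate_session,
    warp_image,
    warp_labels,
    warp_mask,
)
from fracaug.grid import BinaryMask, ImageVolume, LabelVolume

from conftest import constant_field, smooth_random_field, smooth_random_image

IDENTITY = PhiDraw(translation_mm=(0, 0, 0), scale_factor=1.0, rotation_deg=(0, 0, 0))
ZERO_BOUNDS = DeformParams(p_disp_mm=0, p_exp=0, p_shrink=0, p_rot_deg=0)


class TestSamplePhiDraw:
    def test_zero_bounds_give_exact_identity(self):
        draw = sample_phi_draw(ZERO_BOUNDS, np.random.default_rng(0))
        assert draw.is_identity

    def test_uniform_law_bounds_and_mean(self):
        """10^4 draws stay inside the bounds; the empirical mean of each
        translation component is within 3 standard errors of zero."""
        params = DeformParams(p_disp_mm=5.0)
        rng = np.random.default_rng(42)
        draws = np.array([sample_phi_draw(params, rng).translation_mm
                          for _ in range(10_000)])
        assert np.all(np.abs(draws) <= 5.0)
        se = 5.0 / np.sqrt(3) / np.sqrt(len(draws))  # sd of U(-5, 5) is 5/sqrt(3)
        assert np.all(np.abs(draws.mean(axis=0)) <= 3 * se)

    def test_scale_and_rotation_within_bounds(self):
        params = DeformParams(p_exp=0.2, p_shrink=0.1, p_rot_deg=7.0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            draw = sample_phi_draw(params, rng)
            assert 0.9 <= draw.scale_factor <= 1.2
            assert all(abs(r) <= 7.0 for r in draw.rotation_deg)

    def test_same_seed_same_sequence_distinct_draws(self):
        params = DeformParams()
        seq_a = [sample_phi_draw(params, np.random.default_rng(5)) for _ in range(1)]
        rng = np.random.default_rng(5)
        seq_b = [sample_phi_draw(params, rng) for _ in range(3)]
        assert seq_a[0] == seq_b[0]
        assert len(set(seq_b)) == 3  # rng advances between organs


class TestGenerateLabelField:
    def test_identity_draw_gives_zero_field(self, ellipsoid_mask, default_params):
        field = generate_label_field(ellipsoid_mask, IDENTITY, default_params)
        assert not field.vectors.any()

    def test_empty_mask_rejected(self, default_params):
        empty = BinaryMask(voxels=np.zeros((8, 8, 8), bool), spacing_mm=(1, 1, 1))
        with pytest.raises(ValidationError):
            generate_label_field(empty, IDENTITY, default_params)

    def test_translation_recovered_at_warped_centroid(self, ellipsoid_mask,
                                                      default_params):
        t = np.array([4.0, -3.0, 2.0])
        draw = PhiDraw(translation_mm=tuple(t), scale_factor=1.0,
                       rotation_deg=(0, 0, 0))
        field = generate_label_field(ellipsoid_mask, draw, default_params)
        warped = warp_mask(ellipsoid_mask, field)
        shift = warped.centroid_mm() - ellipsoid_mask.centroid_mm()
        # within half a voxel (1 mm grid)
        assert np.all(np.abs(shift - t) <= 0.5)

    def test_fractional_translation_recovered_by_mass_centroid(self, ellipsoid_mask,
                                                               default_params):
        """Sub-voxel translations are recovered by the intensity-weighted
        centroid of the linearly warped mask."""
        t = np.array([3.3, -2.6, 1.8])
        draw = PhiDraw(translation_mm=tuple(t), scale_factor=1.0,
                       rotation_deg=(0, 0, 0))
        field = generate_label_field(ellipsoid_mask, draw, default_params)
        soft = warp_image(ImageVolume(values=ellipsoid_mask.voxels.astype(float),
                                      spacing_mm=ellipsoid_mask.spacing_mm), field)
        coords = soft.world_coordinates()
        centroid = (coords * soft.values).sum(axis=(1, 2, 3)) / soft.values.sum()
        assert np.all(np.abs(centroid - ellipsoid_mask.centroid_mm() - t) <= 0.5)

    def test_expansion_recovers_volume_ratio(self, ellipsoid_mask, default_params):
        s = 1.12
        draw = PhiDraw(translation_mm=(0, 0, 0), scale_factor=s, rotation_deg=(0, 0, 0))
        field = generate_label_field(ellipsoid_mask, draw, default_params)
        warped = warp_mask(ellipsoid_mask, field)
        ratio = warped.voxel_count / ellipsoid_mask.voxel_count
        assert ratio == pytest.approx(s ** 3, rel=0.10)

    def test_shrinkage_recovers_volume_ratio(self, ellipsoid_mask, default_params):
        s = 0.88
        draw = PhiDraw(translation_mm=(0, 0, 0), scale_factor=s, rotation_deg=(0, 0, 0))
        field = generate_label_field(ellipsoid_mask, draw, default_params)
        warped = warp_mask(ellipsoid_mask, field)
        ratio = warped.voxel_count / ellipsoid_mask.voxel_count
        assert ratio == pytest.approx(s ** 3, rel=0.10)


class TestComposeFields:
    def test_zero_is_identity_element(self):
        u = smooth_random_field(seed=3)
        zero = DisplacementField.zero(u)
        np.testing.assert_array_equal(compose_fields(zero, u).vectors, u.vectors)
        np.testing.assert_array_equal(compose_fields(u, zero).vectors, u.vectors)

    def test_matches_sequential_warping_on_smooth_image(self):
        image = smooth_random_image(seed=0)
        u1 = smooth_random_field(seed=1)
        u2 = smooth_random_field(seed=2)
        sequential = warp_image(warp_image(image, u1), u2)
        one_shot = warp_image(image, compose_fields(u1, u2))
        dynamic_range = image.values.max() - image.values.min()
        err = np.abs(sequential.values - one_shot.values).max()
        assert err <= 0.02 * dynamic_range

    def test_translations_compose_additively(self):
        t1, t2 = np.array([3.0, -2.0, 1.0]), np.array([-1.5, 2.5, 0.5])
        composed = compose_fields(constant_field((32, 32, 32), t1),
                                  constant_field((32, 32, 32), t2))
        interior = composed.vectors[3:-3, 3:-3, 3:-3]
        assert np.abs(interior - (t1 + t2)).max() <= 1e-3

    def test_geometry_mismatch_rejected(self):
        u = smooth_random_field(seed=1)
        v = smooth_random_field(seed=1, spacing_mm=(1, 1, 1))
        from fracaug import GeometryError

        with pytest.raises(GeometryError):
            compose_fields(u, v)


class TestWarping:
    def test_zero_field_is_exact_identity(self, phantom):
        image, labels = phantom
        zero = DisplacementField.zero(image)
        np.testing.assert_array_equal(warp_image(image, zero).values, image.values)
        np.testing.assert_array_equal(warp_labels(labels, zero).codes, labels.codes)

    def test_one_voxel_shift_is_exact_in_the_interior(self):
        image = smooth_random_image(seed=4)
        field = constant_field(image.shape, (2.0, 0.0, 0.0))  # one voxel at 2 mm
        shifted = warp_image(image, field)
        np.testing.assert_allclose(shifted.values[:-1], image.values[1:], atol=1e-12)

    def test_warped_intensities_stay_within_source_extrema(self, phantom):
        image, _ = phantom
        field = smooth_random_field(shape=image.shape, seed=6, amplitude=6.0)
        warped = warp_image(image, field)
        assert warped.values.min() >= image.values.min() - 1e-9
        assert warped.values.max() <= image.values.max() + 1e-9

    def test_label_warping_never_creates_codes(self, phantom):
        _, labels = phantom
        field = smooth_random_field(shape=labels.shape, seed=7, amplitude=8.0)
        warped = warp_labels(labels, field)
        assert set(warped.present_codes) <= set(labels.present_codes)

    def test_labels_follow_their_image(self, clean_phantom):
        """After warping image and labels with one field, each organ's mean
        intensity stays at its phantom mean (interior voxels)."""
        from scipy import ndimage

        image, labels = clean_phantom
        from fracaug.phantom import DEFAULT_ORGAN_MEANS

        rng = np.random.default_rng(8)
        params = DeformParams(p_disp_mm=4.0, p_exp=0.08, p_shrink=0.08, p_rot_deg=4.0)
        sim_image, sim_labels, _ = simulate_session(image, labels, params, rng)
        for code in sim_labels.present_codes:
            interior = ndimage.binary_erosion(sim_labels.codes == code)
            if interior.sum() < 10:
                continue
            mean = sim_image.values[interior].mean()
            expected = DEFAULT_ORGAN_MEANS[sim_labels.organ_name(code)]
            assert abs(mean - expected) < 10.0


class TestSimulateSession:
    def test_zero_bounds_are_an_exact_fixed_point(self, phantom):
        image, labels = phantom
        out_image, out_labels, total = simulate_session(
            image, labels, ZERO_BOUNDS, np.random.default_rng(0))
        np.testing.assert_array_equal(out_image.values, image.values)
        np.testing.assert_array_equal(out_labels.codes, labels.codes)
        assert not total.vectors.any()

    def test_deforms_some_organ_and_reproduces(self, phantom, default_params):
        image, labels = phantom
        run = lambda: simulate_session(image, labels, default_params,
                                       np.random.default_rng(21))
        _, labels_a, total_a = run()
        _, labels_b, total_b = run()
        np.testing.assert_array_equal(labels_a.codes, labels_b.codes)
        np.testing.assert_array_equal(total_a.vectors, total_b.vectors)
        dscs = [dice(labels.mask(c), labels_a.mask(c)) for c in labels.present_codes]
        assert min(dscs) < 1.0

    def test_single_organ_reduces_to_one_field_and_warp(self, ellipsoid_mask,
                                                        default_params):
        labels = LabelVolume(codes=ellipsoid_mask.voxels.astype(np.int16),
                             organ_table={1: "blob"},
                             spacing_mm=ellipsoid_mask.spacing_mm)
        image = ImageVolume(values=ellipsoid_mask.voxels * 100.0,
                            spacing_mm=ellipsoid_mask.spacing_mm)
        seed = 33
        sim_image, sim_labels, total = simulate_session(
            image, labels, default_params, np.random.default_rng(seed))
        draw = sample_phi_draw(default_params, np.random.default_rng(seed))
        field = generate_label_field(labels.mask(1), draw, default_params)
        np.testing.assert_array_equal(total.vectors, field.vectors)
        np.testing.assert_array_equal(sim_image.values,
                                      warp_image(image, field).values)
        np.testing.assert_array_equal(sim_labels.codes,
                                      warp_labels(labels, field).codes)

    def test_all_background_rejected(self, default_params):
        labels = LabelVolume(codes=np.zeros((16, 16, 16), np.int16))
        image = ImageVolume(values=np.zeros((16, 16, 16)))
        with pytest.raises(ValidationError):
            simulate_session(image, labels, default_params, np.random.default_rng(0))


class TestJacobian:
    def test_zero_field_has_unit_jacobian(self):
        zero = DisplacementField(vectors=np.zeros((16, 16, 16, 3)), spacing_mm=(2, 2, 2))
        assert jacobian_min(zero) == pytest.approx(1.0)

    def test_translation_has_unit_jacobian(self):
        field = constant_field((16, 16, 16), (5.0, -3.0, 2.0))
        assert jacobian_min(field) == pytest.approx(1.0)

    def test_folding_field_detected(self, caplog):
        # u_x = -2x (in mm) gives dT/dx = 1 - 2 = -1 < 0: a fold.
        x_mm = np.arange(16)[:, None, None] * 2.0
        vectors = np.zeros((16, 16, 16, 3))
        vectors[..., 0] = -2.0 * x_mm
        field = DisplacementField(vectors=vectors, spacing_mm=(2, 2, 2))
        import logging

        with caplog.at_level(logging.WARNING, logger="fracaug.deform"):
            value = jacobian_min(field)
        assert value <= 0
        assert any("fold" in rec.message for rec in caplog.records)
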