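"""Per-cell morphometry: binarization, alignment, profiles, scores, EI."""

import math

import numpy as np
import pytest

from rbcmorph.analytic import (
    AnalyticEllipse,
    AnalyticTwoLobe,
    analytic_asymmetry_score,
    ray_cast_profile,
)
from rbcmorph.morphometry import (
    BinaryMask,
    RadialProfile,
    align_apex,
    asymmetry_score,
    binarize_crop,
    elongation_index,
    find_central_nadir,
    normalize_profile,
    principal_axis_angle,
    radial_profile,
    score_from_areas,
    score_mask,
)
from rbcmorph.synthetic import CellSpec, render_cell_mask

from conftest import render_mask


class TestBinarizeCrop:
    def test_separable_bimodal_crop_recovers_exact_footprint(self):
        mask = render_cell_mask(
            CellSpec("symmetric_ellipse", (32.3, 32.6), 14, 8, orientation=25), (65, 65)
        )
        crop = np.where(mask, 80.0, 200.0)
        got = binarize_crop(crop)
        assert np.array_equal(got.mask, mask)

    def test_ellipse_area_and_centroid(self):
        mask = render_cell_mask(
            CellSpec("symmetric_ellipse", (64.5, 64.5), 40, 20, orientation=90), (129, 129)
        )
        crop = np.where(mask, 90.0, 210.0)
        got = binarize_crop(crop)
        assert got.area == pytest.approx(math.pi * 40 * 20, rel=0.02)
        assert got.centroid[0] == pytest.approx(64.5, abs=0.5)
        assert got.centroid[1] == pytest.approx(64.5, abs=0.5)

    def test_component_nearest_anchor_is_kept(self):
        crop = np.full((64, 64), 200.0)
        crop[10:20, 10:20] = 80.0  # decoy, larger
        crop[40:46, 40:46] = 80.0  # near anchor
        got = binarize_crop(crop, anchor=(43.0, 43.0))
        assert got.mask[42, 42] and not got.mask[15, 15]

    def test_flat_crop_is_invalid(self):
        got = binarize_crop(np.full((32, 32), 128.0))
        assert not got.valid


class TestAlignApex:
    def test_rotated_ellipse_aligns_to_vertical(self):
        bm = render_mask("symmetric_ellipse", 40, 20, orientation=37.0)
        aligned = align_apex(bm)
        angle = principal_axis_angle(aligned)
        assert min(abs(angle - 90), abs(angle + 90), abs(angle - 270)) < 1.0
        assert aligned.area == pytest.approx(bm.area, rel=0.02)

    def test_circle_returned_unrotated_with_isotropy_flag(self):
        bm = render_mask("symmetric_ellipse", 25, 25)
        aligned = align_apex(bm)
        assert "isotropic" in aligned.flags
        assert np.array_equal(aligned.mask, bm.mask)

    def test_two_lobe_long_lobe_points_up(self):
        bm = render_mask("two_lobe", 30, 15, lobe_factor=1.5, orientation=120.0)
        aligned = align_apex(bm)
        rows = np.nonzero(aligned.mask.any(axis=1))[0]
        top_reach = aligned.centroid[0] - rows[0]
        bottom_reach = rows[-1] - aligned.centroid[0]
        assert top_reach > bottom_reach


class TestRadialProfile:
    def test_disk_profile_is_constant_radius(self):
        bm = render_mask("symmetric_ellipse", 20, 20)
        prof = radial_profile(bm)
        assert np.all(np.abs(prof.radii - 20) <= 0.5)

    def test_ellipse_profile_matches_closed_form(self):
        bm = render_mask("symmetric_ellipse", 40, 20, orientation=90.0)
        prof = radial_profile(bm)
        phi = np.deg2rad(np.arange(360) - 90.0)
        expected = 40 * 20 / np.sqrt((20 * np.cos(phi)) ** 2 + (40 * np.sin(phi)) ** 2)
        err = prof.radii - expected
        # pointwise limited by binary-mask quantization (~half a pixel);
        # unbiased on average
        assert np.max(np.abs(err)) <= 0.75
        assert np.sqrt(np.mean((err / expected) ** 2)) <= 0.015

    def test_point_symmetric_mask_gives_half_turn_shifted_profile(self):
        bm = render_mask("symmetric_ellipse", 30, 14, orientation=28.0)
        prof = radial_profile(bm)
        rotated = BinaryMask.from_array(bm.mask[::-1, ::-1])
        prof_rot = radial_profile(rotated)
        np.testing.assert_allclose(
            np.roll(prof.radii, 180), prof_rot.radii, atol=0.35
        )

    def test_empty_centroid_outside_flagged(self):
        # horseshoe: centroid falls in the gap
        rr, cc = np.mgrid[:81, :81]
        ring = ((rr - 40) ** 2 + (cc - 40) ** 2 <= 35**2) & (
            (rr - 40) ** 2 + (cc - 40) ** 2 >= 25**2
        ) & (rr < 55)
        prof = radial_profile(BinaryMask.from_array(ring))
        assert not prof.centroid_inside


class TestNormalizeProfile:
    def test_disk_normalizes_to_unit_radius(self):
        bm = render_mask("symmetric_ellipse", 20, 20)
        prof = normalize_profile(radial_profile(bm), bm.area)
        assert np.allclose(prof.radii, 1.0, atol=0.05)
        assert prof.equivalent_radius == pytest.approx(math.sqrt(bm.area / math.pi))

    def test_score_is_exactly_scale_free(self):
        bm = render_mask("two_lobe", 30, 16, lobe_factor=1.4)
        prof = radial_profile(bm)
        nadir = find_central_nadir(prof)
        raw = asymmetry_score(prof, nadir)
        norm = asymmetry_score(normalize_profile(prof, bm.area), nadir)
        assert norm.score == pytest.approx(raw.score, abs=1e-9)

    def test_doubling_mask_size_preserves_normalized_profile(self):
        small = render_mask("symmetric_ellipse", 20, 10, orientation=90.0)
        big = render_mask("symmetric_ellipse", 40, 20, orientation=90.0)
        p_small = normalize_profile(radial_profile(small), small.area)
        p_big = normalize_profile(radial_profile(big), big.area)
        assert np.max(np.abs(p_small.radii - p_big.radii)) < 0.06

    def test_nonpositive_area_rejected(self):
        bm = render_mask("symmetric_ellipse", 10, 6)
        with pytest.raises(ValueError):
            normalize_profile(radial_profile(bm), 0)


class TestNadir:
    def test_aligned_ellipse_nadir_at_half_turn(self):
        bm = render_mask("symmetric_ellipse", 40, 20, orientation=90.0)
        nadir = find_central_nadir(normalize_profile(radial_profile(bm), bm.area))
        assert nadir.valid
        assert nadir.nadir_index == pytest.approx(180.0, abs=2.0)

    def test_disk_profile_is_not_bimodal(self):
        bm = render_mask("symmetric_ellipse", 20, 20)
        nadir = find_central_nadir(normalize_profile(radial_profile(bm), bm.area))
        assert not nadir.valid

    def test_two_lobe_nadir_matches_analytic_oracle(self):
        lam = 1.5
        asym, _, _ = score_mask(render_mask("two_lobe", 30, 18, lobe_factor=lam))
        _, oracle_nadir = analytic_asymmetry_score(
            AnalyticTwoLobe(30, 18, lam), return_nadir=True
        )
        pipeline_nadir_abs = (asym.shift + asym.nadir_index) % 360.0
        assert pipeline_nadir_abs == pytest.approx(oracle_nadir, abs=3.0)


class TestAsymmetryScore:
    def test_formula_on_given_half_areas(self):
        assert score_from_areas(120.0, 90.0) == pytest.approx(25.0)
        assert score_from_areas(90.0, 120.0) == pytest.approx(100.0 / 3.0)
        with pytest.raises(ValueError):
            score_from_areas(0.0, 1.0)

    def test_mirror_symmetric_ellipse_scores_near_zero(self):
        asym, _, _ = score_mask(render_mask("symmetric_ellipse", 40, 20))
        assert asym.valid
        assert asym.score <= 0.5

    def test_score_nonnegative_and_zero_iff_equal_halves(self):
        profile = RadialProfile(np.ones(360))
        res = asymmetry_score(
            profile,
            find_central_nadir(profile),
        )
        # constant profile is not bimodal: invalid rather than zero
        assert not res.valid
        bm = render_mask("two_lobe", 30, 16, lobe_factor=1.6)
        asym, _, _ = score_mask(bm)
        assert asym.valid and asym.score > 0
        assert asym.A1 > 0 and asym.A2 > 0

    def test_scores_increase_with_lobe_factor(self):
        scores = []
        for lam in (1.0, 1.2, 1.5, 2.0):
            asym, _, _ = score_mask(render_mask("two_lobe", 40, 24, lobe_factor=lam))
            scores.append(asym.score)
        assert scores == sorted(scores)
        assert scores[-1] > scores[0] + 5


class TestElongationIndex:
    def test_circle_has_zero_ei(self):
        _, ei, _ = score_mask(render_mask("symmetric_ellipse", 25, 25))
        assert ei.EI == pytest.approx(0.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        bm = render_mask("symmetric_ellipse", 40, 20)
        ei = elongation_index(align_apex(bm))
        assert ei.EI == pytest.approx(1 / 3, abs=0.02)

    def test_rotated_circle_stays_round(self):
        for ori in (0.0, 30.0, 77.0):
            bm = render_mask("symmetric_ellipse", 30, 30, orientation=ori)
            _, ei, _ = score_mask(bm)
            assert ei.EI <= 0.02

    def test_tiny_mask_invalid(self):
        bm = BinaryMask.from_array(np.pad(np.ones((1, 2), bool), 2))
        assert not elongation_index(bm).valid


class TestScoreInvariances:
    def test_rotation_invariance_of_score(self):
        scores = [
            score_mask(render_mask("symmetric_ellipse", 40, 20, orientation=o))[0].score
            for o in np.linspace(0, 165, 12)
        ]
        assert max(scores) - min(scores) <= 1.0

    def test_scale_invariance_of_score(self):
        for lam in (1.0, 1.5):
            s1 = score_mask(render_mask("two_lobe", 20, 12, lobe_factor=lam))[0].score
            s2 = score_mask(render_mask("two_lobe", 40, 24, lobe_factor=lam))[0].score
            assert abs(s1 - s2) <= 0.5

    def test_pipeline_matches_continuous_oracle_on_random_shapes(self, rng):
        """Spot check of raster-vs-continuous agreement (full sweep in the
        acceptance suite)."""
        for _ in range(5):
            a = rng.uniform(28, 42)
            b = a / rng.uniform(1.6, 2.4)
            lam = rng.uniform(1.0, 1.9)
            ori = rng.uniform(0, 180)
            pipeline = score_mask(
                render_mask("two_lobe", a, b, lobe_factor=lam, orientation=ori)
            )[0].score
            oracle = analytic_asymmetry_score(AnalyticTwoLobe(a, b, lam))
            assert pipeline == pytest.approx(oracle, abs=1.0)


class TestRayCastOracle:
    def test_ellipse_ray_cast_matches_closed_form(self):
        shape = AnalyticEllipse(30, 15, orientation=0.0)
        radii = ray_cast_profile(shape, 1.0)
        phi = np.deg2rad(np.arange(360))
        expected = 30 * 15 / np.sqrt((15 * np.cos(phi)) ** 2 + (30 * np.sin(phi)) ** 2)
        np.testing.assert_allclose(radii, expected, rtol=1e-7)

    def test_analytic_score_increases_with_lobe_factor_at_one_degree(self):
        scores = [
            analytic_asymmetry_score(AnalyticTwoLobe(30, 18, lam), resolution_deg=1.0)
            for lam in np.arange(1.0, 2.01, 0.1)
        ]
        assert all(b > a for a, b in zip(scores, scores[1:]))
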