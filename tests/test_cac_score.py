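"""Agatston machinery: bands, brute-force equivalence, volumes, grading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacstudy import cac_score
from cacstudy.cac_score import ScoringConfig


def brute_force_agatston(volume, pixel_area, threshold=130.0):
    """Per-pixel flood-fill oracle: independent of the vectorized scorer."""
    total = 0.0
    for sl in volume:
        mask = sl >= threshold
        seen = np.zeros_like(mask)
        ny, nx = mask.shape
        for y0 in range(ny):
            for x0 in range(nx):
                if not mask[y0, x0] or seen[y0, x0]:
                    continue
                stack, comp = [(y0, x0)], []
                seen[y0, x0] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                max_hu = max(sl[y, x] for y, x in comp)
                total += len(comp) * pixel_area * cac_score.density_factor(max_hu)
    return total


class TestDensityFactor:
    @pytest.mark.parametrize(
        "hu,factor",
        [(129.9, 0), (130.0, 1), (150.0, 1), (199.9, 1), (200.0, 2),
         (250.0, 2), (300.0, 3), (350.0, 3), (399.9, 3), (400.0, 4), (1200.0, 4)],
    )
    def test_bands(self, hu, factor):
        assert cac_score.density_factor(hu) == factor

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cac_score.density_factor(float("nan"))


class TestCadGrade:
    @pytest.mark.parametrize(
        "score,grade",
        [(0, "No CAD"), (0.5, "Minimal"), (10, "Minimal"), (11, "Mild"),
         (77, "Mild"), (100, "Mild"), (101, "Moderate"), (400, "Moderate"),
         (407, "Severe")],
    )
    def test_bands(self, score, grade):
        assert cac_score.cad_grade(score) == grade


class TestResample:
    def test_pairs_averaged(self):
        vol = np.arange(4 * 2 * 2, dtype=float).reshape(4, 2, 2)
        out = cac_score.resample_to_scoring_slices(vol, 1.5)
        assert out.shape == (2, 2, 2)
        np.testing.assert_allclose(out[0], (vol[0] + vol[1]) / 2)

    def test_constant_volume_unchanged(self):
        vol = np.full((4, 3, 3), 7.0)
        out = cac_score.resample_to_scoring_slices(vol, 1.5)
        np.testing.assert_allclose(out, 7.0)

    def test_alternating_slabs(self):
        vol = np.empty((6, 2, 2))
        vol[0::2] = 10.0
        vol[1::2] = 30.0
        out = cac_score.resample_to_scoring_slices(vol, 1.5)
        np.testing.assert_allclose(out, 20.0)

    def test_indivisible_spacing_rejected(self):
        with pytest.raises(ValueError):
            cac_score.resample_to_scoring_slices(np.zeros((3, 2, 2)), 0.9)


class TestAgatstonScore:
    def test_all_below_threshold_scores_zero(self):
        total, lesions = cac_score.agatston_score(np.full((2, 8, 8), 50.0), (1.0, 1.0))
        assert total == 0.0 and lesions == []

    def test_uniform_lesion_hand_value(self):
        # one 10-pixel lesion of 250 HU at 1 mm^2 pixels: area 10 x factor 2
        vol = np.full((1, 8, 8), 0.0)
        vol[0, 2:4, 1:6] = 250.0
        total, _ = cac_score.agatston_score(vol, (1.0, 1.0))
        assert total == pytest.approx(20.0)

    def test_slice_additivity(self):
        one = np.zeros((1, 8, 8))
        one[0, 2:4, 1:6] = 250.0
        two = np.concatenate([one, one])
        t1, _ = cac_score.agatston_score(one, (1.0, 1.0))
        t2, _ = cac_score.agatston_score(two, (1.0, 1.0))
        assert t2 == pytest.approx(2 * t1)

    def test_matches_brute_force_on_random_volumes(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            vol = rng.normal(100, 120, size=(4, 32, 32))
            pixel_area = 0.32 * 0.32
            total, _ = cac_score.agatston_score(vol, (0.32, 0.32))
            assert total == pytest.approx(brute_force_agatston(vol, pixel_area))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(100, 120, size=(2, 16, 16))
        t0, _ = cac_score.agatston_score(vol, (1.0, 1.0))
        t90, _ = cac_score.agatston_score(np.rot90(vol, axes=(1, 2)), (1.0, 1.0))
        assert t90 == pytest.approx(t0)
        v0 = cac_score.calcium_volume(vol, (1.0, 1.0))
        v90 = cac_score.calcium_volume(np.rot90(vol, axes=(1, 2)), (1.0, 1.0))
        assert v90 == pytest.approx(v0)


class TestCalciumVolume:
    def test_empty_mask_zero(self):
        assert cac_score.calcium_volume(np.zeros((2, 4, 4)), (1.0, 1.0)) == 0.0

    def test_voxel_arithmetic(self):
        vol = np.zeros((1, 20, 20))
        vol[0, :10, :10] = 500.0  # 100 voxels above threshold
        cfg = ScoringConfig(slice_thickness_mm=1.5)
        got = cac_score.calcium_volume(vol, (0.32, 0.32), cfg)
        assert got == pytest.approx(100 * 0.32 * 0.32 * 1.5)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        vol = rng.normal(150, 60, size=(2, 16, 16))
        volumes = [
            cac_score.calcium_volume(vol, (1.0, 1.0), ScoringConfig(threshold_hu=t))
            for t in (100, 130, 200, 300)
        ]
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))


class TestReclassification:
    def test_identical_lists(self):
        assert cac_score.reclassification_rate(["Mild"] * 9, ["Mild"] * 9) == 0.0

    def test_one_in_nine(self):
        ref = ["Mild"] * 9
        got = ref.copy()
        got[0] = "Moderate"
        assert cac_score.reclassification_rate(got, ref) == 11.1

    def test_all_mismatch(self):
        assert cac_score.reclassification_rate(["Mild"] * 9, ["Severe"] * 9) == 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cac_score.reclassification_rate(["Mild"], ["Mild", "Mild"])


class TestScoringProperties:
    """Property-based invariants of the scoring primitives."""

    @given(hu=st.floats(min_value=-500.0, max_value=2000.0, allow_nan=False))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_density_factor_monotone_and_banded(self, hu):
        f = cac_score.density_factor(hu)
        assert f in (0, 1, 2, 3, 4)
        assert cac_score.density_factor(hu + 100.0) >= f
        assert (f == 0) == (hu < 130.0)

    @given(score=st.floats(min_value=0.0, max_value=5000.0, allow_nan=False))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_grade_monotone_in_score(self, score):
        order = {g: i for i, g in enumerate(cac_score.GRADES)}
        g1 = cac_score.cad_grade(score)
        g2 = cac_score.cad_grade(score + 37.0)
        assert order[g2] >= order[g1]

    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_reclassification_bounds_and_identity(self, idx):
        grades = [cac_score.GRADES[i] for i in idx]
        assert cac_score.reclassification_rate(grades, grades) == 0.0
        other = [cac_score.GRADES[(i + 1) % 5] for i in idx]
        rate = cac_score.reclassification_rate(grades, other)
        assert rate == 100.0
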