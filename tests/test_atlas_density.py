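"""Probability-weighted regional density extraction."""

import nibabel as nib
import numpy as np
import pytest

from cytogmd.atlas_density import (
    GrayMatterMap,
    ProbabilisticRegionMap,
    apply_atlas_translation,
    extract_all_regions,
    extract_regional_density,
    load_probability_map,
)
from cytogmd.synthetic_data import simulate_voxel_scene

AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])


def _map(probs, name="r", hemi="left", affine=AFFINE):
    return ProbabilisticRegionMap(name, hemi, np.asarray(probs, float), affine)


def _gm(values, affine=AFFINE):
    return GrayMatterMap(np.asarray(values, float), affine)


def _save(tmp_path, data, name):
    path = tmp_path / name
    nib.save(nib.Nifti1Image(np.asarray(data, float), AFFINE), str(path))
    return path


class TestLoader:
    def test_percent_scale_autodetected(self, tmp_path):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 100.0
        data[2, 2, 2] = 40.0
        m = load_probability_map(_save(tmp_path, data, "p.nii.gz"))
        assert m.probabilities.max() == pytest.approx(1.0)
        assert m.probabilities[2, 2, 2] == pytest.approx(0.4)

    def test_unit_scale_left_unchanged(self, tmp_path):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 0.98
        m = load_probability_map(_save(tmp_path, data, "p.nii.gz"))
        assert m.probabilities[1, 1, 1] == pytest.approx(0.98)

    def test_all_zero_map_rejected(self, tmp_path):
        path = _save(tmp_path, np.zeros((4, 4, 4)), "z.nii.gz")
        with pytest.raises(ValueError, match="empty probability map"):
            load_probability_map(path)

    def test_negative_values_rejected(self, tmp_path):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = -0.5
        data[1, 1, 1] = 0.5
        with pytest.raises(ValueError, match="negative"):
            load_probability_map(_save(tmp_path, data, "n.nii.gz"))

    def test_non_3d_rejected(self, tmp_path):
        path = tmp_path / "v.nii.gz"
        nib.save(nib.Nifti1Image(np.ones((3, 3, 3, 2)), AFFINE), str(path))
        with pytest.raises(ValueError, match="3D"):
            load_probability_map(path)


class TestTranslation:
    def test_zero_shift_is_identity(self):
        m = _map(np.full((4, 4, 4), 0.5))
        shifted = apply_atlas_translation(m, 0.0, 0.0)
        np.testing.assert_array_equal(shifted.affine, m.affine)

    def test_y4_z5_moves_origin(self):
        m = _map(np.full((4, 4, 4), 0.5))
        shifted = apply_atlas_translation(m, 4.0, 5.0)
        assert shifted.affine[1, 3] == m.affine[1, 3] + 4.0
        assert shifted.affine[2, 3] == m.affine[2, 3] + 5.0
        np.testing.assert_array_equal(shifted.probabilities, m.probabilities)

    def test_shift_then_inverse_restores_affine(self):
        m = _map(np.full((4, 4, 4), 0.5))
        back = apply_atlas_translation(apply_atlas_translation(m, 4, 5), -4, -5)
        np.testing.assert_allclose(back.affine, m.affine)


class TestExtraction:
    def test_constant_field_returns_constant(self):
        g = _gm(np.full((5, 5, 5), 0.7))
        left = _map(np.random.default_rng(0).random((5, 5, 5)))
        right = _map(np.random.default_rng(1).random((5, 5, 5)), hemi="right")
        sd = extract_regional_density(g, left, right)
        assert sd.value == pytest.approx(0.7, rel=1e-12)

    def test_hand_computed_weighted_mean(self):
        # three active voxels: g = (1, 2, 3), pooled weights (0.5, 1.0, 0.5)
        g = np.zeros((4, 4, 4))
        g[0, 0, 0], g[1, 1, 1], g[2, 2, 2] = 1.0, 2.0, 3.0
        wl = np.zeros((4, 4, 4))
        wl[0, 0, 0], wl[1, 1, 1] = 0.5, 0.5
        wr = np.zeros((4, 4, 4))
        wr[1, 1, 1], wr[2, 2, 2] = 0.5, 0.5
        sd = extract_regional_density(_gm(g), _map(wl), _map(wr, hemi="right"))
        assert sd.value == pytest.approx(2.0, abs=1e-15)

    def test_zero_weight_errors(self):
        g = _gm(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            ProbabilisticRegionMap("r", "left", np.zeros((4, 4, 4)), AFFINE)
        del g

    def test_shape_mismatch_is_hard_error(self):
        g = _gm(np.ones((5, 5, 5)))
        left = _map(np.full((4, 4, 4), 0.5))
        right = _map(np.full((4, 4, 4), 0.5), hemi="right")
        with pytest.raises(ValueError, match="does not match"):
            extract_regional_density(g, left, right)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        """Vectorised extraction equals an explicit per-voxel loop."""
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 17, size=3))
        g = rng.random(shape)
        wl = rng.random(shape)
        wr = rng.random(shape)
        num = den = 0.0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    num += g[i, j, k] * (wl[i, j, k] + wr[i, j, k])
                    den += wl[i, j, k] + wr[i, j, k]
        sd = extract_regional_density(
            _gm(g), _map(wl), _map(wr, hemi="right")
        )
        assert sd.value == pytest.approx(num / den, rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 2.0])
    def test_scale_equivariance_in_g(self, alpha, rng):
        g = rng.random((6, 6, 6))
        wl = rng.random((6, 6, 6))
        wr = rng.random((6, 6, 6))
        base = extract_regional_density(_gm(g), _map(wl), _map(wr, hemi="right")).value
        scaled = extract_regional_density(
            _gm(alpha * g), _map(wl), _map(wr, hemi="right")
        ).value
        assert scaled == pytest.approx(alpha * base, abs=1e-12)

    def test_weight_rescaling_invariance(self, rng):
        g = rng.random((6, 6, 6))
        wl = rng.random((6, 6, 6))
        wr = rng.random((6, 6, 6))
        base = extract_regional_density(_gm(g), _map(wl), _map(wr, hemi="right")).value
        halved = extract_regional_density(
            _gm(g), _map(0.5 * wl), _map(0.5 * wr, hemi="right")
        ).value
        assert halved == pytest.approx(base, rel=1e-12)

    def test_value_bounded_by_field_range(self, rng):
        g = rng.random((6, 6, 6))
        wl = rng.random((6, 6, 6))
        wr = rng.random((6, 6, 6))
        v = extract_regional_density(_gm(g), _map(wl), _map(wr, hemi="right")).value
        assert g.min() <= v <= g.max()


class TestExtractAllRegions:
    def test_disjoint_regions_give_per_region_means(self, rng):
        """Two disjoint box regions: values equal plain means of g."""
        g = rng.random((8, 8, 8))
        wa = np.zeros((8, 8, 8))
        wa[:3] = 1.0
        wb = np.zeros((8, 8, 8))
        wb[5:] = 1.0
        tiny = np.zeros((8, 8, 8))
        tiny[4, 4, 4] = 1e-30  # negligible opposite-hemisphere support
        atlas = {
            "A": (_map(wa, "A"), _map(tiny, "A", "right")),
            "B": (_map(wb, "B"), _map(tiny, "B", "right")),
        }
        vals = extract_all_regions(_gm(g), atlas)
        assert vals["A"] == pytest.approx(g[:3].mean(), rel=1e-9)
        assert vals["B"] == pytest.approx(g[5:].mean(), rel=1e-9)

    def test_zero_field_gives_zero_everywhere(self):
        gm, atlas, _ = simulate_voxel_scene((8, 8, 8), 2, seed=0)
        zero = GrayMatterMap(np.zeros_like(gm.values), gm.affine)
        vals = extract_all_regions(zero, atlas)
        assert all(v == 0.0 for v in vals.values())

    def test_deterministic_across_calls(self):
        gm, atlas, _ = simulate_voxel_scene((8, 8, 8), 3, seed=1)
        assert extract_all_regions(gm, atlas) == extract_all_regions(gm, atlas)

    def test_scene_truth_matches_extraction(self):
        gm, atlas, truth = simulate_voxel_scene((12, 12, 12), 3, seed=9)
        vals = extract_all_regions(gm, atlas)
        for name, expected in truth.items():
            assert vals[name] == pytest.approx(expected, rel=1e-12)

    def test_empty_atlas_rejected(self):
        gm, _, _ = simulate_voxel_scene((8, 8, 8), 1, seed=0)
        with pytest.raises(ValueError, match="no regions"):
            extract_all_regions(gm, {})


def test_resampling_identity_grid_matches_direct(rng):
    """Nearest-neighbour resampling onto the same grid is a no-op."""
    g = rng.random((6, 6, 6))
    wl = rng.random((6, 6, 6))
    wr = rng.random((6, 6, 6))
    shifted_affine = AFFINE.copy()
    left = ProbabilisticRegionMap("r", "left", wl, shifted_affine)
    right = ProbabilisticRegionMap("r", "right", wr, shifted_affine)
    direct = extract_regional_density(_gm(g), left, right).value
    resampled = extract_regional_density(_gm(g), left, right, resample=True).value
    assert resampled == pytest.approx(direct, rel=1e-12)
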