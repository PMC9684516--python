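import numpy as np
import pytest

from deltarad.exceptions import DegenerateROIError
from deltarad.features import (
    ALL_FEATURES,
    BASE_FEATURES,
    VN_FEATURES,
    extract_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    volume_normalize,
)
from deltarad.imaging import ImageVolume, ROIMask
from deltarad.matrices import build_texture_matrices
from deltarad.preprocessing import quantize_uniform

from . import oracles
from .conftest import make_mask, make_volume, random_levels


def _extract(values, n_levels=8, spacing=(1.0, 1.0, 1.0)):
    vol = make_volume(values, spacing)
    mask = make_mask(np.ones_like(vol.values), spacing)
    q = quantize_uniform(vol, mask, n_levels)
    return vol, mask, q


class TestMatrixOracleEquivalence:
    """Builder matrices equal exhaustive enumeration on small random ROIs."""

    @pytest.mark.parametrize("seed", range(12))
    def test_all_matrices_random_small_rois(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 6, size=3))
        G = int(rng.integers(2, 5))
        levels = random_levels(rng, shape, G)
        tm = build_texture_matrices(levels, G)
        np.testing.assert_allclose(tm.glcm, oracles.glcm_oracle(levels, G), atol=1e-12)
        got = tm.glrlm
        exp = oracles.glrlm_oracle(levels, G)
        np.testing.assert_array_equal(got[:, : exp.shape[1]], exp[:, : got.shape[1]])
        assert got[:, exp.shape[1]:].sum() == 0 and exp[:, got.shape[1]:].sum() == 0
        got_z, exp_z = tm.glszm, oracles.glszm_oracle(levels, G)
        w = min(got_z.shape[1], exp_z.shape[1])
        np.testing.assert_array_equal(got_z[:, :w], exp_z[:, :w])
        assert got_z[:, w:].sum() == 0 and exp_z[:, w:].sum() == 0
        n_i, s_i = oracles.ngtdm_oracle(levels, G)
        np.testing.assert_array_equal(tm.ngtdm_n, n_i)
        np.testing.assert_allclose(tm.ngtdm_s, s_i, atol=1e-10)

    def test_constant_cube(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        tm = build_texture_matrices(levels, 1)
        assert tm.glcm.shape == (1, 1)
        assert tm.glcm[0, 0] == pytest.approx(1.0)
        assert tm.glszm[0].sum() == 1 and tm.glszm[0, 26] == 1  # one zone of 27
        assert tm.ngtdm_s[0] == pytest.approx(0.0)

    def test_2x2x1_alternating_columns(self):
        levels = np.array([[1, 2], [1, 2]], dtype=np.int32).reshape(2, 2, 1)
        tm = build_texture_matrices(levels, 2)
        np.testing.assert_allclose(tm.glcm, oracles.glcm_oracle(levels, 2), atol=1e-12)
        # hand enumeration: 2 same-level pairs (along x), 4 cross pairs (y and diagonals)
        assert tm.glcm[0, 1] == pytest.approx(4 / 12)
        assert tm.glcm[0, 0] == pytest.approx(2 / 12)

    def test_checkerboard_contrast(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 + 1
        levels = board.reshape(4, 4, 1).astype(np.int32)
        tm = build_texture_matrices(levels, 2)
        # all axis-aligned in-plane pairs differ by exactly one level
        a = levels[:-1, :, 0]
        b = levels[1:, :, 0]
        assert np.all(np.abs(a - b) == 1)
        contrast = glcm_features(tm.glcm)["GLCM Contrast"]
        oracle_contrast = float(
            sum(
                (i - j) ** 2 * p
                for i in range(1, 3)
                for j in range(1, 3)
                for p in [oracles.glcm_oracle(levels, 2)[i - 1, j - 1]]
            )
        )
        assert contrast == pytest.approx(oracle_contrast)

    def test_single_voxel_roi_is_an_error(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[1, 1, 1] = 1
        with pytest.raises(DegenerateROIError):
            build_texture_matrices(levels, 4)


class TestMatrixInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_laws(self, seed):
        rng = np.random.default_rng(100 + seed)
        levels = random_levels(rng, (5, 5, 4), 4)
        n_vox = int((levels > 0).sum())
        tm = build_texture_matrices(levels, 4)
        # GLCM: sums to one, symmetric, equal marginals
        assert tm.glcm.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(tm.glcm, tm.glcm.T, atol=1e-15)
        np.testing.assert_allclose(tm.glcm.sum(0), tm.glcm.sum(1), atol=1e-15)
        # GLRLM: each voxel sits in exactly one run per direction
        lengths = np.arange(1, tm.glrlm.shape[1] + 1)
        assert int((tm.glrlm * lengths).sum()) == n_vox * 13
        # GLSZM: zone sizes partition the ROI
        sizes = np.arange(1, tm.glszm.shape[1] + 1)
        assert int((tm.glszm * sizes).sum()) == n_vox


class TestFeatureFormulas:
    def test_against_naive_oracle_random_8cube(self, rng):
        vals = rng.standard_normal((8, 8, 8))
        vol, mask, q = _extract(vals, n_levels=8)
        tm = build_texture_matrices(q.levels, 8)
        got = glcm_features(tm.glcm)
        for name, exp in oracles.glcm_features_oracle(tm.glcm).items():
            assert got[name] == pytest.approx(exp, rel=1e-9), name
        got_rl = glrlm_features(tm.glrlm, tm.n_voxels)
        for name, exp in oracles.rl_features_oracle(tm.glrlm, tm.n_voxels, 13).items():
            assert got_rl[f"GLRLM {name}"] == pytest.approx(exp, rel=1e-9), name
        got_sz = glszm_features(tm.glszm, tm.n_voxels)
        for name, exp in oracles.rl_features_oracle(tm.glszm, tm.n_voxels, 1).items():
            key = f"GLSZM {name}".replace("SRE", "SZE").replace("LRE", "LZE")
            key = (
                key.replace("RLN", "ZSN").replace("RP", "ZP").replace("LGRE", "LGZE")
                .replace("HGRE", "HGZE").replace("SRLGE", "SZLGE").replace("SRHGE", "SZHGE")
                .replace("LRLGE", "LZLGE").replace("LRHGE", "LZHGE").replace("RLV", "ZSV")
            )
            assert got_sz[key] == pytest.approx(exp, rel=1e-9), key
        got_ng = ngtdm_features(tm.ngtdm_n, tm.ngtdm_s)
        for name, exp in oracles.ngtdm_features_oracle(tm.ngtdm_n, tm.ngtdm_s).items():
            assert got_ng[name] == pytest.approx(exp, rel=1e-9), name

    def test_constant_roi_closed_forms(self):
        vol, mask, q = _extract(np.full((4, 4, 4), 9.0), n_levels=8)
        fv = extract_features(vol, mask, q)
        assert fv["Global Variance"] == 0.0
        assert fv["GLCM Energy"] == pytest.approx(1.0)
        assert fv["GLCM Contrast"] == 0.0
        assert fv["NGTDM Contrast"] == 0.0

    def test_roster_counts(self):
        assert len(BASE_FEATURES) == 42
        assert len(set(BASE_FEATURES)) == 42
        assert len(ALL_FEATURES) == 49
        # the per-tree feature count convention: sqrt(49) = 7
        assert int(np.ceil(np.sqrt(len(ALL_FEATURES)))) == 7

    def test_extract_returns_all_names_finite(self, rng):
        vol, mask, q = _extract(rng.standard_normal((6, 6, 6)), n_levels=8)
        fv = extract_features(vol, mask, q)
        assert tuple(fv) == ALL_FEATURES
        assert all(np.isfinite(v) for v in fv.values())

    def test_affine_shift_invariance_after_quantization(self, rng):
        vals = rng.standard_normal((6, 6, 6))
        vol1, mask, q1 = _extract(vals, n_levels=8)
        vol2, _, q2 = _extract(3.0 * vals + 11.0, n_levels=8)
        np.testing.assert_array_equal(q1.levels, q2.levels)
        tm1 = build_texture_matrices(q1.levels, 8)
        tm2 = build_texture_matrices(q2.levels, 8)
        for name, v in glcm_features(tm1.glcm).items():
            assert glcm_features(tm2.glcm)[name] == pytest.approx(v)


class TestVolumeNormalization:
    def test_identity_at_one_voxel(self):
        fv = {
            "GLSZM GLN": 2.0, "GLRLM GLN": 3.0, "GLRLM RLN": 4.0,
            "NGTDM Strength": 5.0, "NGTDM Busyness": 6.0, "NGTDM Coarseness": 7.0,
        }
        out = volume_normalize(fv, 1)
        assert out["GLSZM GLN-VN"] == 2.0
        assert out["NGTDM Coarseness-VN"] == 7.0

    def test_disjoint_duplication_leaves_gln_vn_invariant(self, rng):
        # two separated copies of the same texture: GLN doubles, n doubles
        block = random_levels(rng, (4, 4, 3), 3)
        levels = np.zeros((4, 4, 8), dtype=np.int32)
        levels[:, :, :3] = block
        levels[:, :, 5:] = block  # gap of 2 slices: no adjacency between copies
        tm1 = build_texture_matrices(np.pad(block, ((0, 0), (0, 0), (0, 1))), 3)
        tm2 = build_texture_matrices(levels, 3)
        f1 = volume_normalize(
            {**glrlm_features(tm1.glrlm, tm1.n_voxels),
             **glszm_features(tm1.glszm, tm1.n_voxels),
             **ngtdm_features(tm1.ngtdm_n, tm1.ngtdm_s)},
            tm1.n_voxels,
        )
        f2 = volume_normalize(
            {**glrlm_features(tm2.glrlm, tm2.n_voxels),
             **glszm_features(tm2.glszm, tm2.n_voxels),
             **ngtdm_features(tm2.ngtdm_n, tm2.ngtdm_s)},
            tm2.n_voxels,
        )
        for name in ("GLSZM GLN-VN", "GLRLM GLN-VN", "GLRLM RLN-VN"):
            assert f2[name] == pytest.approx(f1[name], rel=0.05), name

    def test_vn_fields_present_and_finite(self, rng):
        vol, mask, q = _extract(rng.standard_normal((6, 6, 6)), n_levels=8)
        fv = extract_features(vol, mask, q)
        for name in VN_FEATURES:
            assert name in fv and np.isfinite(fv[name])

    def test_prostate_volume_from_mask(self, rng):
        vol, mask, q = _extract(rng.standard_normal((10, 10, 10)), spacing=(1, 1, 1))
        fv = extract_features(vol, mask, q)
        assert fv["Prostate Volume"] == pytest.approx(1.0)  # 1000 voxels of 1 mm^3
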