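"""Enhancement-ratio map and the FGT% / BPE20% / ΔBPE20% metric core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bpequant import (
    VolumeGrid,
    compute_bpe,
    compute_fgt_pct,
    delta_bpe,
    enhancement_ratio_map,
)
from bpequant.bpe import EnhancementMap
from bpequant.segment import SegmentationMasks


def _grid(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(data, float), spacing)


def brute_force_bpe(ratio, valid, breast, fgt, spacing, threshold):
    """Independent voxel-loop oracle for the thresholded enhancing volume.

    Counts voxels one by one and converts to physical volume once at the end
    (integer counts keep the comparison with the implementation exact).
    """
    voxel = float(np.prod(spacing))
    n_breast = n_fgt = n_valid = n_bpe = n_invalid = 0
    nx, ny, nz = ratio.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if breast[i, j, k]:
                    n_breast += 1
                if fgt[i, j, k]:
                    n_fgt += 1
                    if not valid[i, j, k]:
                        n_invalid += 1
                        continue
                    n_valid += 1
                    if ratio[i, j, k] >= threshold:
                        n_bpe += 1
    v_breast, v_fgt = voxel * n_breast, voxel * n_fgt
    v_valid, v_bpe = voxel * n_valid, voxel * n_bpe
    fgt_pct = 100.0 * v_fgt / v_breast if n_breast else float("nan")
    bpe = 100.0 * v_bpe / v_valid if n_valid else float("nan")
    return v_breast, v_fgt, v_valid, v_bpe, fgt_pct, bpe, n_invalid


class TestEnhancementRatio:
    def test_direct_formula(self):
        pre = _grid(np.full((8, 8, 8), 100.0))
        post = _grid(np.full((8, 8, 8), 130.0))
        emap = enhancement_ratio_map(pre, post)
        np.testing.assert_allclose(emap.ratio, 0.30)

    def test_equal_volumes_give_zero(self):
        pre = _grid(np.random.default_rng(0).uniform(50, 200, (8, 8, 8)))
        emap = enhancement_ratio_map(pre, pre)
        assert np.all(emap.ratio == 0)

    def test_zero_pre_voxel_marked_invalid_not_infinite(self):
        pre_data = np.full((8, 8, 8), 100.0)
        pre_data[0, 0, 0] = 0.0
        emap = enhancement_ratio_map(_grid(pre_data), _grid(np.full((8, 8, 8), 130.0)))
        assert not emap.valid[0, 0, 0]
        assert np.all(np.isfinite(emap.ratio))

    def test_floor_excludes_dim_voxels(self):
        pre_data = np.full((8, 8, 8), 100.0)
        pre_data[1, 1, 1] = 0.5
        emap = enhancement_ratio_map(_grid(pre_data), _grid(pre_data * 1.3), floor=1.0)
        assert not emap.valid[1, 1, 1]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            enhancement_ratio_map(
                _grid(np.ones((8, 8, 8))), _grid(np.ones((8, 8, 8)), spacing=(2, 1, 1))
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        pre = rng.uniform(10, 200, (8, 8, 8))
        post = pre * rng.uniform(0.9, 1.6, (8, 8, 8))
        a = enhancement_ratio_map(_grid(pre), _grid(post), floor=1.0)
        b = enhancement_ratio_map(_grid(pre * 7), _grid(post * 7), floor=7.0)
        np.testing.assert_allclose(a.ratio, b.ratio)
        assert np.array_equal(a.valid, b.valid)


class TestComputeBPE:
    def test_worked_example_inclusive_threshold(self):
        """10 FGT voxels, ratios {0.20, 0.25, 0.5, 0.9} plus six below -> 40%."""
        ratio = np.zeros((4, 4, 4))
        fgt = np.zeros((4, 4, 4), bool)
        fgt[0, 0, :4] = fgt[0, 1, :4] = True
        fgt[0, 2, :2] = True  # 10 voxels
        vals = [0.20, 0.25, 0.5, 0.9, 0.1, 0.19, 0.0, -0.1, 0.05, 0.15]
        ratio[fgt] = vals
        breast = np.ones((4, 4, 4), bool)
        masks = SegmentationMasks(breast, fgt, fgt.astype(float))
        emap = EnhancementMap(ratio=ratio, valid=np.ones_like(fgt))
        res = compute_bpe(emap, masks, (1.0, 1.0, 1.0))
        assert res.bpe20_pct == 40.0
        assert res.v_bpe == 4.0

    def test_all_below_threshold_gives_zero(self):
        fgt = np.zeros((4, 4, 4), bool)
        fgt[1] = True
        masks = SegmentationMasks(np.ones((4, 4, 4), bool), fgt, fgt.astype(float))
        emap = EnhancementMap(ratio=np.full((4, 4, 4), 0.1), valid=np.ones((4, 4, 4), bool))
        assert compute_bpe(emap, masks, (1, 1, 1)).bpe20_pct == 0.0

    def test_zero_threshold_saturates(self):
        fgt = np.zeros((4, 4, 4), bool)
        fgt[1] = True
        masks = SegmentationMasks(np.ones((4, 4, 4), bool), fgt, fgt.astype(float))
        emap = EnhancementMap(ratio=np.full((4, 4, 4), 0.1), valid=np.ones((4, 4, 4), bool))
        assert compute_bpe(emap, masks, (1, 1, 1), threshold=0.0).bpe20_pct == 100.0

    def test_empty_fgt_mask_is_an_error(self):
        masks = SegmentationMasks(
            np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4))
        )
        emap = EnhancementMap(ratio=np.zeros((4, 4, 4)), valid=np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="empty"):
            compute_bpe(emap, masks, (1, 1, 1))

    def test_raising_threshold_never_increases_bpe(self):
        rng = np.random.default_rng(3)
        ratio = rng.normal(0.2, 0.3, (10, 10, 10))
        fgt = rng.random((10, 10, 10)) < 0.3
        masks = SegmentationMasks(np.ones((10, 10, 10), bool), fgt, fgt.astype(float))
        emap = EnhancementMap(ratio=ratio, valid=np.ones((10, 10, 10), bool))
        vals = [
            compute_bpe(emap, masks, (1, 1, 1), threshold=t).bpe20_pct
            for t in np.linspace(-0.5, 1.0, 16)
        ]
        assert np.all(np.diff(vals) <= 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 13, 3))
        spacing = tuple(rng.uniform(0.5, 3.0, 3))
        breast = rng.random(shape) < 0.7
        fgt = breast & (rng.random(shape) < 0.5)
        if not fgt.any():
            fgt[tuple(np.argwhere(breast)[0])] = True
        ratio = rng.normal(0.2, 0.4, shape)
        valid = rng.random(shape) < 0.95
        if not (fgt & valid).any():
            valid |= fgt
        threshold = float(rng.uniform(0.0, 0.5))
        masks = SegmentationMasks(breast, fgt, fgt.astype(float))
        emap = EnhancementMap(ratio=ratio, valid=valid)
        res = compute_bpe(emap, masks, spacing, threshold=threshold)
        vb, vf, vv, vbpe, fgt_pct, bpe, n_inv = brute_force_bpe(
            ratio, valid, breast, fgt, spacing, threshold
        )
        assert res.n_invalid == n_inv
        np.testing.assert_allclose(
            [res.v_breast, res.v_fgt, res.v_fgt_valid, res.v_bpe], [vb, vf, vv, vbpe], rtol=1e-12
        )
        np.testing.assert_allclose(res.bpe20_pct, bpe, rtol=1e-12)
        np.testing.assert_allclose(
            compute_fgt_pct(masks, spacing), fgt_pct, rtol=1e-12
        )


class TestFgtPct:
    def test_full_fgt_is_100(self):
        m = np.ones((4, 4, 4), bool)
        masks = SegmentationMasks(m, m, m.astype(float))
        assert compute_fgt_pct(masks, (1, 1, 1)) == 100.0

    def test_direct_count(self):
        breast = np.zeros((10, 10, 1), bool)
        breast[:10, :10, 0] = True
        fgt = np.zeros_like(breast)
        fgt[0, :10, 0] = True
        masks = SegmentationMasks(breast, fgt, fgt.astype(float))
        assert compute_fgt_pct(masks, (1, 1, 1)) == 10.0

    def test_anisotropic_spacing_cancels(self):
        rng = np.random.default_rng(5)
        breast = rng.random((8, 8, 8)) < 0.6
        fgt = breast & (rng.random((8, 8, 8)) < 0.4)
        masks = SegmentationMasks(breast, fgt, fgt.astype(float))
        assert compute_fgt_pct(masks, (1, 1, 3)) == compute_fgt_pct(masks, (1, 1, 1))


class TestDeltaBPE:
    def _res(self, bpe):
        from bpequant.bpe import BPEResult

        return BPEResult(
            v_breast=1000.0, v_fgt=100.0, v_fgt_valid=100.0, v_bpe=bpe,
            fgt_pct=10.0, bpe20_pct=bpe, threshold=0.2, n_invalid=0,
        )

    def test_halving_is_minus_50(self):
        assert delta_bpe(self._res(10.0), self._res(5.0)).delta_pct == -50.0

    def test_no_change_is_zero(self):
        assert delta_bpe(self._res(8.0), self._res(8.0)).delta_pct == 0.0

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            delta_bpe(self._res(0.0), self._res(5.0))
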