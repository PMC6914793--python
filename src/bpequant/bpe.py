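"""Quantitative background parenchymal enhancement (BPE) metrics.

Given a pre-contrast volume I_pre and the registered early post-contrast
volume I_post on the same grid, the per-voxel relative enhancement ratio is

    R_voxel = (I_post - I_pre) / I_pre,

defined where I_pre exceeds a small floor (near-zero fat-suppressed voxels
would otherwise make the ratio explode).  With a breast mask and an FGT mask,

    FGT%    = V_FGT / V_Breast x 100
    V_BPE   = sum of voxel volumes over FGT voxels with R_voxel >= threshold
    BPE20%  = V_BPE / V_FGT x 100            (threshold default 0.20, inclusive)
    dBPE20% = (BPE20%_post - BPE20%_pre) / BPE20%_pre x 100

Volumes are physical (mm^3, voxel volume = product of the spacings).  Voxels
below the floor are excluded from both the numerator and the denominator of
BPE20% (``n_invalid`` counts them); percentages carry full precision, with
rounding left to the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid
from .segment import SegmentationMasks

__all__ = [
    "EnhancementMap",
    "BPEResult",
    "DeltaBPE",
    "default_floor",
    "enhancement_ratio_map",
    "compute_bpe",
    "compute_fgt_pct",
    "delta_bpe",
]

DEFAULT_THRESHOLD = 0.20


@dataclass
class EnhancementMap:
    """Per-voxel relative enhancement ratio with a validity mask."""

    ratio: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, bool)
        if not np.all(np.isfinite(self.ratio[self.valid])):
            raise ValueError("ratio must be finite wherever valid")


@dataclass
class BPEResult:
    """FGT%, BPE20% and component volumes for one study (one timepoint).

    ``v_fgt`` is the full FGT volume; ``v_fgt_valid`` restricts it to voxels
    where the enhancement ratio is defined and is the BPE20% denominator (the
    two coincide whenever ``n_invalid`` is zero).
    """

    v_breast: float  # mm^3
    v_fgt: float  # mm^3
    v_fgt_valid: float  # mm^3
    v_bpe: float  # mm^3
    fgt_pct: float
    bpe20_pct: float
    threshold: float
    n_invalid: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_bpe <= self.v_fgt_valid + 1e-9:
            raise ValueError("require 0 <= v_bpe <= v_fgt_valid")
        if self.v_fgt > self.v_breast + 1e-9:
            raise ValueError("require v_fgt <= v_breast")


@dataclass
class DeltaBPE:
    """Intrasubject BPE20% change between two timepoints (negative = decrease)."""

    pre: BPEResult
    post: BPEResult
    delta_pct: float


def default_floor(pre: VolumeGrid, breast_mask: np.ndarray, fraction: float = 0.01) -> float:
    """Default I_pre floor: ``fraction`` of the in-mask median pre-contrast intensity."""
    mask = np.asarray(breast_mask, bool)
    if not mask.any():
        raise ValueError("breast mask is empty")
    return float(fraction * np.median(pre.data[mask]))


def enhancement_ratio_map(
    pre: VolumeGrid, post_warped: VolumeGrid, floor: float = 0.0
) -> EnhancementMap:
    """R_voxel = (I_post - I_pre) / I_pre where I_pre > floor; invalid elsewhere."""
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if not pre.same_grid(post_warped):
        raise ValueError(
            f"grid mismatch: pre {pre.shape}/{pre.spacing} vs post "
            f"{post_warped.shape}/{post_warped.spacing}"
        )
    valid = pre.data > floor
    ratio = np.zeros(pre.shape)
    np.divide(post_warped.data - pre.data, pre.data, out=ratio, where=valid)
    return EnhancementMap(ratio=ratio, valid=valid)


def compute_bpe(
    emap: EnhancementMap,
    masks: SegmentationMasks,
    spacing: tuple[float, float, float],
    threshold: float = DEFAULT_THRESHOLD,
    valid_denominator: bool = True,
) -> BPEResult:
    """Thresholded enhancing volume and BPE20% for one study.

    A voxel counts toward V_BPE when it is FGT, its ratio is defined, and the
    ratio is at or above the threshold (inclusive).  The denominator is the
    valid FGT volume by default; set ``valid_denominator=False`` to divide by
    the full FGT volume instead.
    """
    if emap.ratio.shape != masks.breast_mask.shape:
        raise ValueError("enhancement map and masks are on different grids")
    voxel = float(np.prod(spacing))
    fgt = masks.fgt_mask
    n_fgt = int(fgt.sum())
    if n_fgt == 0:
        raise ValueError("FGT mask is empty (v_fgt = 0); BPE20% is undefined")
    fgt_valid = fgt & emap.valid
    n_valid = int(fgt_valid.sum())
    n_invalid = n_fgt - n_valid
    n_bpe = int(np.count_nonzero(emap.ratio[fgt_valid] >= threshold))

    v_breast = voxel * int(masks.breast_mask.sum())
    v_fgt = voxel * n_fgt
    v_fgt_valid = voxel * n_valid
    v_bpe = voxel * n_bpe
    denom = v_fgt_valid if valid_denominator else v_fgt
    if denom == 0:
        raise ValueError(f"no valid FGT voxels (n_invalid={n_invalid}); BPE20% is undefined")
    return BPEResult(
        v_breast=v_breast,
        v_fgt=v_fgt,
        v_fgt_valid=v_fgt_valid,
        v_bpe=v_bpe,
        fgt_pct=100.0 * v_fgt / v_breast,
        bpe20_pct=100.0 * v_bpe / denom,
        threshold=threshold,
        n_invalid=n_invalid,
    )


def compute_fgt_pct(masks: SegmentationMasks, spacing: tuple[float, float, float]) -> float:
    """FGT% = V_FGT / V_Breast x 100 (volume ratio of the two masks)."""
    n_breast = int(masks.breast_mask.sum())
    if n_breast == 0:
        raise ValueError("breast mask is empty")
    voxel = float(np.prod(spacing))
    return 100.0 * (voxel * int(masks.fgt_mask.sum())) / (voxel * n_breast)


def delta_bpe(pre: BPEResult, post: BPEResult) -> DeltaBPE:
    """Signed percent change of BPE20% across timepoints; undefined when pre is 0."""
    if pre.bpe20_pct == 0:
        raise ValueError("pre-therapy BPE20% is 0; intrasubject change is undefined")
    delta = 100.0 * (post.bpe20_pct - pre.bpe20_pct) / pre.bpe20_pct
    return DeltaBPE(pre=pre, post=post, delta_pct=delta)
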