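"""Breast-mask construction and fibroglandular-tissue (FGT) segmentation.

The breast mask is delimited by a supervised chest-wall specification —
either an explicit posterior exclusion mask or operator control points on the
chest-wall surface, fitted by smooth (low-order polynomial) interpolation of
``y = f(x, z)`` — intersected with a body/air intensity threshold.  FGT is
then segmented inside the breast mask by two-class fuzzy C-means clustering
of the bias-corrected pre-contrast intensities, binarised at membership 0.5.

Fuzzy C-means is implemented here directly (it is the core of the
segmentation step): memberships ``u_ij ∝ (1/d_ij^2)^(1/(m-1))`` row-normalised,
centres as ``u^m``-weighted means, with deterministic quantile initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu

from .grid import VolumeGrid

__all__ = [
    "ChestWallSpec",
    "SegmentConfig",
    "SegmentationMasks",
    "build_breast_mask",
    "fuzzy_cmeans",
    "segment_fgt",
    "FCMResult",
]


@dataclass
class ChestWallSpec:
    """Supervised chest-wall delimitation.

    Exactly one of ``exclusion_mask`` (boolean grid, True = posterior/excluded)
    or ``control_points`` (N x 3 physical-space mm coordinates sampled on the
    chest-wall surface) must be given.  Control points are fitted by
    least-squares polynomial interpolation of the anterior coordinate
    ``y = f(x, z)`` of total degree ``surface_degree``; the fitted surface
    partitions the grid with no gaps.
    """

    exclusion_mask: np.ndarray | None = None
    control_points: np.ndarray | None = None
    surface_degree: int = 1

    def __post_init__(self) -> None:
        if (self.exclusion_mask is None) == (self.control_points is None):
            raise ValueError("give exactly one of exclusion_mask or control_points")
        if self.control_points is not None:
            self.control_points = np.atleast_2d(np.asarray(self.control_points, float))
            if self.control_points.shape[1] != 3:
                raise ValueError("control_points must be N x 3 (x, y, z) in mm")

    def n_coefficients(self) -> int:
        d = self.surface_degree
        return (d + 1) * (d + 2) // 2

    def wall_height(self, volume: VolumeGrid) -> np.ndarray:
        """Fitted wall coordinate y(x, z), shape (nx, nz), in mm."""
        pts = self.control_points
        n_coef = self.n_coefficients()
        if pts is None or len(pts) < n_coef:
            have = 0 if pts is None else len(pts)
            raise ValueError(
                f"chest-wall fit of degree {self.surface_degree} needs >= {n_coef} "
                f"control points, got {have}"
            )
        px, py, pz = pts[:, 0], pts[:, 1], pts[:, 2]
        terms = [
            px**i * pz**j
            for i in range(self.surface_degree + 1)
            for j in range(self.surface_degree + 1 - i)
        ]
        A = np.column_stack(terms)
        coef, *_ = np.linalg.lstsq(A, py, rcond=None)
        gx = volume.axis_coords(0)[:, None]
        gz = volume.axis_coords(2)[None, :]
        basis = [
            gx**i * gz**j
            for i in range(self.surface_degree + 1)
            for j in range(self.surface_degree + 1 - i)
        ]
        return sum(c * b for c, b in zip(coef, basis))


@dataclass
class SegmentConfig:
    """Settings for breast-mask construction and FGT clustering."""

    fgt_brighter: bool = True  # FGT polarity on fat-suppressed T1: FGT is the brighter class
    membership_cutoff: float = 0.5
    fuzzifier: float = 2.0
    tol: float = 1e-5  # on centre movement, relative to the data range
    max_iter: int = 300
    min_breast_voxels: int = 100
    min_component_voxels: int = 0  # optional small-component cleanup of the FGT mask; 0 disables
    mask_cleanup_voxels: int = 27  # breast mask: drop specks / fill holes below this size
    air_threshold: float | None = None  # absolute; None -> Otsu on the anterior region
    min_class_separation: float = 1e-3  # centres closer than this x data range -> degenerate


@dataclass
class SegmentationMasks:
    """Breast and FGT masks on the pre-contrast grid, with FGT memberships."""

    breast_mask: np.ndarray
    fgt_mask: np.ndarray
    memberships: np.ndarray  # per-voxel FGT membership in [0,1], zero outside breast

    def __post_init__(self) -> None:
        self.breast_mask = np.asarray(self.breast_mask, bool)
        self.fgt_mask = np.asarray(self.fgt_mask, bool)
        if np.any(self.fgt_mask & ~self.breast_mask):
            raise ValueError("fgt_mask must be a subset of breast_mask")


def _drop_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Remove connected components smaller than ``min_voxels`` (6-connectivity)."""
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def body_air_threshold(values: np.ndarray) -> float:
    """Air/body intensity threshold: lowest three-class multi-Otsu cut.

    Three classes (air | fat | fibroglandular) keep the lowest threshold below
    the fat level even when the glandular class dominates; degenerate
    histograms fall back to plain Otsu.
    """
    try:
        return float(threshold_multiotsu(values, classes=3)[0])
    except ValueError:
        return float(threshold_otsu(values))


def build_breast_mask(
    volume: VolumeGrid,
    chest: ChestWallSpec,
    config: SegmentConfig | None = None,
    tumor_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Breast mask = anterior-to-chest-wall region ∩ body intensity, minus tumor."""
    config = config or SegmentConfig()
    if chest.exclusion_mask is not None:
        excl = np.asarray(chest.exclusion_mask, bool)
        if excl.shape != volume.shape:
            raise ValueError("exclusion mask shape does not match the volume")
        anterior = ~excl
    else:
        wall = chest.wall_height(volume)  # (nx, nz)
        y = volume.axis_coords(1)[None, :, None]
        anterior = y >= wall[:, None, :]
    if not anterior.any():
        raise ValueError("chest-wall specification leaves no anterior region")

    vals = volume.data[anterior]
    if config.air_threshold is not None:
        thr = config.air_threshold
    else:
        if np.ptp(vals) == 0:
            raise ValueError("anterior region has constant intensity; cannot separate body from air")
        thr = body_air_threshold(vals)
    mask = anterior & (volume.data > thr)
    if config.mask_cleanup_voxels > 0:
        # noise specks in air and pinholes in tissue are not anatomy
        mask = _drop_small_components(mask, config.mask_cleanup_voxels)
        mask = ~_drop_small_components(~mask, config.mask_cleanup_voxels)
        mask &= anterior
    if tumor_mask is not None:
        mask &= ~np.asarray(tumor_mask, bool)
    if not mask.any():
        raise ValueError("breast mask is empty after body/air thresholding")
    return mask


@dataclass
class FCMResult:
    centers: np.ndarray  # (k,), sorted ascending
    memberships: np.ndarray  # (n, k), rows sum to 1
    objective: list[float]  # per-iteration objective, non-increasing
    n_iter: int
    converged: bool


def fuzzy_cmeans(
    values: np.ndarray,
    k: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
) -> FCMResult:
    """Fuzzy C-means on a 1-D intensity sample.

    Deterministic quantile initialisation of the centres (the ``seed`` argument
    is accepted for interface stability but unused — no random restarts are
    needed in one dimension).  The fixed point iterates memberships
    ``u_ij = (Σ_l (d_ij/d_lj)^(2/(m-1)))^-1`` and centres
    ``c_i = Σ_j u_ij^m x_j / Σ_j u_ij^m``; a voxel lying exactly on a centre
    gets membership 1 for that cluster.  The objective
    ``J = Σ_ij u_ij^m d_ij^2`` is non-increasing across iterations.
    """
    x = np.asarray(values, float).ravel()
    if k < 2:
        raise ValueError("fuzzy C-means needs k >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    if np.unique(x).size < k:
        raise ValueError(f"need >= {k} distinct values, got {np.unique(x).size}")

    # quantile initialisation: centres at the midpoints of k equal-mass bins
    qs = (2 * np.arange(k) + 1) / (2 * k)
    centers = np.quantile(x, qs)
    scale = np.ptp(x)

    objective: list[float] = []
    converged = False
    u = None
    for it in range(max_iter):
        d2 = (x[:, None] - centers[None, :]) ** 2  # (n, k)
        zero = d2 <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)
        hit = zero.any(axis=1)
        if hit.any():  # singularity rule: membership 1 at an exact centre
            u[hit] = 0.0
            u[hit, np.argmax(zero[hit], axis=1)] = 1.0
        um = u**m
        objective.append(float(np.sum(um * d2)))
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        move = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if move <= tol * (scale if scale > 0 else 1.0):
            converged = True
            break
    if not converged:
        delta = objective[-1] - objective[-2] if len(objective) > 1 else float("nan")
        raise RuntimeError(
            f"fuzzy C-means did not converge in {max_iter} iterations "
            f"(final objective delta {delta:.3g})"
        )

    order = np.argsort(centers)
    return FCMResult(
        centers=centers[order],
        memberships=u[:, order],
        objective=objective,
        n_iter=len(objective),
        converged=converged,
    )


def segment_fgt(
    volume: VolumeGrid,
    breast_mask: np.ndarray,
    config: SegmentConfig | None = None,
) -> SegmentationMasks:
    """Segment FGT inside the breast mask by thresholded two-class fuzzy C-means.

    The class whose centre matches the configured FGT polarity (brighter by
    default, for fat-suppressed T1) is FGT; the mask is
    ``membership >= membership_cutoff``.  A homogeneous breast (no separable
    fat/FGT contrast) raises rather than returning an arbitrary split.
    """
    config = config or SegmentConfig()
    breast_mask = np.asarray(breast_mask, bool)
    n = int(breast_mask.sum())
    if n == 0:
        raise ValueError("breast mask is empty")
    if n < config.min_breast_voxels:
        raise ValueError(f"breast mask has {n} voxels, below minimum {config.min_breast_voxels}")

    vals = volume.data[breast_mask]
    spread = np.ptp(vals)
    if spread == 0 or np.unique(vals).size < 2:
        raise ValueError("breast intensities are homogeneous; fat/FGT classes are degenerate")

    res = fuzzy_cmeans(vals, k=2, m=config.fuzzifier, tol=config.tol, max_iter=config.max_iter)
    if (res.centers[1] - res.centers[0]) < config.min_class_separation * spread:
        raise ValueError(
            "degenerate clustering: class centres "
            f"{res.centers.tolist()} are not separated; no FGT contrast detected"
        )
    fgt_col = 1 if config.fgt_brighter else 0
    membership = np.zeros(volume.shape)
    membership[breast_mask] = res.memberships[:, fgt_col]
    fgt_mask = membership >= config.membership_cutoff
    fgt_mask &= breast_mask
    if config.min_component_voxels > 0:
        fgt_mask = _drop_small_components(fgt_mask, config.min_component_voxels)
    return SegmentationMasks(breast_mask=breast_mask, fgt_mask=fgt_mask, memberships=membership)
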