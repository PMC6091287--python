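"""Coarse registration from three valve landmark pairs.

Three non-collinear point correspondences determine a planar affine
transform uniquely; the solved transform maps moving-image coordinates to
fixed-image coordinates, and the moving image is pulled onto the fixed grid
through the inverse map with cubic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Affine2D, GeometryError, Image2D, LandmarkTriplet, Mask2D


@dataclass
class BasicResult:
    """Outcome of the coarse stage: transform, resampled image, residual."""

    t_basic: Affine2D
    resampled: Image2D
    valid: Mask2D
    residual: float  # max landmark mapping error in px


def solve_affine_from_landmarks(fixed: LandmarkTriplet,
                                moving: LandmarkTriplet) -> Affine2D:
    """Solve T with ``fixed_k = T @ moving_k`` (homogeneous) for k = 1..3.

    Raises :class:`GeometryError` for collinear or repeated points (already
    rejected by :class:`LandmarkTriplet`, re-checked here via conditioning).
    """
    src = np.column_stack([moving.points, np.ones(3)])  # rows (x, y, 1)
    if abs(np.linalg.det(src)) <= 1e-9:
        raise GeometryError("moving landmarks are collinear or repeated")
    # src @ [a c; b d; tx ty] = fixed  -> two 3x3 solves, one per output axis
    coeff = np.linalg.solve(src, fixed.points)  # (3, 2)
    m = np.eye(3)
    m[0, :2] = coeff[:2, 0]
    m[0, 2] = coeff[2, 0]
    m[1, :2] = coeff[:2, 1]
    m[1, 2] = coeff[2, 1]
    t = Affine2D(m)
    resid = np.abs(t.apply(moving.points) - fixed.points).max()
    if resid > 1e-6:
        raise GeometryError(f"affine solve residual {resid:.3g} px exceeds 1e-6")
    return t


def _rc_pullback(t: Affine2D):
    """(matrix, offset) for scipy's (row, col)-indexed output->input map."""
    tinv = t.inverse().matrix
    a = tinv[:2, :2]  # acts on (x, y)
    matrix_rc = np.array([[a[1, 1], a[1, 0]], [a[0, 1], a[0, 0]]])
    offset_rc = np.array([tinv[1, 2], tinv[0, 2]])
    return tinv, matrix_rc, offset_rc


def _validity(tinv: np.ndarray, out_shape, in_shape) -> np.ndarray:
    h, w = out_shape
    ih, iw = in_shape
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xm = tinv[0, 0] * cols + tinv[0, 1] * rows + tinv[0, 2]
    ym = tinv[1, 0] * cols + tinv[1, 1] * rows + tinv[1, 2]
    eps = 1e-6  # keep boundary pixels valid under solve round-off
    return ((xm >= -eps) & (xm <= iw - 1 + eps)
            & (ym >= -eps) & (ym <= ih - 1 + eps))


def resample(moving: Image2D, t: Affine2D, out_shape: tuple[int, int],
             order: int = 3) -> tuple[Image2D, Mask2D]:
    """Pull ``moving`` onto a fixed grid of ``out_shape`` through ``t``.

    Output pixel ``(x, y)`` holds the moving intensity interpolated at
    ``t^-1 (x, y)`` (cubic by default); pixels whose source falls outside the
    moving footprint are 0 and flagged False in the returned validity mask.
    Negative overshoot from the cubic kernel is clamped to 0.
    """
    tinv, matrix_rc, offset_rc = _rc_pullback(t)
    # edge-clamped interpolation; the validity mask supplies the zero fill
    # (mode="constant" would blank boundary pixels over sub-ulp round-off)
    out = ndimage.affine_transform(
        moving.pixels, matrix_rc, offset=offset_rc, output_shape=tuple(out_shape),
        order=order, mode="nearest", prefilter=order > 1,
    )
    np.maximum(out, 0.0, out=out)
    valid = _validity(tinv, out_shape, moving.shape)
    out[~valid] = 0.0
    return Image2D(out, pixel_size=moving.pixel_size), Mask2D(valid)


def warp_mask(mask: Mask2D, t: Affine2D, out_shape: tuple[int, int]) -> Mask2D:
    """Nearest-neighbor warp of a binary mask onto a fixed grid."""
    tinv, matrix_rc, offset_rc = _rc_pullback(t)
    out = ndimage.affine_transform(
        mask.bits.astype(np.float64), matrix_rc, offset=offset_rc,
        output_shape=tuple(out_shape), order=0, mode="nearest",
    )
    valid = _validity(tinv, out_shape, mask.shape)
    return Mask2D((out > 0.5) & valid)


def run_basic(fixed: Image2D, moving: Image2D, fixed_lm: LandmarkTriplet,
              moving_lm: LandmarkTriplet) -> BasicResult:
    """Coarse stage: solve the landmark affine and resample the moving image."""
    fixed_lm.require_within(fixed.shape)
    moving_lm.require_within(moving.shape)
    t = solve_affine_from_landmarks(fixed_lm, moving_lm)
    resampled, valid = resample(moving, t, fixed.shape)
    resid = float(np.abs(t.apply(moving_lm.points) - fixed_lm.points).max())
    return BasicResult(t_basic=t, resampled=resampled, valid=valid, residual=resid)
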