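"""Quantitative evaluation: Dice overlap and RMS target registration error.

The reference transform is a "bronze standard": any expert-accepted
registration, or — for synthetic phantoms — the known generating transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basic import warp_mask
from .registration import RegistrationResult
from .types import Affine2D, InputError, Mask2D, ShapeError


@dataclass
class EvaluationReport:
    dice: float
    tre_rms_mm: float
    n_points: int
    reference: str

    def to_dict(self) -> dict:
        return {"dice": self.dice, "tre_rms_mm": self.tre_rms_mm,
                "n_points": self.n_points, "reference": self.reference}


def dice(a: Mask2D, b: Mask2D) -> float:
    """Dice overlap ``2|A∩B| / (|A| + |B|)``; undefined when both are empty."""
    if a.parent_shape != b.parent_shape:
        raise ShapeError(f"mask shapes differ: {a.parent_shape} vs {b.parent_shape}")
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        raise InputError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return 2.0 * inter / (na + nb)


def tre_rms(roi: Mask2D, t_est: Affine2D, t_ref: Affine2D,
            pixel_size: tuple[float, float]) -> float:
    """RMS distance, in mm, between ROI pixels mapped by the two transforms.

    Every ROI-true pixel position is mapped by both transforms; displacement
    components are converted to mm with ``pixel_size = (dy, dx)`` before the
    Euclidean norm.
    """
    roi.require_nonempty("TRE ROI")
    rows, cols = np.nonzero(roi.bits)
    pts = np.column_stack([cols, rows]).astype(float)  # (x, y)
    d = t_est.apply(pts) - t_ref.apply(pts)
    dy, dx = pixel_size
    d[:, 0] *= dx
    d[:, 1] *= dy
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def evaluate_run(result: RegistrationResult, roi: Mask2D, t_ref: Affine2D,
                 pixel_size: tuple[float, float],
                 reference: str = "bronze-standard",
                 out_shape: tuple[int, int] | None = None) -> EvaluationReport:
    """Score a registration run against a reference transform.

    Dice compares the moving-side ROI warped (nearest-neighbor) into fixed
    space by ``t_final`` versus by ``t_ref``; TRE maps every ROI pixel by
    both transforms.
    """
    if t_ref is None:
        raise InputError("a reference transform is required (no silent fallback)")
    shape = out_shape or result.s_final.shape
    warped_est = warp_mask(roi, result.t_final, shape)
    warped_ref = warp_mask(roi, t_ref, shape)
    return EvaluationReport(
        dice=dice(warped_est, warped_ref),
        tre_rms_mm=tre_rms(roi, result.t_final, t_ref, pixel_size),
        n_points=roi.n_foreground,
        reference=reference,
    )
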