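"""Core domain types and the package-wide coordinate convention.

Convention (used by every module): a point is ``(x, y)`` where ``x`` is the
column index and ``y`` the row index, both 0-based, with pixel centers at
integer coordinates.  Arrays are indexed ``[row, col]`` i.e. ``[y, x]``.
An :class:`Affine2D` maps homogeneous moving-image coordinates ``(x, y, 1)``
to fixed-image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np


class VPMMIError(Exception):
    """Base class for all domain errors raised by this package."""


class FormatError(VPMMIError):
    """Unreadable or structurally invalid file content."""


class GeometryError(VPMMIError):
    """Degenerate geometry: collinear landmarks, singular transforms."""


class ShapeError(VPMMIError):
    """Array shapes that are required to agree do not."""


class InputError(VPMMIError):
    """Semantically invalid input (empty mask, bad counts, bad ranges)."""


class DegenerateInputError(VPMMIError):
    """Input on which a metric is undefined (e.g. constant image for NMI)."""


#: fallback spacing when no modality is declared, mm/pixel as (dy, dx)
DEFAULT_PIXEL_SIZE = (1.0, 1.0)
#: per-modality defaults in mm/pixel
MODALITY_PIXEL_SIZE = {"CT": (0.32, 0.32), "TEE": (0.224, 0.224)}


@dataclass
class Image2D:
    """Single-channel 2-D raster with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        Float-valued intensity array, shape ``(height, width)``.  Values from
        8-bit sources lie in [0, 255]; region-enhanced images may exceed 255.
    pixel_size : (float, float)
        ``(dy, dx)`` spacing in mm per pixel.
    """

    pixels: np.ndarray
    pixel_size: tuple[float, float] = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShapeError(f"image must be 2-D, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("image contains non-finite intensities")
        dy, dx = self.pixel_size
        if not (dy > 0 and dx > 0):
            raise InputError(f"pixel_size must be positive, got {self.pixel_size}")
        self.pixel_size = (float(dy), float(dx))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Mask2D:
    """Binary foreground segmentation aligned to an :class:`Image2D`."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(bool)
        if self.bits.ndim != 2:
            raise ShapeError(f"mask must be 2-D, got ndim={self.bits.ndim}")

    @property
    def parent_shape(self) -> tuple[int, int]:
        return self.bits.shape

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    @property
    def n_foreground(self) -> int:
        return int(self.bits.sum())

    def require_nonempty(self, what: str = "mask") -> "Mask2D":
        if self.n_foreground == 0:
            raise InputError(f"{what} has no foreground pixels")
        return self


#: doubled-triangle-area threshold below which a triplet counts as collinear
_COLLINEAR_TOL = 1e-6


@dataclass
class LandmarkTriplet:
    """Exactly three ``(x, y)`` points in the pixel coordinates of one image.

    The three points anchor the valve (two endpoints and the midpoint of the
    valve segment) and must be non-collinear so that they determine a planar
    affine transform uniquely.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.shape != (3, 2):
            raise InputError(
                f"landmark triplet needs exactly 3 (x, y) points, got shape "
                f"{self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise InputError("landmark coordinates must be finite")
        if abs(self.signed_doubled_area()) <= _COLLINEAR_TOL:
            raise GeometryError("landmark triplet is collinear (or has repeats)")

    def signed_doubled_area(self) -> float:
        (x1, y1), (x2, y2), (x3, y3) = self.points
        return float((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))

    def require_within(self, shape: tuple[int, int]) -> "LandmarkTriplet":
        """Check all points lie inside an image of ``shape = (h, w)``."""
        h, w = shape
        x, y = self.points[:, 0], self.points[:, 1]
        if np.any(x < 0) or np.any(x > w - 1) or np.any(y < 0) or np.any(y > h - 1):
            raise InputError(
                f"landmark outside image bounds {shape}: {self.points.tolist()}"
            )
        return self


@dataclass
class Affine2D:
    """3x3 homogeneous planar affine, last row fixed to ``(0, 0, 1)``.

    Maps homogeneous column ``(x, y, 1)`` of the moving image to fixed-image
    coordinates.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (3, 3):
            raise InputError(f"affine matrix must be 3x3, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise InputError("affine matrix must be finite")
        if not np.allclose(self.matrix[2], (0.0, 0.0, 1.0), atol=1e-9):
            raise GeometryError(f"last affine row must be (0,0,1), got {self.matrix[2]}")
        self.matrix[2] = (0.0, 0.0, 1.0)
        if abs(np.linalg.det(self.matrix[:2, :2])) <= 1e-12:
            raise GeometryError("affine transform is singular")

    @classmethod
    def identity(cls) -> "Affine2D":
        return cls(np.eye(3))

    @classmethod
    def from_translation(cls, tx: float, ty: float) -> "Affine2D":
        m = np.eye(3)
        m[0, 2] = tx
        m[1, 2] = ty
        return cls(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(n, 2)`` array of ``(x, y)`` points (also accepts (2,))."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = p @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "Affine2D":
        return Affine2D(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "Affine2D") -> "Affine2D":
        return Affine2D(self.matrix @ other.matrix)


#: transform parameterizations available to the fine-stage optimizer
TRANSFORM_MODELS = ("affine6", "rigid_scale4")


@dataclass
class RegistrationConfig:
    """Tunable parameters of the two-stage registration.

    ``N`` and ``M`` are the region-enhancement levels added inside the ROI of
    the reference (CT-like) and floating (TEE-like) image respectively; the
    defaults are the empirical values the method was developed with.
    """

    N: float = 80.0
    M: float = 100.0
    nmi_bins: int = 64
    powell_xtol: float = 1e-4
    powell_max_iter: int = 100
    transform_model: str = "affine6"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 0 or self.M < 0:
            raise InputError("enhancement levels N, M must be >= 0")
        if self.nmi_bins < 8:
            raise InputError("nmi_bins must be >= 8")
        if not self.powell_xtol > 0:
            raise InputError("powell_xtol must be > 0")
        if self.powell_max_iter < 1:
            raise InputError("powell_max_iter must be >= 1")
        if self.transform_model not in TRANSFORM_MODELS:
            raise InputError(
                f"transform_model must be one of {TRANSFORM_MODELS}, "
                f"got {self.transform_model!r}"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
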