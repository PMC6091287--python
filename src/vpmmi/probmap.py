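"""Region enhancement and ROI-membership probability maps.

The multimodal gray-level gap is bridged by remapping each image into the
probability that a pixel lies inside the segmented region of interest.  A
constant enhancement level (N for the CT-like reference, M for the TEE-like
floating image) is first added inside the ROI so that foreground and
background intensity bins separate; the per-intensity ROI fraction then
becomes a lookup table turning the enhanced image into a probability map.

Enhanced intensities are deliberately NOT clipped at 255: clipping would
merge enhanced foreground bins with bright background bins and destroy the
separation the density estimate relies on, so the intensity domain is the
non-negative integers (8-bit range plus the enhancement level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Image2D, InputError, Mask2D, ShapeError


@dataclass
class DensityTable:
    """Lookup from integer intensity to ROI-membership probability.

    ``probs[i]`` is the fraction of pixels of intensity ``i`` that fall
    inside the ROI, as a fraction in [0, 1]; intensities never observed at
    fit time map to 0.
    """

    probs: dict[int, float]

    def __post_init__(self) -> None:
        for i, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise InputError(f"probability for intensity {i} outside [0,1]: {p}")

    @property
    def support(self) -> set[int]:
        return set(self.probs)

    def lookup(self, i: int) -> float:
        return self.probs.get(int(i), 0.0)


@dataclass
class ProbabilityMap2D:
    """Per-pixel ROI-membership probabilities in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("probability map must be 2-D")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise InputError("probability map values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_enhancement(shape: tuple[int, int], roi: Mask2D, level: float) -> Image2D:
    """Enhancement matrix: ``level`` at ROI pixels, 0 elsewhere."""
    if roi.parent_shape != tuple(shape):
        raise ShapeError(f"roi shape {roi.parent_shape} != image shape {tuple(shape)}")
    if level < 0:
        raise InputError(f"enhancement level must be >= 0, got {level}")
    return Image2D(np.where(roi.bits, float(level), 0.0))


def enhance(image: Image2D, v: Image2D) -> Image2D:
    """Pixelwise sum of an image and its enhancement matrix (no clipping)."""
    if image.shape != v.shape:
        raise ShapeError(f"shape mismatch: {image.shape} vs {v.shape}")
    return Image2D(image.pixels + v.pixels, pixel_size=image.pixel_size)


def _int_intensities(image: Image2D) -> np.ndarray:
    ints = np.rint(image.pixels).astype(np.int64)
    if ints.min() < 0:
        raise InputError("negative intensities have no density bin")
    return ints


def estimate_density(enhanced_image: Image2D, roi: Mask2D) -> DensityTable:
    """Per-intensity ROI fraction over the enhanced image.

    For every integer intensity ``i`` present (after rounding),
    ``probs[i] = #(ROI pixels of intensity i) / #(all pixels of intensity i)``.
    """
    if roi.parent_shape != enhanced_image.shape:
        raise ShapeError(
            f"roi shape {roi.parent_shape} != image shape {enhanced_image.shape}"
        )
    roi.require_nonempty("density ROI")
    ints = _int_intensities(enhanced_image)
    total = np.bincount(ints.ravel())
    fg = np.bincount(ints[roi.bits], minlength=total.size)
    observed = np.nonzero(total)[0]
    return DensityTable({int(i): float(fg[i] / total[i]) for i in observed})


def apply_density(enhanced_image: Image2D, table: DensityTable) -> ProbabilityMap2D:
    """Look every (rounded) pixel intensity up in the density table."""
    ints = _int_intensities(enhanced_image)
    lut = np.zeros(max(int(ints.max()), max(table.probs, default=0)) + 1)
    for i, p in table.probs.items():
        lut[i] = p
    return ProbabilityMap2D(lut[ints])


def make_probability_map(image: Image2D, roi: Mask2D,
                         level: float) -> ProbabilityMap2D:
    """Full pipeline for one modality: enhance, fit density, apply it."""
    v = build_enhancement(image.shape, roi, level)
    enhanced = enhance(image, v)
    table = estimate_density(enhanced, roi)
    return apply_density(enhanced, table)
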