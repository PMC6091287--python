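"""Fine registration: NMI between probability maps, maximized by Powell.

The similarity is Studholme's normalized mutual information
``NMI = (H(A) + H(B)) / H(A, B)``, computed from a joint histogram over the
overlap validity mask only (fill pixels would otherwise fabricate
correlation).  NMI is 2 for identical non-constant inputs and tends to 1 for
independent ones.  The optimizer is the classic derivative-free direction-set
method with Brent line searches, warm-started at the coarse landmark
transform so the search begins near the basin of the global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from . import basic as _basic
from .probmap import ProbabilityMap2D, make_probability_map
from .types import (
    Affine2D,
    DegenerateInputError,
    Image2D,
    InputError,
    LandmarkTriplet,
    Mask2D,
    RegistrationConfig,
    ShapeError,
)

#: NMI of fully independent inputs; worst score assigned to invalid trials
_NMI_FLOOR = 1.0


def _as_array(a) -> np.ndarray:
    if isinstance(a, Image2D):
        return a.pixels
    if isinstance(a, ProbabilityMap2D):
        return a.values
    return np.asarray(a, dtype=np.float64)


def nmi(a, b, bins: int = 64, valid: Mask2D | None = None) -> float:
    """Normalized mutual information ``(H(A)+H(B))/H(A,B)`` in [1, 2].

    Histograms use ``bins`` equal-width bins over each input's observed range
    restricted to the ``valid`` mask (all pixels when omitted).  Constant
    input over the valid region has zero marginal entropy and raises
    :class:`DegenerateInputError`.
    """
    arr_a, arr_b = _as_array(a), _as_array(b)
    if arr_a.shape != arr_b.shape:
        raise ShapeError(f"shape mismatch: {arr_a.shape} vs {arr_b.shape}")
    if valid is None:
        av, bv = arr_a.ravel(), arr_b.ravel()
    else:
        if valid.parent_shape != arr_a.shape:
            raise ShapeError("validity mask shape mismatch")
        av, bv = arr_a[valid.bits], arr_b[valid.bits]
    if av.size == 0:
        raise InputError("empty validity mask")
    alo, ahi = float(av.min()), float(av.max())
    blo, bhi = float(bv.min()), float(bv.max())
    if alo == ahi or blo == bhi:
        raise DegenerateInputError("constant input over valid region")
    ia = np.minimum((av - alo) * (bins / (ahi - alo)), bins - 1).astype(np.intp)
    ib = np.minimum((bv - blo) * (bins / (bhi - blo)), bins - 1).astype(np.intp)
    joint = np.bincount(ia * bins + ib, minlength=bins * bins).astype(np.float64)
    joint /= joint.sum()
    nz = joint[joint > 0]
    h_ab = float(-(nz * np.log(nz)).sum())
    pa = joint.reshape(bins, bins).sum(axis=1)
    pb = joint.reshape(bins, bins).sum(axis=0)
    h_a = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    h_b = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    return (h_a + h_b) / h_ab


# --- transform parameterizations -------------------------------------------
# Parameters are expressed about a center c (the fixed-image center) so that
# rotation/scale perturbations do not drag large translation components:
#   T = Translate(c + t) . R(theta) . [[sx, sh], [0, sy]] . Translate(-c)
# Powell sees a scaled vector (translations in px, angle in rad*100,
# scales/shear *100) so one line-search step is commensurate across axes.

_PARAM_SCALE = {
    "affine6": np.array([1.0, 1.0, 100.0, 100.0, 100.0, 100.0]),
    "rigid_scale4": np.array([1.0, 1.0, 100.0, 100.0]),
}


def params_from_affine(t: Affine2D, model: str, center: np.ndarray) -> np.ndarray:
    """Decompose a transform into the natural (unscaled) parameter vector."""
    m = t.matrix[:2, :2]
    tr = t.matrix[:2, 2] + m @ center - center
    a, b = m[0]
    c, d = m[1]
    sx = float(np.hypot(a, c))
    theta = float(np.arctan2(c, a))
    sh = float(np.cos(theta) * b + np.sin(theta) * d)
    sy = float(-np.sin(theta) * b + np.cos(theta) * d)
    if model == "affine6":
        return np.array([tr[0], tr[1], theta, sx, sy, sh])
    if model == "rigid_scale4":
        return np.array([tr[0], tr[1], theta, 0.5 * (sx + sy)])
    raise InputError(f"unknown transform model {model!r}")


def affine_matrix_from_params(p: np.ndarray, model: str,
                              center: np.ndarray) -> np.ndarray:
    """Recompose the 3x3 matrix; may be singular for extreme parameters."""
    if model == "affine6":
        tx, ty, theta, sx, sy, sh = p
    elif model == "rigid_scale4":
        tx, ty, theta, s = p
        sx = sy = s
        sh = 0.0
    else:
        raise InputError(f"unknown transform model {model!r}")
    ct, st = np.cos(theta), np.sin(theta)
    m = np.array([[ct, -st], [st, ct]]) @ np.array([[sx, sh], [0.0, sy]])
    t = center + np.array([tx, ty]) - m @ center
    out = np.eye(3)
    out[:2, :2] = m
    out[:2, 2] = t
    return out


@dataclass
class PowellTrace:
    """Audit trail of the direction-set search."""

    nmi_values: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    n_iterations: int = 0


def _warp_score(fixed_arr: np.ndarray, moving_arr: np.ndarray,
                matrix: np.ndarray, bins: int) -> float:
    """NMI of the warped moving array against the fixed array.

    Bilinear interpolation inside the metric loop (cubic is reserved for the
    final resample); invalid trials — near-singular matrix, (near-)empty
    overlap, constant overlap — score the NMI floor of 1.0.
    """
    if abs(np.linalg.det(matrix[:2, :2])) < 1e-8:
        return _NMI_FLOOR
    tinv = np.linalg.inv(matrix)
    a = tinv[:2, :2]
    matrix_rc = np.array([[a[1, 1], a[1, 0]], [a[0, 1], a[0, 0]]])
    offset_rc = np.array([tinv[1, 2], tinv[0, 2]])
    warped = ndimage.affine_transform(
        moving_arr, matrix_rc, offset=offset_rc, output_shape=fixed_arr.shape,
        order=1, mode="constant", cval=0.0, prefilter=False,
    )
    valid = _basic._validity(tinv, fixed_arr.shape, moving_arr.shape)
    if valid.sum() < 16:
        return _NMI_FLOOR
    try:
        return nmi(fixed_arr, warped, bins=bins, valid=Mask2D(valid))
    except DegenerateInputError:
        return _NMI_FLOOR


def powell_register(fixed_map, moving_map, t_init: Affine2D,
                    cfg: RegistrationConfig) -> tuple[Affine2D, PowellTrace]:
    """Maximize NMI over the transform parameters, warm-started at ``t_init``.

    Returns the best transform found and the evaluation trace; the result is
    never worse than the starting point.
    """
    fixed_arr, moving_arr = _as_array(fixed_map), _as_array(moving_map)
    h, w = fixed_arr.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    model = cfg.transform_model
    scale = _PARAM_SCALE[model]
    x0 = params_from_affine(t_init, model, center) * scale
    trace = PowellTrace()

    def objective(x: np.ndarray) -> float:
        matrix = affine_matrix_from_params(x / scale, model, center)
        score = _warp_score(fixed_arr, moving_arr, matrix, cfg.nmi_bins)
        trace.nmi_values.append(score)
        trace.n_evaluations += 1
        return -score

    f0 = objective(x0)
    res = optimize.minimize(
        objective, x0, method="Powell",
        options={
            "xtol": cfg.powell_xtol, "ftol": 1e-9,
            "maxiter": cfg.powell_max_iter, "maxfev": 50_000,
        },
    )
    trace.n_iterations = int(res.nit)
    x_best, f_best = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
    t_final = Affine2D(affine_matrix_from_params(x_best / scale, model, center))
    return t_final, trace


@dataclass
class RegistrationResult:
    """Full outcome of a two-stage run."""

    mode: str  # "vpmmi" (probability maps) or "vmi" (raw intensities)
    t_basic: Affine2D
    t_final: Affine2D
    s_final: Image2D
    valid: Mask2D
    nmi_initial: float
    nmi_final: float
    iterations: int
    trace: PowellTrace
    config: RegistrationConfig

    def __post_init__(self) -> None:
        if self.nmi_final < self.nmi_initial - 1e-9:
            raise InputError("optimizer returned a point worse than its start")


def register_vpmmi(fixed: Image2D, moving: Image2D, fixed_mask: Mask2D,
                   moving_mask: Mask2D, fixed_lm: LandmarkTriplet,
                   moving_lm: LandmarkTriplet,
                   cfg: RegistrationConfig | None = None,
                   mode: str = "vpmmi") -> RegistrationResult:
    """Two-stage multimodal registration.

    1. Coarse: solve the affine from the three valve landmark pairs.
    2. Build ROI-membership probability maps (level N for the fixed CT-like
       image, level M for the moving TEE-like image, in native moving space).
    3. Fine: Powell-maximize NMI between the maps, warm-started at the
       coarse transform.
    4. Resample the original moving image through the final transform.

    ``mode="vmi"`` is the ablation baseline: step 2 is skipped and NMI is
    computed on the raw intensities.
    """
    cfg = cfg or RegistrationConfig()
    if mode not in ("vpmmi", "vmi"):
        raise InputError(f"mode must be 'vpmmi' or 'vmi', got {mode!r}")
    if fixed_mask.parent_shape != fixed.shape:
        raise InputError(
            f"fixed mask shape {fixed_mask.parent_shape} != image {fixed.shape}"
        )
    if moving_mask.parent_shape != moving.shape:
        raise InputError(
            f"moving mask shape {moving_mask.parent_shape} != image {moving.shape}"
        )
    fixed_mask.require_nonempty("fixed mask")
    moving_mask.require_nonempty("moving mask")

    coarse = _basic.run_basic(fixed, moving, fixed_lm, moving_lm)
    if mode == "vpmmi":
        fixed_obj = make_probability_map(fixed, fixed_mask, cfg.N)
        moving_obj = make_probability_map(moving, moving_mask, cfg.M)
    else:
        fixed_obj, moving_obj = fixed, moving

    fixed_arr, moving_arr = _as_array(fixed_obj), _as_array(moving_obj)
    nmi_initial = _warp_score(fixed_arr, moving_arr, coarse.t_basic.matrix,
                              cfg.nmi_bins)
    t_final, trace = powell_register(fixed_obj, moving_obj, coarse.t_basic, cfg)
    nmi_final = _warp_score(fixed_arr, moving_arr, t_final.matrix, cfg.nmi_bins)
    if nmi_final < nmi_initial:  # line-search round-off: keep the warm start
        t_final, nmi_final = coarse.t_basic, nmi_initial
    s_final, valid = _basic.resample(moving, t_final, fixed.shape)
    return RegistrationResult(
        mode=mode, t_basic=coarse.t_basic, t_final=t_final, s_final=s_final,
        valid=valid, nmi_initial=nmi_initial, nmi_final=nmi_final,
        iterations=trace.n_iterations, trace=trace, config=cfg,
    )
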