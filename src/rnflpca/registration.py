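"""Spatial normalisation of thickness maps into a common reference frame.

The chain mirrors standard practice for pooling wide-angle RNFL maps:

1. mirror left (OS) eyes to right-eye (OD) orientation;
2. align each eye's baseline scan to a canonical frame via the exact
   two-point (fovea / optic nerve head) similarity transform;
3. refine follow-up scans against the registered baseline by maximising the
   enhanced correlation coefficient (ECC) — a contrast-invariant, zero-mean
   normalised correlation objective — with Gauss-Newton updates;
4. standardise each pixel to zero mean / unit variance across scans.

Pixels that fall outside the source frame after resampling are carried as
NaN and excluded from the standardisation statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (affine_transform, binary_erosion, gaussian_filter,
                           map_coordinates, zoom)

from .maps import ThicknessMap
from .transforms import SimilarityTransform

log = logging.getLogger(__name__)

#: canonical landmark positions as fractions of (W, H); right-eye oriented
#: with the optic nerve head left of the fovea.
CANONICAL_FOVEA_FRAC = (0.62, 0.50)
CANONICAL_ONH_FRAC = (0.30, 0.47)


def canonical_landmarks(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Reference (fovea, ONH) pixel coordinates for an ``(H, W)`` grid."""
    h, w = shape
    fovea = np.array([CANONICAL_FOVEA_FRAC[0] * (w - 1),
                      CANONICAL_FOVEA_FRAC[1] * (h - 1)])
    onh = np.array([CANONICAL_ONH_FRAC[0] * (w - 1),
                    CANONICAL_ONH_FRAC[1] * (h - 1)])
    return fovea, onh


# ---------------------------------------------------------------------------
# flip


def flip_to_od(tmap: ThicknessMap) -> ThicknessMap:
    """Mirror OS maps about the vertical axis into OD orientation.

    OD maps (and maps already flipped) pass through unchanged.
    """
    if tmap.od_oriented or tmap.laterality == "OD":
        return tmap.copy_with(od_oriented=True)
    h, w = tmap.shape
    mirror_x = lambda x: (w - 1) - x  # noqa: E731
    return tmap.copy_with(
        values=tmap.values[:, ::-1].copy(),
        fovea_xy=(mirror_x(tmap.fovea_xy[0]), tmap.fovea_xy[1]),
        onh_xy=(mirror_x(tmap.onh_xy[0]), tmap.onh_xy[1]),
        od_oriented=True,
    )


def unflip(tmap: ThicknessMap) -> ThicknessMap:
    """Inverse of :func:`flip_to_od` (used in tests and simulation)."""
    if tmap.laterality == "OD" or not tmap.od_oriented:
        return tmap.copy_with(od_oriented=False)
    h, w = tmap.shape
    return tmap.copy_with(
        values=tmap.values[:, ::-1].copy(),
        fovea_xy=((w - 1) - tmap.fovea_xy[0], tmap.fovea_xy[1]),
        onh_xy=((w - 1) - tmap.onh_xy[0], tmap.onh_xy[1]),
        od_oriented=False,
    )


# ---------------------------------------------------------------------------
# landmark similarity


def landmark_similarity(src_fovea, src_onh, ref_fovea, ref_onh,
                        min_sep: float = 1e-6) -> SimilarityTransform:
    """Exact similarity mapping the source landmark pair onto the reference.

    Treating points as complex numbers ``z' = a z + b`` has a unique solution
    for two point pairs; this resolves translation, rotation and scale in
    closed form.
    """
    zs_f, zs_o = complex(*src_fovea), complex(*src_onh)
    zr_f, zr_o = complex(*ref_fovea), complex(*ref_onh)
    if abs(zs_f - zs_o) < min_sep or abs(zr_f - zr_o) < min_sep:
        raise ValueError("fovea and ONH landmarks are (nearly) coincident")
    a = (zr_f - zr_o) / (zs_f - zs_o)
    b = zr_f - a * zs_f
    return SimilarityTransform(scale=abs(a), theta=float(np.angle(a)),
                               tx=b.real, ty=b.imag)


# ---------------------------------------------------------------------------
# resampling


def warp_values(values: np.ndarray, transform: SimilarityTransform,
                out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear warp of a grid under ``transform`` (source -> output coords).

    Output pixels that map outside the source frame become NaN.
    """
    inv = transform.inverse().matrix
    # affine_transform works in (row, col); swap axes of the (x, y) matrix
    a = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    offset = np.array([inv[1, 2], inv[0, 2]])
    src = np.ascontiguousarray(values, dtype=float)
    return affine_transform(src, a, offset=offset, output_shape=out_shape,
                            order=1, mode="constant", cval=np.nan)


def resample(tmap: ThicknessMap, transform: SimilarityTransform,
             out_shape: tuple[int, int] | None = None) -> ThicknessMap:
    """Apply a similarity transform to a map; landmarks move consistently."""
    out_shape = out_shape or tmap.shape
    values = warp_values(tmap.values, transform, out_shape)
    values = np.where(np.isfinite(values), np.maximum(values, 0.0), values)
    return tmap.copy_with(
        values=values,
        fovea_xy=tuple(transform.apply(np.asarray(tmap.fovea_xy))),
        onh_xy=tuple(transform.apply(np.asarray(tmap.onh_xy))),
    )


# ---------------------------------------------------------------------------
# ECC registration


@dataclass
class ECCResult:
    transform: SimilarityTransform
    ecc: float
    converged: bool
    n_iters: int


def _ecc_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    x = a[mask] - a[mask].mean()
    y = b[mask] - b[mask].mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    return float(x @ y / denom) if denom > 0 else 0.0


def _ecc_single_scale(moving: np.ndarray, fixed: np.ndarray,
                      p: np.ndarray, motion: str, max_iters: int,
                      eps: float,
                      moving_valid: np.ndarray | None = None,
                      fixed_valid: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, float, bool, int]:
    """Forward-additive ECC maximisation at one pyramid level.

    Parametrisation: Euclidean ``p = (theta, tx, ty)``; similarity
    ``p = (a, b, tx, ty)`` with the linear part ``[[1+a, -b], [b, 1+a]]``
    (a scaled rotation, i.e. an exact similarity). ``*_valid`` masks flag
    pixels with trustworthy data; invalid pixels (e.g. filled sentinel
    borders) are excluded from the correlation and its gradients.
    """
    h, w = fixed.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    gy_m, gx_m = np.gradient(moving)
    j = fixed.copy()
    mv_valid = (np.ones_like(moving) if moving_valid is None
                else moving_valid.astype(float))
    fx_valid = (np.ones(fixed.shape, dtype=bool) if fixed_valid is None
                else fixed_valid.astype(bool))
    rho_prev = -np.inf
    rho = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        if motion == "euclidean":
            theta, tx, ty = p
            c, s = np.cos(theta), np.sin(theta)
            wx = c * xx - s * yy + tx
            wy = s * xx + c * yy + ty
        else:
            a, b, tx, ty = p
            wx = (1 + a) * xx - b * yy + tx
            wy = b * xx + (1 + a) * yy + ty
        coords = np.vstack([wy.ravel(), wx.ravel()])
        iw = map_coordinates(moving, coords, order=1, mode="constant",
                             cval=np.nan).reshape(h, w)
        gx = map_coordinates(gx_m, coords, order=1, mode="constant",
                             cval=np.nan).reshape(h, w)
        gy = map_coordinates(gy_m, coords, order=1, mode="constant",
                             cval=np.nan).reshape(h, w)
        vw = map_coordinates(mv_valid, coords, order=1, mode="constant",
                             cval=0.0).reshape(h, w)
        mask = (np.isfinite(iw) & np.isfinite(j) & np.isfinite(gx)
                & np.isfinite(gy) & (vw > 0.995) & fx_valid)
        n = int(mask.sum())
        if n < 16:
            break
        x, y = xx[mask], yy[mask]
        gxm, gym = gx[mask], gy[mask]
        if motion == "euclidean":
            theta = p[0]
            c, s = np.cos(theta), np.sin(theta)
            d_theta = gxm * (-s * x - c * y) + gym * (c * x - s * y)
            g = np.column_stack([d_theta, gxm, gym])
        else:
            g = np.column_stack([gxm * x + gym * y,      # d/da
                                 -gxm * y + gym * x,     # d/db
                                 gxm, gym])
        iv = iw[mask]
        jv = j[mask]
        ic = iv - iv.mean()
        jc = jv - jv.mean()
        gc = g - g.mean(axis=0)

        rho = float(ic @ jc / (np.linalg.norm(ic) * np.linalg.norm(jc) + 1e-30))
        if abs(rho - rho_prev) < eps:
            converged = True
            break
        rho_prev = rho

        gtg = gc.T @ gc
        try:
            gtg_inv = np.linalg.inv(gtg)
        except np.linalg.LinAlgError:
            break
        gi = gc.T @ ic
        gj = gc.T @ jc
        num = float(ic @ ic - gi @ gtg_inv @ gi)
        den = float(jc @ ic - gj @ gtg_inv @ gi)
        if den <= 0:
            # correlation cannot be improved along this direction (divergence
            # guard from the original algorithm); bail out
            break
        lam = num / den
        err = lam * jc - ic
        dp = gtg_inv @ (gc.T @ err)
        p = p + dp
    return p, rho, converged, it


def ecc_register(moving: ThicknessMap | np.ndarray,
                 fixed: ThicknessMap | np.ndarray,
                 motion: str = "similarity",
                 max_iters: int = 100,
                 eps: float = 1e-7,
                 pyramid_levels: int = 2) -> ECCResult:
    """Estimate the transform aligning ``moving`` onto ``fixed`` by ECC.

    Returns the transform ``T`` such that resampling ``moving`` with ``T``
    (source -> output) best matches ``fixed`` under the enhanced correlation
    coefficient. A coarse-to-fine pyramid widens the convergence basin.

    Non-convergence is reported through ``converged`` rather than raised, so
    callers can fall back to identity / exclude the scan (mirroring manual
    quality-control exclusion of misaligned scans).
    """
    if motion not in ("euclidean", "similarity"):
        raise ValueError("motion must be 'euclidean' or 'similarity'")
    mov = moving.values if isinstance(moving, ThicknessMap) else np.asarray(moving, float)
    fix = fixed.values if isinstance(fixed, ThicknessMap) else np.asarray(fixed, float)
    if mov.shape != fix.shape:
        raise ValueError("moving and fixed maps must share a shape")

    # Fill sentinel pixels with the finite mean so gradients are defined,
    # and carry eroded validity masks so filled borders never enter the
    # correlation.
    def _fill(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        finite = np.isfinite(a)
        valid = binary_erosion(finite, iterations=2) if not finite.all() \
            else finite
        if finite.all():
            return a.astype(float), valid
        out = a.astype(float).copy()
        out[~finite] = a[finite].mean()
        return out, valid

    mov_f, mov_valid = _fill(mov)
    fix_f, fix_valid = _fill(fix)

    n_params = 3 if motion == "euclidean" else 4
    p = np.zeros(n_params)
    converged = False
    iters_total = 0
    rho = -np.inf
    for level in range(pyramid_levels - 1, -1, -1):
        f = 2 ** level
        if f > 1:
            mv = zoom(gaussian_filter(mov_f, f / 2.0), 1.0 / f, order=1)
            fx = zoom(gaussian_filter(fix_f, f / 2.0), 1.0 / f, order=1)
            mvv = zoom(mov_valid.astype(float), 1.0 / f, order=1) > 0.99
            fxv = zoom(fix_valid.astype(float), 1.0 / f, order=1) > 0.99
        else:
            mv, fx = mov_f, fix_f
            mvv, fxv = mov_valid, fix_valid
        # translation components live in pixel units of the level
        p_level = p.copy()
        p_level[-2:] /= f
        p_level, rho, converged, it = _ecc_single_scale(
            mv, fx, p_level, motion, max_iters, eps,
            moving_valid=mvv, fixed_valid=fxv)
        iters_total += it
        p = p_level.copy()
        p[-2:] *= f

    # The fitted warp samples `moving` at W(x) for output pixel x, i.e. it is
    # the map output->source; the source->output transform is its inverse.
    if motion == "euclidean":
        theta, tx, ty = p
        fwd = SimilarityTransform(1.0, float(theta), float(tx), float(ty))
    else:
        a, b, tx, ty = p
        fwd = SimilarityTransform(
            scale=float(np.hypot(1 + a, b)),
            theta=float(np.arctan2(b, 1 + a)),
            tx=float(tx), ty=float(ty))
    return ECCResult(transform=fwd.inverse(), ecc=rho,
                     converged=converged, n_iters=iters_total)


# ---------------------------------------------------------------------------
# per-pixel standardisation


@dataclass
class StandardizationModel:
    """Per-pixel mean / SD learned from a registered training stack."""

    mean: np.ndarray
    sd: np.ndarray
    n_fitted: int
    eps: float = 1e-6
    #: per-pixel count of finite training samples
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]


def fit_standardization(stack: np.ndarray, eps: float = 1e-6) -> StandardizationModel:
    """Fit per-pixel zero-mean / unit-variance scaling.

    ``stack`` is ``(n, H, W)`` with NaN marking out-of-frame pixels, which
    are excluded from the statistics. SD is floored at ``eps`` so constant
    pixels standardise to exactly zero.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (n>=2, H, W) stack")
    counts = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0)
    mean = np.where(counts > 0, mean, 0.0)
    sd = np.where(counts > 1, sd, eps)
    sd = np.maximum(sd, eps)
    return StandardizationModel(mean=mean, sd=sd, n_fitted=stack.shape[0],
                                eps=eps, counts=counts)


def apply_standardization(values: np.ndarray, model: StandardizationModel,
                          impute: float | None = 0.0) -> np.ndarray:
    """Standardise one map (or an ``(n, H, W)`` stack) in the model's frame.

    NaN (out-of-frame) pixels become ``impute`` (standardised-mean 0 by
    default) or stay NaN when ``impute=None``.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-2:] != model.mean.shape:
        raise ValueError("shape mismatch with standardization model")
    out = (v - model.mean) / model.sd
    if impute is not None:
        out = np.where(np.isfinite(out), out, impute)
    return out


# ---------------------------------------------------------------------------
# full chain


def _plausible_refinement(t: SimilarityTransform,
                          shape: tuple[int, int]) -> bool:
    """Reject runaway ECC solutions: a refinement after landmark alignment
    must stay a small correction (follow-up scans share the baseline pose
    up to acquisition jitter)."""
    h, w = shape
    return (0.8 <= t.scale <= 1.25 and abs(t.theta) < 0.35
            and abs(t.tx) < 0.25 * w and abs(t.ty) < 0.25 * h)


@dataclass
class RegisteredScan:
    scan_id: str
    transform: SimilarityTransform
    ecc: float
    converged: bool


def register_scans(maps: list[ThicknessMap],
                   motion: str = "similarity",
                   ecc_refine: bool = True,
                   max_iters: int = 100) -> tuple[np.ndarray, list[RegisteredScan]]:
    """Run flip -> landmark alignment -> ECC refinement over a scan list.

    Baseline scans (earliest visit per eye) are aligned to the canonical
    landmark frame exactly; follow-up scans inherit the baseline transform
    and are refined against their registered baseline by ECC, as only
    baseline landmarks are assumed to be manually marked.

    Returns the registered ``(n, H, W)`` stack (NaN outside the source
    frame) in the input order, plus per-scan records.
    """
    if not maps:
        raise ValueError("no maps to register")
    shape = maps[0].shape
    ref_fovea, ref_onh = canonical_landmarks(shape)

    flipped = [flip_to_od(m) for m in maps]
    # group scan indices by eye, baseline first
    by_eye: dict[str, list[int]] = {}
    for i, m in enumerate(flipped):
        by_eye.setdefault(m.eye_id or f"scan{i}", []).append(i)

    stack = np.full((len(maps), *shape), np.nan)
    records: list[RegisteredScan] = [None] * len(maps)  # type: ignore[list-item]
    for eye, idxs in by_eye.items():
        idxs = sorted(idxs, key=lambda i: flipped[i].visit_month)
        base = flipped[idxs[0]]
        t_base = landmark_similarity(base.fovea_xy, base.onh_xy,
                                     ref_fovea, ref_onh)
        base_reg = resample(base, t_base, shape)
        stack[idxs[0]] = base_reg.values
        records[idxs[0]] = RegisteredScan(base.scan_id, t_base, 1.0, True)
        for i in idxs[1:]:
            m = flipped[i]
            rough = resample(m, t_base, shape)
            if ecc_refine:
                res = ecc_register(rough.values, base_reg.values,
                                   motion=motion, max_iters=max_iters)
                ok = res.converged and _plausible_refinement(res.transform,
                                                            shape)
                if ok:
                    t_full = res.transform.compose(t_base)
                else:
                    log.warning("ECC refinement rejected for %s; using "
                                "landmark transform only", m.scan_id)
                    t_full = t_base
                reg = resample(m, t_full, shape)
                stack[i] = reg.values
                records[i] = RegisteredScan(m.scan_id, t_full, res.ecc, ok)
            else:
                stack[i] = rough.values
                records[i] = RegisteredScan(m.scan_id, t_base, np.nan, True)
    return stack, records
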