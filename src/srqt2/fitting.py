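"""Voxelwise mono-exponential T2 estimation.

Each voxel with signals :math:`S_i` at echo times :math:`TE_i` is fit to
``S(TE) = M0 * exp(-TE / T2)`` in two stages: an unweighted ordinary
least-squares line through ``ln S`` vs ``TE`` (slope = -1/T2) provides the
starting point, and a Nelder-Mead simplex search over ``(M0, T2)``
(default 100 iterations) minimizes the untransformed residual sum of
squares.  The simplex runs batched over all masked voxels at once so
whole-map fits stay fast; the scalar :func:`simplex_fit` is the same
engine with a batch of one.

T2 estimates are clamped to a configurable physical range; voxels whose
log-linear slope is non-negative (no measurable decay) are clamped to the
upper bound and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volumes import GridSpec, ImageVolume

_BIG = 1e30


@dataclass(frozen=True)
class FitConfig:
    """Settings for map-level fitting."""

    t2_min: float = 1.0        # ms, lower clamp
    t2_max: float = 3000.0     # ms, upper clamp
    max_iter: int = 100        # Nelder-Mead iterations per voxel
    ftol: float = 1e-6         # relative RSS spread for convergence
    mask_sigma_mult: float = 3.0  # fit-mask threshold in background-noise SDs


@dataclass
class T2FitResult:
    """Voxelwise fit output: parameter maps plus quality masks."""

    m0_map: ImageVolume
    t2_map: ImageVolume
    rss_map: ImageVolume
    mask: ImageVolume        # 1 where a fit was performed
    converged: ImageVolume   # 1 where the simplex met tolerance and decay was seen

    @property
    def grid(self) -> GridSpec:
        return self.t2_map.grid


# ---------------------------------------------------------------------------
# log-linear initialization
# ---------------------------------------------------------------------------

def loglinear_fit(signals, tes) -> tuple[float, float]:
    """OLS of ``ln S`` on TE: returns ``(M0, T2)``.

    Only strictly positive signals enter the line fit.  Returns
    ``(nan, nan)`` when fewer than two usable points remain and
    ``(M0, inf)`` when the fitted slope is non-negative (non-decaying
    signal, e.g. two equal samples).
    """
    s = np.asarray(signals, dtype=float)
    t = np.asarray(tes, dtype=float)
    if s.shape != t.shape:
        raise ValueError("signals and tes must have equal length")
    keep = s > 0
    if keep.sum() < 2 or np.unique(t[keep]).size < 2:
        return (math.nan, math.nan)
    y = np.log(s[keep])
    x = t[keep]
    slope, intercept = np.polyfit(x, y, 1)
    m0 = float(np.exp(min(intercept, 700.0)))
    if slope >= -1e-12:  # flat or rising within round-off: no decay
        return (m0, math.inf)
    return (m0, float(-1.0 / slope))


def _loglinear_batch(S: np.ndarray, tes: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized log-linear fit. S: (n_vox, n_te). Returns m0, t2, decaying."""
    w = (S > 0).astype(np.float64)
    n = w.sum(axis=1)
    logS = np.where(S > 0, np.log(np.maximum(S, 1e-300)), 0.0)
    x = tes[None, :]
    sw_x = (w * x).sum(axis=1)
    sw_y = (w * logS).sum(axis=1)
    sw_xx = (w * x * x).sum(axis=1)
    sw_xy = (w * x * logS).sum(axis=1)
    denom = n * sw_xx - sw_x ** 2
    ok = (n >= 2) & (denom > 1e-12)
    slope = np.where(ok, (n * sw_xy - sw_x * sw_y) / np.where(ok, denom, 1.0), 0.0)
    intercept = np.where(ok, (sw_y - slope * sw_x) / np.maximum(n, 1.0), 0.0)
    m0 = np.exp(np.clip(intercept, -700.0, 700.0))
    decaying = ok & (slope < 0)
    t2 = np.where(decaying, -1.0 / np.where(slope < 0, slope, -1.0), np.inf)
    t2[~ok] = np.nan
    m0[~ok] = np.nan
    return m0, t2, decaying


# ---------------------------------------------------------------------------
# batched Nelder-Mead over (M0, T2)
# ---------------------------------------------------------------------------

def _rss_batch(params: np.ndarray, S: np.ndarray, tes: np.ndarray) -> np.ndarray:
    """RSS of the decay model; params (..., 2), S (n_vox, n_te)."""
    m0 = params[..., 0]
    t2 = params[..., 1]
    t2c = np.maximum(t2, 1e-6)
    with np.errstate(over="ignore", invalid="ignore"):
        pred = m0[..., None] * np.exp(-tes / t2c[..., None])
        rss = ((S - pred) ** 2).sum(axis=-1)
    rss = np.nan_to_num(rss, nan=_BIG, posinf=_BIG)
    # keep the search in the physical quadrant
    pen = np.where(t2 <= 0, _BIG * (1.0 + np.minimum(np.abs(t2), 1e6)), 0.0)
    pen += np.where(m0 < 0, _BIG * (1.0 + np.minimum(np.abs(m0), 1e6)), 0.0)
    return rss + pen


def _nelder_mead_batch(S: np.ndarray, tes: np.ndarray,
                       init: np.ndarray, max_iter: int, ftol: float
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simultaneous 2-parameter Nelder-Mead for every row of ``S``.

    Standard reflection/expansion/contraction/shrink with coefficients
    (1, 2, 0.5, 0.5); the best vertex never worsens, so the final RSS is
    bounded by the RSS at the initial point.

    Returns (params (n,2), rss (n,), converged (n,) bool).
    """
    n = S.shape[0]
    # initial simplex: 5% relative steps (0.00025 absolute for zero entries),
    # mirroring the common right-angled construction
    v0 = init.copy()
    v1 = init.copy()
    v1[:, 0] += np.where(init[:, 0] != 0, 0.05 * init[:, 0], 0.00025)
    v2 = init.copy()
    v2[:, 1] += np.where(init[:, 1] != 0, 0.05 * init[:, 1], 0.00025)
    f0 = _rss_batch(v0, S, tes)
    f1 = _rss_batch(v1, S, tes)
    f2 = _rss_batch(v2, S, tes)
    # RSS below this is numerically zero at double precision
    floor = 1e-20 * (S ** 2).sum(axis=1)

    def swap(fa, fb, va, vb, cond):
        # enforce fa <= fb where cond; mask-based, no gathers
        c2 = cond[:, None]
        va2 = np.where(c2, vb, va)
        vb2 = np.where(c2, va, vb)
        fa2 = np.where(cond, fb, fa)
        fb2 = np.where(cond, fa, fb)
        return fa2, fb2, va2, vb2

    live = np.ones(n, dtype=bool)
    conv_override = np.zeros(n, dtype=bool)
    overridden = np.zeros(n, dtype=bool)
    for it in range(max_iter):
        # keep the three vertices ordered best -> worst
        f0, f1, v0, v1 = swap(f0, f1, v0, v1, f1 < f0)
        f1, f2, v1, v2 = swap(f1, f2, v1, v2, f2 < f1)
        f0, f1, v0, v1 = swap(f0, f1, v0, v1, f1 < f0)

        live &= ((f2 - f0) > ftol * (np.abs(f0) + 1e-12)) & (f0 > floor)
        if not live.any():
            break
        idx = np.flatnonzero(live)
        if idx.size < n // 2 and it < max_iter - 1:
            # restart compacted from the best vertex for the remaining budget
            b, fb, cv = _nelder_mead_batch(S[idx], tes,
                                           np.stack([v0[idx, 0], v0[idx, 1]], 1),
                                           max_iter=max_iter - it - 1, ftol=ftol)
            v0[idx], f0[idx] = b, fb
            conv_override[idx] = cv
            overridden[idx] = True
            break

        c = 0.5 * (v0 + v1)                    # centroid of best two
        xr = c + (c - v2)
        fr = _rss_batch(xr, S, tes)

        best_r = fr < f0
        fe = np.full(n, np.inf)
        if best_r.any():
            sub = np.flatnonzero(best_r & live)
            xe = c[sub] + 2.0 * (c[sub] - v2[sub])
            fe_s = _rss_batch(xe, S[sub], tes)
            take_e = fe_s < fr[sub]
            tgt = sub[take_e]
            v2[tgt] = xe[take_e]
            f2[tgt] = fe_s[take_e]
            fe[sub] = fe_s
        use_r = live & (((best_r) & (fe >= fr)) | (~best_r & (fr < f1)))
        v2[use_r] = xr[use_r]
        f2[use_r] = fr[use_r]

        rest = live & ~best_r & (fr >= f1)
        if rest.any():
            sub = np.flatnonzero(rest)
            out_c = fr[sub] < f2[sub]
            # outside contraction toward the reflection, inside toward worst
            xc = np.where(out_c[:, None],
                          c[sub] + 0.5 * (xr[sub] - c[sub]),
                          c[sub] + 0.5 * (v2[sub] - c[sub]))
            fc = _rss_batch(xc, S[sub], tes)
            accept = np.where(out_c, fc <= fr[sub], fc < f2[sub])
            tgt = sub[accept]
            v2[tgt] = xc[accept]
            f2[tgt] = fc[accept]
            sh = sub[~accept]
            if sh.size:
                v1[sh] = v0[sh] + 0.5 * (v1[sh] - v0[sh])
                v2[sh] = v0[sh] + 0.5 * (v2[sh] - v0[sh])
                f1[sh] = _rss_batch(v1[sh], S[sh], tes)
                f2[sh] = _rss_batch(v2[sh], S[sh], tes)

    f0, f1, v0, v1 = swap(f0, f1, v0, v1, f1 < f0)
    f1, f2, v1, v2 = swap(f1, f2, v1, v2, f2 < f1)
    f0, f1, v0, v1 = swap(f0, f1, v0, v1, f1 < f0)
    converged = ((f2 - f0) <= ftol * (np.abs(f0) + 1e-12)) | (f0 <= floor)
    converged = np.where(overridden, conv_override, converged)
    return v0, f0, converged


def simplex_fit(signals, tes, init_m0: float, init_t2: float,
                max_iter: int = 100, t2_min: float = 1.0,
                t2_max: float = 3000.0, ftol: float = 1e-6
                ) -> tuple[float, float, float, bool]:
    """Nelder-Mead refinement of a single voxel: returns (M0, T2, RSS, converged).

    The returned RSS never exceeds the RSS of the (clamped) starting
    point; T2 is clamped to ``[t2_min, t2_max]``.
    """
    S = np.asarray(signals, dtype=float)[None, :]
    t = np.asarray(tes, dtype=float)
    init = np.array([[float(init_m0), float(np.clip(init_t2, t2_min, t2_max))]])
    p, f, conv = _nelder_mead_batch(S, t, init, max_iter=max_iter, ftol=ftol)
    p, f = _clamp_with_fallback(p, f, init, S, t, t2_min, t2_max)
    return float(p[0, 0]), float(p[0, 1]), float(f[0]), bool(conv[0])


def _clamp_with_fallback(p, f, init, S, tes, t2_min, t2_max):
    """Clamp T2; if clamping worsened the fit, fall back to the start point."""
    clamped = p.copy()
    clamped[:, 1] = np.clip(clamped[:, 1], t2_min, t2_max)
    clamped[:, 0] = np.maximum(clamped[:, 0], 0.0)
    f_cl = _rss_batch(clamped, S, tes)
    f_init = _rss_batch(init, S, tes)
    worse = f_cl > f_init
    clamped[worse] = init[worse]
    f_cl[worse] = f_init[worse]
    return clamped, f_cl


# ---------------------------------------------------------------------------
# whole-map fitting
# ---------------------------------------------------------------------------

def fit_t2_map(aligned: list[ImageVolume], tes,
               config: FitConfig | None = None,
               validity_masks: list[np.ndarray] | None = None) -> T2FitResult:
    """Two-stage voxelwise fit of aligned multi-TE volumes.

    Voxels enter the fit when the shortest-TE intensity exceeds
    ``mask_sigma_mult`` background-noise SDs (estimated from the
    shortest-TE image itself) and all per-input validity masks are true.
    """
    config = config or FitConfig()
    tes = np.asarray(tes, dtype=float)
    if len(aligned) < 2:
        raise ValueError("need at least two aligned volumes")
    if len(aligned) != len(tes):
        raise ValueError("one TE per aligned volume required")
    ref = aligned[0]
    for v in aligned[1:]:
        if (v.data.shape != ref.data.shape
                or not np.allclose(v.spacing, ref.spacing, atol=1e-6)
                or not np.allclose(v.origin, ref.origin, atol=1e-3)):
            raise ValueError("aligned volumes must share one grid")

    stack = np.stack([np.asarray(v.data, dtype=np.float64).ravel()
                      for v in aligned])            # (n_te, n_vox)
    shortest = int(np.argmin(tes))

    from .denoise import estimate_noise_map  # local import avoids a cycle
    sigma_bg = float(np.median(estimate_noise_map(aligned[shortest]).data))
    threshold = max(config.mask_sigma_mult * sigma_bg, 1e-12)

    mask = stack[shortest] > threshold
    if validity_masks is not None:
        for vm in validity_masks:
            mask &= np.asarray(vm, dtype=bool).ravel()

    shape = ref.data.shape
    t2_map = np.zeros(shape).ravel()
    m0_map = np.zeros(shape).ravel()
    rss_map = np.zeros(shape).ravel()
    conv_map = np.zeros(shape, dtype=bool).ravel()

    idx = np.flatnonzero(mask)
    if idx.size:
        S = stack[:, idx].T                          # (n_fit, n_te)
        m0_i, t2_i, decaying = _loglinear_batch(S, tes)
        fittable = np.isfinite(m0_i)
        mask_flat = mask.copy()
        mask_flat[idx[~fittable]] = False
        idx = idx[fittable]
        S = S[fittable]
        if idx.size:
            init = np.stack([m0_i[fittable],
                             np.clip(np.where(np.isfinite(t2_i[fittable]),
                                              t2_i[fittable], config.t2_max),
                                     config.t2_min, config.t2_max)], axis=1)
            p, f, conv = _nelder_mead_batch(S, tes, init,
                                            max_iter=config.max_iter,
                                            ftol=config.ftol)
            p, f = _clamp_with_fallback(p, f, init, S, tes,
                                        config.t2_min, config.t2_max)
            t2_map[idx] = p[:, 1]
            m0_map[idx] = p[:, 0]
            rss_map[idx] = f
            conv_map[idx] = conv & decaying[fittable]
        mask = mask_flat

    mk = lambda a, dt=np.float64: ImageVolume(
        data=a.reshape(shape).astype(dt), spacing=ref.spacing, origin=ref.origin)
    return T2FitResult(m0_map=mk(m0_map), t2_map=mk(t2_map), rss_map=mk(rss_map),
                       mask=mk(mask.astype(np.float32)),
                       converged=mk(conv_map.astype(np.float32)))
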