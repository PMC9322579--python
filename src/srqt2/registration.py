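"""Rigid multi-resolution registration and super-resolution template building.

Registration maximizes an intensity similarity metric (normalized
cross-correlation by default; mutual information and mean squared error
optionally) over the six rigid parameters with a bounded derivative-free
direction-set (Powell) search, coarse to fine over a pyramid of
blur-matched, subsampled lattices.  The bound (+-15 degrees / +-20 mm
around the initialization) encodes the inter-scan motion scale and keeps
the search out of distant spurious optima.  A tiny magnitude penalty
breaks metric ties toward the smallest transform, which keeps
self-registration exactly at identity.

Super-resolution follows the iterative template-construction scheme: the
orthogonal anisotropic inputs are first upsampled to the isotropic target
grid and averaged (after per-input scaling to unit median intensity, so no
single echo dominates the anatomical template); each input is then
re-registered to the current template and the average rebuilt.  The
returned per-input aligned volumes are *not* intensity-scaled: the T2 fit
downstream needs the true TE-dependent magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize

from .transforms import RigidTransform, params_from_vector
from .volumes import GridSpec, ImageVolume, resample

_TIE_BREAK = 1e-9      # magnitude penalty: smallest transform wins flat metrics
_MIN_OVERLAP = 0.25    # valid-sample fraction below which registration aborts


class RegistrationError(RuntimeError):
    """Registration could not run or left the overlap region."""


@dataclass
class TransformPair:
    """Forward (input -> template world) and inverse transforms."""

    to_template: RigidTransform
    from_template: RigidTransform


@dataclass
class SRResult:
    """Output of super-resolution template construction."""

    template: ImageVolume
    transforms: list[TransformPair]
    aligned_inputs: list[ImageVolume]
    validity_masks: list[np.ndarray]

    @property
    def grid(self) -> GridSpec:
        return self.template.grid


# ---------------------------------------------------------------------------
# metric machinery
# ---------------------------------------------------------------------------

def _foreground_median(data: np.ndarray) -> float:
    """Median intensity of (approximate) foreground voxels."""
    med = float(np.median(data))
    fg = data > 2.0 * med if med > 0 else data > 0
    if fg.sum() < 100:
        fg = data > 0
    vals = data[fg]
    return float(np.median(vals)) if vals.size else 1.0


def _sample_lattice(fixed: ImageVolume, smoothed: np.ndarray, stride: int,
                    max_samples: int = 12000):
    """Deterministic sample of fixed-grid points: world coords and values.

    Samples sit at half-voxel offsets so the fixed values are interpolated
    exactly like the moving values are at a generic pose; on-lattice
    sampling would make the identity pose the only one whose samples keep
    raw (un-averaged) noise, biasing the metric toward misalignment.
    """
    nx, ny, nz = fixed.data.shape
    ix, iy, iz = np.meshgrid(np.arange(0, nx - 1, stride),
                             np.arange(0, ny - 1, stride),
                             np.arange(0, nz - 1, stride), indexing="ij")
    idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()]).astype(float) + 0.5
    vals = map_coordinates(smoothed, idx, order=1, mode="nearest")

    thr = 0.02 * float(np.max(smoothed)) if np.max(smoothed) > 0 else 0.0
    fg = vals > thr
    if fg.sum() >= 500:
        vals, idx = vals[fg], idx[:, fg]
    if vals.size > max_samples:
        step = int(np.ceil(vals.size / max_samples))
        vals, idx = vals[::step], idx[:, ::step]

    org = np.asarray(fixed.origin)[:, None]
    sp = np.asarray(fixed.spacing)[:, None]
    world = org + idx * sp
    return world, vals


_METRICS = ("mi", "ncc", "mse")
_MI_BINS = 32


def _mutual_information(fv: np.ndarray, mv: np.ndarray,
                        f_range: tuple[float, float],
                        m_range: tuple[float, float]) -> float:
    """MI from a soft (bilinearly binned) joint histogram.

    Soft binning keeps the metric continuous in the transform parameters,
    which the derivative-free line searches need.
    """
    bins = _MI_BINS

    def to_bin(x, lo, hi):
        return np.clip((x - lo) / max(hi - lo, 1e-12) * (bins - 1),
                       0.0, bins - 1 - 1e-9)

    bf = to_bin(fv, *f_range)
    bm = to_bin(mv, *m_range)
    i0f = np.floor(bf).astype(np.intp)
    i0m = np.floor(bm).astype(np.intp)
    wf = bf - i0f
    wm = bm - i0m
    H = np.zeros((bins, bins))
    for df, wgtf in ((0, 1.0 - wf), (1, wf)):
        for dm, wgtm in ((0, 1.0 - wm), (1, wm)):
            np.add.at(H, (i0f + df, i0m + dm), wgtf * wgtm)
    H /= H.sum()
    px = H.sum(axis=1, keepdims=True)
    py = H.sum(axis=0, keepdims=True)
    nz = H > 0
    return float(np.sum(H[nz] * np.log(H[nz] / (px @ py)[nz])))


def _metric_cost(vec, world, fixed_vals, moving: ImageVolume,
                 moving_smoothed: np.ndarray, center, metric: str) -> float:
    t = params_from_vector(vec, center)
    idx = moving.world_to_index(t.apply(world))
    shape = moving.data.shape
    inside = np.ones(idx.shape[1], dtype=bool)
    for a in range(3):
        inside &= (idx[a] >= 0) & (idx[a] <= shape[a] - 1)
    if inside.sum() < max(30, 0.05 * inside.size):
        return 2.0 + float(np.sum(np.square(vec)))  # drive back toward overlap
    mv = map_coordinates(moving_smoothed, idx[:, inside], order=1,
                         mode="constant", cval=0.0)
    fv = fixed_vals[inside]
    if metric == "mi":
        # mutual information: useful for cross-contrast pairs with rich
        # histograms, but nearly flat when one tissue class dominates, so
        # correlation remains the default
        cost = -_mutual_information(
            fv, mv,
            (float(fixed_vals.min()), float(fixed_vals.max())),
            (float(moving_smoothed.min()), float(moving_smoothed.max())))
    elif metric == "ncc":
        fv_c = fv - fv.mean()
        mv_c = mv - mv.mean()
        denom = np.sqrt((fv_c ** 2).sum() * (mv_c ** 2).sum())
        ncc = float((fv_c * mv_c).sum() / denom) if denom > 0 else 0.0
        cost = -ncc
    elif metric == "mse":
        cost = float(np.mean((fv - mv) ** 2)) / (float(np.var(fixed_vals)) + 1e-12)
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    return cost + _TIE_BREAK * float(np.sum(np.square(vec)))


def register_rigid(moving: ImageVolume, fixed: ImageVolume,
                   levels: int = 3, metric: str = "ncc",
                   initial: RigidTransform | None = None) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    The returned transform ``T`` is defined so that
    ``resample(moving, T, fixed.grid)`` superimposes the two images, i.e.
    ``T`` maps fixed-grid world points into the moving volume's frame.

    Multi-resolution: ``levels`` pyramid levels with subsampling factors
    ``2**(levels-1) ... 1`` and matching Gaussian smoothing; deterministic
    for fixed inputs and settings.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")
    center = tuple(fixed.grid.center())
    vec = np.zeros(6)
    if initial is not None:
        vec = np.array(list(initial.rotation) + list(initial.translation), float)
    vec0 = vec.copy()

    fixed_data = np.asarray(fixed.data, dtype=np.float64)
    moving_data = np.asarray(moving.data, dtype=np.float64)
    factors = [2 ** (levels - 1 - i) for i in range(levels)]

    checked_overlap = False
    for f in factors:
        # Blur-match both images to a common per-axis total blur.  Two
        # effects make an unsmoothed metric drift: interpolation at a
        # generic pose averages white noise faster than signal, and
        # orthogonal thick-slice inputs carry anisotropic acquisition PSFs
        # that reward tilted poses.  Treating each image's PSF as a boxcar
        # of its voxel size (SD = spacing / sqrt(12)) and topping up to a
        # common Gaussian target neutralizes both.
        sigma_target = 3.5 * np.sqrt(f)

        def _matched(data, spacing):
            sig = [np.sqrt(max(sigma_target ** 2 - sp ** 2 / 12.0, 0.25)) / sp
                   for sp in spacing]
            return gaussian_filter(data, sig)

        fx = _matched(fixed_data, fixed.spacing)
        mv = _matched(moving_data, moving.spacing)
        world, fvals = _sample_lattice(fixed, fx, stride=f)

        if not checked_overlap:
            t0 = params_from_vector(vec, center)
            idx = moving.world_to_index(t0.apply(world))
            inside = np.ones(idx.shape[1], dtype=bool)
            for a in range(3):
                inside &= (idx[a] >= 0) & (idx[a] <= moving.data.shape[a] - 1)
            frac = float(inside.mean())
            if frac < 0.05:
                raise RegistrationError(
                    f"volumes do not overlap at initialization "
                    f"(overlap fraction {frac:.3f})")
            checked_overlap = True

        step = 0.25 * f
        direc = np.diag([step, step, step, 2 * step, 2 * step, 2 * step])
        # capture range: inter-scan motion is at most a few mm / degrees;
        # bounding the search also keeps the optimizer out of distant
        # spurious optima (e.g. the ring symmetry of a multi-element
        # phantom, where a one-element rotation realigns the pattern)
        span = np.array([15.0, 15.0, 15.0, 20.0, 20.0, 20.0])
        bounds = list(zip(vec0 - span, vec0 + span))
        res = minimize(_metric_cost, vec,
                       args=(world, fvals, moving, mv, center, metric),
                       method="Powell", bounds=bounds,
                       options={"xtol": 3e-4, "ftol": 1e-8, "maxiter": 30,
                                "direc": direc})
        vec = res.x

    # components below the optimizer's resolution are noise; snapping them
    # keeps exact-identity cases exactly identity
    vec = np.where(np.abs(vec) < 1e-4, 0.0, vec)
    return params_from_vector(vec, center)


# ---------------------------------------------------------------------------
# super-resolution template construction
# ---------------------------------------------------------------------------

def _average(aligned_norm: list[np.ndarray], masks: list[np.ndarray]) -> np.ndarray:
    """Validity-mask-weighted per-voxel mean (equal input weights)."""
    num = np.zeros_like(aligned_norm[0])
    den = np.zeros(aligned_norm[0].shape)
    for a, m in zip(aligned_norm, masks):
        num += np.where(m, a, 0.0)
        den += m
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def build_sr_template(inputs: list[ImageVolume], target_spacing: float = 1.5,
                      n_iterations: int = 3, metric: str = "ncc",
                      levels: int = 3) -> SRResult:
    """Combine anisotropic orthogonal volumes into one isotropic template.

    Iteration 0 trilinearly upsamples every input onto the isotropic
    target grid and averages; subsequent iterations re-register each input
    to the current template and rebuild the average.  Returns the
    template, per-input forward/inverse transforms and the aligned
    (unscaled) inputs with their validity masks.
    """
    if len(inputs) < 2:
        raise ValueError(f"need at least 2 inputs for SR, got {len(inputs)}")
    min_inplane = min(min(v.spacing) for v in inputs)
    if target_spacing > min_inplane + 1e-9:
        raise ValueError(
            f"target spacing {target_spacing} mm coarser than the finest "
            f"input in-plane spacing {min_inplane} mm")

    # isotropic grid over the union of the input fields of view; symmetric
    # in the input order
    lo = [min(v.origin[a] - v.spacing[a] / 2.0 for v in inputs) for a in range(3)]
    hi = [max(v.origin[a] + (v.data.shape[a] - 0.5) * v.spacing[a] for v in inputs)
          for a in range(3)]
    shape = tuple(max(1, int(np.floor((h - l) / target_spacing + 1e-9)))
                  for l, h in zip(lo, hi))
    grid = GridSpec(shape=shape, spacing=(target_spacing,) * 3,
                    origin=tuple(l + target_spacing / 2.0 for l in lo))
    scales = [_foreground_median(np.asarray(v.data)) for v in inputs]
    mean_scale = float(np.mean(scales))

    transforms = [RigidTransform.identity() for _ in inputs]
    aligned: list[ImageVolume] = []
    masks: list[np.ndarray] = []
    for v, t in zip(inputs, transforms):
        a, m = resample(v, t, grid, interpolation="trilinear")
        aligned.append(a)
        masks.append(m)
    template = _average([a.data / s for a, s in zip(aligned, scales)], masks)

    for it in range(n_iterations):
        new_transforms = []
        for i, v in enumerate(inputs):
            if it == 0:
                # first pass: leave-one-out target.  The template contains
                # each input's own copy, which would lock a badly-moved
                # input onto its own ghost; a ghost-free target recovers
                # large motions first (and is symmetric in input order).
                others = [a.data / s for j, (a, s)
                          in enumerate(zip(aligned, scales)) if j != i]
                other_masks = [m for j, m in enumerate(masks) if j != i]
                target = ImageVolume(
                    data=_average(others, other_masks) * mean_scale,
                    spacing=grid.spacing, origin=grid.origin)
            else:
                # later passes: full template; the input's own (now nearly
                # correctly placed) copy stabilizes against collective drift
                target = ImageVolume(data=template * mean_scale,
                                     spacing=grid.spacing, origin=grid.origin)
            try:
                t = register_rigid(v, target, levels=levels, metric=metric,
                                   initial=transforms[i])
            except RegistrationError as exc:
                raise RegistrationError(f"input {i}: {exc}") from exc
            new_transforms.append(t)
        transforms = new_transforms
        aligned, masks = [], []
        for v, t in zip(inputs, transforms):
            a, m = resample(v, t, grid, interpolation="trilinear")
            aligned.append(a)
            masks.append(m)
        template = _average([a.data / s for a, s in zip(aligned, scales)], masks)

    # re-center the template frame on the consensus pose: subtracting the
    # componentwise median transform pins the frame to the majority of
    # inputs (robust to a single badly-moved acquisition) and keeps the
    # result independent of input order
    med = RigidTransform(
        rotation=tuple(np.median([t.rotation[k] for t in transforms])
                       for k in range(3)),
        translation=tuple(np.median([t.translation[k] for t in transforms])
                          for k in range(3)),
        center=transforms[0].center)
    if med.magnitude > 1e-6:
        transforms = [t.compose(med.inverse()) for t in transforms]
        aligned, masks = [], []
        for v, t in zip(inputs, transforms):
            a, m = resample(v, t, grid, interpolation="trilinear")
            aligned.append(a)
            masks.append(m)
        template = _average([a.data / s for a, s in zip(aligned, scales)], masks)

    pairs = [TransformPair(to_template=t.inverse(), from_template=t)
             for t in transforms]
    template_vol = ImageVolume(data=template * mean_scale,
                               spacing=grid.spacing, origin=grid.origin)
    return SRResult(template=template_vol, transforms=pairs,
                    aligned_inputs=aligned, validity_masks=masks)
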