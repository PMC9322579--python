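"""Agreement and map-quality metrics.

* :func:`icc_agreement` - intraclass correlation in the two-way,
  absolute-agreement, single-measures form ICC(A,1), the variant that
  asks "do the two methods produce the *same numbers*", not merely
  correlated ones.  With items i = 1..n and k = 2 methods,

      ICC(A,1) = (MS_R - MS_E) /
                 (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

  where MS_R, MS_C and MS_E are the rows (items), columns (methods) and
  residual mean squares of the two-way ANOVA.

* :func:`t2_to_noise` - ROI mean / ROI SD of a T2 map, a map-quality
  index.

* :func:`roi_statistics` / :func:`recovery_stats` - per-ROI summaries and
  ground-truth recovery errors for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import T2FitResult
from .phantoms import GroundTruthPhantom
from .volumes import ImageVolume

#: Sentinel reported when the ROI SD is exactly zero (constant map).
T2NR_CAP = 1e6


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation with the ANOVA pieces behind it."""

    value: float
    n: int
    ms_items: float     # between-item (rows) mean square
    ms_methods: float   # between-method (columns) mean square
    ms_error: float     # residual mean square
    form: str = "ICC(A,1)"


def icc_agreement(method_a: Sequence[float], method_b: Sequence[float]
                  ) -> ICCResult:
    """ICC(A,1) between two paired measurement sets."""
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired 1D arrays required, got {a.shape} vs {b.shape}")
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 paired items, got {n}")
    k = 2
    X = np.stack([a, b], axis=1)
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    value = float((ms_r - ms_e) / denom) if denom != 0 else 1.0
    return ICCResult(value=value, n=n, ms_items=float(ms_r),
                     ms_methods=float(ms_c), ms_error=float(ms_e))


def t2_to_noise(t2_map: ImageVolume, roi_mask: np.ndarray | ImageVolume) -> float:
    """ROI mean / ROI sample SD of T2; capped sentinel for a constant ROI."""
    mask = roi_mask.data if isinstance(roi_mask, ImageVolume) else roi_mask
    mask = np.asarray(mask).astype(bool)
    vals = np.asarray(t2_map.data)[mask]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    if vals.size < 2:
        return T2NR_CAP
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        return T2NR_CAP
    return float(np.mean(vals)) / sd


# ---------------------------------------------------------------------------
# ROI tables
# ---------------------------------------------------------------------------

def _axis_overlap_weights(fine_coords: np.ndarray, fine_spacing: float,
                          target_coords: np.ndarray, width: float) -> np.ndarray:
    """(n_target, n_fine) row-normalized overlap of target windows with fine cells.

    Each target sample owns a window of ``width`` mm centered on it; the
    row gives the fraction of that window covered by each fine cell.
    """
    t_lo = target_coords[:, None] - width / 2.0
    t_hi = target_coords[:, None] + width / 2.0
    f_lo = fine_coords[None, :] - fine_spacing / 2.0
    f_hi = fine_coords[None, :] + fine_spacing / 2.0
    ov = np.clip(np.minimum(t_hi, f_hi) - np.maximum(t_lo, f_lo), 0.0, None)
    return ov / width


def resample_labels(phantom: GroundTruthPhantom, target_vol: ImageVolume,
                    footprint_mm: float | None = None,
                    purity: float = 0.99) -> np.ndarray:
    """Interior-only ROI labels on another volume's grid.

    A target voxel receives a label only when the surrounding window -
    its own cell, or the acquisition footprint ``footprint_mm`` when
    given - lies (almost) entirely inside that ROI's pure core.  This
    emulates drawing ROIs on structure interiors and keeps thick-slice
    partial-volume voxels, whose signal mixes neighboring tissues, out of
    the ROI means.
    """
    src = phantom.labels
    tgt = target_vol.grid
    fine = src.grid
    Ws = []
    for a in range(3):
        width = max(tgt.spacing[a], footprint_mm or 0.0)
        fc = fine.origin[a] + fine.spacing[a] * np.arange(fine.shape[a])
        tc = tgt.origin[a] + tgt.spacing[a] * np.arange(tgt.shape[a])
        Ws.append(_axis_overlap_weights(fc, fine.spacing[a], tc, width))

    lab_src = np.round(np.asarray(src.data)).astype(int)
    out = np.zeros(tgt.shape, dtype=int)
    for code in sorted(phantom.roi_table):
        ind = (lab_src == code).astype(np.float64)
        frac = np.tensordot(Ws[0], ind, axes=(1, 0))
        frac = np.moveaxis(np.tensordot(Ws[1], np.moveaxis(frac, 1, 0),
                                        axes=(1, 0)), 0, 1)
        frac = np.moveaxis(np.tensordot(Ws[2], np.moveaxis(frac, 2, 0),
                                        axes=(1, 0)), 0, 2)
        out[frac >= purity] = code
    return out


def roi_statistics(fit: T2FitResult, labels: np.ndarray,
                   roi_table, targets_only: bool = True) -> pd.DataFrame:
    """Per-ROI voxel count, mean T2 and sample SD from a fit result.

    Only voxels inside the fit mask contribute; ROIs that end up empty are
    kept as rows with ``n_voxels = 0`` and NaN statistics so a missing
    region is visible rather than silently dropped.
    """
    t2 = np.asarray(fit.t2_map.data)
    fitted = np.asarray(fit.mask.data) > 0
    rows = []
    for code, roi in sorted(roi_table.items()):
        if targets_only and not roi.is_target:
            continue
        sel = (labels == code) & fitted
        vals = t2[sel]
        rows.append({
            "code": code,
            "name": roi.name,
            "true_t2_ms": roi.t2_ms,
            "n_voxels": int(vals.size),
            "mean_t2_ms": float(np.mean(vals)) if vals.size else np.nan,
            "sd_t2_ms": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def recovery_stats(estimated: T2FitResult, truth: GroundTruthPhantom,
                   footprint_mm: float | None = None) -> pd.DataFrame:
    """Per-ROI bias (ms and %), RMSE and SD of estimated vs true T2.

    ROIs absent from the estimate's fit mask are flagged (``missing``
    column), not dropped.
    """
    labels = resample_labels(truth, estimated.t2_map, footprint_mm=footprint_mm)
    t2 = np.asarray(estimated.t2_map.data)
    fitted = np.asarray(estimated.mask.data) > 0
    rows = []
    for code, roi in sorted(truth.target_rois().items()):
        sel = (labels == code) & fitted
        vals = t2[sel]
        true = roi.t2_ms
        if vals.size:
            bias = float(np.mean(vals) - true)
            rows.append({"code": code, "name": roi.name, "true_t2_ms": true,
                         "n_voxels": int(vals.size), "bias_ms": bias,
                         "bias_pct": 100.0 * bias / true,
                         "rmse_ms": float(np.sqrt(np.mean((vals - true) ** 2))),
                         "sd_ms": float(np.std(vals, ddof=1)) if vals.size > 1
                         else 0.0,
                         "missing": False})
        else:
            rows.append({"code": code, "name": roi.name, "true_t2_ms": true,
                         "n_voxels": 0, "bias_ms": np.nan, "bias_pct": np.nan,
                         "rmse_ms": np.nan, "sd_ms": np.nan, "missing": True})
    return pd.DataFrame(rows)
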