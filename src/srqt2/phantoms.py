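"""Digital ground-truth phantoms with known M0, T2 and ROI labels.

Two families are provided:

* a multi-element relaxometry phantom: spherical elements with assigned T2
  values laid out on a ring inside a uniform cylindrical body, in the
  spirit of the NIST/CaliberMRI system phantoms used to validate
  quantitative MRI;
* a brain-like phantom: an ellipsoidal head with six named white-matter
  ROIs (default T2 values in the 98-118 ms range typical of adult white
  matter), a cortical shell at 130 ms and long-T2 ventricle blobs at
  1500 ms to stress the mono-exponential fit.

Structure boundaries carry a one-voxel partial-volume ramp in M0/T2 so the
thick-slice forward model sees realistic mixed voxels, while the integer
label maps mark only pure-core voxels: inside a labeled voxel the true T2
is exactly the assigned value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .volumes import GridSpec, ImageVolume, read_nifti, write_nifti

DEFAULT_M0 = 1000.0  # arbitrary units, uniform inside the body/head

#: Default white-matter ROI T2 values (ms) for the brain phantom.
DEFAULT_BRAIN_ROI_T2 = {
    "cerebellar_wm": 110.0,
    "corpus_callosum": 112.0,
    "left_frontal_wm": 114.0,
    "right_frontal_wm": 118.0,
    "left_posterior_wm": 98.0,
    "right_posterior_wm": 102.0,
}

TISSUE_T2 = 130.0      # cortical/background tissue shellward of the ROIs
VENTRICLE_T2 = 1500.0  # long-T2 CSF-like compartment
BODY_T2 = 1500.0       # filler liquid of the multi-element phantom

T2_MAX_VALID = 3000.0  # physical sanity bound on any labeled tissue


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the grid."""


class RoiInfo(NamedTuple):
    name: str
    t2_ms: float
    m0: float
    is_target: bool = True  # counted in agreement/recovery statistics


@dataclass
class GroundTruthPhantom:
    """Co-registered M0 map, T2 map (ms) and integer ROI label map."""

    m0: ImageVolume
    t2: ImageVolume
    labels: ImageVolume
    roi_table: dict[int, RoiInfo]

    def __post_init__(self) -> None:
        if not (self.m0.data.shape == self.t2.data.shape == self.labels.data.shape):
            raise ValueError("m0, t2 and labels must share one grid")
        codes = np.unique(self.labels.data[self.labels.data > 0])
        missing = [int(c) for c in codes if int(c) not in self.roi_table]
        if missing:
            raise ValueError(f"label codes missing from roi_table: {missing}")

    @property
    def grid(self) -> GridSpec:
        return self.m0.grid

    def target_rois(self) -> dict[int, RoiInfo]:
        """ROIs that enter agreement and recovery statistics."""
        return {c: r for c, r in self.roi_table.items() if r.is_target}

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_nifti(self.m0, d / "m0.nii.gz")
        write_nifti(self.t2, d / "t2.nii.gz")
        write_nifti(self.labels, d / "labels.nii.gz")
        table = {str(code): {"name": r.name, "t2_ms": r.t2_ms, "m0": r.m0,
                             "is_target": r.is_target}
                 for code, r in self.roi_table.items()}
        (d / "roi_table.json").write_text(json.dumps(table, indent=2))

    @classmethod
    def load(cls, directory) -> "GroundTruthPhantom":
        d = Path(directory)
        table = json.loads((d / "roi_table.json").read_text())
        roi_table = {int(code): RoiInfo(v["name"], float(v["t2_ms"]),
                                        float(v["m0"]), bool(v["is_target"]))
                     for code, v in table.items()}
        return cls(m0=read_nifti(d / "m0.nii.gz"),
                   t2=read_nifti(d / "t2.nii.gz"),
                   labels=read_nifti(d / "labels.nii.gz"),
                   roi_table=roi_table)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _world_grids(grid: GridSpec):
    xs, ys, zs = grid.world_coordinates()
    return np.meshgrid(xs, ys, zs, indexing="ij")


def _ellipsoid_alpha(grid_xyz, center, semiaxes, ramp_mm: float) -> np.ndarray:
    """Inside-fraction in [0, 1] with a linear ramp of width ``ramp_mm``."""
    X, Y, Z = grid_xyz
    cx, cy, cz = center
    ax, ay, az = semiaxes
    rho = np.sqrt(((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2)
    # approximate signed distance to the surface, scaled by the smallest axis
    dist = (rho - 1.0) * min(semiaxes)
    return np.clip(0.5 - dist / ramp_mm, 0.0, 1.0)


def _cylinder_alpha(grid_xyz, center, radius, half_height, ramp_mm: float) -> np.ndarray:
    X, Y, Z = grid_xyz
    cx, cy, cz = center
    r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    a_r = np.clip(0.5 - (r - radius) / ramp_mm, 0.0, 1.0)
    a_z = np.clip(0.5 - (np.abs(Z - cz) - half_height) / ramp_mm, 0.0, 1.0)
    return a_r * a_z


class _Painter:
    """Accumulates structures onto m0/t2/label arrays with alpha blending."""

    CORE = 0.999  # inside-fraction above which a voxel is a pure-core label

    def __init__(self, grid: GridSpec):
        self.grid = grid
        self.xyz = _world_grids(grid)
        self.ramp = float(max(grid.spacing))  # 1-voxel partial-volume ramp
        self.t2 = np.zeros(grid.shape, dtype=np.float64)
        self.m0 = np.zeros(grid.shape, dtype=np.float64)
        self.labels = np.zeros(grid.shape, dtype=np.int16)
        self.roi_table: dict[int, RoiInfo] = {}

    def paint(self, alpha: np.ndarray, t2: float, m0: float,
              code: int | None = None, name: str = "", is_target: bool = True) -> None:
        if t2 <= 0:
            raise ValueError(f"ROI T2 must be positive, got {t2} for {name!r}")
        core = alpha >= self.CORE
        self.t2 = (1.0 - alpha) * self.t2 + alpha * t2
        self.m0 = (1.0 - alpha) * self.m0 + alpha * m0
        # exact values in pure-core voxels (no float blending residue)
        self.t2[core] = t2
        self.m0[core] = m0
        # partial-volume ramp voxels belong to no label
        self.labels[(alpha > 1.0 - self.CORE) & ~core] = 0
        if code is not None:
            self.labels[core] = code
            self.roi_table[code] = RoiInfo(name=name, t2_ms=float(t2),
                                           m0=float(m0), is_target=is_target)

    def finish(self) -> GroundTruthPhantom:
        g = self.grid
        mk = lambda a: ImageVolume(data=a, spacing=g.spacing, origin=g.origin)
        return GroundTruthPhantom(m0=mk(self.m0), t2=mk(self.t2),
                                  labels=mk(self.labels.astype(np.float32)),
                                  roi_table=self.roi_table)


# ---------------------------------------------------------------------------
# multi-element relaxometry phantom
# ---------------------------------------------------------------------------

def make_nist_like_phantom(grid: GridSpec,
                           t2_values: Sequence[float] | None = None,
                           element_radius: float = 9.0,
                           seed: int = 0) -> GroundTruthPhantom:
    """Spherical T2 elements on a ring inside a uniform cylindrical body.

    Parameters
    ----------
    grid : GridSpec
        Isotropic (or near-isotropic) ground-truth grid.
    t2_values : sequence of float, optional
        One T2 (ms) per element; default 10 values log-spaced 40-300 ms,
        a plausible span for a relaxometry phantom at these field strengths.
    element_radius : float
        Sphere radius in mm.
    seed : int
        Rotates the ring by a random phase so instances differ; geometry is
        otherwise deterministic.
    """
    if t2_values is None:
        t2_values = np.geomspace(40.0, 300.0, 10)
    t2_values = [float(v) for v in t2_values]
    n = len(t2_values)
    if n < 2:
        raise GeometryError(f"need at least 2 elements, got {n}")
    if any(v <= 0 for v in t2_values):
        raise ValueError(f"element T2 values must be positive: {t2_values}")

    p = _Painter(grid)
    ext = grid.extent
    center = grid.center()
    body_radius = 0.42 * min(ext[0], ext[1])
    half_height = 0.375 * ext[2]
    ring_radius = 0.6 * body_radius

    ramp = p.ramp
    min_gap = 2.0 * element_radius + 2.0 * ramp
    chord = 2.0 * ring_radius * np.sin(np.pi / n)
    if chord < min_gap or ring_radius + element_radius + ramp > body_radius:
        need = max(min_gap / (2.0 * np.sin(np.pi / n)) / 0.6,
                   (element_radius + ramp) / 0.42) * 2.0 / 0.42
        raise GeometryError(
            f"{n} elements of radius {element_radius} mm do not fit: "
            f"grid extent {ext} mm, need about {need:.0f} mm in-plane")
    if element_radius < max(grid.spacing):
        raise GeometryError(
            f"element radius {element_radius} mm below voxel size {max(grid.spacing)} mm")

    p.paint(_cylinder_alpha(p.xyz, center, body_radius, half_height, ramp),
            t2=BODY_T2, m0=DEFAULT_M0, code=100, name="body", is_target=False)

    phase = float(np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi))
    for i, t2 in enumerate(t2_values):
        ang = phase + 2.0 * np.pi * i / n
        c = (center[0] + ring_radius * np.cos(ang),
             center[1] + ring_radius * np.sin(ang),
             center[2])
        r = element_radius
        p.paint(_ellipsoid_alpha(p.xyz, c, (r, r, r), ramp),
                t2=t2, m0=DEFAULT_M0, code=i + 1,
                name=f"element_{i + 1:02d}")
    return p.finish()


# ---------------------------------------------------------------------------
# brain-like phantom
# ---------------------------------------------------------------------------

# ROI centers (mm, relative to head center) and semi-axes (mm); coarse
# anatomical placement only - the phantom is a fitting testbed, not an atlas.
_BRAIN_ROI_GEOMETRY = {
    "cerebellar_wm": ((0.0, -34.0, -26.0), (13.0, 11.0, 10.0)),
    # stylized: thicker than the anatomical structure so interior voxels
    # survive 5 mm slabs on every acquisition grid
    "corpus_callosum": ((0.0, 4.0, 16.0), (10.0, 18.0, 9.0)),
    "left_frontal_wm": ((-20.0, 36.0, 8.0), (11.0, 11.0, 10.0)),
    "right_frontal_wm": ((20.0, 36.0, 8.0), (11.0, 11.0, 10.0)),
    "left_posterior_wm": ((-22.0, -32.0, 10.0), (11.0, 11.0, 10.0)),
    "right_posterior_wm": ((22.0, -32.0, 10.0), (11.0, 11.0, 10.0)),
}

_HEAD_SEMIAXES = (58.0, 68.0, 56.0)
_VENTRICLES = (((-9.0, 4.0, 10.0), (6.0, 16.0, 8.0)),
               ((9.0, 4.0, 10.0), (6.0, 16.0, 8.0)))


def make_brain_phantom(grid: GridSpec,
                       roi_t2: Mapping[str, float] | None = None,
                       seed: int = 0) -> GroundTruthPhantom:
    """Ellipsoidal head with six named white-matter ROIs.

    The per-seed random jitter (ROI centers +/- 1.5 mm, head axes +/- 2%)
    emulates between-subject anatomical variability while keeping the true
    T2 values fixed, so several seeds play the role of several subjects.

    Parameters
    ----------
    roi_t2 : mapping, optional
        ROI name -> true T2 (ms); defaults to :data:`DEFAULT_BRAIN_ROI_T2`.
    """
    roi_t2 = dict(DEFAULT_BRAIN_ROI_T2 if roi_t2 is None else roi_t2)
    if not roi_t2:
        raise ValueError("roi_t2 must be non-empty")
    unknown = set(roi_t2) - set(_BRAIN_ROI_GEOMETRY)
    if unknown:
        raise ValueError(f"unknown ROI names: {sorted(unknown)}")
    for name, v in roi_t2.items():
        if v <= 0:
            raise ValueError(f"ROI T2 must be positive, got {v} for {name!r}")

    rng = np.random.default_rng(seed)
    head = tuple(a * rng.uniform(0.98, 1.02) for a in _HEAD_SEMIAXES)
    center = grid.center()

    p = _Painter(grid)
    ramp = p.ramp
    p.paint(_ellipsoid_alpha(p.xyz, center, head, ramp),
            t2=TISSUE_T2, m0=DEFAULT_M0, code=7, name="tissue", is_target=False)
    for c, ax in _VENTRICLES:
        jit = rng.uniform(-1.0, 1.0, size=3)
        p.paint(_ellipsoid_alpha(p.xyz, center + np.asarray(c) + jit, ax, ramp),
                t2=VENTRICLE_T2, m0=DEFAULT_M0, code=8, name="ventricles",
                is_target=False)
    for code, (name, (c, ax)) in enumerate(_BRAIN_ROI_GEOMETRY.items(), start=1):
        if name not in roi_t2:
            continue
        jit = rng.uniform(-1.5, 1.5, size=3)
        p.paint(_ellipsoid_alpha(p.xyz, center + np.asarray(c) + jit, ax, ramp),
                t2=float(roi_t2[name]), m0=DEFAULT_M0, code=code, name=name)
    return p.finish()
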