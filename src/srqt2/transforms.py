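"""Rigid world-space transforms.

A :class:`RigidTransform` maps world coordinates (mm, RAS) to world
coordinates: ``p' = R (p - c) + c + t`` where ``R`` is a rotation given by
intrinsic Z-Y-X Euler angles, ``c`` the rotation center and ``t`` a
translation.  Transforms are used both to model subject motion in the
acquisition simulator and as the output of rigid registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Rigid (6 degree-of-freedom) world transform.

    Parameters
    ----------
    rotation : tuple of float
        Euler angles ``(rz, ry, rx)`` in degrees, applied in intrinsic
        Z-Y-X order, i.e. ``R = Rz(rz) @ Ry(ry) @ Rx(rx)``.
    translation : tuple of float
        Translation in mm per world axis.
    center : tuple of float
        Rotation center in world mm.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    # -- construction ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray,
                    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
                    ) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (world mm)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {matrix.shape}")
        R = matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("matrix is not a rigid transform (R R^T != I)")
        rz, ry, rx = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
        c = np.asarray(center, dtype=float)
        # matrix = [R | Rc' ... ] solve t from  p' = R p + m  with m = -R c + c + t
        t = matrix[:3, 3] - (c - R @ c)
        return cls(rotation=(float(rz), float(ry), float(rx)),
                   translation=tuple(float(v) for v in t),
                   center=tuple(float(v) for v in c))

    # -- core algebra ------------------------------------------------------
    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.rotation, degrees=True).as_matrix()

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix equivalent to this transform."""
        R = self.rotation_matrix
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c - R @ c + t
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to points of shape (..., 3) or (3, N)."""
        pts = np.asarray(points, dtype=float)
        R = self.rotation_matrix
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if pts.ndim == 2 and pts.shape[0] == 3 and pts.shape[1] != 3:
            return R @ (pts - c[:, None]) + (c + t)[:, None]
        return (pts - c) @ R.T + (c + t)

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one (same rotation center)."""
        R = self.rotation_matrix
        t = np.asarray(self.translation, dtype=float)
        rz, ry, rx = Rotation.from_matrix(R.T).as_euler("ZYX", degrees=True)
        t_inv = -(R.T @ t)
        return RigidTransform(rotation=(float(rz), float(ry), float(rx)),
                              translation=tuple(float(v) for v in t_inv),
                              center=self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        m = self.as_matrix() @ other.as_matrix()
        return RigidTransform.from_matrix(m, center=self.center)

    # -- utilities ---------------------------------------------------------
    @property
    def magnitude(self) -> float:
        """Scalar size used for tie-breaking: deg and mm summed in quadrature."""
        return float(np.sqrt(np.sum(np.square(self.rotation))
                             + np.sum(np.square(self.translation))))

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.as_matrix(), np.eye(4), atol=atol))

    def save(self, path) -> None:
        """Serialize as a plain-text 4x4 homogeneous matrix (world mm, RAS)."""
        np.savetxt(path, self.as_matrix(), fmt="%.12g",
                   header="rigid world transform, 4x4 homogeneous, mm RAS")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.loadtxt(path))


def params_from_vector(vec: np.ndarray,
                       center: tuple[float, float, float]) -> RigidTransform:
    """Build a transform from an optimizer vector (rz, ry, rx, tx, ty, tz)."""
    v = np.asarray(vec, dtype=float)
    return RigidTransform(rotation=(v[0], v[1], v[2]),
                          translation=(v[3], v[4], v[5]),
                          center=center)
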