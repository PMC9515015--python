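"""Rigid-body (SE(3)) transform algebra for motion-corrected brain PET.

Head motion in any coordinate frame is a 4x4 homogeneous rigid transform

    T = | R  s |        R : 3x3 rotation (r11 ... r33),
        | 0  1 |        s : translation (s_x, s_y, s_z) in mm.

A depth camera observes the head's motion ``M_K`` in its own coordinate
frame.  The camera-to-scanner calibration ``C_KP`` maps *scanner-frame*
point coordinates into *camera-frame* coordinates (p_cam = C_KP p_pet).
The per-frame correction applied to event coordinates in the scanner
frame is the conjugated inverse motion

    M_P = C_KP^-1  M_K^-1  C_KP

which maps the coordinates of a coincidence detected while the head was
at the moved pose back to the reference pose.  The direction convention
for ``C_KP`` matters: with the convention above and the forward
camera-frame motion M_K = C_KP T C_KP^-1 of a scanner-frame motion T,
the sandwich collapses to exactly T^-1.  This module fixes that
convention package-wide.

Euler angles at the interface are intrinsic Z-Y-X in degrees
(T = Trans(t) Rz(rz) Ry(ry) Rx(rx)); radians are used internally.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "PoseParameters",
    "InvalidTransformError",
    "DegeneratePoseError",
    "compose",
    "invert",
    "to_pet_frame",
    "pose_to_transform",
    "transform_to_pose",
    "motion_magnitude",
    "translation",
    "rotation_x",
    "rotation_y",
    "rotation_z",
    "random_transform",
]

_ORTHO_TOL = 1e-9       # drift beyond this triggers SVD re-orthonormalization
_REJECT_TOL = 1e-6      # drift beyond this is a hard error (not a rigid matrix)
GIMBAL_LOCK_DEG = 89.0  # |ry| at/above this: Euler decomposition refused


class InvalidTransformError(ValueError):
    """A matrix that is not (numerically) a rigid-body transform."""


class DegeneratePoseError(ValueError):
    """Euler decomposition requested in the gimbal-lock region."""


def _orthonormality_drift(R: np.ndarray) -> float:
    return float(
        max(np.abs(R.T @ R - np.eye(3)).max(), abs(np.linalg.det(R) - 1.0))
    )


def _project_rotation(R: np.ndarray) -> np.ndarray:
    """Nearest rotation in Frobenius norm (SVD projection, det forced +1)."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid-body transform.

    Construct through :meth:`from_matrix` (validating) or the factory
    helpers (:func:`translation`, :func:`rotation_z`, ...).  Instances
    are immutable; ``A @ B`` composes (B applied first).
    """

    matrix: np.ndarray

    # -- construction -------------------------------------------------

    @classmethod
    def from_matrix(cls, matrix: np.ndarray | Sequence) -> "RigidTransform":
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {M.shape}")
        if not np.all(np.isfinite(M)):
            raise InvalidTransformError("non-finite entries in transform")
        if np.abs(M[3] - np.array([0.0, 0.0, 0.0, 1.0])).max() > 1e-9:
            raise InvalidTransformError(f"bottom row must be (0,0,0,1), got {M[3]}")
        R = M[:3, :3]
        drift = _orthonormality_drift(R)
        if drift > _REJECT_TOL:
            raise InvalidTransformError(
                f"rotation block is not orthonormal (drift {drift:.3e})"
            )
        out = np.eye(4)
        out[:3, :3] = _project_rotation(R) if drift > _ORTHO_TOL else R
        out[:3, 3] = M[:3, 3]
        out.flags.writeable = False
        return cls(out)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls.from_matrix(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, R: np.ndarray, t: Iterable[float]
    ) -> "RigidTransform":
        M = np.eye(4)
        M[:3, :3] = np.asarray(R, dtype=float)
        M[:3, 3] = np.asarray(list(t), dtype=float)
        return cls.from_matrix(M)

    # -- accessors -----------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra -------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    # -- serialization -------------------------------------------------

    def to_flat12(self) -> np.ndarray:
        """r11..r33 (row-major) then s_x, s_y, s_z — the CSV dialect."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_flat12(cls, values: Sequence[float]) -> "RigidTransform":
        v = np.asarray(values, dtype=float)
        if v.shape != (12,):
            raise InvalidTransformError(f"expected 12 values, got {v.shape}")
        return cls.from_rotation_translation(v[:9].reshape(3, 3), v[9:])

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(json.loads(text)["matrix"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        t, r = motion_magnitude(self)
        return f"RigidTransform(|s|={t:.3f} mm, |rot|={r:.3f} deg)"


@dataclasses.dataclass(frozen=True)
class PoseParameters:
    """6-DOF pose: translations in mm, intrinsic Z-Y-X Euler angles in degrees."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "PoseParameters":
        v = np.asarray(v, dtype=float)
        return cls(*v.tolist())


# ---------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------

def compose(A: RigidTransform, B: RigidTransform) -> RigidTransform:
    """A after B: (A ∘ B)(p) = A(B(p))."""
    M = A.matrix @ B.matrix
    return RigidTransform.from_matrix(M)


def invert(T: RigidTransform) -> RigidTransform:
    """Closed-form inverse: R^T block, -R^T s translation."""
    R = T.rotation
    return RigidTransform.from_rotation_translation(R.T, -R.T @ T.translation)


def to_pet_frame(motion_K: RigidTransform, calib_C_KP: RigidTransform) -> RigidTransform:
    """Convert camera-frame head motion into the scanner-frame event correction.

    Returns C_KP^-1 · M_K^-1 · C_KP: the transform that maps the PET-frame
    coordinates of an event detected at the moved head pose back to the
    reference pose (see module docstring for the direction convention).
    """
    return compose(compose(invert(calib_C_KP), invert(motion_K)), calib_C_KP)


def pose_to_transform(p: PoseParameters) -> RigidTransform:
    """T = Trans(t) · Rz(rz) · Ry(ry) · Rx(rx), angles in degrees."""
    R = Rotation.from_euler("ZYX", [p.rz, p.ry, p.rx], degrees=True).as_matrix()
    return RigidTransform.from_rotation_translation(R, (p.tx, p.ty, p.tz))


def transform_to_pose(T: RigidTransform) -> PoseParameters:
    """Inverse of :func:`pose_to_transform`; refuses the gimbal-lock region."""
    rz, ry, rx = Rotation.from_matrix(T.rotation).as_euler("ZYX", degrees=True)
    if abs(ry) >= GIMBAL_LOCK_DEG:
        raise DegeneratePoseError(
            f"|ry| = {abs(ry):.2f} deg is in the gimbal-lock region (>= "
            f"{GIMBAL_LOCK_DEG} deg); Euler decomposition is ill-conditioned"
        )

    def _wrap(a: float) -> float:
        # report angles in (-180, 180]
        return 180.0 if np.isclose(a, -180.0) else float(a)

    t = T.translation
    return PoseParameters(t[0], t[1], t[2], _wrap(rx), _wrap(ry), _wrap(rz))


def motion_magnitude(T: RigidTransform) -> tuple[float, float]:
    """Scalar motion summaries: (|s| in mm, axis-angle rotation in degrees)."""
    trans = float(np.linalg.norm(T.translation))
    rot = float(np.degrees(np.linalg.norm(Rotation.from_matrix(T.rotation).as_rotvec())))
    return trans, rot


# ---------------------------------------------------------------------
# factories
# ---------------------------------------------------------------------

def translation(tx: float, ty: float, tz: float) -> RigidTransform:
    return RigidTransform.from_rotation_translation(np.eye(3), (tx, ty, tz))


def _single_axis(axis: str, angle_deg: float) -> RigidTransform:
    R = Rotation.from_euler(axis, angle_deg, degrees=True).as_matrix()
    return RigidTransform.from_rotation_translation(R, (0.0, 0.0, 0.0))


def rotation_x(angle_deg: float) -> RigidTransform:
    return _single_axis("x", angle_deg)


def rotation_y(angle_deg: float) -> RigidTransform:
    return _single_axis("y", angle_deg)


def rotation_z(angle_deg: float) -> RigidTransform:
    return _single_axis("z", angle_deg)


def random_transform(
    rng: np.random.Generator,
    max_translation_mm: float = 50.0,
    max_rotation_deg: float = 40.0,
) -> RigidTransform:
    """Uniformly random rigid transform, useful for property tests."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_rotation_deg, max_rotation_deg))
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_rotation_translation(R, t)
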