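"""ICP surface registration, sequential face tracking, and camera/scanner calibration.

The tracker follows the eyes+nose patch of the face: a reference 3D
face-shape model is cut from the first depth frame's ROI, and every later
frame is registered to it by point-to-point ICP (nearest-neighbour pairing,
3x-median outlier rejection, closed-form SVD/Kabsch update).  Each frame's
ICP is initialized from the previous frame's estimate ("pre-alignment"),
which keeps the nearest-neighbour pairing sane across large cumulative
motion.

Calibration: the camera-side face model (reference frame's ROI) and the
CT-side face model (skin isosurface, already in scanner coordinates) image
the same physical surface, so ICP between them yields the rigid transform
unifying the two coordinate systems, C_KP (scanner -> camera convention;
see :mod:`facemoco.transforms`).
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .camera import DepthFrame, FaceRoi, select_face_roi
from .transforms import RigidTransform, invert, motion_magnitude

__all__ = [
    "SurfaceModel",
    "IcpResult",
    "TrackingResult",
    "DegenerateRegistrationError",
    "TrackingLossError",
    "CalibrationError",
    "procrustes_rigid",
    "icp_register",
    "track_sequence",
    "compute_calibration",
]


class DegenerateRegistrationError(ValueError):
    """Point geometry too flat/thin for a unique rigid registration."""


class TrackingLossError(RuntimeError):
    """Three consecutive frames failed to register."""


class CalibrationError(RuntimeError):
    """Camera/scanner calibration did not reach an acceptable residual."""


@dataclasses.dataclass
class SurfaceModel:
    """A 3D face-shape model: a tagged point set."""

    points: np.ndarray
    source: Literal["camera", "ct"] = "camera"
    frame: Literal["camera", "pet"] = "camera"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 30:
            raise ValueError(f"surface model needs >= 30 points, got {len(self.points)}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates in surface model")

    def transformed(self, T: RigidTransform) -> "SurfaceModel":
        return SurfaceModel(T.apply(self.points), self.source, self.frame)


@dataclasses.dataclass
class IcpResult:
    transform: RigidTransform
    rms_mm: float
    n_iterations: int
    converged: bool
    inlier_fraction: float
    rms_history: np.ndarray


def procrustes_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping paired points
    ``source`` onto ``target`` (Kabsch: SVD of the cross-covariance, with
    the determinant correction against reflections)."""
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2:
        raise ValueError("paired point sets must have identical (N, 3) shapes")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    H = (src - mu_s).T @ (tgt - mu_t)
    U, S, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform.from_rotation_translation(R, t)


def _effective_rank(points: np.ndarray, rel_tol: float = 1e-9) -> int:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return int(np.sum(s > rel_tol * max(s[0], 1e-300)))


def icp_register(
    source: SurfaceModel | np.ndarray,
    target: SurfaceModel | np.ndarray,
    init: RigidTransform | None = None,
    max_iterations: int = 50,
    tol_mm: float = 1e-6,
    outlier_scale: float = 3.0,
    target_tree: cKDTree | None = None,
) -> IcpResult:
    """Point-to-point ICP: best rigid transform mapping ``source`` into ``target``.

    Each iteration pairs every (transformed) source point with its nearest
    target neighbour, discards pairs farther than ``outlier_scale`` times the
    median pair distance, and solves the closed-form Kabsch update on the
    surviving pairs.  Stops when the pairing RMS improves by less than
    ``tol_mm`` or after ``max_iterations``.
    """
    src = source.points if isinstance(source, SurfaceModel) else np.asarray(source, float)
    tgt = target.points if isinstance(target, SurfaceModel) else np.asarray(target, float)
    if len(src) < 3 or len(tgt) < 3:
        raise DegenerateRegistrationError("need at least 3 points on each side")
    if _effective_rank(src) < 3:
        raise DegenerateRegistrationError(
            "source points are collinear/coplanar (rank < 3): rotation about "
            "the degenerate axis is unobservable"
        )
    tree = target_tree if target_tree is not None else cKDTree(tgt)
    T = RigidTransform.identity() if init is None else init

    rms_history = []
    prev_rms = np.inf
    converged = False
    inlier_fraction = 1.0
    it = 0
    for it in range(1, max_iterations + 1):
        moved = T.apply(src)
        dist, idx = tree.query(moved, k=1)
        med = np.median(dist)
        keep = dist <= outlier_scale * max(med, 1e-12)
        if keep.sum() < 3:
            raise DegenerateRegistrationError("fewer than 3 inlier pairs")
        inlier_fraction = float(keep.mean())
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        rms_history.append(rms)
        if abs(prev_rms - rms) < tol_mm:
            converged = True
            break
        prev_rms = rms
        T = procrustes_rigid(src[keep], tgt[idx[keep]])
    return IcpResult(
        transform=T,
        rms_mm=rms_history[-1],
        n_iterations=it,
        converged=converged,
        inlier_fraction=inlier_fraction,
        rms_history=np.array(rms_history),
    )


@dataclasses.dataclass
class TrackingResult:
    """Per-frame camera-frame motion estimates (the ICP ℑ_K of each frame)."""

    timestamps: np.ndarray
    transforms: list[RigidTransform]
    rms_mm: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.transforms)

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0]) if len(self) > 1 else 0.1

    def frame_index(self, t: np.ndarray | float) -> np.ndarray:
        idx = np.floor((np.asarray(t, dtype=float) - self.timestamps[0]) / self.dt)
        return np.clip(idx, 0, len(self) - 1).astype(np.int64)

    def magnitudes(self) -> np.ndarray:
        return np.array([motion_magnitude(T) for T in self.transforms])

    def to_csv(self, path: str) -> None:
        rows = np.column_stack(
            [
                self.timestamps,
                np.stack([T.to_flat12() for T in self.transforms]),
                self.rms_mm,
                self.valid.astype(float),
            ]
        )
        cols = (
            ["t"]
            + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
            + ["sx", "sy", "sz", "rms_mm", "valid"]
        )
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "TrackingResult":
        df = pd.read_csv(path)
        Ts = [RigidTransform.from_flat12(r) for r in df.iloc[:, 1:13].to_numpy()]
        return cls(
            df["t"].to_numpy(),
            Ts,
            df["rms_mm"].to_numpy(),
            df["valid"].to_numpy() > 0.5,
        )


def track_sequence(
    frames: Sequence[DepthFrame],
    reference_model: SurfaceModel,
    roi: FaceRoi,
    pre_align: bool = True,
    rms_limit_mm: float = 10.0,
    roi_margin_mm: float = 15.0,
    max_iterations: int = 50,
) -> TrackingResult:
    """Track the face through a depth sequence against the reference model.

    For each frame the ROI is propagated by the previous pose estimate,
    and ICP registers the reference model to the selected frame points,
    initialized at the previous estimate when ``pre_align`` is on (the
    pre-processing that keeps correspondences valid after large steps).
    Frames whose ICP residual exceeds ``rms_limit_mm`` (or with too few
    points) are flagged invalid and carry the last valid pose; three
    consecutive invalid frames raise :class:`TrackingLossError`.
    """
    n = len(frames)
    transforms: list[RigidTransform] = []
    rms = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    prev = RigidTransform.identity()
    consecutive_bad = 0
    for i, frame in enumerate(frames):
        pts = select_face_roi(frame, roi, pose=None if i == 0 else prev, margin_mm=roi_margin_mm)
        ok = len(pts) >= 30
        if ok:
            try:
                res = icp_register(
                    reference_model,
                    pts,
                    init=prev if (pre_align or i == 0) else RigidTransform.identity(),
                    max_iterations=max_iterations,
                )
                ok = res.rms_mm <= rms_limit_mm
            except DegenerateRegistrationError:
                ok = False
        if ok:
            prev = res.transform
            transforms.append(res.transform)
            rms[i] = res.rms_mm
            consecutive_bad = 0
        else:
            transforms.append(prev)
            rms[i] = np.nan
            valid[i] = False
            consecutive_bad += 1
            if consecutive_bad >= 3:
                raise TrackingLossError(
                    f"tracking lost at frame {i} (t={frame.timestamp:.1f}s): "
                    "three consecutive frames failed to register"
                )
    return TrackingResult(
        timestamps=np.array([f.timestamp for f in frames]),
        transforms=transforms,
        rms_mm=rms,
        valid=valid,
    )


def _principal_axes_inits(src: np.ndarray, tgt: np.ndarray) -> list[RigidTransform]:
    """Centroid + principal-axes coarse alignments (all 4 proper sign flips)."""
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    _, _, Vs = np.linalg.svd(src - mu_s, full_matrices=False)
    _, _, Vt = np.linalg.svd(tgt - mu_t, full_matrices=False)
    inits = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        D = np.diag([sx, sy, sx * sy])  # keeps det = +1
        R = Vt.T @ D @ Vs
        if np.linalg.det(R) < 0:
            R = Vt.T @ (-D) @ Vs
        t = mu_t - R @ mu_s
        inits.append(RigidTransform.from_rotation_translation(R, t))
    return inits


def _facing_camera_init(ct_pts: np.ndarray, cam_pts: np.ndarray) -> RigidTransform:
    """Coarse scanner->camera init from the facing-camera prior.

    A range camera is placed in front of the face, roughly upright: the
    scanner's face-out axis (+y) maps near the camera's -z (towards the
    camera), scanner-up (+z) near camera -y (image y points down), and the
    nose tips (most protruding point towards the camera on each side)
    coincide.  Valid up to the camera's actual tilt, which ICP absorbs.
    """
    R = np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, -1.0, 0.0]])
    nose_ct = ct_pts[np.argmax(ct_pts[:, 1])]
    nose_cam = cam_pts[np.argmin(cam_pts[:, 2])]
    t = nose_cam - R @ nose_ct
    return RigidTransform.from_rotation_translation(R, t)


def compute_calibration(
    ct_face_model: SurfaceModel,
    camera_face_model: SurfaceModel,
    init: RigidTransform | None = None,
    rms_limit_mm: float = 3.0,
) -> tuple[RigidTransform, IcpResult]:
    """Calibrate the camera to the scanner: returns (C_KP, icp diagnostics).

    ICP maps the camera-side eyes+nose patch onto the CT-side face surface
    (the patch is a strict subset of the face, so pairing in that direction
    is well posed); C_KP is the inverse of that fit, i.e. the transform
    carrying scanner-frame coordinates into camera-frame coordinates.
    Coarse initialization: centroid + principal-axes alignment, all four
    proper sign combinations, best short-ICP residual wins.
    """
    tgt = ct_face_model.points
    src = camera_face_model.points
    tree = cKDTree(tgt)
    if init is not None:
        candidates = [init]
    else:
        # the scanner->camera facing prior (inverted: these ICPs run
        # camera->scanner) plus principal-axes alignments
        candidates = [invert(_facing_camera_init(tgt, src))]
        candidates += _principal_axes_inits(src, tgt)
    best = None
    for cand in candidates:
        # run each candidate close to convergence: a wrong mirror basin can
        # look better than the true one after only a few iterations
        probe = icp_register(src, tgt, init=cand, max_iterations=40, target_tree=tree)
        if best is None or probe.rms_mm < best.rms_mm:
            best = probe
    result = icp_register(src, tgt, init=best.transform, max_iterations=100, target_tree=tree)
    if result.rms_mm > rms_limit_mm:
        raise CalibrationError(
            f"calibration residual {result.rms_mm:.2f} mm exceeds "
            f"{rms_limit_mm} mm; the face models do not superimpose"
        )
    return invert(result.transform), result
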