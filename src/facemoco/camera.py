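"""Range-sensing camera simulation: 10-fps depth frames of the moving head.

The camera casts one ray per pixel of a regular angular grid through the
posed head mesh; the nearest ray/triangle intersection wins (z-buffer
occlusion), back-facing triangles are never returned, and Gaussian depth
noise is added along the ray.  Camera coordinates: +z optical axis
(forward), +x right, +y down; ``CameraModel.pose`` maps world points into
camera coordinates (p_cam = pose · p_world).

Rather than testing every ray against every triangle, triangles are
projected into the pixel grid and candidate (pixel, triangle) pairs are
generated from screen-space bounding boxes; each candidate is then solved
as an exact ray/plane intersection, so returned points lie exactly on the
posed mesh (to machine precision) before noise.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .phantom import MotionTrajectory
from .transforms import RigidTransform

__all__ = [
    "CameraModel",
    "DepthFrame",
    "FaceRoi",
    "default_camera",
    "render_depth_frame",
    "render_depth_sequence",
    "select_face_roi",
]

MIN_ROI_POINTS_REFERENCE = 100  # a usable reference face model
LOW_COVERAGE_POINTS = 30        # below this, tracking is flagged unreliable


@dataclasses.dataclass
class CameraModel:
    """Pinhole-style range camera on a regular angular ray grid."""

    pose: RigidTransform                    # world -> camera
    fov_deg: tuple[float, float] = (60.0, 45.0)
    resolution: tuple[int, int] = (320, 240)
    noise_sigma_mm: float = 1.0
    max_range_mm: float = 1500.0

    def __post_init__(self) -> None:
        for f in self.fov_deg:
            if not 10.0 < f < 120.0:
                raise ValueError(f"field of view {f} deg outside (10, 120)")
        if self.noise_sigma_mm < 0:
            raise ValueError("noise sigma must be >= 0")

    def ray_directions(self) -> np.ndarray:
        """(nx*ny, 3) unit ray directions in camera coordinates."""
        nx, ny = self.resolution
        tx, ty = (np.tan(np.radians(f) / 2.0) for f in self.fov_deg)
        u = ((np.arange(nx) + 0.5) / nx * 2.0 - 1.0) * tx
        v = ((np.arange(ny) + 0.5) / ny * 2.0 - 1.0) * ty
        U, V = np.meshgrid(u, v, indexing="ij")
        d = np.stack([U, V, np.ones_like(U)], axis=-1).reshape(-1, 3)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pose": self.pose.matrix.tolist(),
                    "fov_deg": list(self.fov_deg),
                    "resolution": list(self.resolution),
                    "noise_sigma_mm": self.noise_sigma_mm,
                    "max_range_mm": self.max_range_mm,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "CameraModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            pose=RigidTransform.from_matrix(np.array(d["pose"])),
            fov_deg=tuple(d["fov_deg"]),
            resolution=tuple(d["resolution"]),
            noise_sigma_mm=d["noise_sigma_mm"],
            max_range_mm=d["max_range_mm"],
        )


def default_camera(
    standoff_mm: float = 550.0,
    target: Sequence[float] = (0.0, 85.0, -20.0),
    lateral_mm: float = 0.0,
    height_mm: float = 0.0,
    **kwargs,
) -> CameraModel:
    """Camera in front of the face, looking at the nose region.

    The default phantom's face points along +y with the nose near
    (0, 105, -28) mm, so the camera sits ``standoff_mm`` further along +y
    (optionally offset laterally/vertically) and looks back at ``target``.
    """
    target = np.asarray(target, dtype=float)
    position = target + np.array([lateral_mm, standoff_mm, height_mm])
    z_axis = target - position
    z_axis = z_axis / np.linalg.norm(z_axis)
    up_world = np.array([0.0, 0.0, 1.0])
    y_axis = -up_world + (up_world @ z_axis) * z_axis  # camera y points down
    y_axis = y_axis / np.linalg.norm(y_axis)
    x_axis = np.cross(y_axis, z_axis)
    R = np.stack([x_axis, y_axis, z_axis])  # rows: camera axes in world
    pose = RigidTransform.from_rotation_translation(R, -R @ position)
    return CameraModel(pose=pose, **kwargs)


@dataclasses.dataclass
class DepthFrame:
    """One 10-fps point-cloud frame in camera coordinates."""

    timestamp: float
    points: np.ndarray            # (N, 3) valid points, camera frame, mm
    pixel_indices: np.ndarray     # (N,) flat pixel index of each point
    valid: bool = True
    warnings: list = dataclasses.field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_ply(self, path: str) -> None:
        trimesh.PointCloud(self.points).export(path)


@dataclasses.dataclass
class FaceRoi:
    """Eyes+nose region of interest: a 3D box in the reference camera frame."""

    center: np.ndarray        # camera-frame mm
    half_extents: np.ndarray  # mm

    def contains(self, points: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        d = np.abs(np.atleast_2d(points) - self.center)
        return np.all(d <= self.half_extents + margin_mm, axis=1)

    @classmethod
    def whole_image(cls) -> "FaceRoi":
        return cls(np.zeros(3), np.full(3, np.inf))

    @classmethod
    def around_nose(
        cls,
        reference_frame: DepthFrame,
        half_extents: Sequence[float] = (52.0, 46.0, 36.0),
    ) -> "FaceRoi":
        """Box around the nose tip (the point nearest the camera), shifted up
        towards the eyes — the eyes+nose patch that carries the curvature."""
        if reference_frame.n_points == 0:
            raise ValueError("reference frame has no points")
        pts = reference_frame.points
        nose = pts[np.argmin(pts[:, 2])]  # closest along optical axis
        center = nose + np.array([0.0, -12.0, 12.0])  # up (-y) and behind (+z)
        roi = cls(center, np.asarray(half_extents, dtype=float))
        n = int(roi.contains(pts).sum())
        if n < MIN_ROI_POINTS_REFERENCE:
            raise ValueError(
                f"face ROI selects only {n} reference points "
                f"(need >= {MIN_ROI_POINTS_REFERENCE})"
            )
        return roi


def _rasterize(
    verts_cam: np.ndarray,
    faces: np.ndarray,
    dirs: np.ndarray,
    resolution: tuple[int, int],
    fov_deg: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Z-buffer render: returns (ray lengths per pixel or inf, hit mask)."""
    nx, ny = resolution
    tx, ty = (np.tan(np.radians(f) / 2.0) for f in fov_deg)
    near = 1.0  # mm

    v = verts_cam[faces]                      # (F, 3, 3)
    in_front = np.all(v[:, :, 2] > near, axis=1)
    # back-face cull: outward normal pointing towards the camera has n.c < 0
    n3 = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    centroid = v.mean(axis=1)
    facing = np.einsum("ij,ij->i", n3, centroid) < 0.0
    keep = in_front & facing
    if not np.any(keep):
        return np.full(nx * ny, np.inf), np.zeros(nx * ny, dtype=bool)
    v = v[keep]
    n3 = n3[keep]

    # project to pixel coordinates
    u = v[:, :, 0] / v[:, :, 2]
    w = v[:, :, 1] / v[:, :, 2]
    px = (u / tx + 1.0) / 2.0 * nx - 0.5
    py = (w / ty + 1.0) / 2.0 * ny - 0.5
    x0 = np.clip(np.ceil(px.min(axis=1) - 1e-9), 0, nx - 1).astype(np.int64)
    x1 = np.clip(np.floor(px.max(axis=1) + 1e-9), -1, nx - 1).astype(np.int64)
    y0 = np.clip(np.ceil(py.min(axis=1) - 1e-9), 0, ny - 1).astype(np.int64)
    y1 = np.clip(np.floor(py.max(axis=1) + 1e-9), -1, ny - 1).astype(np.int64)
    wdt = x1 - x0 + 1
    hgt = y1 - y0 + 1
    ok = (wdt > 0) & (hgt > 0)
    v, n3, x0, y0, wdt, hgt = v[ok], n3[ok], x0[ok], y0[ok], wdt[ok], hgt[ok]
    px, py = px[ok], py[ok]
    if len(v) == 0:
        return np.full(nx * ny, np.inf), np.zeros(nx * ny, dtype=bool)

    area = wdt * hgt
    offs = np.concatenate([[0], np.cumsum(area)])
    total = int(offs[-1])
    k = np.arange(total)
    tri = np.searchsorted(offs, k, side="right") - 1
    local = k - offs[tri]
    lx = local % wdt[tri]
    ly = local // wdt[tri]
    gx = x0[tri] + lx
    gy = y0[tri] + ly

    # 2D inside-triangle test in pixel space (consistent orientation per tri)
    ax, ay = px[tri, 0], py[tri, 0]
    bx, by = px[tri, 1], py[tri, 1]
    cx, cy = px[tri, 2], py[tri, 2]
    fx, fy = gx.astype(float), gy.astype(float)
    e0 = (bx - ax) * (fy - ay) - (by - ay) * (fx - ax)
    e1 = (cx - bx) * (fy - by) - (cy - by) * (fx - bx)
    e2 = (ax - cx) * (fy - cy) - (ay - cy) * (fx - cx)
    eps = 1e-12
    inside = ((e0 >= -eps) & (e1 >= -eps) & (e2 >= -eps)) | (
        (e0 <= eps) & (e1 <= eps) & (e2 <= eps)
    )
    tri, gx, gy = tri[inside], gx[inside], gy[inside]
    if len(tri) == 0:
        return np.full(nx * ny, np.inf), np.zeros(nx * ny, dtype=bool)

    pix = gx * ny + gy
    d = dirs[pix]
    denom = np.einsum("ij,ij->i", n3[tri], d)
    num = np.einsum("ij,ij->i", n3[tri], v[tri, 0])
    good = np.abs(denom) > 1e-12
    t = np.full(len(denom), np.inf)
    t[good] = num[good] / denom[good]
    t[t <= near] = np.inf

    zbuf = np.full(nx * ny, np.inf)
    np.minimum.at(zbuf, pix, t)
    return zbuf, np.isfinite(zbuf)


def render_depth_frame(
    mesh: trimesh.Trimesh,
    head_pose: RigidTransform,
    camera: CameraModel,
    timestamp: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DepthFrame:
    """Render one frame of the head posed by ``head_pose`` (world frame)."""
    verts_world = head_pose.apply(np.asarray(mesh.vertices, dtype=float))
    verts_cam = camera.pose.apply(verts_world)
    dirs = camera.ray_directions()
    zbuf, hit = _rasterize(
        verts_cam, np.asarray(mesh.faces), dirs, camera.resolution, camera.fov_deg
    )
    if rng is not None and camera.noise_sigma_mm > 0:
        zbuf = zbuf + np.where(
            hit, rng.normal(0.0, camera.noise_sigma_mm, size=zbuf.shape), 0.0
        )
    hit &= zbuf <= camera.max_range_mm
    pix = np.flatnonzero(hit)
    points = zbuf[pix, None] * dirs[pix]
    return DepthFrame(
        timestamp=timestamp,
        points=points,
        pixel_indices=pix,
        valid=len(pix) > 0,
    )


def render_depth_sequence(
    mesh: trimesh.Trimesh,
    trajectory: MotionTrajectory,
    camera: CameraModel,
    seed: int = 0,
) -> list[DepthFrame]:
    """Render the full 10-fps sequence along a trajectory.

    Frames in which the head misses the view entirely are flagged invalid,
    not raised.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t, T in zip(trajectory.timestamps, trajectory.transforms):
        frames.append(render_depth_frame(mesh, T, camera, float(t), rng))
    return frames


def select_face_roi(
    frame: DepthFrame,
    roi: FaceRoi,
    pose: RigidTransform | None = None,
    margin_mm: float = 0.0,
) -> np.ndarray:
    """Points of ``frame`` inside the ROI.

    ``pose`` (the previous frame's motion estimate) propagates the
    reference-frame ROI to the current head position: a point p is kept if
    pose^-1 · p falls in the box.  Fewer than 30 selected points attaches a
    low-coverage warning to the frame.
    """
    if not frame.valid:
        return np.empty((0, 3))
    pts = frame.points
    if pose is not None:
        pts = pose.inverse().apply(pts)
    sel = roi.contains(pts, margin_mm)
    out = frame.points[sel]
    if len(out) < LOW_COVERAGE_POINTS:
        frame.warnings.append(
            f"low ROI coverage: {len(out)} points at t={frame.timestamp:.1f}s"
        )
    return out


def frames_to_csv(frames: list[DepthFrame], path: str) -> None:
    """All frames as one CSV (t, x, y, z) — the simple interchange dump."""
    rows = [
        np.column_stack([np.full(f.n_points, f.timestamp), f.points])
        for f in frames
        if f.n_points
    ]
    arr = np.vstack(rows) if rows else np.empty((0, 4))
    pd.DataFrame(arr, columns=["t", "x", "y", "z"]).to_csv(path, index=False)
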