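"""CT-side face model: skin-surface extraction and CT-to-PET rigid registration.

The reference PET image (reconstructed from a ~20-s motionless stretch of
the list-mode stream, without attenuation correction) anchors the scanner
coordinate frame.  The CT volume is rigidly registered to it by Nelder-Mead
simplex search over the six pose parameters, maximizing normalized
cross-correlation between the PET image and the CT soft-tissue mask
(mutual information is available as an alternative); the face (skin)
isosurface of the registered CT then provides the scanner-frame 3D
face-shape model used for camera calibration.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, optimize
from skimage import measure

from .phantom import MU_SOFT_TISSUE
from .tracking import SurfaceModel
from .transforms import PoseParameters, RigidTransform, pose_to_transform
from .volume import ImageVolume

__all__ = [
    "EmptySurfaceError",
    "ConvergenceFailureError",
    "RegistrationResult",
    "extract_surface_model",
    "register_ct_to_pet",
    "soft_tissue_mask",
]


class EmptySurfaceError(ValueError):
    """The isosurface threshold is never crossed."""


class ConvergenceFailureError(RuntimeError):
    """Simplex collapsed without meeting tolerance; best-so-far attached."""

    def __init__(self, message: str, best: "RegistrationResult"):
        super().__init__(message)
        self.best = best


def extract_surface_model(
    ct: ImageVolume,
    threshold: float = MU_SOFT_TISSUE / 2.0,
    face_axis: int = 1,
    face_sign: float = 1.0,
    anterior_only: bool = True,
    presmooth_voxels: float = 1.5,
) -> SurfaceModel:
    """Skin isosurface of a CT-like volume as a scanner-frame point set.

    Marching cubes at ``threshold``; vertices are returned in world mm.  With
    ``anterior_only`` the model is cut to the face-side half-space (beyond
    the head centroid along ``face_axis`` with orientation ``face_sign``),
    emulating the facial surface a front-facing camera can see.
    ``presmooth_voxels`` smooths the volume first: on near-binary CT masks
    marching cubes otherwise lands on voxel-edge midpoints, a staircase
    whose offset depends on surface orientation and would bias downstream
    rigid fits.
    """
    vals = np.asarray(ct.values, dtype=float)
    if not (vals.min() < threshold < vals.max()):
        raise EmptySurfaceError(
            f"threshold {threshold} outside value range "
            f"[{vals.min():.4g}, {vals.max():.4g}]"
        )
    if presmooth_voxels > 0:
        vals = ndimage.gaussian_filter(vals, presmooth_voxels)
    verts, _, _, _ = measure.marching_cubes(vals, level=threshold)
    pts = ct.origin + verts * ct.spacing
    if anterior_only:
        inside = vals > threshold
        centroid = ct.index_to_world(np.argwhere(inside).mean(axis=0))
        keep = face_sign * (pts[:, face_axis] - centroid[face_axis]) > 0
        pts = pts[keep]
    if len(pts) < 30:
        raise EmptySurfaceError("extracted surface has fewer than 30 vertices")
    return SurfaceModel(pts, source="ct", frame="pet")


def soft_tissue_mask(ct: ImageVolume, smooth_voxels: float = 1.0) -> ImageVolume:
    """Soft-tissue (non-air, non-bone) mask of a CT-like attenuation volume.

    The bone shell separates the brain-shaped interior component from the
    scalp ring, which is what makes intensity registration against a
    brain-only emission image well posed.
    """
    mu = np.asarray(ct.values, dtype=float)
    mask = ((mu > 0.6 * MU_SOFT_TISSUE) & (mu < 1.4 * MU_SOFT_TISSUE)).astype(float)
    if smooth_voxels > 0:
        mask = ndimage.gaussian_filter(mask, smooth_voxels)
    return ct.copy_with(mask)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


@dataclasses.dataclass
class RegistrationResult:
    transform: RigidTransform
    pose: PoseParameters
    cost: float
    n_evaluations: int
    success: bool
    cost_trace: np.ndarray
    all_starts: list


def register_ct_to_pet(
    ct: ImageVolume,
    reference_pet: ImageVolume,
    init: PoseParameters = PoseParameters(),
    metric: str = "ncc",
    n_starts: int = 5,
    seed: int = 0,
    perturb_mm: float = 10.0,
    perturb_deg: float = 10.0,
    maxiter: int = 400,
) -> RegistrationResult:
    """Rigid CT-to-PET registration by multi-start Nelder-Mead over 6 DOF.

    The CT soft-tissue mask is resampled into the PET grid (trilinear, zeros
    outside) at each cost evaluation; the cost is the negative similarity
    (``ncc`` or ``mi``).  ``n_starts`` simplex runs start from ``init`` plus
    random perturbations of ±``perturb_mm`` / ±``perturb_deg``; the
    lowest-cost run wins.  Returns the CT→PET transform.
    """
    mask = soft_tissue_mask(ct)
    pet_vals = np.asarray(reference_pet.values, dtype=float)
    sim = _ncc if metric == "ncc" else _mutual_information
    if metric not in ("ncc", "mi"):
        raise ValueError(f"unknown metric '{metric}' (use 'ncc' or 'mi')")

    trace: list[float] = []

    def cost(params: np.ndarray) -> float:
        T = pose_to_transform(PoseParameters.from_array(params))
        resampled = mask.resample_like(reference_pet, transform=T, order=1)
        c = -sim(pet_vals, resampled.values)
        trace.append(c)
        return c

    rng = np.random.default_rng(seed)
    starts = [init.as_array()]
    for _ in range(max(0, n_starts - 1)):
        d = np.concatenate(
            [
                rng.uniform(-perturb_mm, perturb_mm, 3),
                rng.uniform(-perturb_deg, perturb_deg, 3),
            ]
        )
        starts.append(init.as_array() + d)

    runs = []
    for s in starts:
        res = optimize.minimize(
            cost,
            s,
            method="Nelder-Mead",
            options={
                "xatol": 0.02,
                "fatol": 1e-7,
                "maxiter": maxiter,
                "initial_simplex": _initial_simplex(s),
            },
        )
        runs.append(res)
    # a run that wandered far outside the perturbation prior is a spurious
    # optimum (the CT-PET misalignment is bounded in practice); keep it only
    # if nothing plausible converged
    def plausible(r):
        d = np.abs(r.x - init.as_array())
        return np.all(d[:3] <= 1.5 * perturb_mm) and np.all(d[3:] <= 1.5 * perturb_deg)

    candidates = [r for r in runs if plausible(r)] or runs
    best = min(candidates, key=lambda r: r.fun)
    pose = PoseParameters.from_array(best.x)
    result = RegistrationResult(
        transform=pose_to_transform(pose),
        pose=pose,
        cost=float(best.fun),
        n_evaluations=len(trace),
        success=bool(any(r.success for r in runs)),
        cost_trace=np.array(trace),
        all_starts=[(s.tolist(), float(r.fun), bool(r.success)) for s, r in zip(starts, runs)],
    )
    if not result.success:
        raise ConvergenceFailureError(
            "Nelder-Mead simplex collapsed without meeting tolerance in all "
            f"{len(runs)} starts (best cost {result.cost:.5f})",
            result,
        )
    return result


def _initial_simplex(x0: np.ndarray) -> np.ndarray:
    """Simplex spanning a few mm / deg so the search does not stall on a
    plateau of the sampled cost."""
    steps = np.array([4.0, 4.0, 4.0, 3.0, 3.0, 3.0])
    simplex = np.tile(x0, (7, 1))
    for i in range(6):
        simplex[i + 1, i] += steps[i]
    return simplex


def rigid_align(
    moving: ImageVolume,
    fixed: ImageVolume,
    init: PoseParameters = PoseParameters(),
    n_starts: int = 3,
    seed: int = 0,
    perturb_mm: float = 4.0,
    perturb_deg: float = 4.0,
    maxiter: int = 250,
) -> RigidTransform:
    """Small-range rigid alignment of two same-modality volumes (raw-value
    NCC, Nelder-Mead).  Used to co-register a reconstruction with the
    anatomy before VOI sampling, the way clinical VOI analysis co-registers
    PET to the subject's anatomical scan."""
    mov = np.asarray(moving.values, dtype=float)
    fix = np.asarray(fixed.values, dtype=float)

    def cost(params: np.ndarray) -> float:
        T = pose_to_transform(PoseParameters.from_array(params))
        res = moving.resample_like(fixed, transform=T, order=1)
        return -_ncc(fix, res.values)

    rng = np.random.default_rng(seed)
    starts = [init.as_array()]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            init.as_array()
            + np.concatenate(
                [rng.uniform(-perturb_mm, perturb_mm, 3),
                 rng.uniform(-perturb_deg, perturb_deg, 3)]
            )
        )
    best = None
    for s in starts:
        r = optimize.minimize(
            cost, s, method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 1e-7, "maxiter": maxiter,
                     "initial_simplex": _initial_simplex(s)},
        )
        if best is None or r.fun < best.fun:
            best = r
    return pose_to_transform(PoseParameters.from_array(best.x))
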