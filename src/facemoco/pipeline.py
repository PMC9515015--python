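"""End-to-end orchestration: phantom → motion → depth frames → list-mode →
reference recon → CT registration → calibration → tracking → corrected
reconstruction → evaluation.

Every stochastic stage draws its seed deterministically from the master
seed and the stage name, so a pipeline run is reproducible end to end and
two stages never share a random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from typing import Sequence

import numpy as np
import yaml

from . import evaluate as ev
from .camera import CameraModel, FaceRoi, default_camera, render_depth_sequence, select_face_roi
from .ctreg import extract_surface_model, register_ct_to_pet
from .listmode import (
    ListModeData,
    ScannerModel,
    find_motionless_period,
    select_events,
    simulate_listmode,
)
from .phantom import (
    HeadPhantom,
    MotionAmplitude,
    make_head_phantom,
    make_marker_trajectory,
    make_static_trajectory,
)
from .recon import ReconConfig, gaussian_postfilter, reconstruct
from .tracking import SurfaceModel, compute_calibration, track_sequence
from .transforms import RigidTransform, PoseParameters, pose_to_transform
from .volume import ImageVolume

__all__ = ["PipelineConfig", "ScanResult", "PipelineResult", "stage_seed",
           "run_scan", "run_pipeline", "run_test_retest"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    duration_s: float = 120.0
    n_events: int = 1_000_000
    # time-compressed marker protocol for the 2-min scaled-down scan: the
    # 3 : 1.5 : 1 dwell ratio of the 60/30/20-s protocol, first dwell long
    # enough to contain the 20-s motionless reference window
    # phantom
    phantom_grid: tuple = (64, 64, 64)
    phantom_voxel_mm: float = 3.0
    # trajectory
    amplitude_translation_mm: float = 30.0
    amplitude_rotation_deg: float = 25.0
    schedule: tuple = (24.0, 12.0, 8.0)
    # camera
    camera_standoff_mm: float = 550.0
    camera_lateral_mm: float = 0.0
    camera_height_mm: float = 0.0
    camera_noise_sigma_mm: float = 1.0
    # scanner
    scanner: ScannerModel = dataclasses.field(default_factory=ScannerModel)
    # reconstruction
    recon_grid: tuple = (48, 48, 48)
    recon_voxel_mm: float = 4.0
    # 2 passes x 8 subsets: the bias-dominated EM regime at desk-scale
    # counts; more passes add voxel variance faster than contrast (see
    # docs/methods.md), and shared convergence bias cancels in comparisons
    n_iterations: int = 2
    n_subsets: int = 8
    fwhm_mm: float = 4.0
    # calibration chain
    ct_offset: tuple = (4.0, 3.0, 0.0, 0.0, 0.0, 5.0)  # tx ty tz rx ry rz
    reference_window_s: float = 20.0
    registration_starts: int = 5
    # extras
    include_uncorrected: bool = True
    include_static: bool = True

    def recon_config(self, motion_correction: bool) -> ReconConfig:
        return ReconConfig(
            n_iterations=self.n_iterations,
            n_subsets=self.n_subsets,
            voxel_mm=self.recon_voxel_mm,
            grid_shape=tuple(self.recon_grid),
            fwhm_mm=self.fwhm_mm,
            motion_correction=motion_correction,
        )

    def amplitude(self) -> MotionAmplitude:
        return MotionAmplitude(self.amplitude_translation_mm, self.amplitude_rotation_deg)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["scanner"] = dataclasses.asdict(self.scanner)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update(overrides)
        if "scanner" in d and isinstance(d["scanner"], dict):
            d["scanner"] = ScannerModel(**d["scanner"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("phantom_grid", "schedule", "recon_grid", "ct_offset"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class ScanResult:
    """Everything one head-moving scan produces."""

    trajectory: object
    tracking: object
    calibration: RigidTransform
    calibration_rms_mm: float
    registration_pose: PoseParameters
    window: object
    events: ListModeData
    sim_info: dict
    reference_recon: ImageVolume
    corrected: ImageVolume
    uncorrected: ImageVolume | None
    camera: CameraModel


def _make_ct(
    phantom: HeadPhantom,
    ct_offset: Sequence[float],
    ct_voxel_mm: float | None = 1.5,
) -> tuple[ImageVolume, RigidTransform]:
    """The separately acquired CT: the same head's attenuation, rasterized
    at CT-like resolution (clinical CT is far finer than the PET grid) and
    expressed in its own (misaligned) frame.  Returns (ct volume, true
    CT→PET transform).

    The fine rasterization is what the camera calibration needs: the skin
    isosurface of a coarse CT carries orientation-dependent quantization
    that biases the surface ICP by 1-2 degrees.  It costs a small, largely
    seed-independent registration offset against a reference PET image
    reconstructed from a coarser phantom rasterization; ``ct_voxel_mm=None``
    reuses the phantom grid instead.
    """
    offset = pose_to_transform(PoseParameters(*ct_offset))
    if ct_voxel_mm is None:
        base = phantom.attenuation
    else:
        n = int(np.ceil(200.0 / ct_voxel_mm)) | 1
        base = make_head_phantom((n, n, n), ct_voxel_mm, uptake=phantom.uptake).attenuation
    ct = base.resample_like(base, transform=offset.inverse(), order=1)
    return ct, offset


def run_scan(
    phantom: HeadPhantom,
    config: PipelineConfig,
    seed_tag: str = "scan",
    camera: CameraModel | None = None,
    log: dict | None = None,
) -> ScanResult:
    """One complete head-moving scan with motion-corrected reconstruction."""
    log = {} if log is None else log
    master = config.seed

    trajectory = make_marker_trajectory(
        config.duration_s,
        schedule=config.schedule,
        amplitude=config.amplitude(),
        seed=stage_seed(master, seed_tag + ":trajectory"),
    ) if (config.amplitude_translation_mm or config.amplitude_rotation_deg) else (
        make_static_trajectory(config.duration_s)
    )
    log["motion_summary"] = ev.motion_summary(trajectory)

    if camera is None:
        camera = default_camera(
            standoff_mm=config.camera_standoff_mm,
            lateral_mm=config.camera_lateral_mm,
            height_mm=config.camera_height_mm,
            noise_sigma_mm=config.camera_noise_sigma_mm,
        )
    frames = render_depth_sequence(
        phantom.surface_mesh, trajectory, camera,
        seed=stage_seed(master, seed_tag + ":camera"),
    )
    roi = FaceRoi.around_nose(frames[0])
    reference_model = SurfaceModel(select_face_roi(frames[0], roi), source="camera")
    tracking = track_sequence(frames, reference_model, roi)
    log["tracking_mean_rms_mm"] = float(np.nanmean(tracking.rms_mm))

    events, sim_info = simulate_listmode(
        phantom.activity, trajectory, config.scanner, config.n_events,
        seed=stage_seed(master, seed_tag + ":listmode"),
    )
    log["sim_info"] = sim_info

    window = find_motionless_period(
        tracking,
        window_s=min(config.reference_window_s, config.duration_s),
        anchor_point=reference_model.points.mean(axis=0),
    )
    log["reference_window"] = {
        "intervals": [list(map(float, iv)) for iv in window.intervals],
        "contiguous": window.contiguous,
    }
    ref_events = select_events(events, window)
    ref_recon, _ = reconstruct(
        ref_events, config.recon_config(motion_correction=False),
        scanner=config.scanner,
    )
    ref_recon = gaussian_postfilter(ref_recon, config.fwhm_mm)

    ct, _true_ct_to_pet = _make_ct(phantom, config.ct_offset)
    reg = register_ct_to_pet(
        ct, ref_recon, n_starts=config.registration_starts,
        seed=stage_seed(master, seed_tag + ":ctreg"),
    )
    log["registration_pose"] = reg.pose.as_array().tolist()

    ct_surface = extract_surface_model(ct)
    ct_surface_pet = ct_surface.transformed(reg.transform)
    ct_surface_pet.frame = "pet"
    # restrict the CT face model to the face vicinity (around the nose tip)
    tip = ct_surface_pet.points[np.argmax(ct_surface_pet.points[:, 1])]
    near = np.linalg.norm(ct_surface_pet.points - tip, axis=1) < 110.0
    ct_face = SurfaceModel(ct_surface_pet.points[near], source="ct", frame="pet")

    # the camera-side model for calibration is the whole visible face (the
    # contoured face area); the tighter eyes+nose patch is kept for tracking
    camera_face = SurfaceModel(frames[0].points, source="camera", frame="camera")
    calib, icp_diag = compute_calibration(ct_face, camera_face)
    log["calibration_rms_mm"] = icp_diag.rms_mm

    corrected, corr_meta = reconstruct(
        events, config.recon_config(motion_correction=True),
        tracking=tracking, calib=calib, scanner=config.scanner,
    )
    corrected = gaussian_postfilter(corrected, config.fwhm_mm)
    log["corrected_meta"] = {k: v for k, v in corr_meta.items() if k != "sensitivity_weighted_total"}

    uncorrected = None
    if config.include_uncorrected:
        uncorrected, _ = reconstruct(
            events, config.recon_config(motion_correction=False),
            scanner=config.scanner,
        )
        uncorrected = gaussian_postfilter(uncorrected, config.fwhm_mm)

    return ScanResult(
        trajectory=trajectory,
        tracking=tracking,
        calibration=calib,
        calibration_rms_mm=icp_diag.rms_mm,
        registration_pose=reg.pose,
        window=window,
        events=events,
        sim_info=sim_info,
        reference_recon=ref_recon,
        corrected=corrected,
        uncorrected=uncorrected,
        camera=camera,
    )


def static_truth_recon(phantom: HeadPhantom, config: PipelineConfig) -> ImageVolume:
    """Head-fixed ('standard of truth') scan: static simulation + plain recon."""
    trajectory = make_static_trajectory(config.duration_s)
    events, _ = simulate_listmode(
        phantom.activity, trajectory, config.scanner, config.n_events,
        seed=stage_seed(config.seed, "static:listmode"),
    )
    recon, _ = reconstruct(
        events, config.recon_config(motion_correction=False), scanner=config.scanner
    )
    return gaussian_postfilter(recon, config.fwhm_mm)


def anatomy_alignment(
    phantom: HeadPhantom,
    image: ImageVolume,
    fwhm_mm: float = 4.0,
    seed: int = 0,
):
    """Rigid transform carrying phantom (anatomy) coordinates onto a
    reconstruction, for VOI sampling.

    Clinical VOI analysis co-registers each PET image to the subject's
    anatomical scan before applying the VOI template; this is the phantom
    analog (the phantom's own activity map, blurred to reconstruction
    resolution, stands in for the anatomical prior).  It absorbs the small
    global rigid offset a reconstruction inherits from the calibration
    chain, exactly as the clinical co-registration step would.
    """
    from .ctreg import rigid_align

    prior = gaussian_postfilter(phantom.activity, fwhm_mm)
    return rigid_align(prior, image, seed=seed)


def aligned_labels(
    phantom: HeadPhantom,
    image: ImageVolume,
    transform=None,
    fwhm_mm: float = 4.0,
    seed: int = 0,
) -> ImageVolume:
    """Phantom VOI labels on the image grid after anatomical co-registration."""
    T = transform if transform is not None else anatomy_alignment(
        phantom, image, fwhm_mm=fwhm_mm, seed=seed
    )
    return phantom.voi_labels.resample_like(image, transform=T, order=0)


@dataclasses.dataclass
class PipelineResult:
    scan: ScanResult
    static: ImageVolume | None
    suvr: dict
    peak_to_valley: dict
    nrmse: dict
    log: dict
    manifest: dict


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> PipelineResult:
    """Full experiment on one phantom: moving scan (corrected + uncorrected)
    plus the head-fixed truth scan, with SUVR / profile / NRMSE evaluation.

    With ``out_dir`` set, artifacts are written and listed (with SHA-256
    checksums and stage seeds) in ``manifest.json``.
    """
    log: dict = {"seed": config.seed}
    phantom = make_head_phantom(config.phantom_grid, config.phantom_voxel_mm)
    scan = run_scan(phantom, config, seed_tag="scan", log=log)
    static = static_truth_recon(phantom, config) if config.include_static else None

    # VOI analysis co-registers each image to the anatomy first (the
    # clinical PET-to-anatomical-scan step)
    images = {"corrected": scan.corrected}
    if scan.uncorrected is not None:
        images["uncorrected"] = scan.uncorrected
    if static is not None:
        images["static"] = static
    base_line = ev.profile_line_through_labels(phantom.voi_labels)
    suvr, p2v = {}, {}
    for name, img in images.items():
        T = anatomy_alignment(
            phantom, img, fwhm_mm=config.fwhm_mm,
            seed=stage_seed(config.seed, f"voireg:{name}"),
        )
        suvr[name] = ev.compute_suvr(
            img, aligned_labels(phantom, img, transform=T)
        )
        p2v[name] = ev.peak_to_valley_or_flat(
            img, (T.apply(base_line[0]), T.apply(base_line[1]))
        )

    nrmse = {}
    if static is not None:
        nrmse["corrected_vs_static"] = ev.nrmse(scan.corrected, static)
        if scan.uncorrected is not None:
            nrmse["uncorrected_vs_static"] = ev.nrmse(scan.uncorrected, static)

    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("scan:trajectory", "scan:camera", "scan:listmode",
                      "scan:ctreg", "static:listmode")
        },
        "log": log,
        "suvr": {k: v.as_dataframe().to_dict(orient="list") for k, v in suvr.items()},
        "peak_to_valley": p2v,
        "nrmse": nrmse,
        "artifacts": {},
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        phantom.save(os.path.join(out_dir, "phantom"))
        paths = {
            "trajectory.csv": lambda p: scan.trajectory.to_csv(p),
            "tracking.csv": lambda p: scan.tracking.to_csv(p),
            "events.csv": lambda p: scan.events.to_csv(p),
            "calibration.json": lambda p: open(p, "w").write(scan.calibration.to_json()),
            "reference_recon.nii.gz": lambda p: scan.reference_recon.to_nifti(p),
            "corrected.nii.gz": lambda p: scan.corrected.to_nifti(p),
        }
        if scan.uncorrected is not None:
            paths["uncorrected.nii.gz"] = lambda p: scan.uncorrected.to_nifti(p)
        if static is not None:
            paths["static.nii.gz"] = lambda p: static.to_nifti(p)
        for name, writer in paths.items():
            p = os.path.join(out_dir, name)
            writer(p)
            manifest["artifacts"][name] = _sha256(p)
        for name, tab in suvr.items():
            p = os.path.join(out_dir, f"suvr_{name}.csv")
            tab.to_csv(p)
            manifest["artifacts"][f"suvr_{name}.csv"] = _sha256(p)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    return PipelineResult(scan, static, suvr, p2v, nrmse, log, manifest)


def run_test_retest(
    config: PipelineConfig,
    camera2_lateral_mm: float = 90.0,
    camera2_height_mm: float = -50.0,
    camera2_standoff_mm: float | None = None,
) -> dict:
    """Two independently simulated, calibrated, tracked and corrected scans of
    one phantom with different camera placements and motion realizations;
    returns both SUVR tables and their agreement (r^2, through-origin slope).
    """
    phantom = make_head_phantom(config.phantom_grid, config.phantom_voxel_mm)
    cfg1 = dataclasses.replace(config, include_uncorrected=False)
    cfg2 = dataclasses.replace(
        config,
        include_uncorrected=False,
        seed=stage_seed(config.seed, "retest"),
        camera_lateral_mm=camera2_lateral_mm,
        camera_height_mm=camera2_height_mm,
        camera_standoff_mm=camera2_standoff_mm or config.camera_standoff_mm,
    )
    scan1 = run_scan(phantom, cfg1, seed_tag="cal1")
    scan2 = run_scan(phantom, cfg2, seed_tag="cal2")
    # each scan's image is co-registered to the anatomy before VOI sampling
    t1 = ev.compute_suvr(
        scan1.corrected,
        aligned_labels(phantom, scan1.corrected, fwhm_mm=config.fwhm_mm,
                       seed=stage_seed(config.seed, "voireg:cal1")),
    )
    t2 = ev.compute_suvr(
        scan2.corrected,
        aligned_labels(phantom, scan2.corrected, fwhm_mm=config.fwhm_mm,
                       seed=stage_seed(config.seed, "voireg:cal2")),
    )
    r2, slope = ev.test_retest(t1, t2)
    return {
        "suvr1": t1,
        "suvr2": t2,
        "r_squared": r2,
        "slope_through_origin": slope,
        "scan1": scan1,
        "scan2": scan2,
    }
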