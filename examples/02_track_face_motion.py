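"""Track head motion with the simulated depth camera and score it against
the ground-truth trajectory.

A 30-s marker-viewing trajectory (30 mm / 25 deg) is rendered at 10 fps
with 1-mm depth noise; the eyes+nose patch of the first frame becomes the
reference 3D face-shape model, and every frame is registered to it by ICP
with frame-to-frame pre-alignment.
"""

import numpy as np

import facemoco as fm
from facemoco.camera import FaceRoi, default_camera, render_depth_sequence, select_face_roi
from facemoco.tracking import SurfaceModel, track_sequence
from facemoco.transforms import compose, invert, motion_magnitude

phantom = fm.make_head_phantom()
trajectory = fm.make_marker_trajectory(
    30.0, schedule=(6.0, 3.0, 2.0), amplitude=fm.MotionAmplitude(30, 25), seed=1
)
camera = default_camera(noise_sigma_mm=1.0)

frames = render_depth_sequence(phantom.surface_mesh, trajectory, camera, seed=2)
roi = FaceRoi.around_nose(frames[0])
reference = SurfaceModel(select_face_roi(frames[0], roi))
print(f"reference face model: {len(reference.points)} points (eyes+nose patch)")

tracking = track_sequence(frames, reference, roi)

# score in the head frame: map each camera-frame estimate through the true
# camera pose and compare with the generating transform
E, E_inv = camera.pose, invert(camera.pose)
errors = np.array([
    motion_magnitude(compose(compose(compose(E_inv, est), E), invert(true)))
    for est, true in zip(tracking.transforms, trajectory.transforms)
])
print(f"tracked {len(frames)} frames, all valid: {bool(tracking.valid.all())}")
print(f"median error: {np.median(errors[:, 0]):.2f} mm, "
      f"{np.median(errors[:, 1]):.2f} deg")
print(f"95th percentile: {np.percentile(errors[:, 0], 95):.2f} mm, "
      f"{np.percentile(errors[:, 1], 95):.2f} deg")
# Sub-millimetre / sub-degree medians mean the tracker follows stepped
# motion up to the configured amplitude without losing the face patch.
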