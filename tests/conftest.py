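"""Shared fixtures: small phantoms, cameras, rendered reference frames.

Session-scoped where construction is expensive; all fixtures are
deterministic (fixed seeds) so the suite is reproducible.
"""

import numpy as np
import pytest

import facemoco as fm
from facemoco.camera import FaceRoi, default_camera, render_depth_frame, select_face_roi
from facemoco.tracking import SurfaceModel
from facemoco.transforms import RigidTransform


@pytest.fixture(scope="session")
def phantom():
    return fm.make_head_phantom()


@pytest.fixture(scope="session")
def camera_clean():
    return default_camera(noise_sigma_mm=0.0)


@pytest.fixture(scope="session")
def reference_frame(phantom, camera_clean):
    return render_depth_frame(
        phantom.surface_mesh, RigidTransform.identity(), camera_clean
    )


@pytest.fixture(scope="session")
def face_roi(reference_frame):
    return FaceRoi.around_nose(reference_frame)


@pytest.fixture(scope="session")
def reference_model(reference_frame, face_roi):
    return SurfaceModel(select_face_roi(reference_frame, face_roi))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
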