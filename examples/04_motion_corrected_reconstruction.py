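"""The full pipeline: moving scan, motion-corrected reconstruction, and the
comparison against an uncorrected and a head-fixed ('truth') image.

Scaled down to run in a few minutes: 40-s scan, 300k events, 48^3 grid.
"""

import numpy as np

from facemoco.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=11,
    duration_s=40.0,
    n_events=300_000,
    schedule=(35.0, 4.0, 3.0),   # quiet start for the reference window
    reference_window_s=10.0,
    amplitude_translation_mm=25.0,
    amplitude_rotation_deg=20.0,
    n_iterations=2,
)
result = run_pipeline(config)

print("reference window:", result.log["reference_window"])
print("motion:", {k: round(v, 1) for k, v in result.log["motion_summary"].items()})
print()
print(f"{'VOI':32s} {'corrected':>10s} {'uncorrected':>12s} {'head-fixed':>11s}")
for i, name in enumerate(result.suvr["corrected"].voi_names):
    print(f"{name:32s} {result.suvr['corrected'].suvr[i]:10.3f} "
          f"{result.suvr['uncorrected'].suvr[i]:12.3f} "
          f"{result.suvr['static'].suvr[i]:11.3f}")
print()
print(f"NRMSE vs head-fixed:  corrected {result.nrmse['corrected_vs_static']:.3f}, "
      f"uncorrected {result.nrmse['uncorrected_vs_static']:.3f}")
# Corrected SUVRs track the head-fixed column; the uncorrected column is
# biased wherever motion smears activity across VOI boundaries (here most
# visibly in the posterior cingulate).  At this deliberately small event
# count the NRMSE of both images is dominated by the Poisson noise floor;
# the acceptance experiments (facemoco.experiments) run the same
# comparison at 4e6 events, where correction roughly halves the error.
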