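# Methods

This note records the models behind `facemoco`, the parameters that
matter, the design decisions taken where the design was genuinely open,
and what the synthetic experiments do and do not demonstrate.

## Coordinate frames and the correction formula

Three frames exist: the **scanner (PET/world) frame**, in which the
phantom, the scanner cylinder and all reconstructions live; the **camera
frame** (+z optical axis, +x right, +y down); and the **CT frame**, the
scanner frame displaced by an unknown rigid offset (the CT is acquired on
a different device).

Head pose is a rigid transform `T = [[R, s], [0, 1]]` (rotation `R`,
translation `s` in mm). The tracker estimates the *forward* camera-frame
motion `M_K(t)` mapping reference-pose face points to their frame-`t`
positions. The calibration `C_KP` maps scanner-frame point coordinates to
camera-frame coordinates (`p_cam = C_KP · p_pet`). With these conventions
the per-event correction

    M_P(t) = C_KP^-1 · M_K(t)^-1 · C_KP

is exactly `T(t)^-1` in the scanner frame: applying it to both endpoints
of a coincidence detected at the moved pose returns the line of response
to the reference pose. The direction convention is load-bearing — with
`C_KP` defined the other way around the sandwich does *not* collapse to
the inverse motion — so it is asserted by a property test
(`tests/test_transforms.py::TestEq2Conversion`).

Euler angles at all interfaces are intrinsic Z-Y-X in degrees
(`T = Trans·Rz·Ry·Rx`); the decomposition refuses |ry| ≥ 89° (gimbal
lock). Rotation magnitude is reported as the single axis–angle scalar;
per-axis decomposition is available for plotting.

## Head phantom

One analytic geometry generates everything, so surface, activity,
attenuation and labels are consistent by construction:

* **Surface**: triaxial ellipsoid (75, 85, 95 mm semi-axes; +y out of the
  face, +z superior), with a nose (25-mm radial Gaussian bump, ~9° wide)
  and two eye sockets (8-mm indentations). The mesh is a subdivided
  icosphere (10 242 vertices) displaced by the same radial rule the voxel
  rasterizer uses; it is closed and encloses all activity.
* **Activity** (cerebellum ≡ 1): frontal 1.15, medial temporal 0.40,
  lateral temporal 0.85, parietal 1.05, occipital 1.25, posterior
  cingulate+precuneus 1.40, striatum 1.50, inferior colliculus 1.50,
  white matter 0.35, extracerebral soft tissue (scalp) 0.25. The values
  follow the qualitative regional pattern of FDG uptake but are spread so
  the cerebellar-normalized SUVRs span ~0.4–1.5: correlation-based
  test–retest statistics need the between-VOI variance to dominate the
  per-VOI counting noise, and with a near-uniform cortex the eight SUVR
  points would nearly coincide. The scalp term matters
  methodologically: a no-attenuation-correction PET of a real FDG subject
  shows the head outline (scalp/muscle uptake), and that outline — nose
  included — is what CT registration locks onto. Without it the
  registration problem is a plateau.
* **Attenuation**: soft tissue 0.0096 /mm, skull shell 0.0171 /mm, air 0.
  The skull gap between brain and scalp is what makes mask-based
  registration well-posed against a brain-dominated emission image.
* **Inferior colliculus**: two 6-mm spheres, centers 8 mm apart
  laterally, in the midbrain — the small-structure benchmark. Their 2-mm
  inter-nucleus gap only exists on rasterizations of ≤ 2 mm, so
  experiments that evaluate the colliculus profile use a 2-mm phantom
  grid (the default quantification grid is 64³ at 3 mm).
* **Labels**: 8 SUVR VOIs (incl. cerebellum), the two colliculus nuclei,
  white matter, scalp, background. Background has zero activity.

## Motion trajectories

The marker-viewing protocol: the scan divides into three equal sets with
per-set dwell times (default 60/30/20 s; a 15-min scan yields
5 + 10 + 15 = 30 moves), the head stepping through 8 virtual wall-marker
poses in ascending order, starting at the identity reference pose. Dwell
poses combine yaw (about +z) and pitch (about +x) with a coupled
translation, scaled so the peak magnitude is 95 % of the configured
amplitude — dwell jitter (σ 0.2 mm / 0.1°, white) then cannot push any
frame past the cap. Transitions are 1-s smoothstep interpolations (slerp
for rotation). Frames are at 10 fps; frame 0 is exactly the identity.

Scaled-down scans compress the dwell schedule proportionally while
keeping the 3 : 1.5 : 1 ratio, with two constraints: the shortest dwell
stays at least twice the transition time (the protocol is
piecewise-stationary, not continuous motion), and the first dwell is long
enough to contain the ~20-s motionless window the reference
reconstruction needs (pipeline default for 120-s scans: 24/12/8 s).

## Depth camera

One ray per pixel of a regular angular grid (default 60°×45° field of
view, 320×240 rays, 550-mm standoff); nearest ray–triangle intersection
kept (z-buffer), back faces never returned; Gaussian depth noise
(default σ = 1 mm, Kinect-class) added along the ray. The rasterizer
generates candidate pixel/triangle pairs from screen-space bounding boxes
and solves each as an exact ray/plane intersection, so noiseless points
lie on the posed mesh to machine precision — the renderer itself
contributes no surface error.

The eyes+nose ROI is a 3D box placed around the nose tip (the closest
point to the camera) on the reference frame and propagated to later
frames by the previous pose estimate. Resolution and ROI size were set by
measuring the tracker, not assumed: at a 4-mm ray pitch the
point-to-point ICP acquires a tangential-slide bias of 1.5–3 mm / 1.5–3°
(different poses sample the surface differently, and the eye sockets
self-occlude pose-dependently), violating the ≤ 1 mm / ≤ 1° tracking
contract; at a 2-mm pitch with a (104×92×72 mm) patch (~2100 reference
points) the full-sequence median error is ~0.25 mm / 0.55° with the 90th
percentile near 1.1°. Real Kinect-class sensors (512×424) are denser
still.

## ICP tracking

Point-to-point ICP: nearest-neighbour pairing of the (transformed)
reference-model points into the frame's ROI points, rejection of pairs
beyond 3× the median pair distance, closed-form Kabsch/SVD update;
convergence at < 1e-6 mm RMS change or 50 iterations. Source point sets
of effective rank < 3 (collinear or coplanar) are refused — rotation
about the degenerate axis is unobservable. Sequential tracking
initializes each frame's ICP at the previous frame's estimate
("pre-alignment"), which keeps correspondences valid across large steps;
frames with residual RMS > 10 mm or < 30 ROI points carry the last valid
pose and a flag, and three consecutive failures abort tracking. Rotations
beyond ~45° hide the eyes and nose from the camera and are out of the
tracking contract.

Tracking error is scored in the *head* frame: the camera-frame estimate
is conjugated through the true camera pose and compared to the generating
transform, translation measured at the head center. Scoring camera-frame
translations directly would multiply every rotation error by the ~600-mm
camera lever arm; the same lever-arm argument is why the motionless-period
search measures motion at a face-anchored point.

## Spatial calibration

1. **Motionless window**: earliest contiguous ~20 s in which every
   frame stays within 1 mm / 1° of the window's first frame (thresholds
   mirror the tracking accuracy; both configurable). If none exists, the
   largest cluster of near-identical poses is assembled from
   discontinuous frames and flagged non-contiguous.
2. **Reference PET**: list-mode events of that window reconstructed
   without attenuation correction.
3. **CT→PET registration**: multi-start Nelder–Mead over the six pose
   parameters, maximizing normalized cross-correlation between the
   reference PET and the CT soft-tissue mask (mutual information is a
   config alternative; the similarity metric is an open choice — no
   published value constrains it). Five starts at ±10 mm/±10°
   perturbations; runs that wander beyond 1.5× the perturbation radius
   are discarded as implausible (the CT–PET misalignment is physically
   bounded), guarding against remote spurious optima.
4. **Face models**: the CT skin isosurface (marching cubes after ~1.5
   voxels of smoothing — on near-binary masks unsmoothed marching cubes
   lands on voxel-edge midpoints, an orientation-dependent staircase that
   biases rigid fits by 1–2°), cut to the anterior half and the nose
   vicinity; and the camera's reference frame. The *whole visible face*
   is used for calibration (the contoured face area), while the tighter
   eyes+nose patch is reserved for tracking, where speed and occlusion
   robustness dominate.
5. **C_KP**: ICP maps the camera cloud onto the CT surface (the cloud is
   a strict subset of the face, so that pairing direction is well-posed);
   coarse initialization combines a facing-camera prior (nose-tip
   landmark + upright-camera orientation) with principal-axes candidates,
   each run near convergence before the best is selected — mirror basins
   of a face-like bowl can look better after a few iterations. Residual
   RMS > 3 mm raises a calibration failure.

The synthetic CT is rasterized at 1.5 mm regardless of the phantom grid
(clinical CT is sub-mm in-plane). This costs a small registration offset
against a reference image reconstructed from a coarser phantom
rasterization — two voxelizations of the same analytic truth carry
resolution-dependent surface shifts — but that offset is shared between
scans of the same phantom, whereas a coarse CT surface would bias each
scan's calibration ICP independently by 1–2°.

## List-mode simulation

Event times uniform; emission voxel ∝ activity, jittered uniformly within
the voxel; pose applied per event at its 0.1-s frame (camera and scanner
share the clock); isotropic direction; the chord's two intersections with
the detector cylinder (default: radius 250 mm, axial 220 mm, 48 rings ×
320 crystals) snapped to nearest crystal centers; chords missing the
axial extent are redrawn and counted. Optional: attenuation thinning
through the moved attenuation map, and an intrinsic-resolution blur of
the emission point (both off by default — the default chain therefore
needs no attenuation correction, matching the reference-image contract).
No scatter, randoms or dead time.

A geometric identity anchors correctness: transforming each moved-scan
LOR with the true inverse motion reproduces the static scan's *line*
distribution. It holds exactly only under near-complete axial acceptance;
on a short scanner, motion also modulates *which* events are detected
(per-pose acceptance), which endpoint correction cannot undo and this
package — like the time-independent sensitivity below — does not model.

## Reconstruction

List-mode MLEM/OSEM with Siddon's exact radiological path as the system
model (adjoint verified to 1e-9). Motion correction transforms both
endpoints of every event by `M_P(t)` once, before iterating. Updates are
the standard multiplicative EM step, subsets (default 8) interleaved in
time, voxels initialized to 1, non-negativity by construction. After each
full pass the sensitivity-weighted total activity equals the number of
events with non-zero forward projection (conserved to 1e-6 — a useful
invariant regardless of how good the sensitivity model is).

The sensitivity image is estimated by backprojecting ~4×10⁵ random
detector chords weighted by the integral-geometry Jacobian
`cos φ₁ cos φ₂ / L²` (uniform endpoint pairs otherwise over-weight long
oblique chords relative to the uniform line measure that isotropic
emission induces). Because the field is smooth at the centimetre scale it
is estimated on a ~6-mm grid, smoothed, and resampled to the
reconstruction grid; estimating it directly on a fine grid leaves
per-voxel Monte-Carlo noise that imprints multiplicatively on the image.
By default the sensitivity is motion-independent: corrected events live
in the reference frame, so reference-frame sensitivity applies. The
time-averaged sensitivity of full motion-compensated EM (each head-fixed
voxel's trajectory sampled through the static field) is implemented and
can be enabled per reconstruction, but measurement shows it does not
improve — and for comparisons against a head-fixed image slightly worsens
— the package's comparative metrics, because the comparison image shares
the motion-independent field's residual shape error. Its absence is one
reason corrected images do not reach exact statistical equivalence with
head-fixed ones.

Event endpoints snapped to crystal centers are spread uniformly over the
crystal face at reconstruction time (aperture modeling). Without this,
the finite discrete LOR set aliases against the smooth sensitivity
estimate and EM noise blows up at voxel scale.

Default grids: 140×140×112 at 2.0 mm (full size), with scaled-down
48³ at 4.0 mm for quantification experiments and 96³ at 2.0 mm for
profile analysis. The post-filter is a separable Gaussian, σ = FWHM /
(2√(2 ln 2)), reflect boundary (mass-preserving); default 4-mm FWHM.

Iteration counts are an explicit bias/variance choice at desk-scale
counts (10⁶ events is ~100× below a clinical scan): early EM passes are
bias-dominated and converge monotonically towards the truth, while voxel
noise grows without bound at higher iteration counts (an unregularized
uniform cylinder reconstructs at ~9 % central CoV after 2 passes but
~50 % after 30). Defaults: 4 iterations × 8 subsets for quantification,
2 × 8 for reference images.

## Evaluation

* **SUVR**: VOI mean / cerebellar mean; exactly scale-invariant. Before
  sampling, each reconstruction is rigidly co-registered to the phantom
  anatomy (same-modality NCC, small search range) and the labels carried
  through that transform — the analog of clinical PET-to-anatomical-scan
  co-registration before VOI template application. This absorbs the small
  global rigid offset a reconstruction inherits from its calibration
  chain; without it, test–retest agreement is limited by that offset
  rather than by the correction itself.
* **Peak-to-valley**: trilinear profile (0.5-mm steps) along the line
  through the two colliculus centroids extended 6 mm past each, placed
  after the same anatomical co-registration; ratio = mean of the two
  flanking local maxima over the central local minimum. "Structure not
  visualized" (no two peaks around a valley) maps to an error, or to
  ratio 1.0 in comparative workflows.
* **Test–retest**: OLS r² between paired SUVR vectors plus a separate
  through-origin slope.
* **Wilcoxon signed-rank**: exact two-sided p by enumeration of all 2ⁿ
  sign assignments (evaluated by convolution over doubled midranks; zero
  differences dropped, ties midranked); cross-checked against brute-force
  enumeration and the continuity-corrected normal approximation.
* **NRMSE**: RMS difference over the reference support (> 5 % of max),
  after mean normalization, relative to the reference RMS — list-mode EM
  does not fix absolute scale.

## What the experiments show — and what they do not

The synthetic world lets every stage be scored against exact ground
truth, which real data never provides. It emulates: geometric visibility
and occlusion, depth noise, Poisson counting statistics, detector
discretization, piecewise-stationary human-like motion, and a genuinely
unknown camera placement. It does not emulate: non-rigid facial motion
(expressions), scatter/randoms, detector normalization and dead time,
time-weighted sensitivity under motion, realistic cortical folding (VOIs
are smooth compartments), or CT Hounsfield physics. Passing tests
therefore demonstrate the correctness and internal consistency of the
correction chain under rigid motion and ideal detection physics, not
clinical image quality.

Problem sizes were chosen so the full suite runs on one CPU in tens of
minutes: 60–120-s scans, 10⁶–4×10⁶ events, 48³–96³ grids. The
contrast experiment uses 4×10⁶ events because at 10⁶ the Poisson noise
floor between two independent reconstructions (~0.35 NRMSE at 48³)
exceeds half the motion artifact itself, leaving the corrected-vs-
uncorrected comparison without discriminating power.

## Known limitations

* Point-to-point ICP between differently-sampled noisy patches carries a
  pose-dependent bias of a few tenths of a degree (occasionally ~1.5°
  for unfavourable pose/occlusion combinations); point-to-plane or
  symmetric objectives would reduce it but are deliberately out of scope.
* The motionless-period thresholds (1 mm / 1°) are set to the tracking
  accuracy, not derived from data.
* Registration accuracy is limited by the phantom's rasterization; on
  3-mm grids the similarity optimum is displaced by up to ~1.5° (shared
  across scans of the same phantom). This is an artifact of voxelized
  synthetic truth, not of the method.
* The uncorrected-scan peak-to-valley "ratio" is reported as 1.0 when no
  bilateral structure survives the motion blur; comparisons treat that as
  the floor.
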