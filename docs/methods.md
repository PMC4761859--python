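# Methods

This note documents the models, algorithms and numerical choices behind
graspkin: what each stage assumes, which parameters matter, what the
synthetic generators do and do not emulate, and the known limits.

## Signals and conventions

A trial is one cycle of the standardized drinking simulation: the hand
approaches the instrumented glass on the table, grasps it, transports
it to the mouth, and returns it. The IMU reports, at a nominal 87 Hz:
specific force **f** (m/s², sensor frame), angular velocity (deg/s),
and the firmware-fused orientation as Euler angles (degrees, intrinsic
Z-Y-X) and/or a unit quaternion. Euler angle Y is the sagittal-plane
tilt of the glass — the primary channel of the task, since drinking is
essentially a tilt toward and away from the mouth. Orientation is
taken as the firmware provides it; no sensor fusion is re-done here.
Gravity is fixed at g = 9.80665 m/s².

Gravity compensation rotates the specific force to the world frame and
subtracts gravity, `a_lin = R·f − (0,0,g)`; its magnitude ("resultant")
is the contact-detection channel. For any static orientation this is
exactly zero up to sensor noise, which the test suite verifies over
random orientations.

### Low-pass filtering

Acceleration is conditioned with a 4th-order zero-phase Butterworth
low-pass at 15 Hz (forward–backward `filtfilt`, so event times are not
delayed). The angle channel is passed through the same filter inside
the segmentation pipeline. The default `filtfilt` padding is far too
short at low normalized cutoffs; the pad is extended to about three
cutoff periods, which makes the filter exact on linear trends and
transparent (≲1e-6) for signals band-limited below half the cutoff.

## Event detection

* **A (contact)** — first local maximum of the filtered resultant above
  `contact_threshold` (default 0.02 m/s²). A band-limited contact
  transient *rings*: the magnitude of the zero-phase-filtered impulse
  has symmetric sidelobes, so all peaks within
  `peak_min_separation_s` (0.3 s) after the first qualifying one are
  treated as one transient and its largest peak is the event. This
  merge keeps detection monotone in the threshold (raising the
  threshold can only move A later).
* **B (onset)** — baseline tilt is the *median* over the 0.5 s before A
  (robust to spikes); B is the first time |θ_Y − baseline| exceeds
  `onset_angle_delta` (default 2°, configurable — the value is an
  empirical choice, echoed into every output) and stays above it for 3
  samples (debounce). The crossing is then refined to sub-sample
  precision with a local quadratic fit over ±7 samples, which also
  cancels the early-trigger bias noise induces in first-passage
  detection.
* **C (apex)** — global maximum of |θ_Y − baseline| after B. The raw
  argmax (earliest sample on exact ties) is exposed as the default of
  the standalone operation; the pipeline refines it with an iterated
  local quartic polynomial fit (window half-width `apex_refine_s`,
  0.35 s then 0.7× that). The quartic captures the cubic flank
  asymmetry of a smooth reversal exactly on noise-free data while
  averaging noise; windows were sized for minimal noise-free bias
  (<1 sample) and worst-case noisy error under 2 samples.
* **D (table contact)** — first qualifying resultant peak (sidelobe
  merged as for A) after C + 0.3 s.
* **E (orientation return)** — first debounced time after C with
  |θ_Y − baseline| back under the onset threshold, refined like B.

The trial end is D by default (`end_rule="table_contact"`); the
orientation-return criterion is retained as an alternative because
either event can legitimately close the trial, and it is the robust
choice when the accelerometer carries large movement accelerations
(see *Limitations*). Phase durations are A→B, B→C, C→end; percentages
are computed from the same total and therefore sum to 100 exactly.

## Kinematic metrics

**Movement units.** The speed profile's acceleration–deceleration
pulses are counted with the classical hysteresis rule: a running
maximum followed by a drop greater than the threshold is one unit; a
rise greater than the threshold re-arms the counter. Sub-threshold
oscillations are thereby ignored on both flanks, the terminal
deceleration to rest counts through its own maximum, and any nonempty
profile yields at least one unit. The count is non-increasing in the
threshold. The default channel is the *rotation speed* |dθ_Y/dt|
(central differences on the tilt after a 5 Hz zero-phase smooth —
voluntary reach movements live well below that), with an 8 °/s
threshold; the classical translational channel (40 mm/s) is available
via the reconstructed path. Units are counted over the transport phase
by default; pass a different window for full-cycle counts.

**Path reconstruction and straightness.** Sagittal-plane linear
acceleration is integrated twice over a phase window with
zero-velocity boundary conditions at both ends (the glass rests on the
table and is momentarily still at the mouth); drift is removed as a
linear velocity ramp between the endpoints. The straightness index is
the chord/arc ratio of the resulting path — 1 for a perfectly straight
reach — and is invariant under rigid motion and uniform scaling (the
floating-point ratio is clamped at 1). Straightness is reported as NaN
when the accelerometer carries no translational signal (< 1 µm of
reconstructed travel): rotation-only recordings cannot support a
path-based index.

**Energy expenditure.** Accelerometer activity counts,
∫‖a_lin‖ dt over a phase window (trapezoidal rule, arbitrary units).
The convention is additive over adjacent windows and monotone in
signal amplitude; no metabolic conversion is attempted.

**Group summaries.** Mean ± SD per group (age and/or gender) as a
metrics × groups table; a single-record group reports SD = 0. No
inferential statistics are computed.

## Grasp vision

**Mirror model and unwrapping.** The mirror annulus (principal point,
inner/outer radii) maps image radius to cylinder height. The true
single-viewpoint mapping of the hyperbolic mirror can be supplied as a
monotone calibration table; the default is linear interpolation
between (inner radius → cylinder top) and (outer radius → boundary of
the rejected band). The bottom 30 mm of the 100 mm cylinder are
excluded by construction: the mirror compresses them into too few
pixels to be usable. Unwrapping samples, for output pixel (row, col),
azimuth θ = 360°·col/W and height h = 30 + 70·row/H mm with bilinear
interpolation; pixels outside the annulus are flagged invalid, never
extrapolated. The panorama is *metric*: 140 mm circumference × 70 mm
height regardless of pixel counts, with column 0 adjacent to column
W−1 on the cylinder. Round-trip accuracy (forward-render a pattern,
unwrap, locate it) is ~0.15 px RMS.

**Annulus auto-calibration.** Otsu threshold → bright-region centroid
(the annulus is rotationally symmetric, so the centroid is its center)
→ radial mean-intensity profile → half-maximum edges with sub-bin
interpolation. Intended to seed the model; a measured configuration
overrides it.

**Skin segmentation.** sRGB → CIELAB (D65), then Lloyd K-means with
k = 3 and Euclidean distance on the (a\*, b\*) chroma plane — dropping
L\* makes the partition insensitive to lighting and sheen; full-Lab
clustering is a switch. Ten seeded restarts; the partition (not the
label indices) is the meaningful output. The skin cluster is the
centroid nearest a configurable reference chroma (default
a\* = 14, b\* = 17, a mid-tone locus). Skin tones vary: the reference
should be calibrated per cohort from one labeled frame. If no centroid
lies within 12 chroma units of the reference the frame is treated as
containing no skin (empty mask) rather than mislabeling glass or
background. Components smaller than 25 px are removed as speckle; the
grasp area is the remaining pixel count × metric pixel area.

**Key instants.** For each event A–E the nearest frame by timestamp is
unwrapped and segmented; an event farther than two median frame
periods from any frame is skipped with a warning rather than
interpolated.

## Synthetic generators

**Trials.** The tilt follows minimum-jerk segments — the standard
primitive of reach kinematics — with the transport rise split into
`n_movement_units` equal sub-movements (velocity peaks). The reversal
at the mouth carries a nonzero angular acceleration (quintic boundary
conditions, sharpness 4·ΔA/ΔT² by default): a child tips the glass
back in one continuous motion rather than pausing dead, and a
dead-stop apex would be ill-defined at sample resolution. The
accelerometer contains gravity rotated by the (noisy) orientation plus
30 ms raised-cosine contact impulses (0.5 m/s²) at grasp and table
contact. Orientation noise enters the Euler channel and the specific
force *consistently* — a real IMU's fused orientation and
accelerometer agree — so gravity compensation residuals reflect
accelerometer noise, not orientation noise. Translational specific
force for the ~250 mm table→mouth reach is opt-in
(`translation_in_acc`), because movement acceleration (~1 m/s²) swamps
the 0.02 m/s² contact threshold and masks the table-contact peak; the
reach is always recorded in the ground-truth path for path-metric
tests.

Ground-truth events are *definition-consistent*: the latent movement
start is placed so the noise-free tilt crosses the onset threshold
exactly at the configured accommodation end (and the analytic
return-crossing gives E), so the configured phase durations are the
true, recoverable ones. Noise defaults — 0.3° RMS orientation jitter,
0.005 m/s² per-axis accelerometer noise, 0.1 °/s gyro noise — are
typical figures for a consumer AHRS module.

**Cohorts.** Per-trial totals and phase splits are sampled from the
typical child statistics (total 2.55 ± 0.6 s; split
13.33/43.24/43.43% with SDs 6.05/7.41/7.73), truncated to keep each
trial feasible and renormalized to 100%; apex angles ~N(45°, 8°);
movement-unit counts drawn from per-age pools that shrink with age
(2–3 units at 5–7 years, 1–2 at 8–10). This *emulates* the cohort
structure of a typically developing 5–10-year-old sample; it does not
reproduce any real recording.

**Frames.** Skin-colored finger bands specified on the cylinder
surface are forward-projected through the mirror model onto the
annulus over glass/background colors (CIELAB: skin (65, 14, 17), glass
(75, −5, −12), background (35, −12, 6) — three well-separated chroma
loci), Gaussian chroma noise (σ = 3 by default) is added, and the
ground-truth mask is recorded in panoramic coordinates. The default
band layout is deliberately offset from exact sample-grid alignment so
the ground truth is not ambiguous at pixel boundaries. Recovery
experiments sample the panorama at 720 × 280 so band-edge mixing
(which scales inversely with resolution) stays well below 1% of
pixels.

What passing these tests shows — and what it does not: the detectors
and the vision chain are exact and robust against the *modeled*
effects (sensor noise, filter transients, discretization, chroma
noise). Real recordings add un-modeled structure: orientation drift
and cross-axis coupling, hand tremor, partial occlusion of the mirror,
specular highlights, clothing in the scene, inter-subject skin-tone
variation. Results on synthetic data bound the algorithmic error, not
the device error.

## Problem sizes

The standard experiment sizes are: 200 trials for event recovery
(noise at 0.005 m/s² / 0.5°, the upper end of the modeled sensor
class), 1000 random profiles for the movement-unit oracle, 100 static
orientations for gravity compensation, 20 rendered frames for
segmentation recovery, and one 48-trial cohort (6 age groups × 8).

## Known limitations

* Multi-cycle recordings must be split upstream; the event chain
  assumes one cycle per trace.
* With `translation_in_acc` enabled (or on real recordings with large
  movement accelerations), the table-contact rule can latch onto
  movement-deceleration peaks; close such trials with
  `end_rule="orientation_return"`.
* The default radius↔height mapping is linear; accurate metric areas
  on a real device need the measured mirror calibration table.
* Skin-mask components are labeled without azimuth wrap-around, so a
  component split exactly at column 0/W−1 may be size-filtered in two
  halves.
* The qualitative grading of thumb opposition from the posture images
  is a visual procedure and out of scope; the package stops at the
  masks, areas and key-instant panoramas.
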