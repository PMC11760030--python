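# Methods

## The measurement model

`gaitkit` treats gait analysis as a signal-measurement problem on landmark
trajectories. The input is a time series of named body landmarks — 2D
pixel coordinates with per-sample visibility from a pose estimator, or 3D
millimetre coordinates from a capture system. All image-plane logic
assumes the pose-estimator convention: origin top-left, y increasing
downward. Frame k of a trajectory occurs at k/frame_rate seconds from that
trajectory's own epoch; alignment across recording systems is done only by
explicit trimming (`trim_sync`), never implicitly.

Missing data are explicit gaps (NaN coordinates, zero visibility), never
sentinels. A sample can be a gap either because the file said so, because
its visibility fell under a configurable floor, or because despiking
removed it.

### Preprocessing

The conditioning order is fixed: despike → interpolate → filter.

* **Despiking.** A sample is a spike when the magnitude of the central
  second difference of its landmark's position exceeds a threshold
  (pixels/frame²). No universal threshold works across pixel scales, so
  the default is 5× the median absolute second difference of that
  landmark's own series (with a tiny absolute floor so a noiseless series
  does not flag everything); a fixed threshold can be supplied.
* **Gap filling.** Gaps up to `max_gap_frames` (default 10 ≈ 0.33 s at
  30 fps) are filled with a not-a-knot cubic spline over the valid
  samples — exact for cubic trajectories, which is what the unit tests
  exploit as an oracle. Longer gaps are left open deliberately: cubic
  interpolation across a long occlusion fabricates motion. Gaps at the
  series ends are never extrapolated.
* **Low-pass.** Zero-lag filtering is forward–backward application of a
  4th-order Butterworth (cutoff 5 Hz), which squares the magnitude
  response and cancels phase; the effective gain of the two-pass filter
  is 1/(1+(f/fc)^(2n)). That closed form describes the *analog*
  prototype; the discrete filter attenuates strongly warped frequencies
  (e.g. 10 Hz at a 30 Hz rate, two-thirds of Nyquist) even more. The
  oracle test therefore checks the analytic response at a 240 Hz sampling
  rate, where warping is negligible, and separately checks that the
  video-rate attenuation is at least the analytic value.
* **Downsampling** decimates when the rates divide (240→30 keeps every
  8th frame, starting at frame 0) and resamples linearly otherwise. No
  separate anti-alias filter is applied: in the intended order the 5 Hz
  low-pass has already removed everything above the target Nyquist.

### Events

Heel strike and toe-off are the extrema of the foot's progression-axis
position relative to the hip centre (mid-point of the two hip landmarks):
maxima → heel strikes, minima → toe-offs. Whether the cited peak-detection
convention places heel strike at the positive peak or at a zero crossing
is not recoverable from the validation literature alone; the positive-peak
reading is implemented. Peaks need a prominence of at least 25% of the
signal's interquartile range (scale-free, drift-tolerant) and must be at
least `min_stride_s` apart (default 0.6 s — a cadence ceiling of 200
steps/min; closer peaks are split peaks, and the larger one is kept).
Strict HS/TO alternation is enforced by dropping the weaker of two
same-type neighbours. Events are stamped at the peak sample, so timing
error is bounded by one frame; parabolic sub-frame refinement exists
behind a flag but is off by default, keeping the default behaviour
honestly frame-quantised.

Signals with unfillable occlusion holes are linearly bridged for peak
finding only; any event whose peak lies within two frames of bridged
samples is discarded as fabricated, and the bilateral pairing stage then
drops the cycles those events would have anchored.

For a near-frontal camera, progression runs along the optical axis and the
forward foot is the nearer, larger-projected one. Heel strikes are taken
from the heel's vertical image coordinate relative to the hip centre and
toe-offs from the toe's: the heel's extreme coincides with ground contact
and the toe's most-retracted, highest projection with lift-off, which is
also why a frontal view resolves temporal parameters well while spatial
parameters are geometrically unavailable from it (the package raises a
documented error rather than guessing). Orientation (approaching vs
receding, facing direction) is estimated from the data — trunk-size trend
for frontal, toe−heel offset for lateral — and can be overridden.

Overground bouts with direction reversals are first segmented into
straight passes by the sign of the smoothed hip-centre progression
velocity (runs ≥ 1 s; the proxy for a frontal camera is apparent trunk
size). A 0.5 s guard band is trimmed from each end of every pass because
steps adjacent to a turn are corrupted by the turning motion and the
camera-angle transition.

### Parameters

Temporal parameters are pure event arithmetic (definitions in the
README); stance + swing = stride holds exactly by construction, and
cadence is defined per cycle (60/step time) so that stride-by-stride
analysis has a cadence value to work with.

Step length is the heel-to-heel progression separation at the strike
instant. The heel is used rather than the ankle because heel and toe are
the landmarks a frontal/lateral camera sees best at the contact events
(configurable to ankle). The instantaneous-separation convention is exact
overground — the trailing heel is planted at its own strike position — and
on a treadmill equals belt speed × step time, i.e. the belt-referenced
step length, so one definition serves both modes; whether a
belt-speed-corrected alternative would match a given lab's convention is
flagged as an open choice. Because event times are frame-quantised while
the trailing heel moves at walking speed (~0.75 m/s, so half a frame is
~1 cm), the strike instant is refined to sub-frame precision with a
parabola through the striking heel's hip-relative progression before the
separation is sampled.

### Kinematics

Joint angles are interior angles at the middle landmark of a triplet
(hip: shoulder–hip–knee; knee: hip–knee–ankle; ankle: knee–ankle–foot,
with the toe as the default foot point since it defines the conventional
foot-segment direction). They are mapped to signed conventions — hip and
knee flexion positive with extension at 0°, ankle dorsiflexion positive
with the neutral (shank ⟂ foot ray) at 0°. Published comparisons report
ROM magnitudes only, so any consistent sign convention reproduces them;
signs come from the triplet's orientation (2D cross product) combined
with the facing direction. 2D video angles live in the image plane; 3D
capture angles are projected onto the progression × vertical plane first.
ROM is per-cycle max − min between consecutive ipsilateral heel strikes,
summarised as mean ± SD across cycles (per-trial max − min would be the
other defensible reading; per-cycle is implemented). Cycles with under
half their angle samples present are skipped.

### Agreement

Cycles are matched one-to-one between systems by greedy nearest-neighbour
pairing of heel-strike times within 0.25 s — under half the minimum
stride bound, so a match cannot skip a cycle. Differences are
candidate − reference throughout. MAE is the mean ± SD of absolute
differences; the regression is OLS of candidate on reference with Pearson
r reported alongside the slope (validation tables in this literature
print a single "linear regression (R)" number that sometimes exceeds 1,
which r cannot — the value must be a slope, so both are emitted and either
reading can be compared); Bland–Altman limits use the sample (n−1) SD.
Participants-mean aggregation averages each subject's matched cycles
before computing statistics; all-step pools every matched cycle. Since
subject averaging removes within-subject noise, participants-mean errors
are systematically ≤ all-step errors — one of the structural properties
the acceptance suite checks.

## The synthetic gait generator

The generator exists because every stage above needs data with *exact*
known answers. It is kinematically prescribed, not dynamically simulated —
it tests measurement code, not biomechanics.

The construction works backwards from what event detection measures. A
monotone phase warp maps stance ([0, stance_fraction] of the stride) to
the first half-period of a cosine and swing to the second; the ankle's
progression position relative to the hip is that warped cosine (plus a
backward baseline offset). Its forward extreme therefore falls *exactly*
at heel strike (phase 0) and its backward extreme exactly at toe-off
(phase = stance fraction), which is what makes ground-truth events exact
by construction rather than themselves the output of a peak finder. An
earlier design that prescribed hip/knee Fourier waveforms and ran forward
kinematics was abandoned: at realistic amplitudes the ankle-relative
signal's global minimum lands in mid-swing, not at toe-off (as it does in
real data, where minima-based toe-off detection is biased late), and no
exact event ground truth survives that.

Around the prescribed ankle path: ankle height follows a flat-foot /
late-stance heel-rise (toe-pivot) / swing-clearance profile built from C¹
smoothstep segments; the pelvis bobs twice per stride (±2 cm), lowest at
mid double support so it is falling through both heel strikes; hip and
knee positions come from two-link inverse kinematics (knee bowing
anteriorly), raising a hyperextension error naming the offending frame if
the prescribed pose exceeds the leg's reach; stance foot pitch is the
prescribed heel rise, while swing foot pitch rides with the shank so the
measured ankle angle follows a smooth profile instead of inheriting the
shank's full swing. Joint-angle ranges are consequences of this geometry.
With the defaults (0.55 m steps, 0.44 m thigh and shank, 0.935 m hip
height) they land at knee ≈ 50°, ankle ≈ 22°, hip ≈ 38° — knee and ankle
near typical side-view reports (≈55°/24°), the hip a little above the
≈29° such studies print because the model's trunk is rigid (no pelvic
tilt absorbs thigh excursion) at this step length.

Default study conditions: stride time 1.1 s, stance fraction 0.62, step
length 0.55 m, 30 s treadmill bouts at 30 fps; cohorts draw stride time
~ N(1.1, 0.1²) s, step length ~ N(0.55, 0.08²) m (clamped to the leg's
reach), stance fraction ~ N(0.62, 0.015²). Overground bouts run
2 round trips over a 6 m walkway with 1.5 s turns during which the phase
freezes; cycles spanning a turn are excluded from ground truth.

Observation models: the lateral camera is orthographic at 320 px/m
(~1920 px across a 6 m walkway) and also projects two floor marks 6 m
apart as the scale-calibration pair; the near-frontal camera is a pinhole
at 3.5 m from a treadmill subject (or beyond the walkway's far end
overground), so progression modulates depth; the capture system reports
millimetres at 240 Hz, noiselessly. An optional radial-quadratic
distortion term (default off) emulates a wide-angle lens; it bends both
the landmarks and the calibration pair, which is what degrades
step-length recovery when enabled. Pose noise is Gaussian jitter (default
σ = 2 px), sparse spike outliers, and an AR(1) visibility score per
landmark whose mean follows per-landmark occlusion profiles typical of
each camera placement — on a left-side treadmill view the far (right) knee
averages ≈0.27 visibility against ≈0.92 for the near knee — with samples
under 0.5 dropped to gaps and jitter inflating as visibility falls. All
randomness flows through one seeded generator; identical seeds give
bit-identical cohorts.

What the generator does **not** emulate: soft-tissue and marker-placement
artefact, pose-model bias (its errors are zero-mean by construction,
where real HPE systematically misplaces joints), belt-speed variability,
true 3D out-of-plane motion, pathological gait phenotypes, and rolling
foot contact (the treadmill "belt" motion is the cosine sweep of the
relative path, not a constant-velocity segment). Passing tests therefore
demonstrate that the *measurement chain* is correct and noise-robust
under a faithful observation geometry — not that any specific clinical
accuracy claim transfers to real recordings.

## Problem sizes and determinism

The shipped acceptance runs use a 24-subject treadmill cohort (30 s each,
≈27 strides/subject), a 12-subject near-frontal cohort, and an 8-subject
distorted-camera cohort — enough cycles (~650 pairs pooled) that the
aggregation-ordering and asymmetry comparisons are stable across seeds
while the whole acceptance script stays in the tens of seconds on one
CPU. Every simulation, test, and script takes an explicit seed;
`run_pipeline` writes a manifest (config hash, seed, version, warnings)
from which a run can be reproduced bit-identically.

## Known limitations

* Events are frame-quantised by default, so stance/swing/double-support
  carry up to ~1 frame of systematic error each; stride and step times
  are differences of like-quantised events and largely cancel it.
* Treadmill step length is belt-referenced; comparing against a lab that
  measures absolute foot displacement requires a convention check.
* The hip-angle ROM of the default synthetic gait runs high (see above).
* Near-frontal agreement assumes the subject walks roughly along the
  optical axis; oblique approaches mix progression into the image x-axis
  and are not modelled.
* Pass segmentation assumes clean direction reversals separated by ≥1 s
  of consistent travel; shuffling or festinating turns would need a
  different segmenter.
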