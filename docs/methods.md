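# Methods

This note documents the models, conventions and numerical choices behind
`planargait`, and what the synthetic validation does and does not show
about real data.

## Coordinate conventions

Image pixels have their origin at the top-left, +u rightward, +v
downward. The world frame is +x along the walking direction, +y up, in
millimetres; the vertical flip between the two happens in exactly one
place (`camera.side_pixels_to_world`). The walkway centre sagittal plane
is the world x–y plane.

## Camera model and its central approximation

The side camera is modeled as an ideal pinhole with Brown radial
distortion (`k₁`, `k₂` on radii normalized by the focal length, so both
are dimensionless). Distortion inversion is a fixed-point iteration with
tolerance 1e-9 px and a 100-iteration cap; with zero coefficients the
inverse is exact and immediate. A stitched multi-camera rig is modeled as
a single equivalent wide-image pinhole (the default side camera is a
7200 × 1080 panorama at 2 mm/px on a walkway 4 m away): stitching happens
upstream of pose estimation, so keypoints arrive seamless.

**Single-plane back-projection.** Every keypoint is assumed to lie in the
subject's sagittal plane at depth `Z = D − δ`. This is the defining
approximation of a 2D system, and its consequences are visible in the
package's own output: limbs actually lie about half a hip width
(±100 mm) off that plane, so left- and right-side lengths are scaled by
`Z/(Z∓w/2)` — about ±2.5% at `Z = 4 m`. Stride length (same-limb
differences) is biased per side but the across-side mean cancels to first
order; step length (cross-limb differences) picks up a
position-dependent error and is therefore the least accurate spatial
parameter. Joint angles are immune: a wrong depth rescales a limb's
keypoints uniformly, and angles are similarity-invariant.

**Front camera.** The mm/px scale is stature divided by the head-to-ankle
pixel span in a standing calibration pose. Because the projection is
perspective, that scale is exact only at the calibration depth; the
subject's mediolateral offset is taken as the median over the trial,
which coincides with the calibration-depth value for a pass roughly
symmetric about the walkway centre. The estimated offset feeds the side
camera's depth, removing the `Z/(Z−δ)` length bias that an uncorrected
off-centre subject would produce.

## Angle conventions

Hip: signed angle from the downward prolongation of the trunk vector
(shoulder→hip) to the thigh vector (hip→knee); flexion (knee forward)
positive. The trunk — not gravity — is the reference because a
keypoint-only system has no pelvis landmarks; a `reference="vertical"`
switch exists for sensitivity analysis. Knee: signed angle from the thigh
prolongation to the shank (knee→ankle); 0 at full extension, flexion
positive, hyperextension negative. Extension peaks are reported signed
(series minima), with magnitudes additionally available, matching the
reporting convention in which hip extension is printed as a positive
magnitude but knee extension as a signed value. Flexion signs follow the
walking direction (inferred from net hip displacement), so a subject
walking in −x is handled by an internal mirror, not by the caller.

No smoothing is applied to angle series by default; an odd-window moving
average (default width 5 when enabled) is available.

## Event detection

The cycle event is the mid-swing ankle-under-hip crossing: a
negative→positive zero crossing of `d(t) = x_ankle − x_hip`, gated by the
ankle's forward velocity exceeding `v_min` (default 20% of the mean hip
speed over the pass). The stance-phase reverse crossing — the hip passing
over the planted foot — fails both the crossing direction and the gate.
Event times are refined by linear interpolation of `d` between the
bracketing frames; `d` is near-linear mid-swing, so linearity makes the
sub-frame time essentially exact. Velocities come from a Savitzky–Golay
first derivative (quadratic, 0.25 s window), which keeps the stance gate
usable under pixel noise where raw frame differences would not be.

Foot placements are maximal runs with ankle forward speed below
`v_stance` (default 100 mm/s) lasting at least 0.1 s; the placement is
the median ankle x over the run. Cycles in which more than 20% of the
required-node samples were gap-filled are flagged invalid and excluded
from aggregation.

Analysis assumes a monotone straight pass; splitting back-and-forth
trials into passes is the caller's responsibility.

## Parameters and aggregation

Stride time is the inter-event interval; stride length the distance
between the successive ipsilateral placements around the cycle's stance;
step length the contralateral-to-preceding-ipsilateral distance; gait
speed is stride/stride-time, so the identity
`speed = stride_mm/1000/stride_time` holds exactly per cycle (a
hip-displacement speed is deliberately not used). Group tables reduce
each subject to its per-parameter mean before taking the across-subject
mean and sample SD (ddof = 1); per-cycle pooling is available via a flag.

## Agreement statistics

ICC forms follow the Shrout–Fleiss definitions from ANOVA mean squares
(`BMS`, `JMS`, `EMS`, `WMS`): ICC(1,k) = (BMS−WMS)/BMS, ICC(3,k) =
(BMS−EMS)/BMS, ICC(2,k) = (BMS−EMS)/(BMS+(JMS−EMS)/n), plus the
single-measure variants needed for variance-component recovery studies.
CIs are the F-based formulas (for the two-way random form, the
Satterthwaite degrees of freedom with a Spearman–Brown step-up from the
single-measure bounds); p-values test H0: ICC = 0 via the corresponding
F test. Cronbach's alpha is computed independently from column/row-sum
variances and is verified to equal ICC(3,k) to 1e-12 — a structural
identity, not a coincidence of any dataset. With a zero error mean
square the F statistic is infinite: p is reported as 0 and the CI
collapses onto the point estimate, while the point estimates remain
defined (a column offset still penalizes the absolute-agreement forms).

The agreement regression treats the camera system as the independent
variable and the reference as dependent; slope/intercept CIs use the t
distribution with n−2 df. Proportional bias ⇔ the slope CI excludes 1;
fixed bias ⇔ the intercept CI excludes 0. Classification bands are
lower-closed intervals: ICC <0.5 poor / 0.5–0.75 moderate / 0.75–0.9
good / ≥0.9 excellent; r 0.2–0.4 small / 0.4–0.7 medium / ≥0.7 large
(an alternative 0.1/0.3/0.5 convention is available as `r_alt`; two
conventions circulate and the package defaults to the stricter one); R²
0.04–0.16 small / 0.16–0.5 medium / ≥0.5 large; alpha acceptable at
≥0.7. SEM = SD·√(1−ICC), MDC95 = 1.96·√2·SEM. p-values are formatted to
three decimals with "<0.001" below. Incomplete paired rows are removed
listwise before matrix construction.

The OLS fit itself is delegated to `scipy.stats.linregress`; the ICC
battery is implemented here and cross-checked in the test suite against
an explicit-loop ANOVA oracle and against `pingouin.intraclass_corr`.

## The synthetic walker

The simulator drives a trunk–thigh–shank chain with joint-angle
templates: a single-harmonic hip (peaking at stance onset and
mid-cycle) and a knee that holds its extension peak through stance and
traces a raised-sine flexion bump through swing. A single-support stance
constraint closes the loop: while a leg is in stance its ankle's forward
position is pinned to the foot placement and the hip's forward position
follows from that leg's template angles, exactly as a body vaulting over
its planted foot. This makes three things exact by construction: the
stance ankle is stationary in x, successive placements are spaced half a
stride, and the angle series measured back from the generated keypoints
reproduce the template peaks.

The requested stride length and the angle template over-determine the
leg geometry, so both leg segment lengths are rescaled by the single
factor that realizes the requested stride under the template sweep
(≈1.01 for the comfortable defaults, ≈0.75 for tandem — real tandem
walkers shorten their effective step through mechanisms the template
does not model). The head keypoint is placed so that the standing
head-to-ankle distance equals the configured stature, making the
front-camera calibration exact. Degenerate zero-amplitude templates
produce a rigidly translating figure ("statue"), on which cycle
detection correctly fails.

Style defaults (stride, cycle time, angle peaks, lateral foot spacing)
are anchored to published camera-system group means for comfortable,
maximum-speed and tandem walking: comfortable 1400 mm / 1.047 s with hip
+30.3/−18.8° and knee +65.7/+2.5°; max 1617.6 mm / 0.86 s; tandem
670.2 mm / 1.17 s with feet nearly in line. These are calibration
anchors for realistic simulation, not claims about any dataset. The
generator default is 10 strides at 60 fps (a common industrial-camera
rate; frame quantization of single-frame peak picking stays well under
0.2° there). Noise is i.i.d. isotropic Gaussian in pixels, with optional
per-node dropout; confidences are uniform in [0.5, 1].

What the simulator does **not** emulate: out-of-plane limb motion
(beyond static lateral offsets), trunk lean and pelvic rotation,
double-support, soft-tissue or pose-estimator-specific error structure
(correlated jitter, left/right swaps), and vertical ground contact
dynamics (the stance ankle may drift vertically by a few cm while pinned
horizontally). Passing tests therefore demonstrate the correctness of
the geometry, event logic and statistics — not that a real pose
estimator achieves these error levels.

The paired-systems generator draws subject truths
`τ ~ N(μ, σ_b²)`, gives system 1 `τ + e₁` and system 2 `a + b·τ + e₂`,
and returns the closed-form variance-component ICCs for `b = 1`:
ICC(2,1) = σ_b²/(σ_b²+a²/2+σ_e²) with the column component `a²/2` absent
from ICC(3,k) ≡ alpha.

## Numerical and design choices

- Pose I/O stores time in float seconds with fps cross-checked against
  timestamps (tolerance half a frame); generic streams default to
  30 fps when the rate cannot be inferred. Missing keypoints are an
  explicit boolean mask (CSV sentinel: empty cells); confidence below
  0.1 is coerced to missing. CSV round trips are exact via `repr`
  serialization and round-trip float parsing.
- Gap filling interpolates runs of ≤3 frames (default) per node per
  axis, never extrapolates past the first/last present sample, and is
  idempotent.
- `detect_cycles` refuses direction-ambiguous passes (net hip
  displacement under 100 mm).
- Reported problem sizes: the validation harness simulates 10-stride
  trials (18 cycles across both limbs), 100–200 paired-design
  replicates at n = 500, and 1000-replicate CI-coverage runs — sizes at
  which every Monte-Carlo check is stable to well inside its tolerance.

## Known limitations

Step length inherits the largest single-plane error (see above).
Hip-angle values are trunk-referenced and therefore not directly
comparable to pelvis-referenced conventions of marker-based models —
between-convention offsets of several degrees are expected and are a
property of the angle definition, not a bug. Transverse- and
frontal-plane quantities are out of reach of a sagittal 2D system and
are not computed. Regression constants are reported in the
measurement's native units.
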