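# Methods

## Model

A standing human is modelled as nine rigid segments in a tree rooted at the
torso: torso (head and neck merged in), right/left upper arms, right/left
forearms (hands merged), right/left thighs, right/left shanks (feet merged).
The merges follow the segments a consumer depth camera can actually track;
the head is folded into the torso because its small range of motion barely
moves the whole-body CoM.

Frame conventions (fixed here; they are a free choice of the method):
global x is anterior (AP), y points toward the subject's right (ML), z is
vertical; the ground is z = 0. Each segment's local z-axis runs from its
proximal to its distal joint, so limb CoM offsets are on-axis vectors
(0, 0, c_z). The torso root origin is the mid-hip point, which both the
skeleton-to-posture conversion and the simulator use consistently; users of
trackers that report a "torso" joint instead can remap before conversion.

The direct (oracle) CoM is the mass-weighted mean of segment CoM positions,

    C = (1/M) * sum_i m_i (A_i c_i + d_i),

with A_i the segment orientation, c_i its local CoM offset and d_i its frame
origin from forward kinematics. Rearranged, C is the end effector of a
serial chain attached to the torso. Restricting limb CoMs to the bone axis
and assuming bilateral symmetry (left/right pairs share mass, length and CoM
offset) collapses the chain to seven constants:

    C - d0 = A1 r1 + (a2+a4) r2 + (a3+a5) r3 + (a6+a8) r6 + (a7+a9) r7,

where a_i is the third column of A_i. `true_sesc_from_model` computes these
constants for a known body model; the torso parameter collects the torso CoM
plus each limb attachment point weighted by the mass of the *entire limb
chain* hanging from it (for the right arm: d12 (m2 + m3)). With that
grouping the chain estimate equals the direct CoM to machine precision for
every symmetric model and posture — the package's central invariant, tested
over a thousand random bodies.

## Identification

The CoP measured during quiet static stance equals the CoM ground
projection, so each held posture contributes two rows (x and y) of the
linear system y = D R, with y the root-relative CoP and D built from the
torso rows and summed limb-pair axis directions. The least-squares solution
uses the SVD pseudo-inverse with a relative singular-value cutoff of 1e-10;
a regressor of column rank below seven raises a rank-deficiency error
(callers may override to obtain the minimum-norm solution with a warning).
Rank, not a posture count, is enforced: two rows per posture mean four
generic postures already suffice for rank 7, and practical protocols use
many more to average noise. The z-components of the parameters are
identifiable from ground measurements alone because limb axes tilt into the
ground plane across varied postures.

Static windows are found by sliding a 1-s window (step one sample) over the
aligned streams; a window is static iff every CoP axis has standard
deviation strictly below 3 mm and every segment's orientation dispersion —
the rms geodesic angle to the window's mean rotation — stays strictly below
5 degrees. Overlapping static windows are merged and averaged over their
union. Two numerical points matter here:

* **Averaging is kept linear.** The regressor entries are linear in the
  rotation-matrix entries, and CoP = root + (B R) is linear too, so the
  identification rows of a window are the exact time-average of the
  per-sample rows. Each `StaticWindow` therefore stores `mean_regressor`,
  the average of per-sample regressor blocks, alongside a `mean_posture`
  whose averaged rotations are projected back to SO(3) by the nearest
  rotation (used for estimation and display, where a proper rotation is
  required). For the same reason resampling and zero-phase filtering of
  rotation streams operate entrywise without re-projection. The payoff is
  exactness: on noiseless data the full resample → filter → detect →
  identify pipeline returns the true parameters to ~1e-16 m even though
  slowly-moving transition-edge samples below the static thresholds enter
  the averages.
* **Limb frames are twist-free.** Two joints determine a bone direction but
  not the twist about it. The conversion completes each limb frame with the
  minimal rotation carrying the hanging direction (0, 0, -1) onto the bone —
  continuous in the bone direction except for a bone pointing straight up
  (x-axis Gram-Schmidt fallback). A thresholded reference-vector fallback
  was rejected: near the threshold the completion's twist jumps ~90 degrees
  between noisy samples, inflating the geodesic dispersion far past the
  5-degree static criterion for near-vertical limbs. CoM estimation itself
  only uses bone directions, so the completion choice cannot bias results.

Streams are aligned by spline interpolation onto a shared 15 Hz grid over
their overlapping span (cubic where enough samples exist; exact for affine
signals) and low-pass filtered with a zero-phase, forward-backward
second-order Butterworth at 5 Hz (amplitude 1/2 at the cutoff: -3 dB applied
twice; sub-millisecond timestamp jitter, e.g. from CSV quantization, is
tolerated when checking grid uniformity). No cross-correlation
synchronization is attempted; both sensors are assumed time-stamped on a
common clock.

## Quality diagnostics

Treating identification as the linear model y = D x + noise with r rows and
c = 7 columns: residual variance s² = ||y - D x||²/(r - c); parameter
covariance s² (DᵀD)⁻¹ evaluated through the SVD; per-parameter standard
deviation, relative standard deviation (percent of the estimate), the
k-ratio of each relative standard deviation to the smallest one, and a
two-sided Student-t coefficient test with r - c degrees of freedom. The
conventions follow standard experimental-identification practice: k > 10
flags a poorly identified parameter, p > 0.01 flags an insignificant one,
and the default condition-number threshold of 20 bounds the range observed
for well-excited 40-posture protocols (simulated sessions land around
12–18). Relative standard deviations are meaningful relative to each other;
only the k-ratio and p-value carry absolute decisions. Degenerate cases: an
exact fit reports zero dispersions and unit k-ratios; a parameter estimated
exactly at zero reports infinite relative standard deviation (flagged),
t = 0 and p = 1. On noisy synthetic identifications the forearm parameter
r3 — two orders of magnitude lighter than the torso term — systematically
shows the largest k, reproducing the known difficulty of identifying
low-mass segments.

## Literature comparator

The packaged Winter-based table stores per merged segment the mass fraction
of body mass, length fraction of stature and CoM fraction of segment length:
upper arm 0.028 / 0.186 / 0.436; forearm+hand 0.022 / 0.146 / 0.682; thigh
0.100 / 0.245 / 0.433; shank 0.0465 / 0.246 / 0.433 with the foot (0.0145)
as a point mass at the ankle, giving a merged shank+foot CoM fraction of
0.5678; the torso+head takes the remaining 0.578 with its CoM at 0.66 of the
hip-to-shoulder distance. Height-normalized chain parameters from this
table are mass-independent and round to r3 = 0.0022, r6 = 0.0256,
r7 = 0.0085. Two values are convention-sensitive and deliberately not pinned:
r2 computes to 0.00636 (prints as 0.0064; tabulated sources round to 0.0063
under slightly different arm-length conventions) and the torso z-parameter
(~0.139) depends on the torso-frame and head-merge conventions. The foot
was placed at the ankle rather than using a combined shank+foot CoM at 0.606
of shank length because only the former reproduces the tabulated r7. Users
may supply alternative tables (e.g. de Leva) through the same JSON schema.
By the chain identity, `literature_com_estimate` equals the classical
segmentation method on the scaled table model; no age/sex/fitness adjustment
is applied.

## Virtual subjects and sessions

`generate_subject` perturbs each merged-segment mass and CoM fraction by a
factor (1 + deviation · u), u ~ U(-1, 1) with left/right tied, then
renormalizes masses to sum to one — so virtual subjects remain bilaterally
symmetric and differ from the table the way real subjects do. Defaults
(1.76 m, 76.1 kg) match the study cohort the protocol is modelled on.

`generate_session` renders held static postures (default 5 s at 15 Hz,
matching the calibration protocol of 40 holds) joined by 1-s smoothstep
transitions excluded from the hold labels. Joint angles are sampled by
stratified (one-per-bin, shuffled) draws over ranges spanning arm raises,
leans and leg lifts — emulating examiner-guided "varied" postures rather
than uniform random ones — which keeps the regressor full-rank with
condition numbers below 20 in practice. CoP is the ground projection of the
direct-model CoM (exact during holds: the quiet-stance CoP=CoM assumption
is true by construction; the CoM-acceleration discrepancy of real data is
out of scope). Sensor noise presets: vicon_like (0.5 deg orientation, 1 mm
CoP, 2 mm root) and kinect_like (5 deg, 3 mm, 15 mm). Orientation noise is
an i.i.d. per-sample small rotation (angle ~ |N(0, sigma)|, uniform axis).
All randomness derives from one integer seed through named SHA-256
sub-streams, making sessions byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real recordings: temporally correlated depth-camera noise
(real skeleton noise drifts smoothly, so the 5-degree static threshold that
works in practice also admits i.i.d. 5-degree noise only marginally; the
Monte-Carlo comparison under kinect_like noise therefore windows the data by
the generator's hold labels rather than threshold detection), occlusion and
skeleton-swap artifacts, balance-board load-dependent bias, CoP-CoM
separation due to CoM acceleration, and marker/soft-tissue artifacts.
Absolute millimeter accuracies measured here are accordingly optimistic;
the qualitative orderings (subject-specific beats literature; low-noise
beats high-noise) are the transferable result.

## Evaluation protocol

Windows are split by a seeded permutation into identification and
validation sets (default 40/40, mirroring the calibration/validation
protocol); rmse is reported over planar residual norms with per-axis AP/ML
rmse, and R² is computed per axis against the CoP series and averaged
across axes (a min-axis aggregation is available; R² is never clamped and
may be negative). Per-session rmse values are averaged across Monte-Carlo
seeds. Default problem sizes — 100 seeds per noise profile, 80-hold
sessions, 1000 model/posture pairs for the identity check — were chosen as
the smallest sizes at which the Monte-Carlo fractions are stable to a few
percent.

## Known limitations

Batch identification only (no recursive updating); no inertia or dynamics
(the chain is exact for statics and, once identified, valid kinematically
for motion); no posture-selection optimization to minimize the condition
number (it is reported, not optimized); multi-surface protocols for
restricted-mobility subjects are out of scope.
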