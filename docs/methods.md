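# Methods

`gaitcov` quantifies motor-equivalent stabilization of gait task variables
from step-to-step joint-angle variability during treadmill walking, and
provides a synthetic-data generator so that every stage of the pipeline is
testable without motion-capture recordings.

## Task variables and forward model

Six scalar task variables are defined at each heel strike, after projecting
the back-foot toe marker (first metatarsophalangeal joint, MTPJ), the
front-foot heel marker and the whole-body centre of mass (CoM) onto the
horizontal plane:

- `stepX`, `stepY` — step length and width: fore-aft and lateral distance
  from back toe to front heel;
- `bCoMX`, `bCoMY` — CoM position relative to the back toe;
- `fCoMX`, `fCoMY` — front heel position relative to the CoM.

By construction `step = bCoM + fCoM` holds exactly in both directions.
Lateral quantities are signed along the axis from the back-foot side toward
the front-foot side, so all six are typically positive in normal gait.
All variables are relative positions and therefore invariant under global
translation.

The forward model maps the joint-angle vector θ to these six scalars
through a configurable kinematic chain: a tree of rigid segments coupled by
Cardan (ordered body-fixed rotation) joints, with per-segment mass fractions
and CoM offsets defining the whole-body CoM as a weighted sum of segment CoM
points. The shipped default (`configs/pig35.yaml`) is a generic whole-body
chain with 16 segments, 15 joints and 35 rotational DOF (spine 3, thorax 3,
neck 3, shoulders 2×3, elbows 2×1, wrists 2×2, hips 2×3, knees 2×2, ankles
2×2). It deliberately does not replicate any vendor's proprietary
marker-to-angle conventions: the analysis depends only on the forward map
and its Jacobian, not on a specific angle parameterization. Mass fractions
and CoM offsets follow Winter's anthropometric table, with the trunk split
into pelvis/abdomen/thorax.

The chain is rooted at the pelvis. The pelvis pose is *not* part of the
35 DOF: translation cancels out of every task variable, and pelvis
orientation enters only as a fixed per-ensemble context (the mean fitted
pelvis rotation). The alternative — counting pelvis orientation among the
DOF — would add three angles whose variation is shared by all task
variables; we document but did not adopt it.

Jacobian rows are computed by central finite differences with a default
step of 1e-4 rad. The forward map is smooth; halving the step changes no
entry by more than 1e-6 m/rad at gait postures, and analytic
differentiation of a configuration-driven chain would add complexity
without accuracy the analysis needs. Linearization error is below 1 mm for
perturbations up to 2° per DOF on the default model.

### Inverse path (markers → angles)

Each segment's pose is fitted to its ≥3 non-collinear markers by
least-squares rigid registration (Kabsch/SVD with determinant correction).
Segments with fewer than three valid markers, or a collinear set (second
singular value of the centred local cloud < 1e-9 of the first), are flagged
unfittable and the frame is treated as incomplete. Joint angles are the
Cardan decomposition of each parent→child relative rotation; for joints
with fewer than three DOF the sequence is padded with the remaining axes
and the locked components dropped (their magnitude is reported). At gimbal
lock (middle angle within 1e-6 of ±π/2) the indeterminate rotation is
assigned to the first Cardan axis and the joint is flagged. Angles lie in
(−π, π].

"Model error" is the per-variable absolute deviation between task variables
computed directly from fitted segment poses (measured) and from the
forward-kinematic reconstruction of the extracted angles (fitted); with
2 mm marker noise it is of millimetre order (≈2 mm fore-aft, ≈3 mm lateral
on synthetic trials), matching the magnitude expected for marker-based
whole-body models.

## Preprocessing

Marker trajectories are low-pass filtered with a third-order Butterworth
filter at 10 Hz, applied forward and backward (zero phase; effective
magnitude response is the single-pass response squared, so gain at the
cutoff is 1/2). Edge transients are controlled by odd-reflective padding of
three filter lengths. Each marker's contiguous valid runs are filtered
independently; runs shorter than the padding are invalidated. Joint angles
are computed frame-wise from the filtered markers, never filtered
themselves, so the smoothing is applied exactly once at marker level.

Heel strikes are detected by the anterior-extreme method standard for
treadmill data: local maxima of the heel marker's fore-aft position
relative to the pelvis, with minimum separation 0.4 of the dominant stride
period (from the periodogram peak in 0.2–3 Hz) and parabolic refinement of
each peak over ±0.08 s, which suppresses frame-level jitter from marker
noise. A flat or aperiodic signal is rejected with a diagnostic.
Ground-truth events can be supplied instead, bypassing detection.

Step postures (whole-body angle vectors at heel-strike frames) are
normalized to the back-foot MTPJ position. Postures with any invalid
required marker are discarded; of the remaining, only the **last 20
complete** postures per foot and trial are analyzed (fewer than 2 is an
error, 2–19 a logged warning).

## Covariation analysis

For one ensemble (one trial, one side) with n×d angle matrix:

- C — unbiased (n−1) sample covariance around the ensemble mean θ̄;
- C₀ — C with every entry coupling angles of *different* joints set to
  zero ("different joints" = different anatomical joints, so within-joint
  correlations survive; per-DOF variances are always preserved);
- J — Jacobian row of a task variable at θ̄;
- TV = J C Jᵀ, TV₀ = J C₀ Jᵀ, COV = TV₀/TV, analyzed as ln COV.

COV > 1 means cross-joint covariation reduces task variability below what
the same per-joint variability would produce without coordination —
motor-equivalent stabilization. COV is invariant to uniform rescaling of C
and equals 1 exactly whenever C has no cross-joint entries. TV below
1e-16 m² yields a flagged result (excluded from aggregation) rather than an
infinite log index.

A non-linearized permutation oracle cross-checks the linearization: each of
n_perm surrogates independently permutes every joint's angle block across
steps (whole blocks move together), re-evaluates the task variable through
the full nonlinear forward model, and averages the surrogate task variances
(TV₀_perm). On ensembles within the small-amplitude regime (≤2° angle SD)
the two routes agree to |Δ ln COV| ≤ 0.05 at n_perm = 1000, and they agree
exactly (to Monte-Carlo error) for linear forward maps.

## Step–CoM correlations

Because step = bCoM + fCoM, Var(step) = Var(b) + Var(f) + 2 Cov(b, f).
The Pearson correlation of per-step bCoM and fCoM (per trial and side)
captures whether the two CoM-related measures covary in a way that inflates
(r > 0, destabilizing) or reduces (r < 0, stabilizing) step variability.
Correlations are Fisher z′-transformed (atanh) before averaging. Pearson
rather than rank correlation is used, as standard with the Fisher
transform. Zero-variance series yield flagged, undefined results.

## Aggregation and inference

Transformed values (ln COV, z′) are averaged per participant × speed cell
across the two sides and two trials — transformation strictly precedes
averaging. Missing cells are flagged, never imputed; duplicate keys are an
error. Group inference uses one-sample t-tests (stabilization: mean
ln COV > 0), Welch's unequal-variance t-test with Welch–Satterthwaite df,
Cohen's d (pooled SD), and Holm's step-down correction within each test
family (delegated to scipy/statsmodels). Repeated-measures ANOVA is out of
scope by design: the participant-level long table is directly consumable by
standard routines.

## Synthetic data generator

The generator emulates the study conditions end to end: 2 groups × 16
participants × 3 speeds (80/100/120% of preferred, implemented as posture-
and variability-scaling factors 0.8/1.0/1.2) × 2 trials, 20 step postures
per foot and trial, 200 Hz trials of 60 s with ~0.9 strides/s per side, 2 mm
marker noise.

**Covariance construction.** Angle fluctuations are multivariate normal
around a speed-scaled mean step posture with baseline SD 1.5° per DOF and
within-joint correlation 0.2 (block-diagonal baseline D). Compensatory
structure for a targeted variable is added as rank-one components built
from pairs of joint blocks whose gradient-aligned contributions cancel,
projected exactly onto the null space of the full task Jacobian: no
variable's empirical task variance changes, while the decorrelated variance
of the target grows by ≈ gain × its baseline (so linearized COV ≈ 1 + gain
before cross-variable leakage, which inflates all indices above 1 — as in
real gait, where every variable shows some stabilization). Range-space
components inflate TV instead. An optional rank-2 update steers the
bCoM–fCoM correlation to a target (bisection on a closed scalar form).
The sum is symmetrized and PSD-projected by eigenvalue clipping with the
clipped magnitude logged. An optional amplitude cap (`max_sd_deg`) shrinks
the covariance uniformly — leaving every COV untouched — to enforce the
small-amplitude regime where the linearization is guaranteed accurate.

**Group deltas.** The "older" group has stepX null-space gain 0.2 (vs 1.0),
baseline SDs inflated ×1.3, and fore-aft bCoM–fCoM target correlation 0
(vs −0.4); the lateral target is +0.6 in both groups. A mild lognormal
participant-level jitter (SD 0.15) on gains and SDs creates
between-participant variance. These conditions reproduce the qualitative
pattern of interest — weaker step-length stabilization and absent fore-aft
step–CoM coupling in the older group, no lateral group differences — and
are fixed study conditions, not tuning knobs.

**Marker-level trials.** Joint-angle trajectories are smooth periodic gait
primitives (constant + first/second stride harmonics, all even around the
strike phase) plus per-step perturbations drawn from the generating
covariance and interpolated with a cosine-squared partition of unity, so
the logged strike posture equals the drawn one exactly and the detection
signal peaks exactly at the true event. The stride period is snapped to an
even number of frames so strikes fall on sampled frames. Markers are
produced by forward kinematics plus isotropic Gaussian noise; dropout
episodes (20-frame spans) exercise the completeness rule. The pelvis
translates with a small even bob and lateral sway; its orientation is kept
at identity.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue artifact and marker placement error
(noise is isotropic and white), non-Gaussian or temporally persistent
step-to-step fluctuations, asymmetric or pathological gait, vendor-specific
angle conventions, and treadmill-speed drift. Recovery results certify the
pipeline's correctness on its own generative model, not the biological
findings themselves.

**Seeding.** Every entity (ensemble, trial, participant, replicate) derives
its RNG stream from a SHA-256 hash of the master seed and its identifiers
(< 2³¹), so any single trial regenerates bit-identically in isolation.

## Problem sizes used in validation

Replicate-study experiments use the full design (16/group × 3 speeds × 2
trials × 2 sides, 20 steps) with 50 replicates per arm — one arm with the
group deltas, one with identical groups for type-I calibration. The
permutation oracle uses 1000 surrogates. Marker-level checks use single
60 s trials at 200 Hz. These sizes give stable Monte-Carlo estimates
(binomial SE ≈ 3% at 50 replicates) at desk-scale runtimes.

## Known limitations

- The linearized index inherits the quality of the Jacobian at the mean
  posture; ensembles with large-amplitude, strongly nonlinear variability
  should rely on the permutation oracle instead.
- With n = 20 steps and d = 35 DOF the sample covariance is rank-deficient
  (rank ≤ 19); COV estimates are noisy at this scale and small-sample bias,
  though empirically below 2 Monte-Carlo SE at the null, is not corrected.
- C3D files are not read directly; trials must be exported to the labeled
  wide-CSV dialect documented in `gaitcov.io`.
- Heel-strike detection assumes treadmill walking with a roughly stationary
  pelvis; overground data would need the detector's signal redefined.
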