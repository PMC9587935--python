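# Methods notes

This note documents the models, conventions and numerical choices behind
soundloc3d, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate frames and conventions

Internal units are meters, seconds and radians; every reported quantity is in
cm, degrees or ms. The head-centered frame is right-handed with x right,
y forward (straight ahead), z up. Azimuth = atan2(x, y) in degrees, positive
**rightward**; elevation = atan2(z, √(x²+y²)), positive up; depth = Euclidean
distance from the head center in cm. The positive-rightward azimuth sign is
an internal convention (the targets are symmetric at ±30°/±150°, so either
sign choice is self-consistent); it is ours, not a property of the paradigm.

The head center is the midpoint of the two tracked ear positions (exact).
The tracked HMD rigid body sits ~10 cm forward of the head pivot; the
calibrated `head_center_offset` (default (0, −0.10, 0) m in head-local
coordinates) translates the rigid-body origin to the ear midpoint. The
reference pose for a trial is the head pose at the detected delivery onset;
the recorded straight-ahead direction is taken from the trial-start head
orientation, which in this paradigm is aligned by construction (the
controller only delivers sound to an aligned head).

Degenerate zero-depth points are flagged rather than raised, and excluded
from aggregates.

## Delivery gating

Three criteria must hold simultaneously: speaker within a **closed** 2.5-cm
ball around its predetermined head-centered position (the tolerance sphere
reads naturally as a closed ball), head deviation ≤ 5°, gaze deviation ≤ 5°.
The angular tolerances of the original controller are not public; 5° is a
plausible crosshair-alignment tolerance and is a config key
(`gating.head_tolerance_deg`, `gating.eye_tolerance_deg`), as is the
placement tolerance. Delivery triggers on the **first** passing sample; no
sustained-hold requirement is imposed (whether the original controller
required one is unknown). The offline re-check tracks the predetermined
target in head-centered coordinates per sample, as the online controller did.

## Kinematics

* **Filter**: linear-phase FIR (Kaiser design, ≥ 40 dB stopband), applied
  forward–backward (zero phase, DC gain 1). With head data at 100 Hz the
  nominal 50 Hz cutoff sits at Nyquist where the filter is a near no-op;
  cutoffs ≥ 0.45 × sample rate are clamped there with a warning. The cutoff
  is `kin.cutoff_hz`.
* **Velocity**: two-point central difference of the filtered positions,
  v[i] = ‖p[i+1] − p[i−1]‖ / (2Δt), in mm/s. Endpoints use one-sided
  differences so the series keeps its length; they are flagged non-central.
  Central differences are exact for linear and quadratic trajectories, which
  the tests exploit as oracles.
* **Segmentation**: maximal runs of samples at/above 80 mm/s
  (`kin.threshold_mm_s`). Onset = first sample at/above threshold (no
  back-extrapolation). Runs shorter than 50 ms (`kin.min_duration_ms`) are
  discarded as single-sample noise crossings — a standard kinematic
  safeguard that is **not** part of the original procedure.
* **Head-movement metrics** count segments whose onset falls inside the
  closed [0, 3] s sound window; later movements (response-phase reorienting)
  are excluded. Speed is the translational speed of the tracked head rigid
  body; an angular criterion is deliberately not used (the threshold is
  defined on position-derived velocity).
* **Compliance**: static trials with a head-movement onset inside (0, 3) s →
  `head_move_in_static`; any trial with a hand-movement onset before 3 s →
  `anticipatory_hand`. When a static trial violates both, the head rule is
  reported (rule order, not a claim about prevalence). Trials whose gating
  criteria never pass offline are excluded separately as `no_delivery` in
  the manifest.
* **Outlier rule**: per-participant percent head movement outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; quartiles use linear interpolation (the
  convention only affects borderline cases). Outlier participants are
  removed from head-movement analyses and correlations only.

## Error metrics

Per-dimension errors compare the response with the **actual speaker position
at delivery** (the physical source), not the nominal grid point. Azimuth
error is the circular difference wrapped to (−180°, 180°]. The variable
error is the SD (n−1) of responses at each position, averaged (unweighted)
across the available positions; positions with fewer than two accepted
trials are skipped with a warning.

For the composite index, C̄ pools every accepted trial irrespective of
position; s̄ is the per-position dispersion of the 3D responses averaged
across positions. Whether that dispersion is a per-axis SD average or a 3D
RMS is ambiguous; both are implemented
(`errors.dispersion = rms | axis_mean`) and **rms**
(√(var_x + var_y + var_z), the RMS distance from the position's mean
response) is the default as the natural 3D extension of "SD of the
responses". By construction error₃D = √(C̄² + s̄²) ≥ max(C̄, s̄).

Sector (front/back, from the target's nominal azimuth — never from the
response), distance category (near/middle/far ↔ 35/55/75 cm) and elevation
reference (0°, ear level) are design labels.

## Statistics

The rm-ANOVA is the classical balanced fully-within decomposition: for each
effect E the error term is the E × participant interaction,
F = MS_E / MS_{E×S}. Replicate observations per participant × cell are
averaged first; group aggregation is always trial → participant → group
(means ± SE over participants). Greenhouse–Geisser epsilon comes from the
covariance of participant-level orthonormal-contrast scores and is applied
to every effect with more than one numerator df (two-level factors are
sphericity-trivial); both dfs are scaled before the p value. Generalized eta
squared uses the observed-variance denominator for fully-within designs:
η²_g = SS_E / (SS_E + SS_S + Σ SS_{E′×S}). The implementation is original
(pingouin cannot fit the three-factor depth design) and is cross-checked
against pingouin for one- and two-factor designs in the test suite.

Holm–Bonferroni is the step-down adjustment, monotone and capped at 1. The
contrast family for Holm is the set of within-sector condition comparisons
per dependent variable — the family definition is a config choice, since the
original correction family is not spelled out. Kendall correlation is tau-b
(tie-corrected) with a two-sided p. Degenerate paired contrasts
(zero-variance differences with a nonzero shift) are flagged with an
undefined p rather than silently reported.

## Synthetic-experiment generator

The generator is a stated world, not a tuning knob: defaults encode the
study design (12 positions × 2 conditions × 8 trials/cell in 4 ABBA
counterbalanced blocks of 48) and published group-level behavior; where the
source is silent the default is a standard motor-control or psychoacoustic
choice, fixed once.

* **Placement**: per-axis Gaussian noise (SD 1.2 cm) rejection-truncated to
  the 2.5-cm ball, so every generated trial is deliverable. 1.2 cm
  reproduces per-axis mean absolute deviations near 0.8–1 cm and a mean 3D
  error near 1.6–2 cm.
* **Responses**: spherical model around the actual source. Azimuth bias is
  *eccentric* (applied with the sign of the target azimuth; defaults
  20°/8° front static/active, 10° back), elevation bias upward (25°/12°
  front, 12° back), response SDs per condition × sector (azimuth 9–17°,
  elevation 16–22°, depth 10 cm). Depth uses an affine compression
  (gain 0.675, intercept 18.2 cm, least-squares fit to the reported
  perceived depths 39.4/60.2/66.4 cm for 35/55/75-cm targets) because a
  constant bias cannot express distance-dependent under/overestimation.
  Participant-level random biases (SD 5°/8°/4 cm) create between-subject
  variance for the repeated-measures designs.
* **Head movements** (active blocks): per-participant movement propensity
  ~N(0.736, 0.24) clipped to [0, 1]; onset ~N(1077, 300) ms; count
  1 + Poisson(0.2); minimum-jerk angular profiles about a pivot 10 cm
  behind the HMD marker, so the 80 mm/s detector sees bell-shaped speed
  with peaks well above threshold. Front targets orient to the target
  (±5°); back targets mix full turns with front-quadrant orienting on the
  target side (weight 0.5). Movements are scheduled so threshold crossings
  stay safely inside/outside the 3-s window, keeping count labels exact.
* **Hand**: minimum-jerk reach starting ~N(3.65, 0.48) s after sound onset
  (clipped ≥ 3.05 s), or uniformly in 1.5–2.8 s on anticipatory trials
  (rate 0.06; static blocks additionally get head-movement violations at
  rate 0.01). The hand holds the pointed position to the end of the track;
  the pipeline reads the response as the mean over the final 200 ms.
* **Timeline**: tracks run from 0.5 s before delivery to 6 s after, head at
  100 Hz and gaze at 60 Hz. The speaker approaches during the pre-roll and
  first satisfies the tolerance exactly at onset (the final sub-centimeter
  settle is instantaneous between samples — only the crossing structure
  matters); the gaze aligns by a saccade just before. World placements are
  anchored at the measured head pose at onset (sway included), which is how
  the online controller gated delivery.
* **Stimulus**: uniform broadband noise carrier × sinusoidal envelope
  between (1 − depth) and 1, peak-normalized; modulation rate 2 Hz is a
  package default (the original AM rate is unpublished).

What the generator does **not** emulate: acoustic cues (ILD/ITD/HRTF) and
their dependence on head orientation — response statistics are injected, not
emergent; trunk/head decomposition; gaze dynamics beyond compliance;
tracker dropouts and marker occlusions. A green recovery test therefore
establishes that the pipeline measures what was injected, not that the
injected world is acoustically mechanistic.

## Numerical and design choices

* Quaternions are validated to unit norm (1e-6 in files, 1e-9 in poses);
  frame round-trips hold to 1e-9 m.
* Azimuth wrapping maps −180° to +180° so the range is (−180°, 180°].
* Zero error SS with zero effect SS reports F = 0, p = 1 (rather than NaN).
* The Holm and tau-b implementations are thin wrappers over statsmodels and
  scipy, pinned by brute-force enumeration oracles in the tests.
* Scaling: the acceptance script runs 8 participants × 4 trials/cell with
  full tracks (768 trials) to stay well inside a single-CPU time budget;
  the design-count and recovery tests use the full 8-trials/cell design
  where it matters (without tracks) and noiseless small-track cohorts where
  exactness is asserted.

## Known limitations

* The adapter for ingesting an external deposit's native layout is limited
  to the documented long-format CSV schema; mapping a specific archive's
  files requires a thin conversion step written against that archive.
* The rm-ANOVA requires a complete balanced design after rejection; heavily
  rejected small cohorts can lose cells, in which case the affected ANOVA
  block is skipped with a warning rather than imputed.
* Compliance detection is threshold-based; extremely slow ("sub-threshold")
  head drifts in static trials are not violations under the 80 mm/s rule,
  in the original procedure as here.
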