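# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `templatesig`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The augmented bipedal SLIP

The walker is a point mass M on two massless legs.  Each leg in ground
contact applies force

    F_j = −[k_L(L−L₀) + c_L·L̇]·q/L − [k_s·θ + c_s·θ̇]·q/L_s²
          − [k_f·φ + c_f·φ̇]·q/L_f²

with q the CoM position relative to the foot.  World axes are
(anterior–posterior, vertical, mediolateral); the ground is the plane y = 0.
Angles are **planar-projection** angles: θ = atan2(q_x, q_y) in the
sagittal plane (positive with the CoM anterior to the foot) and
φ = atan2(±q_z, q_y) in the frontal plane, sign-mirrored between legs so
that positive φ means CoM displacement toward the contralateral side.
L_s, L_f are the in-plane projection lengths.  A spherical-angle reading of
the same force law is possible; the planar convention is implemented because
it matches how the states are measured from CoM-minus-foot vectors.

Two points about the rotary terms deserve emphasis:

- As written, the rotary forces act **along the leg axis** (direction
  q/L_s², q/L_f²).  A physical rotary spring at the foot forces transverse
  to the leg; `rotary_transverse=True` switches both the simulator and the
  library to that variant consistently.  The default implements the
  along-the-leg form.
- The along-the-leg rotary force is **not conservative** (it is not the
  gradient of ½k_sθ²).  A stride-map fixed-point search shows it performs
  nonzero net work per stride, so the rotary-augmented walker admits no
  periodic passive gait under the default form.  Energy-conservation tests
  therefore apply to the pure-spring walker only.

### Hybrid integration

Adaptive RK45 (rtol 1e−9, atol 1e−10) with terminal events:

- **touchdown** — the swing foot, virtually placed at the touchdown angles
  with length L₀ from the CoM, reaches ground height (standard bipedal-SLIP
  touchdown policy: fixed leg angles relative to vertical);
- **liftoff** — a stance spring returns to its resting length (zero force,
  so CoM acceleration is continuous at both transition types for pure-spring
  walkers);
- **failure** — the CoM drops below 0.4·L_bio, or both feet leave the
  ground (flight; running is out of scope).  Failures raise
  `GaitFailureError` carrying the partial trajectory.

Stance feet are fixed in place; swing-foot trajectories (massless, hence
dynamically irrelevant) are reconstructed between the exact liftoff and
touchdown events with a minimum-jerk horizontal profile and a C¹ vertical
clearance bump (default 5 cm), giving contact detection from kinematics a
realistic target.

### The canonical ground-truth walker

Found by a stride-map fixed-point search (state at right touchdown:
trailing-foot offset, forward and vertical velocity) and frozen in
`config.py`:

    M = 70 kg, g = 9.81 m/s², L_bio = 1 m,
    κ_L = 16.7 (k_L = 11 467.9 N/m), L̃₀ = 0.98, θ_td = −0.44 rad,
    fixed point (0.20601746, 1.28120399, −0.56761239)

κ_L = 16.7 is a representative human single-support value; the gait walks at
1.22 m/s with a stride period of ~1.02 s and survives > 130 strides under
the default tolerances (the stride map's largest Floquet multiplier is
~1.02, and the fixed point is accurate enough that drift stays negligible at
trial lengths).  Each double-support phase occupies ~15% of the stride —
somewhat above the human 10–12%, as expected for a conservative spring-mass
gait; tests check a sanity band, not the human value.

The cycle is **planar** (frontal touchdown angle 0, mediolateral states
identically zero).  This is deliberate: the default (along-the-leg) rotary
force cannot supply lateral restoring force, so no passively stable 3D
lateral cycle exists under the implemented dynamics.  The simulator itself
is fully 3D — mirrored and laterally perturbed initial conditions produce
mirrored 3D trajectories — but the canonical fixture exercises the ML
direction only through noise.  Consequences: on noise-free canonical data
the four frontal-plane library columns are exactly zero (handled by
minimum-norm least squares and thresholding), and reconstruction r² omits
the zero-variance ML direction with a warning.

### Measurement-noise model

`add_noise` adds i.i.d. zero-mean Gaussian noise to all nine position
signals; the default SD of 1 mm is a standard marker-based motion-capture
error magnitude.  Real marker noise is temporally correlated and
soft-tissue artifact is not modeled, so passing tests bound performance
under white noise only.

## State computation

Velocities and accelerations come from Savitzky–Golay differentiation.  The
filter is the pipeline's key bias/variance trade-off: a wide window
suppresses second-derivative noise amplification but smears the acceleration
across contact transitions (where its time-derivative jumps), and that
smearing bias is a *smooth* function of phase which neighboring library
columns can absorb — biasing both coefficient estimates and model selection.
By default the filter is therefore chosen from the data: a robust position
noise estimate (MAD of 4th-order differences, which annihilate the smooth
trajectory; variance 70σ² for white noise) selects

- (window 5, order 4) — minimal smoothing — when σ̂ < 0.1 mm (numerically
  clean signals, bias-dominated), and
- (window 21, order 7) at motion-capture noise levels (variance-dominated).

Both settings, and the switching threshold, are explicit config fields; the
selection rule is the standard residual-analysis logic of biomechanics
filtering.

The continuous phase ψ is the wrapped angle of the reference (right) leg's
normalized (θ, θ̇) phase portrait — each coordinate centered and scaled by
half its peak-to-peak amplitude — mapped to [0, 100)% and anchored so ψ = 0
at the circular-mean right heel-strike phase.  Amplitude (not
angular-frequency) scaling is used.  Gait phases are labeled from contact
flags; a kinematic fallback (foot below 1% of L_bio and slower than
0.05 m/s) agrees with the simulator's flags on ≥ 98% of canonical-trial
samples.

## Function library and normalization

Fourteen dimensionless columns (7 per leg) expand the force law so each
column multiplies exactly one coefficient: the radial spring splits into a
−q/L_bio term (coefficient κ_L) and a +q/L term (coefficient κ_L·L̃₀);
dampers are estimated on linear dimensionless surrogates
c̃_L = c_L/(M·√(g/L_bio)) and c̃_{s,f} = c/(M·L_bio·√(g·L_bio)) and
converted to conventional damping ratios ζ afterwards, because the ζ
definitions are nonlinear in the estimated stiffnesses (ζ_L = c_L/2√(k_L·M);
the rotary ζ use the normalized stiffness inside the radical).  Gravity
lives on the target side, (q̈ − g)/g, never as a column.  Both legs' columns
are always present — sparsity, not masking, decides which leg's mechanisms
survive, which is how swing-leg coefficients arise.  L̃₀ is recovered as the
ratio of the product term to κ_L and is meaningless (reported missing) when
κ_L is thresholded to zero.

## Clustering, STLSQ, and candidate filtering

Nearest neighbors use circular phase distance (mod 100), ties broken by
sample index; cluster centroids carry the circular-mean phase and the
majority gait-phase label (mixed-phase clusters are allowed — their poor
held-out error removes them downstream).  STLSQ iterates least squares with
hard zeroing below λ until the active set is stable; rank-deficient active
sets take the smallest-norm solution with a debug log.  The λ grid is 40
log-spaced values from 1–100% of the largest unthresholded cluster
coefficient.  Structures seen in **strictly less than 1%** of clusters are
discarded (exactly 1% is retained); frequency is counted over clusters, not
(cluster, λ) pairs.

## Selection and multi-model inference

Candidate structures are refit per gait phase on all training samples of
that phase (structure-driven scoring: the sweep does not say which cluster's
coefficients should represent a recurring structure), then scored on the
held-out samples of the same phase:

    AIC  = 2k + ρ·ln(rss/ρ),  rss pooled over the 3 directions
    AICc = AIC + 2(k+1)(k+2)/(ρ−k−2)

with k the support size and ρ the number of held-out samples in the phase.
(The per-phase ρ replaces the trial-level 3600 because per-phase comparison
needs per-phase residuals; full-cycle scoring is available via config.)
ΔAICc ≤ 3 defines plausibility; Akaike weights ω = exp(−Δ/2)/Σexp(−Δ/2)
average the plausible coefficients, absent terms contributing zero.

One structural consequence of the ΔAICc ≤ 3 band: a nested superset that
fits the held-out data equally well scores ΔAICc ≈ 2·Δk ≤ 3, so on very
clean data the plausible set always contains supersets of the best model.
The *selected structure* is therefore the ΔAICc = 0 model (which is also
what a unique-plausible-structure outcome reduces to), and it is this
structure the bootstrap estimates by default (`bootstrap_structure:
"union"` switches to the plausible-set union).

## Bootstrap

200 refits of the fixed structure on resamples drawn with replacement from
the phase's training pool.  The 3600-sample trial-level resample budget is
allocated to phases **proportionally to their occupancy** — equivalent on
average to resampling the whole trial and splitting by phase — so shorter
phases (double support) naturally yield wider bootstrap distributions, which
is the sample-size effect the CV is meant to expose.  Rank-deficient
resamples are redrawn (error if > 10% redraw).  Final coefficients are
bootstrap means; CV = SD/|mean|.

## Analysis layer

r² per direction (zero-variance directions omitted with a warning) and
averaged; one-sample right-tailed t-tests of mean ΔAICc > 3 for
structure-plausibility transfer across conditions (zero-variance samples
compared exactly); Holm–Šidák step-down correction with rank-i critical
level 1−(1−α)^{1/(f−i+1)} (clamped at α against float round-off); percent
differences 100·(a−b)/|b| with the reference explicit.

## Desk-scale problem sizes

The full-scale protocol (3600 cluster seeds × 800 neighbors over a
10,800-sample pool, 3600 held-out) is the package default and runs in
minutes.  Tests and the acceptance script use a scaled configuration chosen
as the package's standard desk-scale setting: 70-stride trials
(~8600 samples at 120 Hz), 600 cluster seeds × 400 neighbors
(the neighborhood keeps roughly the full-scale 7%-of-pool share), the same
3600-sample held-out set, and 200 bootstrap draws.  All sizes are config
fields.

## Known limitations

- Massless swing legs; no torso or angular momentum; level ground; walking
  only (flight phases are a failure mode, not a gait).
- The canonical fixture's ML direction carries no signal (above), so
  frontal-plane mechanism recovery is verified at the regression level
  (library completeness against the force law on arbitrary states), not
  through a 3D limit cycle.
- Damping mechanisms are absent from the canonical ground truth (a damped
  passive walker has no periodic gait), so damping-coefficient recovery is
  exercised only through the library/force-law identities and the
  simulator's acceleration oracle.
- Human data involve treadmill drift, asymmetry, and phase-varying dynamics
  that the generator does not emulate; passing tests demonstrate correctness
  of the algorithmic chain under the stated synthetic conditions, not
  field performance on measured gait.
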