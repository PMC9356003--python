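# Methods

`myosynergy` implements a complete analysis chain for quantifying motor
control and phantom-limb perception after transtibial amputation from
surface EMG of four shank muscles (tibialis anterior TA, tibialis posterior
TP, lateral gastrocnemius GA, peroneus longus PL), two-degree-of-freedom
(ankle and subtalar) goniometry, and ultrasound-derived muscle fascicle
strain summaries.  Because individual participant recordings of this kind
are not publicly available, the package ships a synthetic cohort generator
whose statistical structure matches the assumptions of the analysis; every
stage is exercised and validated against that generator.

## The synergy model

Muscle activation patterns are modelled as non-negative linear combinations
of time-invariant muscle synergies:

    m(t) = Σ_i c_i(t) w_i + ε(t),   w_i ≥ 0, c_i(t) ≥ 0

`synergy.nmf_decompose` extracts (W, C) by multiplicative-update NMF
minimizing squared Frobenius error.  The protocol is: random [0, 1]
initialization; iterate until the change of uncentred VAF
(1 − ‖M − WC‖²_F/‖M‖²_F) stays below 1e-5 for 50 consecutive iterations
(`nmf_tol`, `nmf_tol_window`; hard cap `nmf_max_iter = 500`); repeat from 30
random initializations (`nmf_restarts`) and keep the highest-VAF solution.
The synergy count is the smallest N with VAF > 0.95 (`vaf_threshold`).
Scale indeterminacy is resolved by unit-norm synergy columns with the scale
folded into C, so scalar-product similarities between synergies are
well-defined.  VAF is global; a per-muscle variant is exposed
(`per_muscle_vaf`) without being the default criterion.

Per movement (plantarflexion PF, dorsiflexion DF, inversion IN, eversion
EV), the synergy activation vector u_task is the unit-normalized vector of
time-averaged coefficients over the task windows.  Bases and activation
vectors of limbs with fewer than three synergies are zero-padded to the
universal dimensionality of 3.

## Naturalness and robustness

Synergy correspondence across limbs uses greedy maximum-scalar-product
matching (descending over the remaining pairs; exact ties resolve to the
lowest index pair).  The reference basis is the unit-normalized element-wise
mean of the matched synergies of the biologically intact (BIO) limbs,
anchored to the first BIO limb's ordering; order invariance is verified by
test.  Muscle synergy similarity (m.s.s.) is the mean matched scalar
product against this reference; synergy activation similarity (s.a.s.) is
the analogous mean over the four movements' activation vectors, after
bringing each limb's synergy axes into the reference ordering through the
same matching.  BIO limbs are scored leave-one-out.  Robustness of two
movements i, j is the margin

    φ_ij = acos(u_iᵀu_j) − mean_t |acos(u_iᵀ ĉ_i(t))| − mean_t |acos(u_jᵀ ĉ_j(t))|

(tolerance between average commands minus within-task angular variability);
φ_ij > 0 flags the pair as robustly decoupled.  Zero-norm coefficient
samples are excluded from the means.

## Motor-intent decoding (α-space)

Arbitrary activation patterns are projected onto the fixed extracted basis
by per-sample non-negative least squares (the optimum of NMF with W held
fixed, but deterministic and restart-free), giving synergy activations
U_S(t) padded to 3 axes.  Each sample decodes to the motor-intent plane:

    α_PFDF = [acos(u_PF·Û) − acos(u_DF·Û)] / acos(u_PF·u_DF),  Û = U_S/‖U_S‖

and analogously α_INEV from (u_IN, u_EV); both are clamped to [−1, 1], and
the coordinate order is (α_INEV, α_PFDF) so the ideal targets are
χ_PF = (0, −1), χ_DF = (0, 1), χ_IN = (−1, 0), χ_EV = (1, 0).  Samples with
‖U_S‖ below 1e-3 of the trial maximum are treated as rest and excluded; the
source protocol is silent on rest periods, so this threshold is a package
choice.

## Motor metrics

* **2-DoF controllability** segments the α trajectory into maximal runs of
  at least 5 consecutive samples strictly inside one quadrant (samples
  within 1e-6 of an axis belong to no quadrant).  Velocities come from
  central finite differences; speeds below 1e-6/s are excluded.  Per sample
  θ = acos(δ₁₁·|α̇|/‖α̇‖) ∈ [0, π/4] with δ₁₁ = (1/√2, 1/√2); θ is
  time-averaged per trajectory, averaged over trajectories per quadrant,
  and the quadrant scores 1 − θ̄/(π/4) are averaged over the four quadrants
  with empty quadrants contributing 0.  The per-quadrant averaging follows
  the descriptive definition of the measure; the summation-only variant is
  recovered when each quadrant holds one trajectory.
* **Motor control performance** = 1 − (1/(2(T_E−T_S))) ∫‖χ_j − α(t)‖ dt with
  the Euclidean plane norm, so the maximal error (opposite target, distance
  2) maps to 0; integration is trapezoidal and the result clipped to [0, 1].
* **Economy of motion** = time-average of |α_j(t)|/‖α(t)‖ over non-origin
  samples (α_j = α_PFDF for PF/DF, α_INEV for IN/EV); invariant to radial
  scaling.
* **Index of difficulty** ID(T) = ln(2.0/T)/ln 4, anchored to 0 at the 2.0 s
  and 1 at the 0.5 s time constraint; values outside [0.5, 2.0] s raise an
  extrapolation warning.

## Perception capacity

Intended phantom positions θ are the trial averages of ‖U_S‖·α per degree
of freedom; perceived positions θ̂ are mirrored goniometer angles
normalized to [−1, 1] by the intact-limb range of motion.  A monotone
cumulative Gaussian θ̂ = lo + (hi−lo)·Φ((θ−μ)/σ) is fitted per DoF by least
squares with asymptotes clamped to the observed perceived extremes (only μ
and σ are free).  The functional form is a package choice — none is named
in the underlying protocol; the Gaussian CDF cannot track a perfectly
linear mapping at the range extremes (≈0.13 deviation at θ = ±1 with
R² ≈ 0.99), which does not affect the capacity value.  A DoF is degenerate
when perceived responses show no one-sided positive rank correlation with
intent (Kendall P ≥ 0.05), which covers both absent and inconsistent
phantom sensation.  Capacity per DoF is the perceived-range width between
the 5% and 95% response levels of the fitted function, truncated to the
observed extremes when unreached, normalized by the full ±1 scale; overall
capacity is the mean over the two DoFs (0.90 for a perfect identity mapping
over the full range; 0 for degenerate perception).  An alternative reading
of the capacity summary (mean function value between the levels) was
considered and rejected because it does not yield a [0, 1] range measure.

## AMS degree and response-curve statistics

The agonist-antagonist muscle strain (AMS) degree is the mean over the
PF-DF and IN-EV degrees of freedom of maximum fascicle strain divided by
the nominal intact-limb strain range, each ratio clipped to [0, 1] (the
clipping rule is a package choice consistent with the [0, 1] definition of
the degree).  Each response variable y is related to AMS by the first-order
exponential y = y∞(1 − exp(−λ·AMS)) fitted by Levenberg-Marquardt with
deterministic initialization (y∞ from the response maximum, λ from a
log-linearization); an intercept variant is exposed, default off.  The
critical degree AMS_c = ln(20)/λ is where the curve reaches 95% of its
asymptote.  A fit is saturating only when λ > 0, y∞ > 0, and the fit beats
the flat mean (R² > 0); otherwise AMS_c is undefined.  Uncertainty is the
plain mean ± s.d. of the n leave-one-out AMS_c estimates (bias-corrected
pseudo-value variant exposed; non-saturating replicates are excluded with a
warning).  Association is tested by Kendall's tau-b with a one-sided P for
positive association (exact enumeration for small n via scipy).  Group
comparisons: paired one-tailed t (unaffected minus affected; identical
samples give t = 0, P = 0.5 by convention), unpaired two-tailed t with
Cohen's d (pooled s.d.), Shapiro-Wilk per group (n ≥ 3), and a two-way
interaction ANOVA (group × limb side) via OLS.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions: 14 subjects (7 AMI, 7 CTL), each contributing a residual limb
with a configured AMS degree and a biologically intact limb at AMS = 1;
40 repetitions of the fixed PF-IN-DF-EV discrete sequence; 10
draw-a-circle cycles; 5 time-constraint blocks (2.0/1.5/1.0/0.8/0.5 s) × 4
movements × 10 repetitions in block-randomized order; 40 randomized PF/DF
perception trials at 25/50/75/100% range of motion plus 30 randomized
IN/EV trials at 50/100%.  Signals are emitted in the envelope domain at
50 Hz (the analysis consumes 5 Hz-low-passed envelopes, so this retains the
full information content); an optional carrier-modulated raw mode at 1 kHz
exercises the EMG chain.  Envelope noise is additive Gaussian with
s.d. 0.05 of the calibrated maximum, band-limited to the 5 Hz envelope
bandwidth (noise in a measured envelope passes the same low-pass as the
signal) and clipped at zero so envelopes stay non-negative; perception
noise is Gaussian with s.d. 0.05 of the range of motion.  The AMS grids (AMI 0.19–1.0, CTL
0.12–0.45) span the degrees reported for individual residual limbs in this
population (≈0.19–0.26 for the named cases, with wide variance).

**Geometry.**  The natural basis has a GA+TP plantarflexion synergy, a PL
synergy and a TA synergy, each column touching the non-negative orthant
boundary (true zero entries), which makes the factorization identifiable.
Movement directions sit on a 30° cone around the symmetric axis of synergy
space at azimuths 0/90/180/270° (PF/EV/DF/IN), so every direction is
equidistant from the two directions of the orthogonal degree of freedom and
decodes exactly onto its cardinal α-space point.  Within each discrete
trial the three synergy bursts are half-sines with staggered onsets and
equal integrals: each synergy is briefly active alone somewhere in the
record (identifiability) while the window-averaged direction equals the
template exactly.

**Degradation.**  All motor degradation is driven by a configured response
curve r(a) = (1−e^{−λa})/(1−e^{−λ}), λ = ln 20/AMS_c (unit-normalised so a
fully intact limb is exactly uncorrupted), with AMS_c = 0.21 for motor
structure and 0.61 for perception gain by default.  Three mechanisms:

1. *Basis corruption*: convex mixing of each synergy column toward a fixed
   pathological coordination basis (altered TP:GA balance, TP+PL and TA+GA
   cross-couplings) whose columns lie outside the natural basis cone — the
   mixing weight is solved per limb so the matched-cosine similarity of the
   corrupted to the natural basis equals r(a) exactly.  A centroid collapse
   (full coactivation) engages only above 80% fusion, reproducing merged
   synergies under near-total strain loss.
2. *Direction corruption*: an azimuthal rotation of the whole direction
   cone (altered coordination mapping; preserves the mutual geometry and
   hence a well-conditioned decode) solved so the mean cosine to the
   natural directions equals r(a), plus a fusion-driven antagonist merge
   (capped at weight 0.45) that erodes the decoupling margins.
3. *Trajectory degradation*: circle-task intent blends from a diamond
   (simultaneous 2-DoF) toward an axis-aligned square with the fusion level
   1 − r(a); speed-accuracy tracking uses a first-order approach to the
   target whose time constant and Ornstein-Uhlenbeck intent wander grow
   with fusion.  Perceived positions are gain r_perc(a) times the commanded
   position plus noise; a zero-sensation mode emits uncorrelated angles.

Intent trajectories are realized by inverting the α-map on the two-parameter
direction cone (warm-started least squares at stride-sampled knots with
multi-start over azimuths, normalized linear interpolation between knots).

Because the corruption is calibrated against the very quantities the
pipeline measures, a noiseless cohort sits exactly on the configured
response curves, making end-to-end recovery of AMS_c a meaningful
round-trip test: the full pipeline recovers the motor AMS_c within ±0.02
noiselessly (m.s.s., s.a.s. and 2-DoF controllability paths) and the
perception AMS_c within ±0.02 through the psychometric path; with default
noise the m.s.s. recovery error stays within ±0.05 (median over 20 seeds).
Known noise biases, deliberately not corrected: observed-extreme clamping
inflates capacity under perception noise, lowering the apparent perception
AMS_c by roughly 0.1 at the default noise level; velocity-direction jitter
dominates the 2-DoF controllability at that noise level, compressing its
range across limbs so its rank correlation on a noisy cohort is weak even
though the noiseless recovery is exact — a genuine sensitivity of
velocity-direction measures rather than a defect of the estimator; and
economy of motion saturates near 1 for high-AMS limbs, so its rank
correlation is driven by the low-AMS half of the cohort.

**What the generator does not emulate.**  Real interference-pattern EMG
(crosstalk, electrode artefacts, non-stationary noise), muscle fatigue,
inter-trial learning, non-exponential individual differences, and the
anatomical diversity of residual limbs.  Passing tests therefore validate
the computational chain and its statistical behaviour under the stated
model, not clinical performance on human recordings.

## Problem sizes

Unit and property tests run reduced protocols (6–8 discrete repetitions,
2–4 circle cycles, 1–2 speed repetitions per movement, 5–8 NMF restarts)
chosen so each suite completes in seconds while preserving the protocol
structure; the acceptance script runs the full default protocol (40
repetitions, 10 cycles, 200 speed-accuracy trials, 70 perception trials,
30 NMF restarts) on the 28-limb cohort.  NMF input is decimated to 25 Hz
(`nmf_decimate = 2`), far above the 5 Hz envelope bandwidth.

## Known limitations

* The α-map inversion is numerical; targets outside the reachable set of a
  heavily fused limb's direction geometry land on its boundary.
* The exponential response fit is unweighted least squares; no
  heteroscedasticity handling.
* No multiple-testing correction across the six response variables, by
  design of the reporting layer.
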