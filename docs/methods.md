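# Methods

## Model and procedure

The pipeline treats each participant's per-segment functional connectome
(FC) as a point on the SPD manifold and measures between-condition
reconfiguration in a common tangent space.

1. **Segmentation.** Two scans are cut into five 4-minute analysis segments
   (R1.1, R1.2 in the resting scan; SST, R2.1, R2.2 in the task–rest scan).
   Volume indices are 0-based half-open intervals. The first `ceil(7 s/TR)`
   calibration volumes of each scan are discarded *from the first segment
   only* and the `12 s/TR` announced-transition volumes are discarded
   between SST and R2.1. The alternative — shifting all boundaries by the
   calibration — would break the printed scan totals (400 and 610 volumes
   at TR = 1.2 s) or the 4-minute marks; keeping later boundaries nominal
   leaves R1.1 and SST six volumes short (194 vs 200 at TR = 1.2 s), which
   is immaterial for correlation estimates at this length.
2. **FC estimation.** Pearson correlation per region pair (raw `r`
   throughout; no Fisher transform, matching the correlation-distance
   comparisons downstream). Zero-variance regions are a hard error naming
   the region. When a segment has fewer time points than regions the FC is
   singular; the package never clips eigenvalues — the user must
   regularize, because λ is an explicit, reported analysis parameter.
3. **Regularization.** `C + λI`, default λ = 0.001 (the grid's bold
   midpoint; small values preserve tangent-element variance, see the sweep
   below). Every eigenvalue shifts by exactly λ.
4. **Reference.** The Karcher (Riemann) mean of the regularized
   resting-state FCs of the reference segments (default R1.1). Task
   segments are refused as reference by default: projecting at a reference
   containing SST structure would cancel the very structure whose change is
   being measured. Override with `allow_task_reference=True`.
5. **Projection.** `Ŝ = logm(C_ref^{-1/2} S C_ref^{-1/2})`, explicitly
   symmetrized; each tangent matrix records its `reference_id`, and
   distances across different references are refused.
6. **Identifiability.** Correlation distance (`1 − r`) of
   diagonal-excluded upper-triangle vectorizations (the FC diagonal is
   identically 1; tangent diagonals are excluded for consistency; a flag
   restores them). Identification rates average the row (A→B) and column
   (B→A) matching directions — the direction is not intrinsic to the
   definition, and the symmetric summary is standard in the fingerprinting
   literature; argmin ties count as misidentification (conservative and
   deterministic).
7. **Models.** OLS with intercept on raw (unstandardized) predictors — sex
   (male = 1), age (years), education (years), SSRT (ms), CES-D score,
   recent-drinking composite (PC1 of z-scored AUDIT, drinking days, drinks
   per week, drinks per drinking day; sign fixed so the AUDIT loading is
   positive; scores standardized), FHA (1 = positive). Coefficients are in
   distance units per natural predictor unit; a `standardize` choice can be
   applied upstream by the caller. The additive-R² sequence is the only
   quantity that depends on predictor order; both conventional orders are
   provided (`PREDICTORS`, `RESULTS_ORDER`) and any order is accepted.
8. **SSRT.** x-th percentile of Go reaction times minus the mean stop
   signal delay, x = stop-failure rate. The percentile uses linear
   interpolation (the ubiquitous "type 7" default); the definition is a
   single function and swappable.

## Numerical choices

* All matrix functions use a symmetric eigendecomposition with forced
  re-symmetrization `(X + Xᵀ)/2` after every recomposition, bounding
  floating-point asymmetry drift across chained operations. Symmetry
  tolerance: `max|A − Aᵀ| ≤ 1e-10·max|A|`; SPD tolerance: smallest
  eigenvalue > `1e-12`·largest.
* Karcher iteration: init = arithmetic mean, unit step, stop when the mean
  tangent's Frobenius norm < 1e-8, cap 200 iterations; non-convergence is
  an error carrying the last gradient norm. Unit step converges for
  well-conditioned FC sets; no step-size control is attempted.
* Degenerate p = 1 inputs (scalars) are supported so analytic tests stay
  trivial.
* Matrix TSV round trips are written at 17 significant digits
  (bit-stable for float64); covariate CSVs are parsed with pandas'
  round-trip float parser.
* Paired t tests with (numerically) constant differences degenerate to
  t = 0, p = 1 (zero shift) or signed infinity, p = 0.

## The synthetic cohort generator

The generator emulates the two-scan design so that every stage is testable
without data access. Per subject `s`, the latent rest covariance is
`B_s = G + f·F_s + D`, with `G` a shared low-rank component (rank 6),
`F_s` a subject-specific low-rank fingerprint (rank 3, weight f = 3.0), and
`D` a heterogeneous diagonal (entries uniform in [0.5, 1.5]). The task
state is displaced along `Δ = τ·D_task − μ·G` (task-positive coupling of
rank 2 with weight τ = 0.9 appears, a fraction μ = 0.3 of the shared
baseline coupling is suppressed) scaled by a per-subject engaging amplitude
`a_s`; post-task rest retains fractions `(1 − g_s)` (R2.1) and `(1 − h_s)`
(R2.2) of that displacement, and all scan-2 segments add a common scan
component (rank 2, weight 0.3). Segment time series are multivariate
normal with covariance `Σ_segment + noise_sd²·I` (noise_sd = 0.4),
sampled at the full protocol layout including the discarded calibration
and transition volumes. Because every component is PSD and the amplitude
is clipped so `μ·a_s < 1`, all latent covariances are SPD by construction.

Covariate effects act on the log scale:
`a_s = exp(−0.35·z_drink − 0.30·z_sex + 0.22·z_cesd + ε)` and
`g_s = 0.65·exp(−0.55·z_fha + 0.30·z_edu + 0.22·z_cesd + ε)` (ε i.i.d.
normal, sd 0.25; `h_s = g_s + 0.25(1 − g_s)`). This yields engaging ∝ a_s,
disengaging ∝ a_s·g_s and within-rest ∝ a_s(h_s − g_s), so engaging >
disengaging > within-rest holds by construction for moderate amplitudes,
and the covariate directions match the modeled phenomenon (less
reconfiguration with recent drinking and male sex when engaging; less with
positive family history, more with education and CES-D when disengaging).
The weights were calibrated once, as part of generator design, so that the
default cohort sits in the regime the method targets — near-perfect
tangent fingerprinting, drinking/FHA t statistics around 3–7 at n = 54 —
and then frozen.

Covariates reproduce the cohort description: exact FHA-positive (23/54)
and male (25/54) counts, age ~ N(22.64, 1.62²) clipped to [21, 26],
education ~ N(15.25, 1.20²), SSRT ~ N(238, 51²), CES-D ~ N(5.96, 5.09²)
floored at 0, and four drinking measures sharing a latent factor
(equicorrelation 0.533, so their first principal component carries ≈65% of
the variance) with FHA-shifted group means.

**What the generator does not emulate:** hemodynamic autocorrelation and
spectra, head motion and scrubbing, spatially structured physiological
noise, non-Gaussian BOLD marginals, region-level anatomy, and drinking
measures are unbounded (clipping would distort the documented moments).
Passing tests therefore demonstrate that the *pipeline* recovers structure
it is designed to measure under a faithful statistical emulation — not
that any specific biological effect exists in real cohorts.

## The recovery estimand

Finite scan length makes sampled FC entries noisy; after the matrix
logarithm the noise concentrates in small-eigenvalue directions, and the
correlation distance of noisy tangent vectors is an attenuated affine
function of its noise-free counterpart. Distance-scale regression
coefficients estimated from finite scans are therefore systematically
smaller (by ≈0.55–0.65 under the default conditions) than the coefficients
the same pipeline produces on the exact segment covariances. This is a
property of the measurement, not an estimator defect — the same shrinkage
phenomenon the regularization sweep exhibits in the λ direction.

Validation consequently separates two questions. *Direction:* fitted
coefficients must carry the generating sign (tested per effect over 100
seeded replicate cohorts at n = 54, p = 50). *Calibration:* each
replicate's 95% confidence interval must cover the ensemble-expected
coefficient — the Monte-Carlo mean of the estimator over 40 independent
seeds at the same generating conditions, which is the natural estimand on
the measured-reconfiguration scale. The noise-free coefficients remain
available in `GroundTruth.true_coefficients` for reference. Type-I
calibration uses 200 replicate cohorts with all generating effects zero;
these run at p = 25 regions (the calibration does not depend on the
region count, and the smaller size keeps the experiment at desk scale).

## Known behavior and limitations

* **Whitening.** Segments used to build the reference lose their common
  structure after projection, so their identifiability blocks show the
  largest between-participant distances (reference segment R1.1 by
  default). This is expected, not an artifact.
* **Reference robustness.** Engaging and disengaging reconfiguration
  vectors are highly stable to the rest-segment reference choice
  (correlations > 0.97 across R1.1 / R2.2 / combined on the default
  cohort). The within-rest vector is not stable under a reference that
  contains one of its own segments (R2.2): its signal is the smallest of
  the three transitions and, at 50 regions (1225 tangent features), the
  whitening perturbation is not averaged away — correlations drop to
  ≈0.6–0.7. With finer parcellations the effect shrinks; comparisons of a
  transition should avoid references containing its segments.
* **Regularization.** Pooled tangent-element variance decreases
  monotonically in λ (by ≈60× from 0.0001 to 10 on the default cohort);
  large λ flattens the very differences the models explain, so the default
  stays small. Identification is much less sensitive to λ than the
  regressions are.
* The sweep, LOO and replication experiments re-run the full pipeline and
  scale linearly in their replicate counts; default problem sizes (n = 54,
  p = 50; tests additionally use n = 10, p = 8–12 cohorts) were chosen to
  keep a complete validation run in minutes on one CPU.
* Leave-one-out distributions are descriptive stability checks, not
  inference; no multiple-testing correction is applied across models
  (p values are reported unadjusted by design).
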