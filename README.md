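# tanrec — tangent-space functional connectome reconfiguration

`tanrec` quantifies how whole-brain functional connectivity reorganizes when
people transition between fMRI conditions — engaging in a task after rest,
and disengaging from it back into rest — and relates the size of that
reconfiguration to behavioral covariates.

It is written for researchers analyzing parcellated BOLD time series from a
two-scan rest/task/rest design (8 min rest; then 4 min stop signal task, a
12-s transition, and 8 min rest), but every stage is exposed as a library
and works on any set of per-condition functional connectomes.

## The method

A functional connectome (FC) is the region-by-region Pearson correlation
matrix of BOLD time series. Full-rank FCs are symmetric positive-definite
(SPD) and live on a curved manifold under the affine-invariant Riemannian
metric (AIRM),

    d_G(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F .

Because FC entries are interrelated on the manifold, FCs are compared after
*tangent space projection*: each regularized FC `S` (diagonal incremented by
λ, default 0.001, to guarantee positive-definiteness) is mapped to

    Ŝ = logm(C_ref^{-1/2} · S · C_ref^{-1/2}),

where the reference `C_ref` is the Riemann (Karcher/Fréchet) mean of the
resting-state FCs,

    C_ref = argmin_C Σ_i d_G(C, S_i)²,

computed by the standard fixed-point iteration from the arithmetic mean.
Tangent-FCs from two segments are compared across all participants by the
correlation distance `1 − r` of their vectorized upper triangles, giving an
n×n *identifiability matrix*; the 5×5 grid over the segments
R1.1, R1.2, SST, R2.1, R2.2 is the *meta-identifiability matrix*. Its
cross-segment diagonals are the per-participant *reconfiguration vectors* —
engaging (R1.2→SST), disengaging (SST→R2.1) and within-rest (R2.1→R2.2) —
which are modeled by ordinary least squares on seven covariates (sex, age,
education, SSRT, CES-D, a PCA-composite recent-drinking score, family
history of alcohol use disorder), with an additive-R² sequence as predictors
enter in a declared order. Identification ("fingerprinting") rates, two
leave-one-out stability analyses (model-level and reference-level), a
regularization sweep, and a reference-choice robustness comparison complete
the toolkit.

Because raw cohort data of this kind are generally not shareable, the
package includes a first-class synthetic cohort generator
(`tanrec.synthetic`) that emulates the design: subject fingerprints, task
and scan components, observation noise, and covariate-driven
reconfiguration differences, with full ground truth for validation.

## Worked example

```python
from tanrec import FunctionalReconfiguration, SyntheticConfig, generate_cohort

cohort = generate_cohort(SyntheticConfig(seed=7))     # 54 subjects, 50 regions
model = FunctionalReconfiguration.from_cohort(cohort) # λ=0.001, C_ref from R1.1
results = model.fit()
print(results.summary())
```

```
Functional reconfiguration pipeline
  participants: 54, regions: 50, lambda: 0.001, reference: R1.1

Cross-segment identification rates (%):
       R1.1   R1.2    SST   R2.1   R2.2
R1.1    NaN  100.0  100.0  100.0  100.0
R1.2  100.0    NaN  100.0  100.0  100.0
SST   100.0  100.0    NaN  100.0  100.0
R2.1  100.0  100.0  100.0    NaN  100.0
R2.2  100.0  100.0  100.0  100.0    NaN

engaging     mean reconfiguration 0.3943 (sd 0.0422)
disengaging  mean reconfiguration 0.2293 (sd 0.0459)
within_rest  mean reconfiguration 0.2036 (sd 0.0204)

--- engaging model ---
OLS reconfiguration model (n = 54, R^2 = 0.690)
predictor           coef          SE         p   add R^2
const             0.3958     0.07899    0.0000
sex             -0.02401    0.007233    0.0018     0.181
age            -0.003315    0.002904    0.2596     0.182
education       0.002294    0.003079    0.4601     0.182
ssrt           9.703e-05   7.298e-05    0.1902     0.258
cesd            0.003709    0.000926    0.0002     0.361
drinking        -0.02867    0.004146    0.0000     0.656
fha              0.01835    0.008131    0.0288     0.690
...
```

Reading the output: every participant's tangent-FC is their own nearest
match in every other segment (perfect fingerprinting); participants
reconfigure more when engaging in the task (mean correlation distance 0.39)
than when disengaging (0.23), and least within rest (0.20); and in the
engaging model, higher recent drinking and male sex predict *less*
reconfiguration while higher CES-D predicts more — the directions built
into the generating conditions. The `add R^2` column is the cumulative
explained variance as predictors enter in the declared order.

Stability and sensitivity analyses hang off the model object:

```python
model.loo_reference_stability("disengaging")  # rebuild C_ref n times
model.regularization_sweep()                  # λ grid 0.0001 … 10
model.compare_references()                    # R1.1 vs R2.2 vs both
```

A `tanrec` command-line interface wraps the same pipeline for file-based
workflows (`tanrec simulate`, `fc`, `project`, `identify`, `reconfig`,
`model`, `sweep`, `loo`, `compare-refs`, `run`); inputs are TSV time
series with a YAML manifest and a CSV covariate table, outputs are
TSV/JSON artifacts plus a JSON-lines run log.

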