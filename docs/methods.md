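# Methods

## Model

A CGM sensor reading g_m (mg/dL) is modeled as the true blood glucose g_r
plus a structured error d_k = g_m − g_r. The calibrator is a set of six
regressors, one per clinically defined glucose range, each predicting d_k
from eight inputs: the measured value itself (x1 = g_m) and seven
personalized covariates — physical activity (g), peak acceleration (g),
posture (degrees), heart rate (BPM), breath rate (BPM), skin temperature
(°C), and food intake (calories). The corrected value is
g_p = g_m − d_pred, floored at 1 mg/dL so relative metrics stay defined.

Stratifying by glucose range is knowledge-based, not data-driven: insulin
response — and with it the sensor-error pattern — differs systematically
across hypoglycemic, euglycemic and hyperglycemic ranges, so each range
gets its own model and its own hyperparameters. Range boundaries are
80 / 115 / 150 / 180 / 250 mg/dL, each boundary inclusive in the lower
cluster (half-open intervals; 80 → cluster 0, 81 → cluster 1). At
deployment only g_m exists, so cluster membership defaults to the measured
value; a reference-based mode (`assign_by="reference"`) is provided for
experiments where conditioning on the true range is the point (see
“Recovery experiments” below).

## Training and model selection

Within each cluster, data are split 70:30 (shuffled, fixed seed; the split
is shared by all grid candidates of that cluster). The eight features and
the target d_k are centered and scaled on the training split only; the
target scaling is a pure numerical-conditioning choice — it is linear, so
tree/KNN predictions are unchanged, while the MLP and SVR train on a
well-scaled response. Scaler state is frozen into the fitted model so
inference reproduces the training-time transform exactly.

Regressors are scikit-learn estimators. Six families are supported for the
initial screen (SVR, KNN, decision tree, random forest, AdaBoost, MLP) with
library-default hyperparameters unless configured; the per-cluster search
is over MLPs. The search grid crosses seven axes:

| axis | values |
|---|---|
| hidden layers | (20), (100), (200), (10,10), (20,20), (10,10,10,10), (20,20,20,20) |
| initial learning rate | 0.001, 0.01, 0.05, 0.1, 0.5, 1 |
| learning-rate schedule | constant, invscaling, adaptive |
| activation | tanh, relu |
| solver | lbfgs, sgd, adam |
| iteration budget | 100, 500, 1000 |
| momentum | 0.9, 0.99 |

Momentum only affects the SGD solver but remains a full axis for every
solver, so the grid cardinality is 7·6·3·2·3·3·2 = 4536. Enumeration is a
deterministic Cartesian product with the architecture outermost and the
solver innermost. Each candidate gets a reproducible estimator seed derived
from (cluster, candidate index, base seed).

The winner per cluster minimizes held-out (absolute RMSE, then MARD,
then enumeration order) lexicographically. The published selection rule
“smallest RMSE and smallest MARD” is ambiguous when the two minimizers
differ; RMSE-first matches the rule's own emphasis, and the tie-break makes
selection total and deterministic. Relative RMSE and signed error extrema
are logged for every candidate but do not drive selection. An optional
accuracy goal (`goal_mard`) short-circuits the search; it is disabled by
default since no numeric goal is canonical. Clusters with fewer than 10
readings (configurable) fall back to the identity correction with a
warning rather than an error — small hypoglycemic clusters are the norm in
realistic cohorts, and a calibrator must still cover the full range.

A 4-candidate `HyperparameterGrid.reduced()` preset (architectures (20,)
and (10,10), adam and lbfgs, lr 0.05, adaptive schedule, relu, 1000
iterations) exists for routine runs, tests and the acceptance script; the
full 4536-point grid is exact but takes hours on one core for a
thousand-reading cohort, which is a cost decision left to the user
(`--preset full`).

## Evaluation

* **MARD** = mean of 100·|g − g_r|/g_r (per-pair percentages averaged).
* **RMSE** absolute (mg/dL) and relative (% — RMS of the signed relative
  errors). Both are always reported because "RMSE" on a percent scale is
  common in the CGM literature and the two are not interchangeable.
* **Error extrema**: max and min signed relative error, %.
* **Clarke error grid**: the standard ordered piecewise-linear rule set
  with priority A, E, C, D, else B; zone counts and percentages with empty
  zones reported as zero. The test suite cross-checks the rules against an
  independent shapely point-in-polygon oracle built from the zone boundary
  geometry.
* **FDA compliance**: per-pair rule keyed on the *sensor* value — below
  100 mg/dL the absolute error must be within 20 (adjunctive) / 10
  (nonadjunctive) mg/dL, at or above 100 mg/dL the relative error within
  20% / 10%.
* The before/after report has seven rows (six clusters + overall), rows
  clustered on the measured value by default so a pair occupies the same
  row on both sides.

## Synthetic cohorts

The generator emulates a small free-living type-1-diabetes study: by
default 9 patients × 14 days, CGM every 5 minutes, and 6 fingerstick
references per day placed just before each of ~3 meals and two hours
after, snapped to the CGM grid. Reference glucose follows a mean-reverting
(OU) baseline (mean 150 mg/dL, stationary SD 55, 120-minute reversion
time) plus exponentially decaying meal spikes (amplitude 80 mg/dL, 90-min
decay), clipped to [40, 400]; these values reproduce the glycemic profile
of insulin-treated patients (substantial time above 180 and ~5–10% above
250) so every cluster is populated. Covariates are autocorrelated AR(1)
series within physiological ranges (heart rate 50–160 BPM, breath rate
8–30 BPM, skin temperature 30–38 °C, posture −90–90°, non-negative
activity/acceleration) and calories are logged at meal steps.

The sensor error is closed-form: per-cluster bias (defaults
12, 8, −7, 10, −12, −22 mg/dL) plus per-cluster gain on g_r (0.06, 0.04,
0.03, −0.04, 0.03, 0.05) plus a linear covariate term, a per-patient
offset (SD 5 mg/dL) and Gaussian noise (SD 6 mg/dL). The cluster of the
*reference* value keys the bias/gain — the mechanism lives in truth-space.
These defaults put the uncalibrated sensor near 20% MARD, the band
reported for uncorrected minimally invasive sensing. Every generated
reading is returned with its error decomposition, and with noise and
patient offset at zero the recorded error equals the closed form exactly.

What the generator does **not** emulate: sensor drift over wear time,
interstitial-fluid lag (errors here are memoryless given the covariates),
missing data and sensor dropouts, discrete fingerstick meter quantization,
and realistic food-diary semantics (food quality labels are accepted by
the reader but never generated). Passing tests therefore demonstrate that
the pipeline recovers a known mechanism of this family, not that any
particular real sensor will improve by the amounts shown.

## Recovery experiments and numerical choices

With the noiseless linear mechanism, d_k restricted to a *reference*-keyed
cluster is exactly linear in the features, so held-out MARD under 1% per
cluster is an achievable bar and is asserted in the tests (reference-based
assignment; measured-value assignment mixes adjacent mechanisms near
boundaries, where the target is not even a function of the features — the
observed residual there is a property of the problem, not the optimizer).
The noisy-improvement experiment (sensor noise 10 mg/dL, 10 generation
seeds, ~1000 readings each) compares held-out MARD before vs after
calibration and requires the median to improve.

Other numerical choices: corrected glucose floored at 1 mg/dL;
`StandardScaler` guards a zero-variance target by substituting unit scale;
MLP convergence warnings are suppressed during grid search (short iteration
budgets are grid points, not errors); candidate failures are logged with
inf scores and skipped, and only an all-candidate failure raises. All
randomness flows from explicit seeds: cohort generation uses a
`SeedSequence` per patient, splits and estimators derive seeds from the
caller's base seed, and identical configuration yields byte-identical
outputs end to end.

The default test/acceptance problem sizes (cohorts of ~750–1000 readings,
the 4-candidate reduced grid) keep a full run on one core in the tens of
seconds while leaving every cluster populated; they are stated here as the
package's standard desk-scale conditions.

## Known limitations

* The per-cluster models share no information across clusters; sparse
  extreme ranges would benefit from partial pooling.
* Cluster assignment by measured value at deployment means readings whose
  measurement error crosses a boundary are corrected by the neighboring
  cluster's model; the reference-based training mode quantifies the cost.
* The grid search evaluates a single fixed split per cluster (the search's
  published structure); an optional cross-validated variant would reduce
  selection variance on small clusters.
* The Clarke grid is the 1987 geometry; Parkes/consensus and surveillance
  grids are out of scope.
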