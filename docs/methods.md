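# Methods

## Setting and unit of analysis

The package models the node-level evaluation of PET/CT-based prediction
of lymph-node involvement in stage-III NSCLC. The unit of analysis is a
single EBUS-TBNA-sampled lymph node; patient-level covariates (primary
tumour SUVmax and laterality, histology, the patient's largest echelon-2
node SUVmax) are denormalised onto node rows. Nodes are grouped into
drainage echelons: 1 = ipsilateral hilum, 2 = ipsilateral central
mediastinum, 3 = upper ipsilateral/contralateral mediastinum or
contralateral hilum. EBUS-TBNA histopathology is the reference label;
its specificity is treated as perfect throughout, while its sensitivity
against latent truth is a free parameter of the observation model.

## Synthetic cohort generator

The generator emulates a 180-patient cohort with ≈675 sampled nodes.
Defaults (all overridable through `CohortConfig`):

| parameter | default | origin |
|---|---|---|
| patients | 180 | cohort size being emulated |
| mean nodes/patient per echelon | 169/180, 297/180, 209/180 | published echelon counts |
| involvement prevalence per echelon | 0.86, 0.42, 0.096 | published EBUS-positive fractions |
| EBUS sensitivity | 1.0 (0.85 in combined-test studies) | observation model |
| primary SUVmax | log-normal, median 14.65, 5–95% 4.85–30.35 | published quantiles |
| positive-node model | log SUV = β₀ + 0.55·log SUVprimary + δₑ + ε | published slope and echelon offsets δ₂ = −0.328, δ₃ = −0.422 |
| residual sd σ_res | ≈ 0.593 (derived, see below) | variance decomposition |
| negative-node SUVmax | log-normal, median 2.43, 5–95% 0.90–5.30 | published quantiles |
| diameters | log-normal per echelon × status from published quartiles | published quartiles |
| conglomerate probability | 0.03 | rare-event choice consistent with the ≥6 cm size-group rule |
| adenocarcinoma fraction | 304/675 | published histology split |
| right-sided primary fraction | 337/675 | published laterality split |
| station-4R-with-left-primary rate | 55/338 of left-primary nodes | marginal flag count ≈ 55/675 |

**Distribution family.** Every positive continuous quantity is
log-normal, consistent with the observation that log SUVmax of involved
nodes is approximately normal. A published median and one quantile pair
pin the parameters: `mu = ln(median)` exactly, and
`sigma = (ln q_hi − ln q_lo)/(z_hi − z_lo)`. When both an IQR and a
5–95% span are available for the same quantity, the IQR is used (more
central, less tail-sensitive). A log-asymmetric printed pair then cannot
be matched at both ends; the fit preserves the median and the quantile
*ratio*, which the tests check by simulation.

**Residual variance.** The marginal sd of log SUVmax among echelon-1
positives, from the published quartile ratio, is ≈ 0.668. Subtracting
the variance explained by the primary, 0.55² × var(log SUVprimary)
(primary log-sd ≈ 0.557), leaves σ_res ≈ 0.593. The alternative
constraint implied by the published fit correlation R ≈ 0.45 would give
a somewhat different σ_res; the quartile-matching value is the default
and the discrepancy is accepted as a known, unresolved tension.

**Intercept.** β₀ is chosen so the median echelon-1 positive SUVmax at
the median primary equals 10.6: β₀ = ln 10.6 − 0.55·ln 14.65 ≈ 0.885.

**Structure deliberately not modelled.** Node involvement is independent
across nodes given echelon; the real cohort shows intra-patient spread
structure (station-4R crossover for left-sided primaries, the largest
echelon-2 SUV as a predictor) that implies correlated involvement. Only
the marginal features are produced. Consequently, passing tests
demonstrate calibration and internal consistency of the pipeline on this
generative regime — not classifier performance on real patients, where
intra-patient correlation, scanner effects and reader behaviour matter.

**Randomness.** One root seed is split into a child stream per patient
(`SeedSequence.spawn`); within a patient, draws follow a fixed order
(primary SUV, laterality, histology, node counts, then nodes
echelon-ascending). Adding downstream features therefore never perturbs
earlier draws, and a fixed seed yields bit-identical cohorts. Patients
whose Poisson node counts are all zero are redrawn once and then
accepted. Node diameters are truncated below at 0.5 cm (EBUS samples
nodes ≥ 5 mm); conglomerate nodes are drawn from the same distribution
truncated at 6 cm. A patient with no echelon-2 node receives one
auxiliary draw from the negative-node distribution as its "largest
echelon-2 SUV" — an unsampled background node, so the feature exists for
every record without leaking truth.

## Weighted logistic model

The design encodes echelon by reference (dummy) coding with echelon-1 as
baseline plus SUVmax × echelon interaction products; covariates enter in
raw units (SUV, cm). Case weights are `w` on EBUS-positive nodes and 1
on negatives, normalised to sum to the sample size; the weighted
Bernoulli log-likelihood is maximised by IRLS with step-halving
(tolerance 1e-8 on coefficients, 100 iterations). The covariance is the
inverse weighted Fisher information; Wald χ² tests are 1-df per column,
with the echelon contrasts and the interaction pair tested jointly
(2 df).

Numerical choices:

* **Separation.** Divergence is declared when any coefficient exceeds
  100 on internally standardised inputs and reported as an error. The
  bound is deliberately loose: with raw-unit covariates and interaction
  columns, legitimate converged fits on this generator's regime produce
  standardised magnitudes of 10–30.
* **Quasi-separation.** A flat likelihood (relative change < 1e-12)
  with still-moving coefficients — typically a rare binary flag that is
  perfectly predictive in sample — is accepted as converged; the
  affected coefficient is at its in-sample supremum direction but
  predictions are unaffected.
* **Cross-validation folds.** The fold-level trainer reduces the design
  to a maximal linearly independent column set (pivoted QR) before
  fitting, because small training subsets can leave a rare column
  constant; if a fold still separates (e.g. no positive echelon-3 node
  in the subset), the monotone IRLS is run to its iteration cap and the
  saturated probabilities are used for scoring.

Backward elimination is not applied: the full covariate set is always
fit, since the model's role in the pipeline is scoring, not inference on
a reduced model.

## Machine-learning backends

The tree ensemble is a 200-tree random forest; the feed-forward network
has four hidden layers of 8 units (scikit-learn defaults otherwise,
fixed seed). Both satisfy a common contract: design matrix in,
probability of EBUS-positivity out, deterministic under the seed. The
feed-forward optimiser takes no per-sample weights, so integer case
weights are realised by row replication, which maximises the same
weighted likelihood up to the regularisation scale. Variable importance
reports structural split counts (from the ensemble's trees) together
with a held-out permutation loss reduction (mean increase in log-loss
when one column is permuted; negative values are possible and
meaningful). For a backend without introspectable trees the split counts
are zero and the report is flagged permutation-only.

## Calibration and cross-validation

Two levers fix an operating point: the positive-case weight during
training (searched over the integer grid 1–20 at a fixed cut-off of
0.5, smallest weight whose cross-validated sensitivity reaches the
target) and the probability cut-off (largest observed score whose
"at-or-above" rule reaches the target sensitivity — equivalently the
⌈target·n_pos⌉-th largest positive score). Calibration always uses
cross-validated scores, not resubstitution.

Outer folds are threefold, formed by sorting uniform random keys into
near-equal blocks. For nested CV each outer training set is subdivided
into five inner samples by independent uniform draws (inner sizes are
random by design); each of the five candidates trains on four samples
and is ranked by sensitivity, then specificity, computed on its own
training data at cut-off 0.5 — matching the selection rule being
emulated, despite its optimistic bias — with ties broken by lowest
inner-sample id. The winner scores the untouched outer fold, so every
record's score comes from a model that never saw it. An outer training
set with an empty inner sample is re-randomised with an incremented
sub-seed and the event logged.

## Comparison statistics

* **Weighted exact McNemar.** Per record, correctness of each classifier
  against the label; discordant records accumulate weight `w_MCN` when
  EBUS-positive and 1 otherwise; weights are normalised to sum to n over
  all records; the two discordant totals are rounded to integers b*, c*
  and the two-sided exact binomial p-value is
  `min(1, 2·P(Bin(b*+c*, ½) ≤ min(b*, c*)))`. With weight 1 this is
  exactly the classical exact McNemar test (verified against
  enumeration). The normalise-then-round treatment of fractional
  weighted counts is this package's interpretation of weighted
  frequency-table software behaviour, which is not fully documented
  elsewhere; the unweighted path is standard.
* **Fisher exact / Kruskal–Wallis** delegate to SciPy (two-sided
  hypergeometric-enumeration definition; tie-corrected H), with
  degenerate inputs (zero margin, all-equal values) mapped to p = 1
  rather than errors.
* **AUC.** Mann–Whitney probability with half credit for ties; variance
  and paired comparison via DeLong structural components; Wald CI
  clipped to [0, 1]. Identical score vectors compare as χ² = 0, p = 1;
  a zero-variance difference with unequal AUCs returns an undefined
  marker.
* **Log-SUV models.** `primary_covariance`: log node SUV on log primary
  SUV plus echelon dummies; `intra_patient`: patient and echelon factor
  dummies. F tests are drop-term (full model vs. model with the term's
  columns removed), the Type-III construction under this coding. Echelon
  dummies are built only for echelons present in the data, keeping
  two-echelon subsets identifiable.
* **Confusion metrics.** Cells are real-valued so expected (fractional)
  counts from the combined-test arithmetic flow through the same code;
  FDR = FP/(FP+TP); undefined ratios return NaN markers. A printed
  (MCR, FN) pair plus totals reconstructs the full 2×2 table.

## Combined tests

Under independence, the OR-combination obeys
`SE_ab = SE_a + SE_b − SE_a·SE_b` and `SP_ab = SP_a·SP_b`. The
expected-error arithmetic back-calculates prevalence as
(observed positives)/(assumed reference sensitivity) — 291/0.85 ≈ 342 —
and computes expected FN = prevalence·(1 − SE), expected
TP = prevalence − FN, expected FP = called-positives − expected TP
(floored at zero with an inconsistency flag), misclassifications =
FP + FN. By convention the called-positive count for a
classifier∨reference combination is the classifier-alone count (349 in
the worked example), reproducing the printed arithmetic; an
augmented-positives variant — adding the reference-only positives (365)
— can be computed by passing that count instead. Empirical OR-combined
sensitivity on real calls falls below the independence prediction when
the two tests' errors are positively dependent; the identity holds in
expectation only under independent error mechanisms, which the tests
verify by Monte Carlo.

## Experiment driver

`run_experiment` wires the stages together: cohort (generated or
loaded), cross-validated scores per classifier (plain threefold for the
logistic and tree-ensemble models, nested for the feed-forward model),
weight calibration to the lowest target then cut-off calibration per
target, and the report bundle. The McNemar reference is a
"pseudo-expert": the fixed SUV-threshold scorer calibrated to 94.5%
sensitivity against latent truth — a synthetic stand-in for the human
expert rater a real dataset would provide, labelled as such in outputs.
The fixed-threshold classifier (default SUVmax ≥ 2.5) ignores target
calibration and reports its native operating point. All outputs carry
the seed and a hash of the semantic config fields; two runs with the
same config produce byte-identical CSVs.

## Problem sizes

The default test and acceptance runs use the generator's native scale:
one 180-patient cohort (~675 nodes) for single-cohort checks, 200
replicate cohorts for the prevalence-calibration average, 10⁵ draws for
distribution medians, and oracle suites at n ≤ 500 (brute-force
likelihood maximisation, pairwise AUC counting) or n ≤ 30–40 (exact-test
enumeration). Smaller 60-patient cohorts exercise the cross-validation
and backend paths where full-size runs would add nothing but time.

## Known limitations

* Independence of node involvement given echelon understates
  intra-patient clustering; per-patient error rates on real data will be
  more variable than the generator suggests.
* The weighted McNemar's rounding step makes its p-value piecewise
  constant in the weight; very large weights with few discordant
  negatives can round a tail count to zero.
* Data-dependent published quantities (AUCs ≈ 0.95, specific McNemar
  p-values, per-echelon FDR percentages) require the original
  patient-level data and are out of reach by design; the pipeline
  reproduces the procedures and the closed-form arithmetic, and its
  stochastic checks are statements about the generator's regime.
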