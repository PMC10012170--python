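# Methods

This note records the modelling choices behind `nanohazard`: what each
stage assumes, the defaults and why, and what the synthetic data can
and cannot show.

## Problem setting

One row of the experiment table is a single in-vitro exposure of a
human cell line (A549 lung epithelial or HCT-116 intestinal) to a
silver nanoform (AgNF) at a dose of 0.1–100 ppm for 24 h, with the
measured cellular viability (%) as outcome. Each nanoform is
identified by an ERM code and carries a constant system-independent
fingerprint (XPS atomic concentrations of O 1s / Ag 3d / C 1s / Na 1s
/ N 1s, TEM core size, XRD crystallinity and average crystallite
size, and its coating), while the system-dependent state in medium
(DLS hydrodynamic size and polydispersity index at t0 and t24)
varies with dose and pretreatment. HCT-116 exposures may use a
digestion-cascade pretreatment of the nanoform.

The outcome is discretized by the ISO 10993-5 thresholds: safe
(viability ≥ 70 %), toxic ([30, 70)), very toxic (< 30 %). Both
boundaries are left-closed on the stated inequalities; viability above
100 % (assay noise) is retained unmodified and classifies as safe.

The spherical surface area is the closed form 4π·s² with the
tabulated core-size value s plugged directly into the squared term.
This convention reproduces the published tercile edges (17.8 nm →
3981.53 nm², 20 nm → 5026.55 nm²) to within 0.1 %; inconsistent input
rows are a data-quality issue to be flagged, not repaired.

## Synthetic study design

The generator's defaults *are* the study conditions: 6 nanoform
profiles keyed by the study's ERM identifiers, 5 exposure arms
(A549 × MTT, A549 × Alamar blue, HCT-116 × WST-1 digested /
non-digested / untreated control), a 10-value dose grid spanning
0.1–100 ppm, and 3 replicates — 900 rows. A 9-value grid over the
4 assay/pretreatment arms cannot produce a 900-row table for any
integer replicate count, so the grid gains one mid-range dose
(2.5 ppm) and HCT-116 an untreated control arm; both are ordinary
choices for this kind of design.

Viability follows a Hill dose–response,
V = 100 / (1 + (dose/EC50)^h) + ε with ε ~ N(0, noise_sd²),
the minimal monotone mechanism the network must recover. Defaults:
per-profile EC50 of {5, 10, 20, 40, 150, 600} ppm so that the dose
grid populates all three classes with a safe majority (≈ 69 / 11 / 20 %
safe / toxic / very toxic at seed 42); hill slope 1.8 (transitions
spread over roughly a half-decade of dose, so the toxic band is
populated but not dominant); noise_sd 4 % viability (typical
plate-assay replicate scatter, rarely flips a class). Digestion
multiplies EC50 by 0.8 (mildly increased bioavailable silver), the
Alamar-blue readout by 1.1.

The DLS state is one measurement per exposure condition, shared by
replicates: t24 size = t0 size · (1 + r·log10(1 + dose)) with
agglomeration rate r = 0.25, and the polydispersity index grows with
the same term. Missingness is MCAR at the study rates (0.47 on the
four DLS columns, 0.19 on the spherical surface area); an optional
anchor-dose mode blanks all non-anchor doses instead, to exercise
interpolation specifically.

What the generator does **not** emulate: dissolution/ion-release
kinetics, assay interference, informative (non-MCAR) missingness,
and between-batch variation of the fingerprints. Passing tests
therefore show that the pipeline recovers structure it is designed to
recover, not that the published biological conclusions transfer.

## Preprocessing

Interpolation fills a missing system-dependent value at dose d
linearly between the nearest observed smaller and larger doses of the
same (nanoform, cell line, pretreatment) stratum; outside the
observed dose range the cell stays missing, and values never cross
strata. Replicate observations at one dose are averaged before
interpolation.

Chained imputation then models each incomplete numeric column as a
LightGBM regression on all other features, with the ERM identifier
and the categorical context one-hot encoded as fully observed
predictors. Columns are visited in ascending-missingness order from a
column-median initialization, for at most 10 rounds or until the
largest cell change falls below 1e-3 relative to the column scale
(scikit-learn's `IterativeImputer` drives the loop). These settings
are fixed for reproducibility; the visitation order and stopping rule
are otherwise unidentified.

The final modeling view keeps 15 inputs + outcome: the organ column
is dropped as redundant with the cell line, multiwell and cell type
as near-constant free text, Na 1s and N 1s for their redundant zero
values, duration as constant (24 h), the ERM identifier as a label
rather than a causal feature, and the pretreatment flag (absent from
the final feature list; its effect reaches the model through the
system-dependent DLS state).

SMOTE balances the hazard classes on the 80 % training split only:
each synthetic row is x + u·(x_nn − x), u ~ U(0,1), with x_nn one of
the k = 5 same-class Euclidean nearest neighbours found on z-scored
features (interpolation happens in the original feature space; the
two are affinely equivalent). The published account of the row count
after balancing is ambiguous between balancing the training split and
balancing all rows; both modes are supported and neither is asserted
in tests.

Tercile discretization places edges at the 33.33rd and 66.67th
percentiles (linear-interpolation percentile definition, the common
default). Bins are left-closed with the high bin open-ended; values
below the fitted minimum fall into *low*. For the network, categorical
features stay single multi-state nodes (one-hot indicators would break
the interpretability of the extracted rules); one-hot encoding is used
for the numeric baselines only.

## Association analysis

Numeric–numeric pairs use Spearman's ρ; any pair involving a
categorical column uses classical Cramér's V (χ² without continuity
correction, no Bergsma bias correction — users comparing against
bias-corrected toolkits will see smaller values there), with numeric
members tercile-binned first for consistency with the discretization
stage. Undefined cells (constant or single-state columns) are
reported as missing, never coerced to 0. Skewness is the adjusted
Fisher–Pearson standardized third moment. The Mapper summary covers
the lens range with overlapping intervals, single-linkage clusters
each preimage on min–max-scaled features, and joins clusters sharing
rows; with one interval it degenerates to plain single-linkage
clustering, which is the behaviour tests pin.

## Bayesian network

Structure search optimizes a decomposable score — BDeu with
equivalent sample size 1 by default, BIC as the alternative — over
constraint-permitted parent sets. Exact search runs a per-node
best-parent-set table plus dynamic programming over variable subsets
and is practical to about a dozen nodes (the implementation refuses
larger inputs and points to the hill climber); its default parent cap
is 4, with named nodes exemptable so that the outcome can keep
dose/assay/descriptor parents simultaneously. Hill climbing starts
from the constraint-seeded graph and greedily applies the best
add/delete/reverse move (six-parent limit, lexicographic first-found
tie-break, so the search is deterministic).

The expert constraint set: dose → hazard and assay → hazard required,
dose and assay roots with no other outgoing arcs; nothing may
determine dose or assay; coating → spherical surface area and
coating → Ag 3d required while core size → coating is forbidden;
t24 dispersion states may not parent t0 states; the hazard node is
the unique sink. Score-driven search alone cannot make a node's
childlessness illegal, so after the search every childless non-sink
node receives its single best-scoring permitted outgoing arc
(respecting acyclicity and the child's parent cap). This repair is
part of constraint enforcement, costs the score only what the
chosen arc costs, and keeps the constrained score at or below the
unconstrained one.

CPTs are smoothed relative frequencies,
(count + α) / (total + α·|states|), with α = 0.5; unobserved parent
configurations yield the uniform row. Inference is exact variable
elimination with a min-degree ordering (posteriors are
order-invariant; tests check two orderings against each other and
against full joint enumeration at ≤ 6 nodes). Evidence with zero
joint probability raises a distinct signal rather than returning a
uniform distribution. Class prediction takes the posterior argmax
with exact ties broken toward the more hazardous class
(precautionary).

## Rule extraction

The default evidence set is the outcome's Markov blanket (for the
learned structures this is the outcome's parent set, since the sink
has no children). Each nonzero-probability configuration contributes
one rule per class with the class posterior p and CF = p/(1 − p).
The posterior-odds definition is adopted because it reproduces the
published worked pair (p = 0.87, CF = 6.7) exactly; an
evidence-likelihood-ratio variant P(X|T)/P(X|¬T) is provided for
comparison but is not the default. Merging over a free feature
(typically dose) averages member probabilities and member CFs
*separately* — the mean of odds, not the odds of the mean — which is
how a merged rule with average probability 0.87 can carry a CF an
order of magnitude above 6.7 when one member is near-certain. The
averages are unweighted by data support (the weighting is
unidentified; support counts are attached so users can reweight).
Zero-probability configurations (skipped) and infinite-CF rules
(discarded) are counted separately in the extraction log.

## Validation

Regression baselines report MAE, RMSE and R² (reported as computed,
possibly negative on test data); classifiers and the networks report
one-vs-rest per-class precision, recall, F1 and balanced accuracy
(TPR + TNR)/2, the overall balanced accuracy as the macro mean of
per-class recalls, and the multiclass Matthews correlation
coefficient. The baseline sweep is a fixed representative set
(random forest, extremely randomized trees, LightGBM, and a linear
model) with library-default hyperparameters and pinned seeds, with
10-fold internal cross-validation on the 80 % split and external
metrics on the 20 % split.

## Problem sizes and numerical choices

The test suite and the pipeline run at the study's own scale
(900 rows, 16 nodes); structure-search oracles use 4-node exhaustive
enumeration (543 DAGs) and 5-node sampled recovery at n = 5000;
inference oracles enumerate joints at ≤ 6 nodes with a 1e-10
agreement tolerance. CPT rows are validated to sum to 1 within
1e-12. All stochastic stages take explicit seeds and the pipeline
writes byte-identical JSON artifacts on re-runs with the same config.

## Known limitations

- Hazard classes are treated as nominal by the network and the
  metrics; the ordering enters only through the precautionary
  tie-break.
- The unique-sink repair adds arcs for constraint reasons, not score
  reasons; on data where a feature is genuinely disconnected this
  slightly biases the structure toward connectivity.
- MCAR missingness makes the imputation benchmark easier than
  dose-conditional missingness in real DLS campaigns.
- Exact structure search is exponential in the node count and is not
  intended for the full 16-node problem; the hill climber carries no
  optimality guarantee there.
- The Mapper summary depends on cover and linkage parameters; it is a
  descriptive view, not an inferential one.
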