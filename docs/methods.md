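# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind the package, and what the synthetic-data experiments do
and do not demonstrate.

## Curation model

Bioactivity records are accepted only with endpoint in {IC50, EC50, Ki, Kd},
unit nM, relation "=", and molecule type "Small molecule"; everything else
is dropped and counted per filter, so `kept + Σ dropped = input` holds for
any input.  Potencies are modeled on the p-scale, pIC50 = −log₁₀(value [M])
= 9 − log₁₀(value [nM]).

Duplicate (compound, dataset) measurements are replaced by their mean pIC50.
In base-model mode the pair is discarded outright when the sample (n−1)
standard deviation of its duplicates is ≥ 0.5 pIC50 units; single
measurements are always kept.  The threshold is applied on the p-scale —
the natural scale for multiplicative assay error, and the scale on which
the 0.5 threshold is commensurate with the ~0.5 pIC50 experimental
uncertainty of heterogeneous public IC50 data.  Endpoint-dataset mode (used
for the modeled cell-line/target sets) averages duplicates without the SD
guard, keeping as much data as possible for benchmarking.

Structure standardization reimplements the standard preprocessing rules
directly in RDKit: parse (SMILES or SDF), split fragments, reject entries
with no organic fragment (no carbon bonded to H or another carbon), keep
the largest organic fragment (heavy-atom count, ties broken by canonical
SMILES order so the choice is deterministic), neutralize protonated/
deprotonated atoms via the usual charged-atom SMARTS pattern (excluding
charge-separated motifs such as nitro groups), and emit canonical SMILES.
Standardization is idempotent.  Tautomer canonicalization beyond these
rules and 3-D descriptors are out of scope.

## Descriptors

- **Morgan2**: hashed circular fingerprints, radius 2, 1024 bits, binary.
- **Physchem**: RDKit's full fixed list of 1-D/2-D physicochemical
  descriptors (~210 in the RDKit release pinned here; the canonical list of
  this kind is usually quoted as ~200 — the exact count tracks the RDKit
  version).  Column order is fixed; non-finite values are imputed with the
  column median over the featurized set (0 if a whole column is
  non-finite); constant columns are retained, which is harmless for tree
  learners.

## Base models and scores

Each per-target base model is a `RandomForestRegressor` with 100 trees and
library defaults otherwise (RF is robust across parameter values at this
scale; tree count beyond 100 yields no practical gain).  Training uses a
seeded random 70/30 train/test split, then 10-fold cross-validation on the
training portion.  Scores:

- **q²** — squared Pearson correlation between observed values and pooled
  out-of-fold predictions (default).  No single formula for q² is
  universal; the 1 − PRESS/SS variant is available via
  `ModelConfig(q2_variant="press")`.
- **R²_test** — squared Pearson correlation on the held-out 30%, from a
  final model refit on the full training portion.  By default this is a
  single seeded split; averaging over repeated splits can be done by the
  caller (the benchmark module does exactly that with shared splits).

Both scores define the selection gates q² > 0.5 and R²_test > 0.6 (strict
inequalities); thresholds are parameters, not constants.  R² of a constant
prediction vector is defined as 0.

## Cross-conformal intervals

The nonconformity score is the raw absolute out-of-fold residual |y − ŷ|,
kept per CV fold — unnormalized, since no error-model normalization is
assumed (a hook for a normalized variant exists in the calibration object).
For a fold with n scores at confidence 1−ε the half-width is the k-th
smallest score with k = ⌈(1−ε)(n+1)⌉, the finite-sample-valid convention;
k > n means the fold cannot certify that confidence and is undefined.
Folds are aggregated by the **median** of defined per-fold half-widths
(configurable: `pooled` merges all scores first, `max` is the most
conservative).  If every fold is undefined the interval is +∞ — such
predictions are always outside the applicability domain.  Because the score
is unnormalized, the half-width is a per-model constant at a given
confidence.

Marginal validity (coverage ≥ 1−ε up to Monte-Carlo error on exchangeable
data) is exercised in the test suite and recomputed from scratch by
`scripts/acceptance.py` (10 linear features, unit Gaussian noise, n_cal =
n_test = 500, 20 seeds, 90% confidence).

## QAFFP assembly

rv-QAFFP columns are base-model ids in registry order (registry order is
the fingerprint bit order contract); the companion error matrix holds
conformal half-widths at the configured confidence (default 0.90).
b-QAFFP sets bit = 1 iff prediction > 5 pIC50 **and** half-width < 2 pIC50.
Both comparisons are strict; boundary cases (prediction exactly 5,
half-width exactly 2) yield 0.  The applicability-domain threshold is
interpreted as the interval *half*-width (±2 pIC50) and is configurable,
since "interval lower than 2" and "no wider than ±2" describe different
widths; the half-width reading was chosen as the stricter, symmetric one.
Sub-cutoff predictions inside the AD and all predictions outside the AD
(including infinite half-widths) are 0, on the assumption that an arbitrary
compound is more likely inactive than active on an arbitrary target.

Model subsets: `selected_only` (gate-passing models), `all`, or
`r2_cutoff:x` (R²_test ≥ x, preserving registry order; subsets are nested
in x).  When fingerprinting a modeled protein target, base models for that
target and its orthologue group are excluded; cell-line datasets have no
protein target and are unaffected.  The benchmark menu comprises 11
descriptor sets: three QAFFP variants (rv selected, b selected, rv all),
two baselines (Morgan2, Physchem), and the six QAFFP × baseline
concatenations.

## Factorial benchmark and analysis

The benchmark is a balanced fixed-effect full-factorial design with
replications: every (dataset, descriptor set, replicate) cell trains one RF
(100 trees) on a seeded 70/30 split and records RMSE_test and R²_test.  The
split seed is derived by stable hashing of (master seed, dataset id,
replicate index) — never the descriptor — so all descriptor sets within a
replicate share the identical partition.  This shared-split contract is
what makes the descriptor contrast a within-replicate comparison.

The analysis fits `RMSE_test ~ dataset * descriptor` by OLS with treatment
coding against a chosen reference cell, so the intercept μ₀ is the
reference cell's mean RMSE and slopes are cell-mean differences; with the
full interaction the model is saturated and fitted values equal cell means
(verified against an independent cell-means oracle).  Reported: adjusted
R², residual SE, an interaction F-test, and residual diagnostics
(residual-vs-fitted, histogram, normal Q–Q, and a Breusch–Pagan flag for
heteroscedasticity at α = 0.05 — a numeric stand-in for visual
inspection).  Designs without within-cell replication have zero residual
degrees of freedom; their standard errors are undefined (NaN) and adjusted
R² is reported as 1 when the fit is exact.

Other analyses: Y-scrambling permutes training labels only (test labels
untouched); AEP tables bucket pooled test instances by joint absolute error
of two descriptor sets using **cumulative** thresholds (both ≤ 0.5 counts
inside both ≤ 1.0), pooling instances across replicates; the similarity
analysis pairs Jaccard–Needham dissimilarity on Morgan bits — with the
all-zero/all-zero pair defined as 0, a convention for pathological
moleculeless rows — against Pearson correlation of rv-QAFFP profiles, and
reports the across-pairs correlation with a two-sided p-value.

## Synthetic data

The generator emulates the *shape* of public bioactivity data, not its
chemistry: molecules come from a scaffold-plus-substituent SMILES grammar
(8 scaffolds × 24 substituents, all parseable and standardizable), with a
configurable fraction carrying counterions, duplicated measurements, and
">" relations to exercise every curation filter.  Per-target pIC50 is a
sparse linear function of the compound's Morgan bits (8 signal bits drawn
from bits with 5–95% prevalence, coefficients ~ N(0, 2.0 pIC50), baseline
6.0) plus N(0, noise_sd).  The sparsity and coefficient scale are chosen so
that the noise-free map is fully learnable by a 100-tree forest at n = 300
— the generator's purpose is pipeline verification with known ground
truth.  Cell-line activities are sparse linear combinations of the *true*
per-target activities (3 active targets, weights ~ N(0,1), centred on the
baseline), so an affinity fingerprint from well-trained base models is
predictive of them by construction, and a label-permuted control is not.

Consequently, passing tests demonstrate correctness of the machinery —
curation arithmetic, split sharing, conformal validity, recovery of
planted signal — and *not* chemical realism or transferability to ChEMBL-
scale data, whose headline error levels depend on external data
heterogeneity that this generator deliberately does not model.

All randomness flows from integer seeds through SHA-256-based fan-out
(`qaffp._seeds.derive_seed`), so every stage, benchmark job and simulation
stream is independent and platform-stable, and end-to-end runs are
reproducible bit-for-bit.

## Problem sizes

The test suite trains base models at n = 60–300 compounds per target and
benchmarks at 1–5 replicates; the end-to-end recovery experiment uses 5
targets × 300 compounds and 2 cell lines (noise-free), and the coverage
simulation uses 500/500 calibration/test points over 20 seeds.  These sizes
were chosen as the smallest at which the measured properties (q² gates,
coverage, recovery R²) are stable across seeds.

## Known limitations

- The eTOX-style standardizer rule set is reimplemented from its stated
  behavior (fragment choice, inorganic rejection, neutralization), not
  byte-compatible with any external binary; exotic organometallics and
  tautomer normalization are out of scope.
- Nonconformity scores are unnormalized, so intervals are constant per
  model rather than per-compound adaptive.
- The factorial model treats replicates as exchangeable; it does not model
  replicate-level correlation induced by overlapping training sets (the
  usual caveat of repeated random splits).
- The registry scales to thousands of models but stores dense matrices;
  bit-packed/sparse storage and streaming featurization are non-goals.
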