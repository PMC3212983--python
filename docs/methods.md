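# Methods

## Problem and model

The quantity predicted is per-chain disorder content: y = (# disordered
residues) / L ∈ [0, 1], where "disordered" follows the usual structural
convention (residues without resolved coordinates, or curated disordered
segments). The predictor is chain-level by design: instead of sliding a
window over residues, every input track is aggregated over the whole chain
into one fixed-length feature vector, and a penalized linear model maps that
vector to the content. Inputs beyond the sequence (profiles, secondary
structure, RSA, B-factor/flexibility, domain and signal-peptide tracks) are
consumed as precomputed per-residue annotations; running the upstream
predictors is out of scope.

## Feature catalog

The default catalog enumerates nine families to 453 features. It is an
explicit, fingerprinted object (`FeatureCatalog`): vectors are only
comparable when their catalog fingerprints match, and the fitted model
refuses mismatched inputs.

* **aa_comp** (22): the 20 residue fractions plus the order-promoting
  {W,Y,F,I,L,V,C,N} and disorder-promoting {A,R,G,Q,S,E,P,K} group
  fractions.
* **segment families** (ss_segment / exposure / flexibility / domain /
  signal; 126 + 1): for each track–state mask, run statistics: run count /L,
  fraction of residues in runs, fraction in runs of length ≥ k for
  k ∈ {2, 4, 6, 8, 10, 15, 20} (the ladder covers short and long segments
  around the diagnostically useful k = 10), longest and mean run length /L,
  and relative locations (first run start, last run end, longest-run
  midpoint, all /L, measured from the N-terminus; 0 when the mask is empty).
  `CHC...CHSeg` is the longest secondary-structure stretch containing no
  strand, reported as a raw residue count (its definition is a count; all
  other lengths are /L).
* **fusion** (176): fractions of residues satisfying conjunctions of 2–4
  sources among SS state-set ({H}, {E}, {C}, {H,E}, {C,H}, {C,E}), exposure,
  rigidity and domain membership. Two historically named members keep their
  names: `SS_HE_DOM_in_BFNS_low_RSA_B` and `SS_CH_BFNS_high_DOM_notin`.
* **profile_entropy** (12): per matrix (PSSM, WOP) the mean/min/max per-row
  Shannon entropy, mean per-row relative entropy, and the entropy and
  relative entropy of the normalized column-mean vector (`EntAvePSSM`,
  `EntAveWOP`). Entropies are in bits; row entropies lie in [0, log₂20].
* **conditioned_entropy** (116): mean per-row (relative) entropy restricted
  to residues of a given amino acid, SS state, exposure, flexibility or
  domain class; 0 with a flag when no residue qualifies.

### Preprocessing

Before extraction: maximal helix runs shorter than 3 residues are rewritten
to coil (strand runs untouched); raw ASA is divided by a standard
residue-type maximal-ASA table and clipped to [0, 1] (already-relative RSA
passes through); exposure is RSA > 0.25 (the conventional cutoff); rigidity
is normalized B-factor ≤ 0 (normalized B-factors are centred at zero, so the
sign separates rigid from flexible). The strict/non-strict flexibility
tracks are used as-is where a feature names flexibility rather than
B-factor.

### Numerical choices

* PSSM scores are mapped to probabilities by the logistic squashing
  1/(1+e^(−s)) per cell followed by row renormalization — a standard
  monotone transform that keeps entropies defined for integer log-odds.
* WOP percentages are divided by 100 and renormalized; all-zero rows (which
  profile generators emit at some positions) become the uniform row rather
  than leaving entropy undefined.
* The relative-entropy background is uniform (1/20) by default and
  configurable to a composition table.
* Missing-track policy: a feature needing an absent track evaluates to 0 and
  is flagged in the extraction log; training refuses datasets whose records
  differ in track completeness unless explicitly overridden, because silent
  zero-imputation would corrupt the correlation filters.

## Feature selection

Step 1 (correlation): each feature's |PCC| with the content is averaged over
the training folds of a 5-fold cross validation; features below 0.2 are
dropped. Survivors are walked in decreasing target-|PCC| order and kept only
if their fold-averaged pairwise |PCC| with every already-kept feature is
below 0.9 (pairwise correlations are computed on the same folds as the
target correlations, mirroring that protocol). Ties are broken
lexicographically by feature id everywhere, so the outcome is independent of
input column order.

Step 2 (wrapper): a greedy single-scan best-first search. Forward: from the
empty set, scan candidates in decreasing target-|PCC| order, accepting an
addition only when it lowers the incumbent repeated-CV MSE by more than
1e−6 (guarding against float-noise churn); backward is symmetric with
removals from the full set. One confirmation pass re-scans the remaining
moves; the search stops at the first pass with no acceptance. A classical
queue with backtracking is deliberately not the default: the stopping rule
is a scan. Note the asymmetry this creates: backward search may retain a
harmless feature whose removal changes the MSE by less than the tolerance.

Scoring: 5-fold CV, re-randomized up to 5 times, stopping after ≥ 2
repetitions once the coefficient of variation of per-repetition MSEs falls
below 0.02. Repetition fold seeds derive deterministically from the run
seed. A mean MSE below 1e−12 is treated as CoV 0 (its relative spread is
float noise). The estimator used inside the wrapper is grid-parameterized
beforehand on a representative subset containing, per feature family, the
feature with the highest target-|PCC|; after selection, one
re-parameterization pass is run on the selected subset (the grid/selection
alternation is not iterated further: a single pass is deterministic, cheap,
and in practice the winning hyperparameters rarely move).

## Regression models

Ridge regression is the deployed model; epsilon-SVR with polynomial
(degree 1–2), RBF, and Pearson VII universal (PUK) kernels completes the
4-estimator × 2-search-direction design space. Grids: ridge
λ ∈ 10^{−11,−9,−7,−5,−3,−1,1,2} (the printed ladder's spacing is
inconsistent; this interpretation keeps step 2 up to 10⁻¹ and adds the two
printed endpoints, and is configurable), poly degree {1,2} × C = 2^{−8..2},
RBF γ = 2^{−11..2} × C = 2^{−3..6}, PUK ω = 2^{−4..1} × C = 2^{−4..5} with
σ fixed at 1 (only ω is swept). SVR ε is fixed at 0.001 — small relative to
a [0, 1] target. Ties in grid MSE go to the lower-complexity point (smaller
C, then smaller secondary parameter).

Features are standardized to mean 0 / SD 1 inside the model and the
constants stored, because the ridge penalty and kernel distances are
scale-sensitive. Predictions are clamped to [0, 1]. Models serialize to a
single JSON document (kind, hyperparameters, coefficients or support
representation, standardization constants, feature ids, catalog
fingerprint) and are bit-stable across save/load.

## Evaluation

Content: MSE, MAE, sample-covariance PCC (reported as missing, never 0,
under zero variance), and the over/under decomposition (fractions of chains
with predicted > / < / = native content, with conditional MAEs; empty
subsets are flagged missing). Residue level: accuracy, MCC (0 by convention
when the denominator vanishes, i.e. single-class predictions), and
rank-statistic AUC with average-rank ties (undefined for single-class
references). Method comparison: Shapiro–Wilk on paired differences, then a
paired t-test; when normality is rejected a Wilcoxon sign-rank fallback runs
and is flagged as such, so downstream consumers can tell which test produced
a p-value. The
PCC comparison draws 200 subsets of 100 chains (without replacement within a
subset, with replacement across subsets — the resampling policy is
underdetermined and this one is seeded and simple) and paired-tests the
per-subset PCCs. Significance is coded ++/+/= at 0.01/0.05.

## Thresholding

`content_guided_binarize` labels exactly m = round(c·L) residues disordered
(round half-up; the matching rule between content and count is
underdetermined, and rounding the count is the variant that is exact under
ties), taking the m highest propensities with ties broken toward the
N-terminus — stable, so the disordered set is nested as c grows.
`optimal_fixed_cutoff` scans midpoints of consecutive distinct pooled
propensities plus sentinels, maximizing pooled MCC (ties → lower cutoff).
`content_class_sweep` classifies chains above/below each cutoff
t ∈ {0, 0.05, …, 1} by native and predicted content and reports the MCC per
cutoff; single-class cutoffs are flagged missing rather than fabricated as
0. The hybrid rule returns the residue-level predictor's own content when it
is > 0.65 or < 0.1 and the regression content otherwise.

## Synthetic data

The generator draws, per chain, a target content (15% of chains fully
ordered, otherwise Beta(1.2, 2.2), mean ≈ 0.35 — a mixed
structured/disordered benchmark) and realizes it as alternating
geometric-length ordered/disordered segments (disordered mean run 25;
acceptance-resampling keeps the realization within 0.08 of the target,
keeping the closest draw otherwise). Conditional on the state:

* SS is segmental — ordered regions mix helix/strand/coil runs, disordered
  regions are long coil with occasional short helices;
* RSA ~ Beta(5, 2.5) disordered vs Beta(2.5, 5) ordered;
* B-factor ~ N(0.7, 0.45) vs N(−0.35, 0.45): normalization is emulated at
  the corpus level (a chain of typical content averages ≈ 0) rather than
  per chain, since exact per-chain centring would erase the chain-level
  signal the model aggregates;
* flexibility flags are Bernoulli (strict 0.6/0.1, non-strict 0.85/0.25);
  domain membership 0.12/0.92; 10% of chains carry an N-terminal
  signal peptide of 15–25 residues;
* profile rows are Dirichlet: ordered positions concentrate on one
  preferred residue (weight 8 over a 0.3 floor — strong conservation);
  disordered positions are high-temperature and biased toward the
  disorder-promoting residues (weight 2 over a 0.25 floor), implementing
  both the faster evolution and the compositional bias of disordered
  regions. The sequence itself is sampled from the profile row, and PSSM
  rows are the integer logit of the row probabilities — the inverse of the
  extraction-time squashing, so both profile encodings are consistent.

The propensity simulator smooths the true labels with a 9-residue moving
average, adds a per-chain bias ~ N(0, 0.25) and residue noise
~ N(0, 0.08), and squashes through a logistic link: a monotone,
chain-biased distortion reproducing the over-/under-prediction pathology
that content-guided thresholding corrects.

What this generator does *not* emulate: realistic amino-acid dependence
between neighbouring positions, length-dependent disorder priors,
predictor-specific error structure, or the annotation noise of real
disorder references. The couplings are strong, so held-out accuracy on
synthetic data (PCC ≈ 1) is an upper bound that demonstrates the pipeline's
correctness, not the accuracy attainable on real chains.

## Problem sizes and determinism

Tests and the acceptance script use 60–300 chains of length 60–300, chosen
so the complete pipeline (extraction → filters → grid search → wrapper →
evaluation) runs in seconds while leaving all statistical checks
well-powered. Every stochastic stage is seeded; the end-to-end pipeline is
reproducible bit-for-bit at the report level for a fixed seed, and dataset
directories written with the same config are byte-identical.

## Known limitations

* The exact historical 29-feature deployment set is not reconstructable
  from public information; the pipeline re-selects from its own catalog
  (five named features are guaranteed present and bit-stable).
* The catalog enumerates ~450 features, not the original 614; the
  enumeration of the original universe was never published.
* "Relative location" features are N-terminus-referenced only (not
  symmetrized) — an assumption.
* SVR models store their full support representation in JSON; for large
  training sets ridge is the practical choice (it is also the deployed
  configuration).
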