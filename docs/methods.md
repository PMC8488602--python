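# Methods

## Scope and data flow

The package models how a photoautotrophic microorganism redistributes
metabolic flux across growth conditions when its genome-scale model is
constrained by both the growth environment and transcript abundance,
and how informative features can then be pulled out of the joint
transcript + flux dataset. The stages are: model curation → transcript
fold-change preparation → condition-specific regularized FBA →
multi-omic fusion → PCA / clustering / LASSO / correlation, each with a
pathway-level aggregation step.

## Model curation

Subsystem annotations in public reconstructions are inconsistent; a
synonym table merges spelling variants ('Amino Acid Metabolisms' →
'Amino acid metabolism', 'Exchange Reaction' → 'Exchange', empty/None →
'Unassigned'), and composite annotations joined by the word "and" are
split into separate subsystems. Names that legitimately contain "and"
(e.g. 'Metabolism of terpenoids and polyketides') are first rewritten
with '&' so they survive. The split matches "and" as a whole word,
case-insensitively — a character-level split would corrupt names such
as 'Island'. Empty fragments are dropped rather than removed at
hard-coded positions. Objective selection is name-based; the binary
indicator vectors `f` and `g` (primary/secondary objective) each carry
exactly one 1 after selection and are cleared on re-selection.

## GPR evaluation

Gene rules are compiled by a recursive-descent parser with the grammar
`rule := term ('or' term)*`, `term := factor ('and' factor)*`, so AND
binds tighter than OR and the MIN nodes are always evaluated before the
MAX nodes; source parentheses are honored. This replaces the
string-substitution approach (substituting gene names longest-first)
with a real tokenizer, which removes the prefix-corruption failure mode
entirely; the `genes_by_length` index is kept as a compatibility field.
Gene matching between model and expression table strips exactly one
terminal `.<digit>` transcript suffix; multi-digit suffixes are outside
the pattern and left intact. The expression vector is rebuilt from all
ones for every condition, so unmatched genes stay neutral and values
cannot leak between conditions.

## Condition-specific regularized FBA

Environmental bounds come from a packaged per-condition table of
exchange bounds (mmol/gDW/h). Dark conditions keep a small residual
photon uptake (lb −0.003); the anoxic/low-O₂ conditions clamp the O₂
exchange to [−0.01, −0.01]; nutrient-limited conditions close the
corresponding exchange to −0.01; the nitrate condition sets the nitrate
exchange lb to −12 (12 mM supplementation), and mixotrophy opens
glycerol uptake at −10. Photon uptake can instead be computed as
`P_U = LC·SA/DCW`; inputs are treated as already per-hour so the result
is in flux units.

Expression mapping is valve-like: bounds are scaled multiplicatively by
φ(θ) = (1 + γ|ln θ|)^sgn(θ−1) with the natural logarithm. γ defaults to
1 and is exposed (`--gamma`) for sensitivity scans. φ is undefined at
θ = 0; levels below `theta_floor` (default 1e−12) silence the reaction
(φ = 0), the continuous limit of the map. Negative lower bounds scale
in magnitude with sign preserved.

The solver is strictly lexicographic: (1) LP maximizing the primary
flux (HiGHS), (2) LP maximizing the secondary flux with the primary
fixed at its optimum within a relative tolerance of 1e−9, (3) minimize
Σv² over the doubly fixed polytope (SLSQP with analytic gradients,
ftol 1e−14). A weighted-penalty blend of the objectives was considered
and rejected: the lexicographic form matches the stated intent of
"norm-2 minimization after objective maximization" without introducing
a tuning weight. Strict convexity of step (3) makes the reported flux
vector unique; two successive solves agree to ≤1e−6 per flux. FVA
constrains only the primary objective (fraction of optimum, default
100%) and reports per-reaction min/max plus the midpoint.

Post-processing takes absolute values and zeroes entries ≤1e−4 (two
orders of magnitude above the 1e−6 solver tolerance); the threshold is
exposed for robustness scans.

## Multi-omic fusion

Transcript fold changes divide each condition column by the mean of the
three control replicates; the per-dataset control normalization lets
two separately-generated tables merge into one 23-condition matrix.
Flux fold changes divide condition rows by the control row, then apply,
in order: values ≤1e−4 → 0, NaN (0/0) → 1, Inf (active over silent
control) → the maximum finite fold change of the matrix (computed
beforehand with Inf treated as 0 and NaN ignored). Transcript fold
changes are deliberately *not* zeroed at the threshold — the asymmetry
is deliberate and preserved. Zero control means in the
transcript table (not addressed by the flux policy's source) adopt the
same NaN/Inf policy for consistency and are logged. The fused matrix
appends an all-ones row for the standard control, giving 24 rows; the
transcript-only analysis matrix has 23 rows by default
(`include_control_in_transcript_pca` adds the ones row).

## Statistics and machine learning

**PCA** standardizes columns with the population (1/n) denominator and
eigendecomposes the correlation matrix via SVD. Variable coordinates
are loading·√eigenvalue, contributions are 100·coord²/eigenvalue (sum
100 per component), individual cos² is the squared coordinate
normalized over all components (sum 1 per row). Signs follow the
largest-magnitude-loading-positive convention.

**Near-constant features.** Optimizer noise (~1e−9) on a constant flux
column would be amplified into a full-variance pseudo-feature by
standardization, so any feature (or profile row) with
sd ≤ 1e−8·max(1, |mean|) is treated exactly as constant: zero PCA
contribution, never selected by LASSO, NaN correlation, unit
correlation distance. This guard exists in all four analyses.

**Clustering** keeps an intentional asymmetry: the
cluster-count scan uses correlation-distance k-means scored by the mean
silhouette (default scan 2–30, 5 restarts, seeded), while the final
clustering is city-block k-means. City-block centroids are
per-coordinate medians — the minimizer of that distance; a mean-update
compatibility mode exists. Empty clusters are refilled with the point
farthest from its centroid. The display embedding is nonmetric MDS
minimizing squared stress (L-BFGS-B on the coordinates, analytic
gradient, ≤500 iterations, seeded random start); degenerate embeddings
(co-located points) trigger a ×1.01 dissimilarity rescale and restart,
up to 10 times.

**LASSO** uses a geometric 100-value penalty grid from λ_max (the
smallest all-zero penalty) down to λ_max·1e−4 — the conventional path
defaults, exposed as options. Predictors are standardized internally
(sample sd) and coefficients reported on the original scale. The mean
predictor coefficient (MPC) averages over the whole path including
zeros; an option averages nonzero entries only — both definitions of
the MPC are in circulation, and whole-path averaging is the default
because it penalizes late path entry. Retention
keeps |MPC| > 0.01, sorted by MPC descending.

**Correlation** reports Pearson r, a two-sided p from
t = r·√((n−2)/(1−r²)) on n−2 df, and a 95% CI via Fisher z ± 1.96/√(n−3)
back-transformed; |r| = 1 collapses the interval and p to zero.
Pathway aggregation sets NaN coefficients to 0, averages |r| per
subsystem, and counts signed r in seven half-open bins partitioning
[−0.7, 0.7); coefficients outside the range go to an explicit overflow
column instead of being dropped.

Pathway aggregation (both PCA and correlation) counts a multi-subsystem
reaction once in every subsystem it belongs to, so subsystem sums
partition the total only on single-membership data.

## Synthetic fixtures

The toy network is a curated, hand-balanced photoautotroph: photon
exchange driving photosystem-like ATP and NADPH production, carbon
fixation, glycerol catabolism, three nitrogen assimilation routes
(nitrate/ammonium/urea), sulfate and iron uptake, a biomass sink, ATP
maintenance, an O₂ dissipation sink (so forced O₂ uptake under anoxic
bounds remains feasible), and a pair of stoichiometrically identical
parallel pathways that exercise the 2-norm tie-break (the unique
solution splits their flux exactly equally). GPR rules include one
parenthesized isozyme rule and one AND/OR mix; one reaction carries a
composite subsystem annotation that the curation step must split. The
topology is fixed — the network is feasible with nonzero biomass under
every packaged condition-bound set — and only the transcriptome
generator is stochastic: RPKM-like values are baseline × per-condition
effect × lognormal noise (CV 0.1 by default, chosen as a realistic
replicate-level variation for RNA-seq abundance estimates; lognormal
for positivity). Planted effects mirror the biology the bounds encode
(photosystem genes down in darkness, `glpK` up 4× under mixotrophy,
assimilation genes tracking the nitrogen source), so fold-change
recovery and flux silencing are testable end to end.

The generator emulates replicate noise and condition effects but not
library-size artifacts, batch effects, count discreteness at low
abundance, or between-study normalization problems; passing tests
demonstrate the pipeline's correctness and sensitivity under clean
multiplicative signals, not robustness to those artifacts.

The LASSO recovery fixture places 3 planted predictors (coefficients
2, −2, 2; residual noise sd 0.1) among 50 noise predictors that share 5
latent factors (idiosyncratic sd 0.3) across n = 12 conditions. The
factor structure mirrors co-regulated transcript modules and is also
what makes support recovery statistically possible at n = 12: with 50
unstructured Gaussian noise predictors, the irrepresentable condition
fails often enough that no effect size yields reliable recovery.

Growth rates for the regression subset are the packaged 12-value table
(standard control first, 0.075 h⁻¹, through high salt, 0.0278 h⁻¹).

## Problem sizes and determinism

Default runs use the 22-reaction network, 24 conditions, 18 transcript
features and the 12-condition regression subset; a full pipeline run
completes in a few seconds on one CPU. All stochastic components
(transcriptome generator, k-means restarts, MDS starts) take explicit
seeds; the pipeline manifest records parameters, seed and SHA-256
hashes, and a rerun with the same seed reproduces every artifact
byte-for-byte.

## Known limitations

- The expression map is valve-like only; switch-like integration
  (removing inactive reactions), omics-guided objectives, loopless or
  resource-allocation FBA variants are out of scope.
- Batch correction / cross-study normalization of expression tables is
  delegated to upstream tools.
- The FVA secondary objective is not constrained (only the primary
  enters the constraint set), matching single-objective variability
  semantics.
- The squared-stress MDS is a local optimizer from a seeded random
  start; different seeds give different (equally valid) embeddings.
- COG-category metadata for transcripts is carried through but not
  aggregated; pathway aggregation applies to reactions via subsystems.
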