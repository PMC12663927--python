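# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design choices made where more than one
defensible option existed.

## Sequence identity and alignment handling

All identity computations run on a single multiple sequence alignment
(the package consumes alignments; it does not build them).  Identity
between two aligned rows is the fraction of matching columns among
compared columns, where columns gapped in *both* rows are excluded from
the comparison, a gap against a residue is a mismatch, and the
ambiguity code `X` matches nothing (including another `X`).  This keeps
`identity(a, a) = 1`, symmetry, and values in [0, 1].  One identity
definition is used everywhere — clustering, coverage, model weighting
and CV thresholding — so results are internally consistent even though
different tools in the wider literature differ in their gap handling.

Alignment columns with a gap fraction *strictly above* 0.95 are removed
before analysis (the keep-rule convention of common trimming tools: a
column at exactly 95% gaps stays).  Trimming records a `column_map`
back to original coordinates and is idempotent.  Ungapped sequence
lengths outside [300, 700] residues are filtered out, bounds inclusive.

Greedy centroid clustering scans sequences in a deterministic order
(decreasing ungapped length, ties by identifier) and assigns each to
the first centroid it matches at or above the threshold, else founds a
new cluster.  The resulting invariants — members ≥ threshold to their
centroid, centroids pairwise < threshold — are enforced by brute-force
oracles in the tests.  The scan order is a parameter; results for
thresholds near the data's identity quantiles depend on it, which is
why it is pinned.

**Diversity coverage** at threshold X is the fraction of representative
sequences (typically 90%-identity cluster centroids) whose best
identity to any kinetically characterized variant is at least X.  It is
non-increasing in X by construction.  The default threshold grid is
0.50–1.00 in steps of 0.05.

## Rate harmonization

Carboxylation turnover numbers (k_cat,C, per active site per second)
enter from two routes — a coupled spectrophotometric pipeline and
direct-assay literature values — and are harmonized in this order:

1. **Q10 correction** to 30 °C with Q10 = 2.2:
   k′ = k · Q10^((30 − T)/10).  The correction is exactly invertible,
   which the tests exploit as a round-trip identity.  Literature
   variants with several published values are collapsed by the median;
   pipeline replicates by the geometric mean (rates are approximately
   log-normal within a form, so the geometric mean is the natural
   within-variant average; the median mirrors how heterogeneous
   published values are usually summarized).
2. **Control normalization**: each pipeline batch is rescaled so the
   geometric mean of its control-variant measurements equals the
   control's reference value.  The control reference is configuration,
   not a constant.  Batches lacking a control are left untouched and
   reported rather than guessed at.
3. **Assay correction**: coupled assays systematically underestimate
   rates.  With the log–log slope fixed to 1, the correction factor
   reduces to the geometric-mean ratio exp(b), b = mean(ln k_direct −
   ln k_coupled) over variants measured by both routes.  The 95%
   interval is a t-interval on the log-ratios — the minimal defensible
   choice given n ≈ 11 pairs, and one whose nominal coverage is
   verified by simulation (200 replicates with an injected 2.1-fold
   bias; coverage ≥ 90% is asserted, leaving slack for Monte-Carlo
   error around the nominal 95%).

Summaries use linear-interpolation quantiles.  The rate-ratio
landscape computes, for every unordered pair of measured variants, the
fold difference max/min ≥ 1 and bins it by pairwise identity; the
median per bin quantifies how smooth the rate landscape is in sequence
space.

## Prediction models

All models operate on natural-log rates.  Sequence features are one-hot
encodings of alignment columns over 21 states (20 amino acids + gap),
position-major, fixed state order; `X` encodes as an all-zero block so
it contributes no similarity.

* **nn** — ln-rate of the most similar training sequence; ties average.
* **mean** — unweighted mean of training ln-rates.
* **weighted_mean** — weights w = exp(−λ(1 − identity)).  Default
  λ = 14, i.e. a 5-point identity drop halves the weight; λ = 0 recovers
  the mean exactly and large λ approaches nn.  The exponential form and
  scale are this package's choice; λ is exposed.
* **svr_rbf** — ε-insensitive support-vector regression, RBF kernel,
  pinned to C = 1.0, ε = 0.1, γ = 1/(n_features × Var(X)) (the backing
  library's documented defaults, stated numerically so any
  re-implementation can match).  A single-sequence training set cannot
  support an SVR fit and degenerates to that sequence's value.

**Identity-thresholded LOO-CV**: for each held-out variant and
threshold X, the training set is every other characterized variant at
identity ≥ X (optionally restricted to the same form).  Targets with no
training sequence at X are excluded from that threshold's RMSE and
reported via `n_evaluable` — so the error at high X describes the
well-covered subset, which is precisely what a practitioner deciding
whether to trust a prediction at a given identity wants to know.
Errors are ln-space RMSE and the fold-change equivalent exp(RMSE) ≥ 1.
All four models are deterministic, so CV results are bit-reproducible.

Per-form prediction trains one model per form on its characterized
members and refuses forms with fewer than 3 (no extrapolation across
forms); predictions are back-transformed to s⁻¹ and carry the form's
CV fold-change error.

## Position association

The association procedure fits 100 depth-3 regression trees
(variance-reduction splits) on seeded random 75% subsamples of the
one-hot matrix and attributes each held-out row's prediction to
features with **exact Shapley values**.  The coalition value v(S) is
the conditional expectation of the tree output with the features in S
fixed: the tree is traversed following the row's branch at nodes
splitting on S and averaging children by training-sample weights
elsewhere.  Because a depth-3 tree uses at most 7 distinct features,
the full 2^|F| coalition enumeration is exact and cheap; features the
tree never uses get exactly zero and local accuracy (base + Σφ = tree
prediction) holds to machine precision, which the tests assert on
every tree.  Per feature the mean |φ| over held-out rows is taken; per
position the feature values of its (mutually exclusive) residue states
are summed; the final score is the mean over iterations.  Held-out
rows are used for attribution (training rows would reward overfit
splits); one master seed derives per-iteration seeds as seed + i, so a
fixed seed gives bit-identical scores.  Tie-breaking between
equal-gain splits follows the backing tree library's seeded behaviour;
determinism, not a specific tie order, is the guaranteed property.

Positions are reported in the residue numbering of a reference
sequence (columns where the reference is gapped are unmapped).
Rate-by-residue comparisons use the tie-corrected Kruskal–Wallis H
(degenerate all-equal input returns H = 0 rather than dividing by
zero) followed by Dunn pairwise z tests with Bonferroni adjustment;
with two tie-free groups the Dunn z satisfies H = z², which the tests
use as a cross-check.

## The synthetic-data generator

The generator produces survey-shaped datasets whose injected parameters
the analyses must recover.

**Tree.** One Kingman coalescent subtree per enzyme form (weights
0.40/0.25/0.15/0.20 for forms I, II, II/III, III), joined at a root
depth of 2.5 coalescent units.  This two-scale structure — within-form
identity roughly 0.85–1.0, between-form roughly 0.30–0.45 — mirrors
real rubisco form structure, where forms are anciently diverged clades.
A single coalescent cannot reproduce this: it holds only ~10 lineages
at 90%-identity depth regardless of sample size, which would blanket
any characterized panel with near-identical neighbours.

**Sequences.** Evolved site-independently down the tree under a uniform
20-state jump model at rate μ = 0.2 substitutions/site per unit branch
length; sequences are born aligned (no indels — alignment construction
is out of scope, and all analyses operate on alignments).

**Latent rate.** The ln-rate follows Brownian motion with variance
σ² = 0.25 per unit branch length from a root value ln 7 (so the central
simulated rate is 7 s⁻¹); an Ornstein–Uhlenbeck mean-reversion
parameter is available and defaults to 0.  μ and σ² were set jointly so
that variant pairs at ≥50% identity differ by less than about twofold
at the median while pairs above 90% are nearly equal — the smooth
rate-landscape regime.  Within a form, leaf ln-rates are Gaussian
(log-normal rates) by construction.

**Causal sites.** A planted site assigns a trigger residue to an
i.i.d. random carrier fraction (default 0.5) of leaves, adding δ to
their ln-rate — a *convergent* trait deliberately uncorrelated with the
tree, so attribution recovery is identifiable.  (A clade-confined
trigger is perfectly collinear with every other substitution on the
same branch, and no attribution method can single it out; passing an
explicit residue instead plants the effect with natural phylogenetic
linkage for harder, non-identifiable scenarios.)  The planted-recovery
tests use δ = 1 with low noise; the form-II-scope reproduction scenario
uses δ = 2.5, sized to the strong single-position effect a survey of
this kind reports.

**Characterized panel.** Default 25% of the corpus, chosen as a
sequential diversity screen: greedy cluster centroids collected at an
identity ladder (0.55, 0.70, 0.80, 0.85, 0.90, 0.95), topped up with
random leaves.  This reproduces the broad nearest-neighbour identity
spectrum of a real screening panel (panels are picked to *cover*
diversity, not sampled uniformly) and is what makes the
identity-thresholded CV informative; a uniform subsample of a
coalescent gives every panel member a ≥99%-identity neighbour and
flattens the threshold effect.

**Observations.** Each characterized variant is observed once through
the coupled assay: true rate ÷ β (default 2.1), × a per-batch
log-normal scale factor (σ = 0.1, 8 batches), × log-normal measurement
noise (σ_obs = 0.2; 0.1 in low-noise configurations), at a temperature
drawn from N(25, 3²) °C clipped to [10, 40] with the true Q10 = 2.2
applied.  A control variant (true rate 5 s⁻¹) is measured in every
batch.  A paired coupled/direct table over 11 variants supports the
assay-correction fit.

**What the generator does not emulate**, and hence what passing tests
do not establish about real data: insertions/deletions and alignment
error; site-specific substitution rates, residue exchangeabilities and
structural constraints; epistasis (causal effects are additive);
selection on the rate itself; non-log-normal measurement error;
partial sequences; and annotation errors in form labels.  Tests passing
on this generator show the *methods* recover what was injected under
the stated statistical structure, not that the structure is a complete
model of rubisco biology.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen so the full suite
completes in about a minute: corpora of 60–150 sequences of length
120–150, 100 association iterations, 20–50 replicates for stochastic
properties and 200 for CI coverage.  The acceptance script reports the
`n` actually used alongside every value.  Numerical conventions:
natural logs throughout; geometric means for multiplicative
quantities; linear-interpolation quantiles; strict inequality for
gap-column removal; identity thresholds clamped to [0, 1]; the
degenerate all-equal Kruskal–Wallis input returns H = 0; zero-variance
log-ratio samples give a point confidence interval.

## Known limitations

* The published correction-interval method is not uniquely determined
  by its description; a bootstrap or regression-software interval would
  differ slightly from the t-interval in the tails.
* The exponential weight scale of the weighted-mean model is a package
  choice; published weighted-mean errors are not exactly reproducible
  without it.
* Exact Shapley enumeration is exponential in the number of distinct
  split features and is intended for shallow trees (≤ ~25 features; the
  analysis uses depth 3, i.e. ≤ 7).
* Greedy clustering depends on scan order, as in the tools it mirrors;
  the order is pinned and parameterized rather than hidden.
* Per-form prediction refuses forms with < 3 characterized members
  rather than falling back to cross-form training.
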