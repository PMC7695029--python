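# Methods

## The data and what the generator emulates

A GC-FID fatty-acid analysis reports, per chromatogram, the relative
percentage of each identified FAME — compositional data on 17 features
summing to 100%. The study design emulated here has four origin groups
(codes 0–3: Norway farmed, Chile farmed, Canada farmed, Canada wild) of
25/24/25/26 fish; each fish contributes a *sample block* of up to 6
replicate chromatograms (3 independent lipid extractions × 2 injections),
with 4 of the 600 chromatograms lost to instrument problems, leaving 596
instances. Only per-group summary statistics of the underlying study are
public — per-feature mean ± SD per group — so the generator works from that
parameter table.

Generative model, per group g, fish i, replicate r:

    specimen_i  =  mu_g + sigma_g ∘ z_i,   z_i ~ N(0, I)
    replicate_r =  specimen_i ∘ (1 + cv · e_r),   e_r ~ N(0, I)

followed by truncation at zero and closure (renormalization of each row to
sum exactly 100). The published SD is interpreted as **between-fish**
variation; the analytical repeatability is unpublished, so replicates get
multiplicative noise with relative SD `replicate_cv = 0.02` — small enough
to leave the between-fish moments essentially untouched, large enough that
replicates are not byte-copies.

**The feed factor.** The two farmed groups that overlap in practice —
Chile and Canada — are coupled: one standardized vector `z*`, drawn once
per dataset, shifts every fish of both groups,

    specimen_i = mu_g + sigma_g ∘ (√ρ · z* + √(1−ρ) · z_i),

so the correlation between the two groups' deviations on any feature is
exactly ρ (`between_group_correlation`, default 0.5). The reading is
physical: feed composition is a farm-level, not a fish-level, effect, and
these two groups' farms draw on similar feed supplies. Averaged over seeds
the marginals keep the published mean and SD; within one dataset the two
groups move **together**, staying as entangled in low-dimensional
projections as their nearly identical means dictate, while the between-
group gap itself is untouched — apparent overlap with genuine
separability, which is the structure the emulated study reports (overlap
in the 2-D PCA view, near-perfect classification in the full space).

**What the generator does not emulate.** Real groups are mixtures of farms
and catch sites: multimodal, with tight within-farm clusters. Independent
Gaussian marginals are the maximum-entropy — i.e. hardest — realization of
the published moments. Consequences observed and accepted:

* nearest-neighbor classifiers lose 2–4 Canada-farmed fish per dataset to
  the tight Chile cluster (a density asymmetry: Canada's SDs are 2–6×
  Chile's), capping leave-one-fish-out kNN accuracy near 0.95–0.99 where
  the real study reached ~1.0;
* the gain-ratio scores of the 5–6 most informative features overlap
  within their seed-to-seed noise, so the *exact* top-3 set fluctuates even
  though the score means track the published ranking closely;
* the minimal feature count found by the threshold search therefore
  scatters (4–17) instead of landing on a single value.

Passing tests on this data show the pipeline machinery is correct and that
headline accuracies are reproduced to within a few test-set fish; they do
not show that the generator reproduces fine, raw-data-dependent quantities
(exact rank order, exact minimal k). Also deliberately not modeled:
chromatographic drift, retention times, co-elution beyond the two summed
peaks, detector response, diet covariates.

Degenerate inputs: negative draws are truncated at zero (for the published
parameters this matters for a single feature, Canada-farmed
22:1n11+22:1n9, where mean ≈ SD; the tests therefore check sample means
against the zero-truncated-Gaussian closed form `μΦ(μ/σ) + σφ(μ/σ)`, which
reduces to μ everywhere else). Sums such as ΣSFA are never generated —
always derived from the 17 base features. All randomness flows from
explicit seeds; there is no global random state.

## Feature ranking

Continuous features are discretized by recursive entropy partitioning with
the MDL stopping rule: the candidate cut minimizing weighted class entropy
is accepted iff its information gain exceeds `(log2(N−1) + Δ)/N` with
`Δ = log2(3^k − 2) − [k·H(S) − k1·H(S1) − k2·H(S2)]`, recursing on both
sides. The gain ratio is `IG/SplitInfo` in bits, with the convention that
a feature left in a single bin (SplitInfo = 0) scores 0 — an unsplittable
feature carries no usable information. Ties in the ranking break by
canonical feature order, making the ranking a deterministic function of
the data. Ranking operates on chromatogram instances (as the emulated
workflow did), not on replicate-averaged fish.

Gain ratio has a known pathology: a feature allowing one clean,
low-SplitInfo binary split (here: any feature separating only wild from
farmed) can outscore features that separate all four groups. On Gaussian
synthetic data this occurs for ~1 feature in ~30% of seeds and is the main
source of top-3 instability.

## Minimal-feature search

Bisection over ranked-prefix lengths for the smallest prefix whose
evaluator accuracy reaches the threshold (default 0.99; values > 1 are
read as percent). Two corrections relative to the usual sketch of this
search: the success predicate is `accuracy ≥ threshold` (strict
inequalities leave exact-threshold results driving neither branch), and on
termination the reported count is `R+1`, re-verified against the
threshold; if even the full set fails, the result is *n* with a
`used_all_features` flag. The evaluator is injected and memoized; the
default is kNN under leave-one-sample-out CV. Monotonicity of prefix
accuracy is assumed, as in any bisection; `linear_scan_minimal` is the
definitional fallback and test oracle, and the two provably agree on
monotone sequences (property-tested on 1,000 random monotone cases).

## Embeddings

PCA standardizes features by default (correlation PCA): the 17 features
share the % unit but span two orders of magnitude, and the published
two-component variance share (~88%) is only consistent with the
standardized variant — centering-only PCA on this data concentrates ~97%
in two components because three abundant acids dominate the covariance.
`standardize=False` restores covariance PCA. Component signs are
canonicalized (largest-magnitude loading positive) so scores are
regression-stable.

t-SNE (perplexity 30, 1,000 iterations, PCA initialization, fixed seed,
standardized inputs) is used two ways: as a visualization, and as a
**transductive feature stage** — the 2-D coordinates of all instances,
fitted jointly *before* any train/test split, become the classifier
inputs. That joint fit is how the emulated pipeline works and is
information leakage by construction: test-set geometry shapes the map.
`inductive_tsne_features` provides the honest alternative (fit on train,
test points inherit their nearest training neighbor's coordinates) for
measuring how much the transductive default flatters the classifiers.
Perplexity is shrunk with a warning when a dataset is too small for it.

## Classifier bench

Seven families with fixed published hyperparameters (kNN: 3 neighbors,
Euclidean, distance-weighted; tree: depth ≤ 100, min split 2, min leaf 3;
SVM: C = 15, RBF, gamma = 1/n_features; forest: 15 trees, min split 5;
ANN: one hidden layer of 300 ReLU units, Adam, L2 = 0.02; Gaussian naive
Bayes; AdaBoost: 80 estimators, learning rate 0.7). Choices where the
published table is silent or the ecosystem has moved:

* **Input scaling**: kNN, SVM and the ANN receive a standardizing
  preprocessor fitted on training data only; tree-based learners and
  naive Bayes are scale-invariant and run raw. Distance and RBF-kernel
  methods are degenerate on raw percentages spanning 0.2–44%.
* **AdaBoost** boosts full decision trees with the SAMME algorithm (the
  variant modern scikit-learn provides; depth-1 stumps under SAMME are
  wildly unstable on this 4-class problem).
* **ANN**: "300 neurons in hidden layers" is read as a single hidden layer
  of 300 units; `max_iter` is raised to 1,000 and non-convergence surfaces
  as the standard warning, never swallowed.
* **F1** is class-frequency-weighted (the groups are near-balanced, so
  macro vs weighted differ negligibly); switchable via `compute_metrics`.

Validation is always block-aware: the 20:80 holdout assigns whole sample
blocks, stratified per class (round(0.2·n) blocks each, ≥ 1); the
leave-one-sample-out CV holds out one fish's whole block per fold and
pools predictions. Every evaluation asserts that no sample id appears on
both sides; replicate chromatograms of one fish are near-copies, and
letting them straddle the boundary would be leakage, not validation.
Wall-clock prediction time is logged in reports but never asserted —
it is hardware, not science.

## Composition summaries

The unit of analysis is the fish: replicates are averaged per sample
before any statistic (596 chromatograms are only ~100 independent
observations; using them raw would pseudo-replicate). Derived quantities
are computed per fish and then summarized: ΣSFA = 14:0+16:0+18:0; ΣMUFA =
16:1+18:1n9c+18:1n7+20:1n9+22:1n11+22:1n9+24:1n9; ΣPUFA = the remaining
eight. For n3/n6 the co-eluting peak 20:3n3+20:4n6 mixes an n3 and an n6
acid; the default excludes it from both sums, `n3n6_coelution="half"`
apportions it 50/50 — neither convention exactly recovers published ratio
values, so neither is asserted numerically. The ratio is the mean of
per-fish ratios (consistent with reporting an SD for it), not the ratio of
means.

ANOVA is one-way on fish-level values; Tukey HSD uses the studentized
range distribution; letters come from the insert-and-absorb compact-letter
algorithm (start with one column holding all groups; for each significant
pair, split every column containing both; absorb subset columns), lettered
alphabetically from the lowest group mean. Two groups share a letter iff
their comparison is non-significant at α = 0.05 — property-tested over
random significance patterns. Zero within-group variance (exact ties) is
reported as fully significant between distinct means, with a warning, as
the studentized range is undefined there.

## Pipeline and reproducibility

`run_pipeline` executes simulate → rank → select → embed → bench →
summarize from one config. Stage seeds are derived by hashing
`(master_seed, stage_name)` (blake2s, reduced below 2³¹), so changing one
stage's options never perturbs another stage's randomness; the report JSON
is timing-free and byte-identical across reruns of the same config.
Evaluations cover three feature regimes — all 17 features, the selected
prefix, and the 2-D t-SNE map of the top-3 — each model sharing one seeded
split per run. The manifest records package version, config hash, stage
seeds and dataset shape.

Problem sizes are chosen so the full default pipeline runs in ~2 minutes
and the complete test suite in under a minute on one core: the
study-design dataset (596 instances) everywhere results are reported, a
reduced design (32 fish × 3 replicates) for pipeline-determinism and
CLI tests, and n = 10,000 fish/group for moment-recovery checks.

## Known limitations

* Published group moments under-determine the joint distribution; all
  covariance structure beyond the single feed factor is absent, and
  raw-data-dependent quantities (exact gain-ratio rank order, the exact
  minimal feature count) are not stably recoverable — see the generator
  section for what the corresponding tests do and do not show.
* The transductive t-SNE regime's accuracies are optimistic by
  construction; use the inductive variant for honest generalization
  estimates.
* The n3/n6 co-elution convention is unresolved in the source tables;
  both implemented conventions are approximations.
* Compact letters are one valid minimal representation; letter *names*
  (not the sharing relation) can differ from other software's output.
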