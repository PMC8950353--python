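# Methods

This note documents the models, estimators and numerical choices behind
`morelnet`, in the package's own terms: what each procedure assumes,
which parameters matter, and what the synthetic-data validation does and
does not demonstrate.

## The synthetic-data generator

**Model.** Counts follow a logistic-normal-multinomial. For sample j in
group g with plot b:

1. latent log abundances z_j ~ MVN(μ + δ_g + η_b, σ² R), where R is the
   planted latent correlation matrix, σ = `latent_sd` (default 1.0),
   δ_g the group effects and η_b ~ N(0, `plot_sd`² I) a per-plot,
   per-taxon random effect shared by a plot's replicates;
2. proportions p_j = softmax(z_j);
3. counts x_j ~ Multinomial(L_j, p_j) with library size L_j either
   fixed (default 10,000 reads) or log-normal around the stated mean.

The logistic-normal was chosen over a Dirichlet-multinomial because it
admits an explicit planted correlation matrix, which the
network-recovery validation needs as ground truth. The cost is that
planted quantities are exact only on the latent scale: a planted log2
fold change and a planted correlation are both attenuated by the softmax
(compositional closure) and by multinomial resampling noise. Observed
Spearman correlations for a latent block at r = 0.8 with 100 samples
typically land near 0.7–0.75.

**Correlation structure.** Block specifications set all within-block
off-diagonals to the block's r. A hub specification is built as a
one-factor block — hub-spoke correlation r, spoke-spoke r² — which is
positive semi-definite by construction and keeps spoke-spoke
correlations (r² = 0.56 at r = 0.75) below the edge threshold, so the
hub is the planted degree maximum. If the assembled matrix is still not
positive definite (overlapping, contradictory blocks), eigenvalues below
1e-8 are clipped, the diagonal is renormalized to 1, and the maximum
absolute entry perturbation is recorded on the returned truth object; a
perturbation above `repair_tolerance` (default 0.1) is an error naming
the blocks, since the planted truth would no longer describe the
simulation.

**Baseline abundances.** Base latent means are drawn log-uniform over
`base_log_range` (default (0, 4)), giving roughly three orders of
magnitude of rank-abundance skew — a deliberately simple stand-in for
the steeper, heavier-tailed abundance distributions of real soil
communities.

**Study design.** `emulate_study_design` reproduces the 23-plot x
4-replicate layout (92 samples) with each plot's site, cultivation
class, yield class (H = high yield, L/N = low/no yield, control) and
high-yield (II) / low-or-no-yield (III) analysis-group membership; 12
plots are group II and 7 group III. Other plot counts generate a
generic balanced layout. `plot_sd` defaults to 0.5 — half the
within-plot latent sd — which makes the plot factor clearly detectable
by PERMANOVA without overwhelming planted taxon-level structure.

**What passing tests show.** Recovery and calibration results
demonstrate that the inference chain is correct *under this generative
model*: compositional closure, multinomial noise, plot random effects
and skewed baselines are represented; sequencing-depth heterogeneity
beyond log-normal libraries, taxonomic mis-assignment, zero inflation
beyond what the multinomial induces, and phylogenetic correlation are
not. Results on real tables inherit none of the recovery guarantees.

## Abundance processing

The rare-taxon filter drops taxa whose grand-total count is strictly
below `fraction` (default 1e-5, i.e. 0.001%) of all reads, before genus
aggregation (order reversible via the API by calling the functions in
either order). Total-sum scaling divides each cell by its sample sum;
all-zero samples are an error, not a silent NaN. Top-N selection ranks
genera by the *unweighted mean* relative abundance over the scoped
samples — robust to library-size differences, unlike pooled counts —
with exact ties broken lexicographically so results are reproducible.

## Alpha diversity

Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined
even when F₂ = 0. ACE uses the canonical rare cutoff of 10 reads; its
coverage estimate C_ACE = 1 − F₁/N_rare degenerates to 0 when every
rare taxon is a singleton, in which case the function falls back to
Chao1 with a warning rather than dividing by zero. Shannon defaults to
natural log (configurable base); Simpson is reported as the Gini-Simpson
diversity 1 − Σp² — note that the complementary dominance form is also
commonly called "Simpson's index". The rarefaction curve is analytic
(hypergeometric expectation, computed with log-gamma for stability);
a seeded Monte-Carlo mode exists for cross-checking. Group comparisons
use one-way ANOVA plus Tukey HSD; the compact letter display is built
greedily, visiting groups in descending-mean order and appending each to
every compatible letter class.

## Beta diversity

The distance metric defaults to Bray-Curtis on TSS abundances (any scipy
metric is accepted). PCA operates on taxon-centered relative abundances
(Hellinger transform optional); axis percentages are reported over all
axes and sum to 100, and scores are deterministic up to sign. PERMANOVA
partitions squared dissimilarities (SS_total = N⁻¹ Σ_{i<j} d²_ij;
within-group analogue per group), with p from seeded label permutations
and the +1 correction, so the attainable minimum is 1/(B+1). 999
permutations is the default. Only the one-factor design is implemented;
the permutation scheme assumes exchangeable samples, so p-values for a
factor nested above the exchangeable unit (e.g. yield class over
plot-correlated replicates) are anti-conservative — plots, not
replicates, should be permuted for such questions.

## Differential abundance

The two-group test mirrors the Metastats recipe: Welch t on
within-sample proportions, two-sided permutation p with B = 1000
(seeded), and an exact-test fallback for sparse genera. The sparsity
threshold defaults to the number of samples — a genus averaging under
one read per sample has too many zeros for a meaningful t — and the
fallback is a two-sided Fisher exact test on the pooled genus-vs-rest
2x2 table. BH adjustment runs across all genera of the comparison.
All-zero genera are flagged and given p = 1. Proportion-based testing
makes the statistic invariant to global library rescaling. Under the
simulator's defaults (latent sd 1.0, log-uniform baselines), measured
power for a planted 4-fold change at n = 20/20 is about 0.85 at
p ≤ 0.01 — the permutation p is consistently *more* powerful there than
the analytic Welch p, which is conservative on the skewed,
lognormal-like proportion distributions.

## Co-occurrence networks

Spearman rho is computed as Pearson correlation of average-tie
mid-ranks. Two-sided p-values use the t approximation
t = ρ√((n−2)/(1−ρ²)) when n ≥ 10; below that the null is the exact
permutation distribution (all n! orderings when n! ≤ 10,000, otherwise
10,000 seeded Monte-Carlo draws, both with the +1 correction).
Constant genera are untestable and get ρ = 0, p = 1, and a flag. BH
runs over the C(G, 2) unique pairs of one group's matrix, not pooled
across groups. An edge requires |ρ| ≥ 0.6 (inclusive) *and* q < 0.05
(strict); the significance filter is interpreted as applying to the
BH-adjusted values. Isolated genera are dropped from the node set by
default (`keep_isolates` retains them), since published node counts for
such networks conventionally count connected genera.

Summary metrics: average neighbors 2E/N; mean local clustering
coefficient (0 for degree < 2); average path length averaged over all
connected pairs, which weights each component by its pair count;
density 2E/(N(N−1)). Modules come from Clauset-Newman-Moore greedy
modularity maximization on a sorted node order, making the partition
deterministic without a seed; modularity Q is reported for the
unweighted graph. The per-module score is density x node count
(MCODE-style) and is reported alongside the raw size, as no single
convention exists for "module score". Hubs are nodes with degree ≥ 10,
ranked by degree with lexicographic tie-break.

## Validation problem sizes

The calibration suite uses 200 null simulations for PERMANOVA type-I
error (2 x 10 samples, 30 taxa, 199 permutations), 200 for the
differential-abundance false-call rate (50 genera, 2 x 10 samples,
B = 1000) and 20 for the null-network false-edge rate (50 genera, 50
samples). The recovery suite uses 20 simulation seeds at 100
samples/group with latent r = 0.8 blocks (edges), a 15-spoke r = 0.75
hub, and two r = 0.9 blocks (modules, scored by adjusted Rand index).
These sizes give binomial standard errors of 1.5–2 percentage points on
the estimated rates, small enough to distinguish calibrated (5%) from
broken (≥ 10%) behavior.

## Known limitations

* Spearman networks on relative abundances inherit compositional bias;
  no SparCC/SPIEC-EASI-style correction is attempted. With ~50 roughly
  even genera the induced negative correlation is ≈ −1/49 and far below
  the 0.6 threshold, but a strongly dominant taxon (a real feature of
  morel-cultivated soils) can push spurious negative edges past it.
* PERMANOVA is single-factor; nested/stratified permutation is not
  implemented.
* The differential-abundance module handles exactly two groups;
  multi-group designs must be orchestrated as repeated pairwise calls.
* Rarefaction is a per-sample curve, not a normalization strategy; the
  pipeline normalizes by TSS only.
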