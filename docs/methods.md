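# Methods

This note documents the statistical models behind `mirsig`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions. It states no empirical result that the test
suite does not itself compute.

## Normalization

Microarray intensities carry smooth intensity-dependent biases (optical
background at the low end, saturation at the high end). On log2 intensities,
such a bias appears as a smooth trend of the deviation `M_j = x_j − r` of
sample j from a reference `r` as a function of `r` — the single-channel
analogue of an MA-plot trend. `mirsig` takes the per-gene median across all
samples as the reference profile, estimates each sample's trend with robust
LOWESS (locally weighted linear regression, tricube weights), and subtracts
it. Affine per-sample biases are removed exactly up to fit tolerance;
quadratic ones to within the local-linear bias of the smoother.

Defaults: span 0.4 (fraction of points per local window), 3 robustifying
iterations — typical values for this smoother; the paper-era tooling did not
expose them either. The correction runs on log2 intensities; running it on a
linear scale is possible by skipping the caller's log step, but log-space is
the standard for intensity-dependent correction and matches the downstream
log2 analysis. For speed on chip-sized matrices the smoother evaluates the
local fit on a subsample and linearly interpolates within windows of 0.5% of
the abscissa range; a test asserts this stays within 0.01 of the exact fit.

After correction, values are log2-transformed (when starting from linear
intensities) and every gene is centered at its **median** (not mean), so a
gene's values are displacements from its typical expression.

Idempotence (re-normalizing changes nothing beyond 0.05) and invariance to
gene/sample reordering are asserted as properties.

## Clustering and collective tests

Similarity between expression profiles is the uncentered Pearson correlation
`s = Σxy/√(Σx²Σy²)` (cosine similarity), distance `d = 1 − s ∈ [0, 2]`. It is
scale-invariant but deliberately **not** shift-invariant: after gene-median
centering, two genes agree only if they deviate on the same samples in the
same direction. An all-zero profile has similarity 0 with everything
(`d = 1`) by convention.

Trees are built by unweighted average linkage (UPGMA), which is monotone on
this distance; the implementation is checked against a brute-force O(n³)
UPGMA oracle. Gene clusters are the maximal subtrees whose internal merges
all sit at or below a cut height of `fraction × root merge height` (default
fraction 0.2). A fractional cut was chosen over an absolute `d = 0.2` cut
because it is robust to the overall correlation level of the matrix; the
absolute variant is exposed as an option. Clusters below `min_size = 10` are
discarded — signature clusters of interest contain hundreds of genes, and
tiny fragments at this granularity are noise.

Each cluster is scored per group contrast with a **collective p-value**: the
per-sample mean over the cluster's genes is computed, and the two groups are
compared with a Student (equal-variance) two-sample t-test; Welch is
available by flag. Since each cluster contributes a single test, this stage
needs no multiple-testing correction. Clusters significant in at least one
contrast (default α = 0.05, unstated in the source methodology) are retained
and annotated with a direction pattern ("down in A, unchanged in B", ...).

## Moderated t-statistics

Gene-wise residual variances from small-n two-group designs are unstable.
The hierarchical model treats the true variances as draws from a scaled
inverse-χ² prior with d₀ degrees of freedom and scale s₀². The prior is fit
by moment matching of `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)` (ψ the
digamma function): the excess of the empirical variance of `e_g` over the
sampling term `ψ′(d_g/2)` identifies `ψ′(d₀/2)`, inverted by a monotone
Newton iteration to |Δ| < 1e-8; non-positive excess yields d₀ = ∞ (all
variances compatible with one value). The posterior variance
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` replaces `s²_g` in the pooled
two-sample t, which then has `d_g + d₀` degrees of freedom (normal reference
for d₀ = ∞). d₀ = 0 disables moderation and reproduces the classical pooled
t exactly — asserted to 1e-9 against scipy's implementation.

Benjamini-Hochberg step-up q-values control FDR; NaN p-values propagate as
NaN and are excluded from the test count. Differential genes are selected at
q below a threshold and |fold change| above a threshold on the anti-logged
scale (default FDR 0.05, 2-fold, i.e. |log2FC| > 1); branch statistics on
external cohorts use FDR 0.01 with no fold filter.

## Enrichment

For a gene list L and a term/target set T, both intersected with the
background N (the genes of the processed matrix — the "whole chip", not the
genome), the fold-enrichment is `(k/m)/(K/N)` with k = |L∩T|, m = |L|,
K = |T|. Significance is a one-sided (greater) Fisher exact test — the
claims being tested are enrichment claims; the one-sided-less and two-sided
alternatives are exposed for depletion. BH correction is applied across the
emitted table. The complement list "outside" (background minus all lists) is
added automatically so that depletion outside a signature is visible next to
enrichment inside it. The Fisher p is verified against an exact
integer-arithmetic hypergeometric tail sum.

## Signature and projection

The signature is the union of the retained differential clusters with
per-gene cluster provenance (clusters from one cut are disjoint by
construction, so the union is duplicate-free). Reduction keeps the genes
present in **both** of two target lists (e.g. predicted targets of the two
miRs); overlap counts with further sets (e.g. an RBP's targets) are recorded
as metadata.

Projection subsets an external cohort to the matched signature genes (exact,
trimmed, case-sensitive symbol equality; below a 20% match rate the run
aborts and advises identifier harmonization), gene-median-centers, and
clusters the **samples** with the same metric and linkage. The two children
of the dendrogram root define the left and right branches; root bipartition
is the only parameter-free reading of "the two dominant branches of the
tree". Branch names are arbitrary (LB holds the first retained sample) and
every agreement statistic in the tests is label-swap tolerant. Designated
control samples can be excluded; they are labelled but take no part in
branch statistics. Branch-wise moderated-t statistics then run on the whole
transcriptome, not only the signature genes.

## Synthetic data: the stated world

`generate_dataset` draws, for G genes and three groups (control, mimic A,
mimic B; n = 6 each):

- baseline `μ_g ~ U(4, 12)` — a log2 microarray-like dynamic range;
- variances `σ²_g ~ s₀²·d₀/χ²(d₀)` with default (d₀, s₀²) = (4, 0.05) — a
  moderate-shrinkage regime where moderated and ordinary t visibly differ,
  and the prior is recoverable by the estimator;
- five planted clusters of 400 genes (defaults) with group shift patterns
  mirroring the archetypes: down in A; up in B; down in both; up in both;
  up in A / down in B; shift magnitude ±1 log2 (a 2-fold effect, matching
  the conventional differential threshold);
- cluster gene values `μ_g + a_g(pattern[group(j)] + 0.5·z_j) + ε`, with a
  per-sample latent factor z shared across the cluster (cofactor_sd 0.5)
  that makes member genes correlate beyond their group shifts;
- optional per-sample distortion `y = x + c₁(x − x̄) + c₂(x − x̄)²` with
  |c₁| ≤ 0.05 and |c₂| ∈ [0.02, 0.03]: monotone over the simulated range yet
  guaranteeing a planted trend amplitude ≥ 0.3 for the LOWESS test;
- target lists by Bernoulli membership: rate `background_rate` outside
  clusters, `min(1, φ_c·background_rate)` inside cluster c (defaults: two
  miR-style lists, 10% background, 4-fold in the clusters their mimic
  shifts);
- an external cohort generator planting two sample subpopulations with
  ±effect/2 shifts (random sign per gene) on the signature genes only.

Per-gene loadings `a_g = |N(1, loading_sd)|` default to homogeneous
(loading_sd = 0). This is a deliberate calibration, not a claim about
biology: with the heavy-tailed variance prior, roughly one planted gene in
seven has noise variance comparable to the cluster signal and falls above
the 1/5 tree cut, which places cluster recovery (adjusted Rand index against
the planted labels, unassigned genes as singletons) at about 0.82 — already
at the boundary of the 0.8 recovery property. Loading heterogeneity of
0.2–0.3 lowers recovery to roughly 0.74–0.78 by adding weakly-loaded genes
that the cut cannot claim. Noise defaults here are chosen for testability of
the pipeline's contracts, not for fidelity to any particular dataset; tests
that probe robustness set loading_sd explicitly.

What the generator does **not** emulate: probe-level chemistry and scanner
effects, batch structure, correlated backgrounds between clusters,
non-Gaussian noise, missing values, or annotation ambiguity. A green
synthetic test therefore establishes that the algorithms implement their
contracts on data satisfying the model assumptions — not that any particular
biological dataset will reproduce specific counts.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give identical datasets and reports.
- Distance matrices are clipped to [0, 2] and symmetrized before linkage;
  linkage tie-breaking follows scipy's deterministic nearest-neighbor-chain
  order.
- Zero residual variances are offset to half the smallest positive variance
  before prior estimation (counted in the log); a gene constant in both
  groups with equal means yields t = 0, p = 1, otherwise its statistic rests
  on the prior variance alone.
- Fold-enrichment of an empty term is reported as 0 with q = 1 rather than
  NaN.
- File output uses period decimals and 6 significant digits; readers
  roundtrip losslessly at that precision.

## Known limitations

- Two-group contrasts only; no general design matrices, paired designs or
  covariates.
- Gene-identifier matching in projection is exact string equality; no alias
  resolution is bundled.
- Cluster recovery under the fractional cut is intrinsically marginal in the
  stated world (see above): heavy-tailed gene variances put a floor on the
  fraction of genes a correlation cut-off cannot claim.
- The collective-test stage assumes cluster membership was found without
  reference to the group labels; applying it to clusters selected by a
  supervised procedure would invalidate the single-test argument.
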