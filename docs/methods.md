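# Methods

This package re-implements, as tested library code, an integrated
symptom + multi-omic cluster analysis for cohorts of healthy controls and
patients with disorders of gut-brain interaction (DGBI), together with a
synthetic cohort generator that plants recoverable ground truth. This
note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments do and do not
demonstrate.

## Pipeline overview

1. **Symptom factor analysis** (`cohortclust.efa`) — questionnaire items
   → latent symptom factors → per-participant factor scores.
2. **Latent profile analysis** (`cohortclust.lpa`) — Gaussian mixture on
   factor scores with profile count chosen by bootstrap likelihood-ratio
   testing (BLRT); maximum-posterior assignment.
3. **Omics preprocessing** (`cohortclust.prep`) — total sum scaling and
   abundance/prevalence/flag filters for count tables; loess run-order
   normalization and QC-RSD filtering for LC-MS intensity tables; derived
   microbiome measures.
4. **Biological clustering** (`cohortclust.nemo`) — neighborhood-based
   multi-omics clustering: per-block scaled-exponential-kernel affinity,
   kNN relative similarity, partial-data averaging across blocks,
   eigengap cluster count, spectral clustering.
5. **Stability** (`cohortclust.stability`) — bootstrap pair-consensus:
   1,000 re-clusterings of 75 % subsamples (without replacement), pair
   co-sampling (M) and co-assignment (I) counts, consensus C = I/M, and a
   0.5-threshold one-sample location test per reference cluster.
6. **Integration** (`cohortclust.integrate`) — unweighted average of the
   symptom and biological consensus matrices, complete-linkage
   hierarchical clustering of 1 − C, cluster count by silhouette and
   medoid Davies-Bouldin, stability re-assessed on the merged matrix.
7. **Downstream contrasts** (`cohortclust.differential`,
   `cohortclust.groupstats`) — Dirichlet-Monte-Carlo CLR Welch tests for
   gene counts, robust volcano calls for metabolites, hypergeometric
   over-representation, and normality-gated cluster-wise comparisons with
   compact letter displays.

## Factor analysis

Suitability uses the Kaiser-Meyer-Olkin index
(KMO = Σr² / (Σr² + Σq²) over off-diagonal correlation/anti-image pairs;
≥ 0.5 is treated as adequate) and Bartlett's sphericity statistic
−[(n−1) − (2p+5)/6]·ln det(R) on p(p−1)/2 degrees of freedom.

Extraction is maximum likelihood on the Pearson correlation matrix via
the classical profile likelihood over uniquenesses (the discrepancy
Σ_{j>m}(λ_j − ln λ_j − 1) on the eigenvalues of Ψ^{-1/2}RΨ^{-1/2},
minimised by L-BFGS-B with uniquenesses bounded in [0.005, 1]; loadings
recovered from the top-m eigenstructure). Items are analysed as
continuous variables: the generator produces continuous responses, so a
weighted-least-squares treatment of ordinal items is out of scope by
design. Uniquenesses pinned at the lower bound are reported as Heywood
diagnostics with the offending item ids.

Rotation is oblique **geomin**, criterion
Σ_i [Π_j (λ_ij² + ε)]^{1/m} with ε = 0.01, minimised by gradient
projection. Thirty starts are used (identity plus 29 random unit-column
matrices); the lowest criterion wins, ties resolving to the earliest
start. Each factor is oriented so its largest-magnitude loading is
positive. Item pruning is a single pass — fit, drop items with no
|loading| ≥ 0.4, refit once — and cross-loading items are retained.

Factor-count selection is Velicer's minimum average partial test in its
original squared-partial-correlation form (the 4th-power revision is
available via `revised=True`). Factor scores are the regression method,
scores = zΣ⁻¹ΛΦ, which is the posterior mode under a N(0, Φ) prior for
this linear-Gaussian model; participants with at least 50 % of retained
items are scored via their missingness pattern's submatrix, others are
flagged missing. Listwise-complete rows feed the correlation matrix.

## Latent profile analysis

The mixture has **equal variances and zero covariances**: one diagonal
covariance shared by all profiles. The EM loop is implemented directly
because this structure sits between the library options (shared-full or
per-component-diagonal); the loop asserts monotone log-likelihood every
iteration, re-seeds empty components from the worst-explained point, and
floors variances at 1e-6 × the mean data variance. Ten kmeans++ restarts
by default; best final likelihood wins. Convergence at relative
log-likelihood change < 1e-8 or 1,000 iterations.

BLRT compares k−1 vs k sequentially from k = 2: the observed statistic
2(ℓ_k − ℓ_{k−1}) is referred to a parametric bootstrap null (simulate
from the fitted k−1 model, refit both), p = (1 + #{boot ≥ obs})/(B + 1),
stopping at the first non-significant test (α = 0.05). The default is
B = 99 bootstrap draws (desk scale; configurable to 999). Bootstrap
refits use fewer restarts (3) and a 250-iteration cap — the null
statistics are far from the observed ones in practice, so the truncation
is conservative.

## Omics preprocessing

* "0.005 %" mean abundance is interpreted as 5e-5 of the TSS total;
  "10 % non-zero" as *keep at* ≥ 10 % prevalence (strict "less than"
  excluded). Filter order is flagged → abundance → prevalence, the first
  failing rule claiming each dropped feature; re-filtering the output
  drops nothing (idempotence is tested).
* Shannon diversity is averaged over 100 rarefactions to the
  dataset-minimum depth, drawn without replacement
  (multivariate-hypergeometric sampling); expected richness is the
  analytic hypergeometric form E[S] = Σ_k [1 − C(N−N_k, d)/C(N, d)].
* The QC-RSD filter drops features with 100·sd/mean **strictly above**
  30 % across QC injections; zero-QC-mean features are dropped as
  unmeasurable.
* Run-order normalization fits a locally weighted (tricube/loess)
  regression of QC intensity on injection order (span 0.75 by default,
  via statsmodels lowess with interpolation), divides every sample by the
  interpolated trend and rescales to the feature's pre-normalization
  median. Fewer than 4 QC points degrade to median-centering with a
  warning.

## Biological clustering

Per block, features are z-scored (constant features dropped with a
warning) and Euclidean distances kerned with the scaled exponential
kernel W_ij = exp(−d²_ij/(μ·ε_ij)), μ = 0.5,
ε_ij = (mean kNN distance of i + of j + d_ij)/3. The kNN **relative
similarity** row-normalizes W over each participant's k nearest
neighbors (self excluded, k = round(n/6) by default) and is symmetrized.
Count blocks enter after TSS + filtering + log10(x + 1e-6); intensity
blocks after run-order normalization (both then z-scored) — the input
transform is a declared choice, configurable.

Blocks are merged by averaging each pair's relative similarity over the
blocks measuring both participants; participants sharing no block with
anyone are excluded. The cluster count maximises the eigengap
λ_{k+1} − λ_k of the symmetric normalized Laplacian over k = 2..15, and
labels come from spectral clustering (bottom-k eigenvectors,
row-normalized, k-means with 30 seeded restarts).

## Stability

The subsample size is ⌊0.75·n⌋ without replacement; the subsampling
stream is seeded separately from the clustering callback so callback
randomness cannot desynchronise the draw sequence. Verdicts are
branch-consistent: if the within-cluster consensus values pass
Shapiro-Wilk (α = 0.05, subsampled to 5,000 values when larger), a
one-sided one-sample t-test against 0.5 ("greater") must reject *and*
the mean must exceed 0.5; otherwise the Wilcoxon signed-rank test and
the median. One-sided alternatives are deliberate — a two-sided test
would flag super-stable clusters as it would unstable ones. Constant
samples bypass the tests (stable iff the constant exceeds 0.5); clusters
with fewer than three defined pairs are reported unstable with reason
"insufficient pairs" / "no pairs".

**Known limitation:** subsample-consensus stability of a *forced* k on
unimodal data does not generally fall below the 0.5 threshold. A
Gaussian mixture forced onto one blob splits it along data-determined
directions that persist under 75 % subsampling, so within-cluster
consensus settles around 0.55–0.9 — and with thousands of pairs the
location test rejects for any mean trivially above 0.5. This matches the
documented over-confidence of consensus matrices on null data; the 0.5
rule is effective as a *relative* filter between clusters (the use made
of it here and in practice), not as a null-calibrated hypothesis test.

## Integration

Similarity → distance via D = 1 − C (the standard complement, preserving
[0, 1]). Trees are cut by **merge order** (R `cutree` semantics) rather
than by threshold: consensus-derived complete-linkage heights tie at
exactly 1.0 whenever some cross-cluster pair was never co-assigned, which
makes threshold cuts skip small k entirely. The Davies-Bouldin index is
computed in medoid form (center = medoid under D, scatter = mean distance
to medoid, separation = medoid–medoid distance) because centroids are
undefined for pure-distance data; silhouette is computed from D directly
and is the primary selector when the two criteria disagree (the
disagreement is logged prominently). Pairs undefined in one modality's
consensus use the other alone.

**Expected behavior under partial concordance:** when the symptom and
biological partitions disagree for a subset of participants, the merged
consensus genuinely contains their (symptom × biological) combination
groups — within-combination consensus ≈ 1, cross ≈ 0.5. Selection
therefore returns *more* clusters than either modality, exactly as the
motivating study observed (11 integrated clusters from 7 symptom × 4
biological). Simulations at concordance 0.9 select k ≈ 9 from 3 × 3
planted clusters with near-perfect silhouette; only perfect concordance
collapses the integrated solution back to the matched count. Small
combination groups with one or two members are reported unstable for
lack of pairs.

## Differential analysis and enrichment

Gene contrasts: 128 Monte-Carlo instances of Dirichlet(counts + 0.5)
proportions, CLR transform, per-feature Welch's t-test; expected p =
mean over instances, BH-adjusted across features. The effect size is the
median over instances of (between-group median CLR difference) divided by
the larger within-group median absolute deviation — a documented stand-in
for the reference effect-size denominator, sign-compatible with it.
Metabolite contrasts: Wilcoxon rank-sum p-values with a Tukey-biweight
(kernel-weighted) location for the log2 fold change; calls require BH
p < 0.05 **and** |LFC| strictly > 1; non-positive location estimates are
flagged untestable. Over-representation is the hypergeometric upper tail
against a user-supplied background with BH adjustment, up- and
down-regulated hit lists tested separately at q < 0.05 (gene pathways) or
q < 0.1 (metabolite sets); an empty hit list yields an empty table rather
than an error. The reference-cluster helper picks the stable cluster
with the lowest mean symptom burden, ties broken by the highest control
proportion.

## Group comparisons

Per measure: Shapiro-Wilk per cluster with Bonferroni correction across
clusters; all normal → one-way ANOVA with Tukey HSD, otherwise
Kruskal-Wallis with Dunn's rank test (tie-corrected) under BH adjustment.
Pairwise tests run only when the omnibus p < 0.05. Compact letter
displays use the insert-absorb construction, so clusters share a letter
iff their adjusted pairwise p ≥ 0.05 (round-trip tested). Cohort-level
comparisons are a Welch t-test (age) and a chi-square test with optional
continuity correction (2×2 sex table), warning when expected cells drop
below 5.

## Synthetic cohort generator

The generator emulates the study's data *structure*, not its content:

* **Factor scores**: Gaussian mixture with shared identity covariance.
  Cluster means sit at the vertices of a regular simplex with edge
  2 × `factor_separation` (each mean is `factor_separation` SDs from any
  pair midpoint) — the geometry under which a 3-SD separation is reliably
  recoverable at n = 300. Item responses are loadings × scores + unique
  noise, loadings ~ N(0.8, 0.05) clipped to [0.3, 0.95], six items per
  factor: strong, realistic questionnaire items.
* **Biological labels**: equal to a deterministic map of the symptom
  label with probability `concordance`, otherwise uniform — letting the
  "biological clusters need not match clinical definitions" regime be
  simulated at concordance ≈ chance.
* **Count blocks**: Dirichlet-multinomial around a log-normal baseline
  composition (concentration 300), Poisson depths, cluster-specific
  ±log2-shift sign patterns on the designated shifted features; row sums
  equal the drawn depths by construction. A few taxa carry
  environmental/unassigned flags to exercise the filters.
* **Intensity blocks**: log-normal (log2 SD 0.8) with the same cluster
  shift scheme, pooled-QC injections every `qc_every` slots starting at
  position 1, and a low-order polynomial multiplicative drift across the
  injection order (per-feature amplitude jitter).
* **Missingness**: independent participant × modality masking with a
  guard retaining the lowest-index modality when all draws fail.

One integer seed feeds a `SeedSequence`; every block consumes an
independent child stream, so outputs are byte-identical across runs and
stable under block reconfiguration.

What the synthetic experiments do **not** show: real questionnaires are
ordinal and skewed, real taxa compositions are far sparser and more
overdispersed than Dirichlet-multinomial with fixed concentration, LC-MS
drift is not polynomial, and real cluster structure is much weaker than
the planted 3-SD separation. Passing recovery tests demonstrates the
machinery is correct and calibrated, not that equally crisp structure
exists in patient data.

## Problem sizes used in the automated checks

The acceptance-style tests run the full pipeline at n = 300 with 200
bootstrap subsamples and 59-draw BLRTs over 20 seeds (planted
structure), 50 seeds for null BLRT behavior, 11 seeds for forced-k
stability, and 100 simulated tables for false-discovery control — sizes
chosen so the whole suite completes on a single CPU while leaving the
Monte-Carlo tolerances meaningful. The demonstration analyses under
`analysis/` use a 150-participant cohort with 200 bootstrap subsamples.
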