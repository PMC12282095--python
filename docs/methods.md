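# Methods

This document records the model assumptions behind the synthetic
generator, the statistical conventions used by each analysis module, the
default parameter values and why they were chosen, and known limitations.
Quantitative behavior cited here is limited to properties exercised by
`tests/` and `scripts/acceptance.py`.

## Synthetic cohort generator

### Model

1. **Planted association structure.** For each group a sparse precision
   matrix over latent log-abundances is assembled: a random backbone of
   `n_backbone_edges` taxon pairs receives off-diagonal magnitudes drawn
   uniformly from [0.15, 0.35] (sign positive with probability
   `frac_positive`, default 0.9), and the diagonal is set by diagonal
   dominance with a margin of 0.1 to guarantee positive definiteness.
   The matrix is then rescaled symmetrically (Ω → DΩD) so latent
   variances are exactly 1. The rescaling preserves the support, the edge
   signs, positive definiteness, and the partial correlations, while
   removing an otherwise arbitrary variance pattern that would confound
   recovery experiments.
2. **Counts.** Latent samples are drawn from the multivariate normal
   implied by the group precision matrix, exponentiated, normalized to a
   composition, and read counts are multinomial at fixed `depth`
   (default 10,000). This is the standard logistic-normal–multinomial
   model for compositional sequencing data.
3. **Group differences.** `n_differential_pairs` (default 6) backbone
   pairs differ between the two patient groups, and a disjoint set of
   taxa receives a mean shift, giving ground truth for differential
   association and differential abundance.
4. **Batch effect.** Each batch applies per-taxon location shifts and
   scale factors on the log scale. `batch_mode="study"` assigns one
   batch per group (a confounded design, as when groups come from
   different studies); `"crossed"` randomizes batch within group so the
   adjustment can be evaluated against a non-confounded truth.
5. **Metabolites and symptoms.** Metabolite intensities are linear in
   the latent taxa plus Gaussian noise, with named couplings recorded in
   the truth object; 0–10 symptom scores are linear in metabolites,
   clipped to the instrument range. Questionnaire item tables are
   generated per instrument with a group-level shift
   (`questionnaire_group_shift`, default 2.0) on the latent severity.

### Default cohort shape

Defaults (`n_low=25`, `n_high=14`, `n_tcd=48`, `n_taxa=50`) mirror the
scale of a realistic two-patient-group plus treated-control design:
small, unbalanced patient arms and a larger control arm. This is the
regime in which the estimators must behave, so it is the regime the
defaults exercise.

### What the generator does not emulate

Zero inflation beyond what the multinomial produces, phylogenetic
structure (so no UniFrac), sequencing error, instrument drift or
missingness in metabolomics, nonlinear taxon–metabolite relations, and
longitudinal sampling.

## Community profiling

- **Filtering** keeps taxa exceeding a relative abundance of 1e-4 in at
  least 10% of samples.
- **Alpha diversity**: observed richness, bias-corrected Chao1 (warned
  and degraded to observed richness on relative data, where singleton
  counts are undefined), Shannon (natural log), Simpson (1−D by default,
  inverse optional).
- **PERMANOVA** follows the classical pseudo-F on a distance matrix with
  label permutations; the p-value is `(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`.
  Its null calibration (rejection rate at alpha 0.05 within [0.03, 0.07])
  is asserted in `tests/test_acceptance.py`, and the statistic is
  cross-checked against scikit-bio when that package is present.
- **Batch adjustment** is a deliberate simplification: per-taxon
  location–scale standardization of log abundances within batch, zeros
  preserved. It refuses batch labels perfectly confounded with groups,
  because location adjustment would then remove the group signal.
- **Differential abundance** uses Welch's t-test (default) or White's
  nonparametric bootstrap t-test on percentage-scale abundances, BH
  correction, and a biological-relevance filter: a feature is flagged
  only when q < 0.05 *and* the group difference is at least 0.75
  percentage points.

## Co-occurrence networks

- **CLR transform** with a pseudocount of half the minimum nonzero value
  per table; rows sum to zero by construction.
- **Inference** is neighborhood selection: each taxon is lasso-regressed
  on all others along a decreasing penalty path, an edge requiring mutual
  selection (AND rule, default). The penalty is chosen by StARS:
  `stars_subsamples=50` subsamples of size `min(n−1, floor(10·sqrt(n)))`,
  per-pair selection frequency ξ, instability D = mean 2ξ(1−ξ),
  monotonized from the sparse end, selecting the densest penalty with
  monotonized instability ≤ 0.05.
- **Default penalty path**: 10 points, geometric from the maximum
  absolute CLR correlation down to 0.01 of it. The grid is deliberately
  coarse. On independent data the instability budget is exhausted within
  the first geometric step, so the selected model is empty (asserted:
  at most 2 edges in ≥90% of independent-Gaussian datasets at n=200,
  p=30), while planted structure keeps instability low for several steps
  and is recovered (asserted: median precision ≥ 0.7 and recall ≥ 0.5 at
  p=50, 60 edges, n=200). A fine grid instead allows the selector to
  creep up to the instability boundary, where a handful of chance
  associations survive; both behaviors were measured before fixing the
  default.
- **Topology**: size = edge count, order = non-isolated node count,
  density = 2·size/(order·(order−1)), mean local clustering, average
  shortest path on the largest connected component, greedy modularity.
- **Keystones**: nodes whose degree and betweenness both exceed the 0.90
  quantile of a fitted log-normal; with fewer than three distinct
  positive values the empirical quantile is used (with a warning).
- **Attacks** operate on the positive-edge subgraph, tracking the
  largest connected component under degree-targeted,
  betweenness-targeted (static or adaptive ranking), or random removal;
  random attacks report per-replicate curves so Monte-Carlo error is
  quantifiable.
- **Differential association** compares per-pair Pearson correlations
  between groups with the Fisher Z statistic,
  `z = (atanh r_A − atanh r_B)/sqrt(1/(n_A−3) + 1/(n_B−3))`, BH-corrected.
  Perfect correlations are clamped (with a warning) to keep atanh finite.

## Clustering

- **MFA** standardizes variables, weights each block by the inverse of
  its leading singular value, and runs a global SVD; with a single block
  it reduces to PCA of standardized data up to the block weight.
- **Variable selection** ranks variables by their contribution to the
  factors covering a cumulative-variance target (default 0.70).
- **Distance** is Canberra, which weights coordinate differences
  relative to magnitude and so remains informative for near-zero,
  skewed clinical variables.
- **Embedding** is classical (Torgerson) MDS. By default the embedding
  keeps the axes whose eigenvalue is at least half the top eigenvalue
  (capped at 10): separation structure concentrates in the dominant
  axes, and feeding trailing noise axes to the mixture model lets BIC
  favor degenerate components.
- **GMM** fits k = 1..5 with spherical/diagonal/full covariances,
  selecting by BIC. Two numerical safeguards: `reg_covar` is scaled to
  1e-2 of the mean embedding variance (an absolute floor is meaningless
  across embedding scales and a tiny floor lets components collapse onto
  near-duplicate points), and full-covariance candidates are skipped
  when n/k < dim+1, where a full covariance is not estimable. Recovery
  of planted subgroups (median adjusted Rand index) is asserted in
  `tests/test_acceptance.py`.
- **Group comparisons** use exact two-sided Wilcoxon rank-sum
  enumeration when both groups have at most 25 tie-free observations
  (normal approximation otherwise), or Welch's t-test; BH correction.

## Integration

- **Pathway enrichment** is the upper-tail hypergeometric probability
  P(X ≥ k) computed per pathway within each origin stratum, BH-corrected
  within stratum. It matches exhaustive subset enumeration exactly on
  small universes (asserted for N ≤ 12).
- **Microbe–metabolite correlation** is Spearman with a p-value
  threshold (default 0.05) for edge inclusion.
- **Integration networks** are tripartite: taxa–metabolite correlation
  edges and metabolite–pathway membership edges only; no direct
  taxon–pathway edges.
- **Symptom–feature association** is a Pearson correlation grid with BH
  correction and significance stars on both raw and adjusted p-values.

## Limitations

- The batch adjustment is a location–scale approximation, not a
  mixed-model correction; it cannot rescue designs where batch and group
  are perfectly confounded.
- Network inference assumes approximate latent Gaussianity after CLR;
  heavy zero inflation or depths far below the default will degrade the
  recovery guarantees, which are only asserted at the tested scale
  (n=200, p=50).
- The coarse default penalty path trades penalty resolution for null
  sparsity; applications needing a finer density continuum should pass
  an explicit `lambda_path` and interpret the extra edges accordingly.
- Exact Wilcoxon enumeration is used only for small tie-free groups;
  elsewhere p-values are asymptotic.
- The generator's couplings are linear; estimators validated here are
  not thereby validated for strongly nonlinear biology.
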