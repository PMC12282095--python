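# nrcd

Analysis toolkit for microbiome–metabolome–symptom studies of
non-responsive celiac disease (NRCD), with a fully synthetic data
generator for validating every step of the pipeline.

## Scientific problem

A subset of celiac-disease patients report persistent symptoms despite a
gluten-free diet. Studies of such cohorts typically collect, per
participant:

- stool metagenomic taxonomic profiles (relative abundances),
- stool metabolite intensity panels with origin annotations
  (host / microbiota / co-metabolism / food / drug),
- symptom and quality-of-life questionnaires (GSRS-CD, CeD-Pro, CD-QOL)
  and a diet-adherence instrument (CDAT),
- clinical markers,

and ask: do symptom-burden subgroups differ in community composition, in
microbial co-occurrence structure, and in metabolite pathways, and how do
those layers connect? This package implements the statistical machinery
for that question end to end, plus a generator that produces cohorts with
*known* group structure, association networks, and cross-layer couplings,
so every estimator can be checked against planted ground truth.

## Core model

- **Synthetic cohorts** (`nrcd.synthetic`): taxa counts are
  logistic-normal–multinomial draws from group-specific planted precision
  matrices (sparse partial-correlation structure, rescaled to unit latent
  variances so partial correlations are preserved); metabolites are linear
  functions of latent taxa plus noise; 0–10 symptom scores are coupled to
  metabolites; a study-of-origin batch effect shifts and scales taxa.
- **Questionnaires** (`nrcd.questionnaires`): GSRS-CD sums, CeD-Pro and
  CD-QOL Likert means, CDAT totals with the standard adherence categories.
- **Community profiling** (`nrcd.community`): prevalence/abundance
  filtering, alpha diversity (observed, Chao1, Shannon, Simpson),
  Bray–Curtis + PERMANOVA, a simplified location–scale batch adjustment,
  and Welch / White differential abundance with BH correction.
- **Networks** (`nrcd.networks`): CLR transform, neighborhood-selection
  sparse inverse covariance (SPIEC-EASI-style) with StARS penalty
  selection, topology summaries, log-normal-quantile keystone detection,
  attack-robustness curves, and Fisher-Z differential association.
- **Clustering** (`nrcd.clustering`): multiple factor analysis across
  variable blocks, informative-variable selection, Canberra distance,
  classical MDS, and BIC-selected Gaussian-mixture clustering.
- **Integration** (`nrcd.integration`): origin-stratified hypergeometric
  pathway enrichment, Spearman microbe–metabolite correlation, tripartite
  taxa–metabolite–pathway networks, symptom–feature association tables.

## Worked example

```python
import numpy as np
from nrcd import (CohortConfig, generate_cohort, alpha_diversity,
                  beta_diversity_permanova, clr_transform, infer_network,
                  topology_summary, score_cdat, attack_robustness)

cohort = generate_cohort(CohortConfig(), seed=7)
print("samples:", cohort.abundance.data.shape[1],
      "taxa:", cohort.abundance.data.shape[0])

alpha = alpha_diversity(cohort.abundance)
print("mean Shannon:", round(alpha["shannon"].mean(), 3))

f, r2, p = beta_diversity_permanova(cohort.abundance, cohort.true_groups,
                                    n_perm=999, seed=0)
print(f"PERMANOVA: F={f:.3f} R2={r2:.3f} p={p:.3f}")

rel = cohort.abundance.to_relative().data
low = rel.loc[:, np.asarray(cohort.true_groups) == "low"]
net = infer_network(clr_transform(low.T), seed=0)
topo = topology_summary(net)
print(f"low-group network: size={topo.size} order={topo.order} "
      f"density={topo.edge_density:.3f} positive={topo.positive_edge_pct:.1f}%")

curve = attack_robustness(net, "degree")
print("LCC after 5 removals:", curve.lcc_sizes[:6].tolist())

s = score_cdat([1, 2, 1, 3, 1, 2, 1])
print("CDAT total:", s.total, "category:", s.category)
```

Output:

```text
samples: 87 taxa: 50
mean Shannon: 2.707
PERMANOVA: F=4.878 R2=0.104 p=0.001
low-group network: size=98 order=50 density=0.080 positive=51.0%
LCC after 5 removals: [43, 42, 37, 25, 21, 18]
CDAT total: 11.0 category: very good
```

## Reproduction

`scripts/acceptance.py` runs the main validation computations (planted
network recovery, null calibrations of the differential-association and
PERMANOVA tests, clustering recovery, attack-curve reproducibility,
enrichment versus exhaustive enumeration, and a full simulated-cohort
pipeline) and writes each quantity with its sample size as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With `--seed 1` this reports, among others: planted-network recovery
median precision 0.882 and recall 0.75 (5 seeds, p=50 taxa, 60 edges,
n=200 samples), empty-network rate 1.0 on independent-Gaussian nulls,
differential-association null discovery rate 0.00047, PERMANOVA null
rejection rate 0.045 at alpha 0.05, and clustering median adjusted Rand
index 1.0 against the planted subgroups. The same properties are asserted
with tolerances in `tests/test_acceptance.py`; methodological details and
parameter rationale are in `docs/methods.md`.
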