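"""Community-level preprocessing and testing for shotgun taxonomic profiles.

Covers the standard stages between a merged taxonomic profile and the
network/integration analyses: prevalence-abundance filtering, alpha
diversity (observed richness, Chao1, Shannon, Simpson), Bray-Curtis
PERMANOVA for between-group beta diversity, a location/scale batch
adjustment on the log scale (for merging cohorts profiled in different
studies), and two-group differential abundance with Welch's t-test or a
nonparametric bootstrap ("White's") test, Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceTable",
    "read_metaphlan_tsv",
    "filter_prevalence",
    "alpha_diversity",
    "bray_curtis",
    "permanova",
    "beta_diversity_permanova",
    "batch_adjust",
    "differential_abundance",
]


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Taxa-by-sample abundance matrix with taxonomy and sample labels.

    ``data`` holds taxa as rows and samples as columns, either raw counts
    or relative abundances (``is_relative``). ``taxonomy`` maps each taxon
    id to its rank-prefixed lineage string (``k__...|p__...|...|s__...``).
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None
    batch_of: pd.Series | None = None
    group_of: pd.Series | None = None
    is_relative: bool = False

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.data.index.duplicated().any():
            raise ValueError("taxon ids must be unique")
        if self.is_relative:
            colsums = self.data.sum(axis=0).to_numpy()
            if (colsums > 1 + 1e-6).any():
                raise ValueError("relative abundances must sum to at most 1 per sample")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def to_relative(self) -> "AbundanceTable":
        """Per-sample total-sum scaling; all-zero samples stay zero."""
        if self.is_relative:
            return self
        totals = self.data.sum(axis=0).replace(0, np.nan)
        rel = self.data.div(totals, axis=1).fillna(0.0)
        return replace(self, data=rel, is_relative=True)

    def subset_samples(self, samples) -> "AbundanceTable":
        samples = list(samples)
        return replace(
            self,
            data=self.data[samples],
            batch_of=None if self.batch_of is None else self.batch_of.loc[samples],
            group_of=None if self.group_of is None else self.group_of.loc[samples],
        )


def read_metaphlan_tsv(path, species_only: bool = True) -> AbundanceTable:
    """Read a merged MetaPhlAn-style relative-abundance TSV.

    The first column carries the rank-prefixed lineage; by default only
    species-level rows (containing ``s__`` but no strain ``t__`` marker)
    are retained. Percentages are rescaled to proportions.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    lineages = raw.index.astype(str)
    if species_only:
        keep = lineages.str.contains("s__") & ~lineages.str.contains("t__")
        raw = raw.loc[keep]
        lineages = raw.index.astype(str)
    species = [ln.split("|")[-1].replace("s__", "") for ln in lineages]
    data = raw.set_axis(species, axis=0).astype(float)
    if (data.sum(axis=0) > 1 + 1e-6).any():  # percentage scale
        data = data / 100.0
    return AbundanceTable(data=data, taxonomy=pd.Series(lineages.to_numpy(), index=species),
                          is_relative=True)


# ---------------------------------------------------------------------------
# prevalence/abundance filter
# ---------------------------------------------------------------------------

def filter_prevalence(table: AbundanceTable, abundance_threshold: float = 1e-4,
                      prevalence_threshold: float = 0.10) -> AbundanceTable:
    """Keep taxa whose relative abundance strictly exceeds the threshold
    in at least ``ceil(prevalence_threshold * n_samples)`` samples.

    Defaults implement the common "above 0.01% in 10% of samples" rule.
    Counts tables are converted to relative abundances for the decision
    only; the surviving rows keep their original scale.
    """
    rel = table.to_relative()
    n = rel.data.shape[1]
    need = int(np.ceil(prevalence_threshold * n))
    hits = (rel.data > abundance_threshold).sum(axis=1)
    keep = hits[hits >= need].index
    if len(keep) == 0:
        warnings.warn("prevalence filter removed every taxon")
    out = replace(table, data=table.data.loc[keep])
    if table.taxonomy is not None:
        out.taxonomy = table.taxonomy.loc[keep]
    return out


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _alpha_one(x: np.ndarray) -> tuple[float, float, float, float]:
    total = x.sum()
    if total == 0:
        warnings.warn("all-zero sample: diversity indices set to 0")
        return 0.0, 0.0, 0.0, 0.0
    observed = float((x > 0).sum())
    # bias-corrected Chao1; finite even without doubletons
    f1 = float((x == 1).sum())
    f2 = float((x == 2).sum())
    chao1 = observed + f1 * (f1 - 1) / (2 * (f2 + 1))
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p ** 2).sum())
    return observed, chao1, shannon, simpson


def alpha_diversity(table: AbundanceTable, simpson_kind: str = "gini") -> pd.DataFrame:
    """Per-sample observed richness, Chao1, Shannon (natural log) and Simpson.

    Simpson defaults to the Gini-Simpson form ``1 - sum(p^2)``;
    ``simpson_kind='inverse'`` reports ``1 / sum(p^2)`` instead. Chao1
    assumes integer counts; on a relative table it degrades to observed
    richness (no singleton information) and a warning is emitted.
    """
    if table.is_relative:
        warnings.warn("Chao1 is undefined on relative abundances; reporting observed richness")
    rows = {}
    for s in table.samples:
        x = table.data[s].to_numpy(dtype=float)
        observed, chao1, shannon, simpson = _alpha_one(x)
        if table.is_relative:
            chao1 = observed
        if simpson_kind == "inverse" and simpson < 1:
            simpson = 1.0 / (1.0 - simpson)
        rows[s] = {"observed": observed, "chao1": chao1,
                   "shannon": shannon, "simpson": simpson}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity / PERMANOVA
# ---------------------------------------------------------------------------

def bray_curtis(matrix: np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity between rows (samples) of ``matrix``."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(matrix, dtype=float), metric="braycurtis"))


def permanova(dist: np.ndarray, labels, n_perm: int = 999, seed: int | None = None
              ) -> tuple[float, float, float]:
    """One-way PERMANOVA on a distance matrix (Anderson's pseudo-F).

    Returns ``(pseudo_F, R2, p)`` with the permutation p-value
    ``(#{F_perm >= F_obs} + 1) / (n_perm + 1)``.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = dist.shape[0]
    groups, inv = np.unique(labels, return_inverse=True)
    a = len(groups)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        raise ValueError("every group must contain at least two samples")

    d2 = dist ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def ss_within(assign: np.ndarray) -> float:
        ssw = 0.0
        for g in range(a):
            idx = np.flatnonzero(assign == g)
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ssw

    def f_stat(assign: np.ndarray) -> float:
        ssw = ss_within(assign)
        ssa = ss_total - ssw
        return (ssa / (a - 1)) / (ssw / (n - a))

    f_obs = f_stat(inv)
    r2 = 1.0 - ss_within(inv) / ss_total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(inv)) >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return float(f_obs), float(r2), float(p)


def beta_diversity_permanova(table: AbundanceTable, labels=None, distance: str = "bray-curtis",
                             n_perm: int = 999, seed: int | None = None
                             ) -> tuple[float, float, float]:
    """Bray-Curtis distances between samples + PERMANOVA across ``labels``.

    ``labels`` defaults to the table's group assignment.
    """
    if distance != "bray-curtis":
        raise ValueError("only the Bray-Curtis distance is built in")
    if labels is None:
        if table.group_of is None:
            raise ValueError("no labels given and the table carries no group assignment")
        labels = table.group_of.loc[table.samples]
    rel = table.to_relative()
    dist = bray_curtis(rel.data.to_numpy().T)
    return permanova(dist, np.asarray(labels), n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# batch adjustment
# ---------------------------------------------------------------------------

def batch_adjust(table: AbundanceTable, batch_of: pd.Series | None = None,
                 covariate: pd.Series | None = None) -> AbundanceTable:
    """Location/scale batch adjustment of log relative abundances.

    Per feature: log-transform the nonzero relative abundances (pseudocount
    = half the smallest nonzero value in the table), regress out the
    biological covariate (group means), estimate batch location and scale
    from the residuals, remove them, back-transform and renormalize each
    sample. Structural zeros are preserved exactly.

    Raises if batch and covariate are in one-to-one correspondence, in
    which case the batch effect is unidentifiable.
    """
    batch = table.batch_of if batch_of is None else batch_of
    if batch is None:
        raise ValueError("no batch assignment available")
    batch = batch.loc[table.samples]
    if batch.nunique() < 2:
        return table.to_relative()
    group = table.group_of if covariate is None else covariate
    if group is not None:
        group = group.loc[table.samples]
        ct = pd.crosstab(batch, group)
        if (ct.to_numpy() > 0).sum() == max(ct.shape) and ct.shape[0] == ct.shape[1]:
            raise ValueError("batch is fully confounded with the covariate; "
                             "the batch effect is unidentifiable")

    rel = table.to_relative()
    x = rel.data.to_numpy(dtype=float)  # taxa x samples
    nonzero = x > 0
    pseudo = 0.5 * x[nonzero].min()
    logx = np.log(np.where(nonzero, x, pseudo))

    batch_codes = pd.Categorical(batch).codes
    group_codes = (pd.Categorical(group).codes if group is not None
                   else np.zeros(len(batch), dtype=int))

    adj = logx.copy()
    for f in range(logx.shape[0]):
        row = logx[f]
        resid = row.copy()
        for g in np.unique(group_codes):
            m = group_codes == g
            resid[m] = row[m] - row[m].mean()
        group_fit = row - resid
        pooled_sd = resid.std(ddof=1)
        for b in np.unique(batch_codes):
            m = batch_codes == b
            loc = resid[m].mean()
            sd = (resid[m] - loc).std(ddof=1)
            scale = pooled_sd / sd if sd > 0 and pooled_sd > 0 else 1.0
            adj[f, m] = group_fit[m] + (resid[m] - loc) * scale
    back = np.exp(adj)
    back[~nonzero] = 0.0
    totals = back.sum(axis=0)
    totals[totals == 0] = 1.0
    back = back / totals
    out = pd.DataFrame(back, index=rel.data.index, columns=rel.data.columns)
    return replace(rel, data=out)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def _white_bootstrap_p(x: np.ndarray, y: np.ndarray, n_boot: int,
                       rng: np.random.Generator) -> float:
    """Two-sided bootstrap test of equal means (within-group resampling).

    The bootstrap null distribution of the mean difference is centred at
    zero; the p-value is the fraction of null draws at least as extreme as
    the observed difference (add-one corrected).
    """
    obs = x.mean() - y.mean()
    xc = x - x.mean()
    yc = y - y.mean()
    bx = rng.choice(xc, size=(n_boot, x.size), replace=True).mean(axis=1)
    by = rng.choice(yc, size=(n_boot, y.size), replace=True).mean(axis=1)
    null = bx - by
    return float((np.sum(np.abs(null) >= abs(obs)) + 1) / (n_boot + 1))


def differential_abundance(table: AbundanceTable, labels=None, test: str = "welch",
                           effect_size_min: float = 0.75, n_boot: int = 10000,
                           seed: int | None = None) -> pd.DataFrame:
    """Two-group feature tests on the percentage scale.

    ``test='welch'`` uses the unequal-variance t-test; ``test='white'``
    uses a within-group bootstrap of the mean difference. Features with
    zero variance in both groups get p = 1. Returns the full per-feature
    table with group means (%), mean difference (%), p, BH q, and a
    ``significant`` flag requiring both q < 0.05 and
    ``|difference| >= effect_size_min`` (percentage points).
    """
    if labels is None:
        if table.group_of is None:
            raise ValueError("no labels given and the table carries no group assignment")
        labels = table.group_of.loc[table.samples]
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError("differential abundance requires exactly two groups")
    rel = table.to_relative()
    pct = rel.data.to_numpy(dtype=float) * 100.0
    a = pct[:, labels == names[0]]
    b = pct[:, labels == names[1]]
    rng = np.random.default_rng(seed)

    rows = []
    for f, taxon in enumerate(rel.data.index):
        x, y = a[f], b[f]
        if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
            stat, p = 0.0, 1.0
        elif test == "welch":
            stat, p = stats.ttest_ind(x, y, equal_var=False)
            if np.isnan(p):  # zero variance in both groups, unequal means
                stat, p = np.inf, 0.0
        elif test == "white":
            stat = x.mean() - y.mean()
            p = _white_bootstrap_p(x, y, n_boot, rng)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({
            "feature": taxon,
            f"mean_{names[0]}": x.mean(),
            f"mean_{names[1]}": y.mean(),
            "difference": x.mean() - y.mean(),
            "statistic": float(stat),
            "p": float(p),
        })
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["q"] < 0.05) & (out["difference"].abs() >= effect_size_min)
    out["test"] = test
    return out
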