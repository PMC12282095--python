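"""Patient stratification from mixed clinical variable blocks.

The stage mirrors a common clinical-phenotyping recipe: multiple factor
analysis (MFA) across blocks of variables (symptomatology, diet,
anthropometry, inflammation, ...), selection of the most informative
variables by their summed factor contributions, Canberra distances over
the selected variables, classical metric multidimensional scaling of the
distance matrix, and Gaussian-mixture clustering with the component
number chosen by BIC. A comparison-table helper reproduces the usual
per-variable group summary (mean, SD, test p, BH q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VariableGroups",
    "MFAResult",
    "ClusteringResult",
    "mfa",
    "select_informative_variables",
    "canberra_distance",
    "classical_mds",
    "gmm_cluster",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# MFA
# ---------------------------------------------------------------------------

@dataclass
class VariableGroups:
    """Samples-by-variables matrix partitioned into named variable blocks."""

    matrix: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [v for v in self.matrix.columns if v not in self.group_of]
        if missing:
            raise ValueError(f"variables without a group: {missing}")
        zero_var = self.matrix.columns[self.matrix.std(ddof=0) == 0].tolist()
        if zero_var:
            raise ValueError(f"constant variables cannot enter MFA: {zero_var}")

    def blocks(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for v in self.matrix.columns:
            out.setdefault(self.group_of[v], []).append(v)
        return out


@dataclass
class MFAResult:
    scores: pd.DataFrame            # samples x factors
    contributions: pd.DataFrame     # variables x factors, columns sum to 1
    explained_variance_ratio: np.ndarray
    block_weights: dict[str, float]


def mfa(groups: VariableGroups, n_factors: int | None = None) -> MFAResult:
    """Multiple factor analysis: block-weighted global PCA.

    Each block is standardized (zero mean, unit variance per variable)
    and divided by its largest singular value, so no single block
    dominates the first global axis; the weighted blocks are concatenated
    and decomposed by SVD. Per-variable contributions are squared
    loadings normalized within each factor.
    """
    x = groups.matrix
    if x.shape[0] < 2:
        raise ValueError("MFA needs at least 2 samples")
    z = (x - x.mean()) / x.std(ddof=0)
    weights: dict[str, float] = {}
    weighted = z.copy()
    for name, cols in groups.blocks().items():
        s1 = np.linalg.svd(z[cols].to_numpy(), compute_uv=False)[0]
        weights[name] = float(s1)
        weighted[cols] = z[cols] / s1
    u, s, vt = np.linalg.svd(weighted.to_numpy(), full_matrices=False)
    k = len(s) if n_factors is None else min(n_factors, len(s))
    factors = [f"F{i+1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=x.index, columns=factors)
    loadings = vt[:k].T * s[:k]  # variables x factors
    contrib = loadings ** 2
    contrib = contrib / contrib.sum(axis=0, keepdims=True)
    ev = s ** 2
    return MFAResult(
        scores=scores,
        contributions=pd.DataFrame(contrib, index=x.columns, columns=factors),
        explained_variance_ratio=ev[:k] / ev.sum(),
        block_weights=weights,
    )


def select_informative_variables(result: MFAResult, n_keep: int,
                                 variance_target: float = 0.70) -> list[str]:
    """Top-``n_keep`` variables by summed contribution over leading factors.

    Factors are retained until their cumulative explained variance reaches
    ``variance_target`` (at least one factor). Ties resolve by variable
    order, making the selection deterministic.
    """
    if n_keep > result.contributions.shape[0]:
        raise ValueError("cannot keep more variables than exist")
    cum = np.cumsum(result.explained_variance_ratio)
    n_fact = max(1, int(np.searchsorted(cum, variance_target) + 1))
    n_fact = min(n_fact, result.contributions.shape[1])
    score = result.contributions.iloc[:, :n_fact].sum(axis=1)
    order = score.sort_values(ascending=False, kind="stable")
    return order.index[:n_keep].tolist()


# ---------------------------------------------------------------------------
# distances and clustering
# ---------------------------------------------------------------------------

def canberra_distance(matrix) -> np.ndarray:
    """Pairwise Canberra distances between rows.

    ``d(x, y) = sum_i |x_i - y_i| / (|x_i| + |y_i|)`` with coordinates
    where both entries are zero contributing nothing.
    """
    x = np.asarray(pd.DataFrame(matrix), dtype=float)
    if np.isnan(x).all(axis=1).any():
        raise ValueError("rows entirely NaN are not allowed")
    return squareform(pdist(x, metric="canberra"))


def classical_mds(dist: np.ndarray, n_dim: int | None = None,
                  max_dim: int = 10, eigen_ratio: float = 0.5) -> np.ndarray:
    """Classical (Torgerson) metric MDS embedding of a distance matrix.

    Double-centers the squared distances and embeds on the leading
    eigenvectors. By default only axes whose eigenvalue is at least
    ``eigen_ratio`` times the leading one are kept (capped at
    ``max_dim``): non-Euclidean distances such as Canberra produce a long
    tail of comparable "noise" eigenvalues that carries no cluster
    structure but dominates likelihood-based model selection downstream.
    Pass ``n_dim`` for an exact dimension, or ``eigen_ratio=0`` to keep
    every positive-eigenvalue axis up to the cap.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(vals.max(), 1.0)
    if n_dim is None:
        k = int((pos & (vals >= eigen_ratio * vals.max())).sum())
    else:
        k = n_dim
    k = min(k, max_dim, n - 1)
    if k < 1:
        raise ValueError("distance matrix admits no positive-eigenvalue embedding")
    return vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))


@dataclass
class ClusteringResult:
    selected_variables: list[str]
    labels: np.ndarray
    n_components: int
    bic_table: pd.DataFrame
    embedding: np.ndarray
    covariance_type: str = "full"


def gmm_cluster(dist: np.ndarray, max_components: int = 5, embed_dim: int | None = None,
                seed: int | None = None,
                selected_variables: list[str] | None = None) -> ClusteringResult:
    """Gaussian-mixture clustering of a distance matrix via MDS embedding.

    The matrix is embedded by classical MDS (default dimension: leading
    axes carrying at least half the top eigenvalue, capped at 10);
    mixtures with 1..``max_components``
    components and spherical/diagonal/full covariances are fitted by EM
    with k-means initialization, and the lowest-BIC model labels the
    samples.
    """
    d = np.asarray(dist, dtype=float)
    if not np.allclose(d, d.T) or (d < -1e-12).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    n = d.shape[0]
    if embed_dim is not None and embed_dim >= n:
        raise ValueError("embed_dim must be smaller than the number of samples")
    emb = classical_mds(d, n_dim=embed_dim)
    dim = emb.shape[1]
    # scale-aware variance floor: stops components collapsing onto a few
    # near-duplicate points, which otherwise wins BIC at small n
    reg = 1e-2 * float(emb.var(axis=0).mean())
    rows = []
    best = None
    for k in range(1, max_components + 1):
        for cov in ("spherical", "diag", "full"):
            # a full covariance needs >= dim+1 points per component to be
            # non-degenerate; skip unestimable models (as mclust drops them)
            if cov == "full" and n / k < dim + 1:
                continue
            gm = GaussianMixture(n_components=k, covariance_type=cov,
                                 random_state=seed, n_init=3, reg_covar=reg)
            gm.fit(emb)
            bic = gm.bic(emb)
            rows.append({"n_components": k, "covariance_type": cov, "bic": bic})
            if best is None or bic < best[0]:
                best = (bic, k, cov, gm)
    _, k, cov, gm = best
    return ClusteringResult(
        selected_variables=selected_variables or [],
        labels=gm.predict(emb),
        n_components=k,
        bic_table=pd.DataFrame(rows),
        embedding=emb,
        covariance_type=cov,
    )


# ---------------------------------------------------------------------------
# group comparison tables
# ---------------------------------------------------------------------------

def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p: exact for small tie-free samples, else
    normal approximation with tie correction."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(data: pd.DataFrame, labels, test: str = "wilcoxon") -> pd.DataFrame:
    """Per-variable two-group comparison table.

    Returns group means and SDs, the test statistic and p-value
    (``wilcoxon`` rank-sum or ``welch`` t-test), and BH-adjusted q with a
    significance flag at q < 0.05.
    """
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    if min((labels == g).sum() for g in names) < 2:
        raise ValueError("each group needs at least two samples")
    rows = []
    for var in data.columns:
        x = data.loc[labels == names[0], var].dropna().to_numpy(dtype=float)
        y = data.loc[labels == names[1], var].dropna().to_numpy(dtype=float)
        pooled = np.concatenate([x, y])
        if len(pooled) and np.all(pooled == pooled[0]):
            stat, p = 0.0, 1.0  # every observation tied: no evidence either way
        elif test == "wilcoxon":
            stat, p = _wilcoxon_p(x, y)
        elif test == "welch":
            stat, p = stats.ttest_ind(x, y, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({
            "variable": var,
            f"mean_{names[0]}": x.mean(), f"sd_{names[0]}": x.std(ddof=1),
            f"mean_{names[1]}": y.mean(), f"sd_{names[1]}": y.std(ddof=1),
            "statistic": float(stat), "p": float(p),
        })
    out = pd.DataFrame(rows).set_index("variable")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < 0.05
    return out
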