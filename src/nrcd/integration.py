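"""Microbe-metabolite-symptom integration.

Stratifies metabolites by origin (host, microbiota, co-metabolism, drug,
food, environment, unknown), tests pathway enrichment of differential
metabolites with the upper-tail hypergeometric test (BH-corrected within
each origin stratum), correlates taxa with metabolites (Spearman), and
assembles a tripartite taxon-metabolite-pathway network. A final helper
computes symptom-feature Pearson correlation grids with significance
stars for heatmap-style reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ORIGINS",
    "read_annotation",
    "classify_metabolites",
    "pathway_enrichment",
    "microbe_metabolite_correlation",
    "build_integration_network",
    "symptom_feature_association",
]

ORIGINS = ("host", "microbiota", "co-metabolism", "drug", "food", "environment", "unknown")


def read_annotation(path) -> pd.DataFrame:
    """Read a metabolite annotation TSV.

    Expected columns: ``metabolite_id``, ``origin``, ``pathway_ids``
    (semicolon-separated, may be empty).
    """
    ann = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"metabolite_id", "origin", "pathway_ids"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return ann


def _pathways_of(row: str) -> set[str]:
    return {p for p in str(row).split(";") if p}


def classify_metabolites(metabolite_ids, annotation: pd.DataFrame
                         ) -> tuple[pd.Series, dict[str, int]]:
    """Partition metabolites by annotated origin.

    Metabolites absent from the annotation are labelled ``unknown``.
    Returns the per-metabolite origin series plus a count summary.
    """
    ids = list(metabolite_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate metabolite ids")
    lookup = dict(zip(annotation["metabolite_id"], annotation["origin"]))
    bad = set(lookup.values()) - set(ORIGINS)
    if bad:
        raise ValueError(f"unknown origin labels: {sorted(bad)}")
    origin = pd.Series({m: lookup.get(m, "unknown") for m in ids}, name="origin")[ids]
    counts = origin.value_counts().to_dict()
    return origin, counts


def pathway_enrichment(differential_ids, annotation: pd.DataFrame,
                       origins=("microbiota", "co-metabolism")) -> pd.DataFrame:
    """Hypergeometric pathway over-representation, per origin stratum.

    For each pathway with K annotated metabolites in a universe of N
    (the annotated metabolites of that origin), of which n are
    differential and k differential-in-pathway, the upper-tail p-value is
    ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``. BH correction is
    applied within each origin stratum; pathways with K = 0 are skipped.
    """
    differential = set(differential_ids)
    unknown = differential - set(annotation["metabolite_id"])
    if unknown:
        raise ValueError(f"differential metabolites missing from the annotation: {sorted(unknown)}")
    rows = []
    for origin in origins:
        stratum = annotation[annotation["origin"] == origin]
        universe = list(stratum["metabolite_id"])
        n_universe = len(universe)
        if n_universe == 0:
            continue
        diff_in = [m for m in universe if m in differential]
        pathways: dict[str, set[str]] = {}
        for m, pw in zip(stratum["metabolite_id"], stratum["pathway_ids"]):
            for p in _pathways_of(pw):
                pathways.setdefault(p, set()).add(m)
        for p, members in sorted(pathways.items()):
            big_k = len(members)
            k = len(members & set(diff_in))
            pval = float(stats.hypergeom.sf(k - 1, n_universe, big_k, len(diff_in)))
            rows.append({"origin": origin, "pathway": p, "k": k, "K": big_k,
                         "n": len(diff_in), "N": n_universe, "p": pval})
    out = pd.DataFrame(rows, columns=["origin", "pathway", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = np.nan
        for origin in out["origin"].unique():
            m = out["origin"] == origin
            out.loc[m, "q"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def microbe_metabolite_correlation(taxa_clr: pd.DataFrame, metabolite_log: pd.DataFrame,
                                   p_threshold: float = 0.05) -> pd.DataFrame:
    """Spearman correlation edges between taxa and metabolites.

    Both matrices are samples-by-features with matched row order. Pairs
    involving a constant column are skipped with a warning. Edges with
    two-sided p below ``p_threshold`` are returned with their sign.
    """
    if list(taxa_clr.index) != list(metabolite_log.index):
        raise ValueError("taxa and metabolite matrices must share sample order")
    rows = []
    skipped = 0
    for t in taxa_clr.columns:
        x = taxa_clr[t].to_numpy(dtype=float)
        if np.all(x == x[0]):
            skipped += 1
            continue
        for m in metabolite_log.columns:
            y = metabolite_log[m].to_numpy(dtype=float)
            if np.all(y == y[0]):
                skipped += 1
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"taxon": t, "metabolite": m, "rho": float(rho),
                         "p": float(p), "sign": int(np.sign(rho))})
    if skipped:
        warnings.warn(f"skipped {skipped} constant-column pairings")
    edges = pd.DataFrame(rows, columns=["taxon", "metabolite", "rho", "p", "sign"])
    return edges[edges["p"] < p_threshold].reset_index(drop=True)


def build_integration_network(enrichment: pd.DataFrame, correlation_edges: pd.DataFrame,
                              metabolite_groups: dict[str, str] | None = None,
                              taxon_groups: dict[str, str] | None = None,
                              q_threshold: float = 0.05,
                              annotation: pd.DataFrame | None = None) -> nx.Graph:
    """Assemble the tripartite taxon-metabolite-pathway network.

    Nodes are the significantly enriched pathways (q below
    ``q_threshold``), their differential metabolites (membership edges
    from the annotation), and every taxon with at least one significant
    correlation edge to one of those metabolites. Node attribute
    ``kind`` distinguishes the three classes; ``group`` carries the
    enrichment direction label where known; node ``degree`` is stored
    for display sizing. Taxa never connect directly to pathways.
    """
    g = nx.Graph()
    sig = enrichment[enrichment["q"] < q_threshold] if len(enrichment) else enrichment
    pathway_members: dict[str, set[str]] = {}
    if annotation is not None:
        for m, pw in zip(annotation["metabolite_id"], annotation["pathway_ids"]):
            for p in _pathways_of(pw):
                pathway_members.setdefault(p, set()).add(m)
    diff_metabs = set(metabolite_groups or {})
    for row in sig.itertuples():
        g.add_node(row.pathway, kind="pathway", origin=row.origin)
        for m in sorted(pathway_members.get(row.pathway, set()) & diff_metabs):
            g.add_node(m, kind="metabolite", group=(metabolite_groups or {}).get(m))
            g.add_edge(row.pathway, m, kind="membership")
    metab_nodes = {v for v, d in g.nodes(data=True) if d["kind"] == "metabolite"}
    if not metab_nodes and not len(sig):  # no pathway layer: connect to all differentials
        for m in sorted(diff_metabs):
            g.add_node(m, kind="metabolite", group=(metabolite_groups or {}).get(m))
        metab_nodes = set(diff_metabs)
    for row in correlation_edges.itertuples():
        if row.metabolite in metab_nodes:
            g.add_node(row.taxon, kind="taxon", group=(taxon_groups or {}).get(row.taxon))
            g.add_edge(row.taxon, row.metabolite, kind="correlation",
                       rho=row.rho, p=row.p, sign=row.sign, significant=True)
    for v in g.nodes:
        g.nodes[v]["degree"] = g.degree(v)
    return g


def symptom_feature_association(symptoms: pd.DataFrame, features: pd.DataFrame
                                ) -> pd.DataFrame:
    """Pearson correlation grid between symptom scores and features.

    Returns the long-format table (symptom, feature, r, p, BH q over the
    whole grid, and star annotations: ``*`` for p < 0.05, ``**`` for
    p < 0.01; ``q_stars`` applies the same rule to the adjusted values).
    """
    if list(symptoms.index) != list(features.index):
        raise ValueError("symptom and feature matrices must share sample order")
    if len(symptoms) < 4:
        raise ValueError("association needs at least 4 samples")
    rows = []
    for s in symptoms.columns:
        x = symptoms[s].to_numpy(dtype=float)
        for f in features.columns:
            y = features[f].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                r, p = np.nan, 1.0
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"symptom": s, "feature": f, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]

    def star(p):
        return "**" if p < 0.01 else "*" if p < 0.05 else ""

    out["stars"] = out["p"].map(star)
    out["q_stars"] = out["q"].map(star)
    return out
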