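"""Origin classification, enrichment, correlation and integration network."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nrcd import CohortConfig, generate_cohort
from nrcd.integration import (
    build_integration_network,
    classify_metabolites,
    microbe_metabolite_correlation,
    pathway_enrichment,
    read_annotation,
    symptom_feature_association,
)
from nrcd.networks import clr_transform


def _annotation(rows):
    return pd.DataFrame(rows, columns=["metabolite_id", "origin", "pathway_ids"])


class TestClassify:
    def test_empty_annotation_all_unknown(self):
        origin, counts = classify_metabolites(["a", "b"], _annotation([]))
        assert (origin == "unknown").all()
        assert counts == {"unknown": 2}

    def test_partial_annotation(self):
        ann = _annotation([(m, "microbiota", "") for m in ["a", "b", "c"]])
        origin, counts = classify_metabolites(["a", "b", "c", "d", "e"], ann)
        assert counts == {"microbiota": 3, "unknown": 2}

    def test_counts_conserve_total(self, annotation_path):
        ann = read_annotation(annotation_path)
        ids = [f"M{i:03d}" for i in range(20)]
        origin, counts = classify_metabolites(ids, ann)
        assert sum(counts.values()) == len(ids)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            classify_metabolites(["a", "a"], _annotation([]))

    def test_bad_origin_label_rejected(self):
        with pytest.raises(ValueError, match="origin"):
            classify_metabolites(["a"], _annotation([("a", "martian", "")]))


def _enrichment_enumeration_p(N, K, n, k):
    """Exhaustive oracle: fraction of n-subsets with >= k pathway members."""
    universe = list(range(N))
    pathway = set(range(K))
    hits = sum(1 for draw in combinations(universe, n)
               if len(pathway & set(draw)) >= k)
    from math import comb
    return hits / comb(N, n)


class TestEnrichment:
    def test_extreme_case_closed_form(self):
        # N=10, K=5, n=5, k=5: only one of C(10,5)=252 subsets qualifies
        ann = _annotation(
            [(f"m{i}", "microbiota", "pw" if i < 5 else "") for i in range(10)])
        out = pathway_enrichment([f"m{i}" for i in range(5)], ann)
        row = out[out.pathway == "pw"].iloc[0]
        assert row.p == pytest.approx(1 / 252)
        assert (row.k, row.K, row.n, row.N) == (5, 5, 5, 10)

    def test_k_zero_gives_p_one(self):
        ann = _annotation(
            [(f"m{i}", "microbiota", "pw" if i < 3 else "") for i in range(8)])
        out = pathway_enrichment(["m5", "m6"], ann)
        assert out[out.pathway == "pw"].iloc[0].p == pytest.approx(1.0)

    def test_monotone_in_k(self):
        ps = [float(stats.hypergeom.sf(k - 1, 20, 8, 6)) for k in range(0, 7)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_matches_enumeration_small_universe(self):
        for N in (6, 9):
            for K in (2, N // 2):
                ann = _annotation(
                    [(f"m{i}", "microbiota", "pw" if i < K else "")
                     for i in range(N)])
                for n in (2, N - 1):
                    diff = [f"m{i}" for i in range(N - n, N)][:n]
                    out = pathway_enrichment(diff, ann)
                    row = out[out.pathway == "pw"].iloc[0]
                    oracle = _enrichment_enumeration_p(N, K, n, row.k)
                    assert row.p == pytest.approx(oracle, rel=1e-12)

    def test_bh_within_origin_stratum(self, annotation_path):
        ann = read_annotation(str(annotation_path))
        diff = ["M000", "M001", "M005", "M007"]
        out = pathway_enrichment(diff, ann)
        for origin in out["origin"].unique():
            sub = out[out["origin"] == origin]
            from statsmodels.stats.multitest import multipletests
            np.testing.assert_allclose(
                sub["q"], multipletests(sub["p"], method="fdr_bh")[1], atol=1e-12)

    def test_unannotated_differential_rejected(self):
        ann = _annotation([("a", "microbiota", "pw")])
        with pytest.raises(ValueError, match="missing"):
            pathway_enrichment(["zzz"], ann)


class TestCorrelation:
    def test_monotone_transform_perfect_rho(self, rng):
        x = rng.normal(size=30)
        taxa = pd.DataFrame({"t": x})
        metab = pd.DataFrame({"m": np.exp(x)})
        out = microbe_metabolite_correlation(taxa, metab, p_threshold=0.05)
        assert out.iloc[0].rho == pytest.approx(1.0)
        assert out.iloc[0].sign == 1

    def test_reversal_flips_sign(self, rng):
        x = rng.normal(size=30)
        taxa = pd.DataFrame({"t": x})
        out_pos = microbe_metabolite_correlation(taxa, pd.DataFrame({"m": x + 0.01}))
        out_neg = microbe_metabolite_correlation(taxa, pd.DataFrame({"m": -x}))
        assert out_pos.iloc[0].sign == 1 and out_neg.iloc[0].sign == -1

    def test_null_calibration(self):
        kept = total = 0
        for s in range(60):
            r = np.random.default_rng(s)
            taxa = pd.DataFrame(r.normal(size=(40, 4)),
                                columns=[f"t{i}" for i in range(4)])
            metab = pd.DataFrame(r.normal(size=(40, 4)),
                                 columns=[f"m{i}" for i in range(4)])
            out = microbe_metabolite_correlation(taxa, metab)
            kept += len(out)
            total += 16
        assert 0.03 <= kept / total <= 0.07

    def test_constant_column_skipped(self, rng):
        taxa = pd.DataFrame({"t": np.ones(20)})
        metab = pd.DataFrame({"m": rng.normal(size=20)})
        with pytest.warns(UserWarning, match="constant"):
            out = microbe_metabolite_correlation(taxa, metab)
        assert len(out) == 0

    def test_sample_mismatch_rejected(self, rng):
        taxa = pd.DataFrame({"t": rng.normal(size=5)}, index=list("abcde"))
        metab = pd.DataFrame({"m": rng.normal(size=5)}, index=list("edcba"))
        with pytest.raises(ValueError):
            microbe_metabolite_correlation(taxa, metab)


class TestIntegrationNetwork:
    def _enrichment(self):
        return pd.DataFrame([
            {"origin": "microbiota", "pathway": "pw1", "k": 3, "K": 4,
             "n": 3, "N": 10, "p": 0.001, "q": 0.004},
            {"origin": "microbiota", "pathway": "pw2", "k": 0, "K": 3,
             "n": 3, "N": 10, "p": 1.0, "q": 1.0},
        ])

    def test_no_correlations_no_taxa(self):
        ann = _annotation([("mA", "microbiota", "pw1"), ("mB", "microbiota", "pw1")])
        g = build_integration_network(
            self._enrichment(), pd.DataFrame(columns=["taxon", "metabolite",
                                                      "rho", "p", "sign"]),
            metabolite_groups={"mA": "low", "mB": "high"}, annotation=ann)
        kinds = {d["kind"] for _, d in g.nodes(data=True)}
        assert "taxon" not in kinds
        assert "pathway" in kinds and "metabolite" in kinds

    def test_taxon_degree(self):
        ann = _annotation([("mA", "microbiota", "pw1"), ("mB", "microbiota", "pw1")])
        edges = pd.DataFrame([
            {"taxon": "T1", "metabolite": "mA", "rho": 0.8, "p": 0.001, "sign": 1},
            {"taxon": "T1", "metabolite": "mB", "rho": -0.7, "p": 0.002, "sign": -1},
        ])
        g = build_integration_network(self._enrichment(), edges,
                                      metabolite_groups={"mA": "low", "mB": "low"},
                                      annotation=ann)
        assert g.nodes["T1"]["degree"] == 2

    def test_bipartite_no_taxon_pathway_edges(self):
        ann = _annotation([("mA", "microbiota", "pw1")])
        edges = pd.DataFrame([
            {"taxon": "T1", "metabolite": "mA", "rho": 0.8, "p": 0.001, "sign": 1}])
        g = build_integration_network(self._enrichment(), edges,
                                      metabolite_groups={"mA": "low"},
                                      annotation=ann)
        for u, v in g.edges:
            kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            assert kinds != {"taxon", "pathway"}

    def test_end_to_end_planted_chain_connected(self, annotation_path):
        # taxon -> metabolite coupling chains appear in the assembled network
        ann = read_annotation(annotation_path)
        connected = 0
        n_seeds = 8
        for s in range(n_seeds):
            co = generate_cohort(CohortConfig(), seed=200 + s)
            clr = clr_transform(co.abundance.to_relative().data.T)
            logm = np.log(co.metabolites)
            metab, terms = next(iter(co.truth["metabolite_couplings"].items()))
            taxon = terms[0][0]
            edges = microbe_metabolite_correlation(clr[[taxon]], logm[[metab]])
            enrich = pd.DataFrame([{"origin": "microbiota", "pathway": "path_scfa",
                                    "k": 2, "K": 3, "n": 2, "N": 10,
                                    "p": 0.01, "q": 0.03}])
            g = build_integration_network(enrich, edges,
                                          metabolite_groups={metab: "high"},
                                          annotation=ann)
            import networkx as nx
            if g.has_node(taxon) and g.has_node(metab) and nx.has_path(g, taxon, metab):
                connected += 1
        assert connected >= int(0.7 * n_seeds)


class TestSymptomAssociation:
    def test_identical_columns(self, rng):
        x = rng.normal(size=20)
        out = symptom_feature_association(pd.DataFrame({"s": x}),
                                          pd.DataFrame({"f": x}))
        row = out.iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p < 1e-10 and row.stars == "**"

    def test_grid_shape_and_lookup(self, rng):
        sympt = pd.DataFrame(rng.normal(size=(15, 2)), columns=["s1", "s2"])
        feats = pd.DataFrame(rng.normal(size=(15, 3)), columns=["f1", "f2", "f3"])
        out = symptom_feature_association(sympt, feats)
        assert len(out) == 6
        wide = out.pivot(index="symptom", columns="feature", values="r")
        row = out[(out.symptom == "s2") & (out.feature == "f3")].iloc[0]
        assert wide.loc["s2", "f3"] == pytest.approx(row.r)

    def test_planted_coupling_starred(self):
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            co = generate_cohort(CohortConfig(), seed=s)
            mask = np.isin(co.true_groups, ["low", "high"])
            out = symptom_feature_association(co.symptoms.loc[mask],
                                              np.log(co.metabolites.loc[mask]))
            item, terms = next(iter(co.truth["symptom_couplings"].items()))
            metab = terms[0][0]
            row = out[(out.symptom == item) & (out.feature == metab)].iloc[0]
            hits += (row.stars != "")
        assert hits >= int(0.8 * n_seeds)

    def test_minimum_samples(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 1)), columns=["s"])
        with pytest.raises(ValueError):
            symptom_feature_association(x, x.rename(columns={"s": "f"}))
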