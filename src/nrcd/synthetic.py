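"""Synthetic cohorts with planted microbiome-metabolome-symptom structure.

The generator emulates a three-group celiac follow-up cohort — two
symptom-defined patient groups ("low" and "high" grade symptoms, 25 and
14 patients by default) plus 48 asymptomatic treated controls ("tCD")
merged from a second study — with complete ground truth:

* per-group co-occurrence structure planted as a sparse symmetric
  precision matrix (logistic-normal-multinomial counts: latent Gaussian
  log-abundances, softmax composition, multinomial sequencing depth);
* the two patient groups share a network backbone but differ on a
  designated set of taxon pairs (opposite-sign or present/absent partial
  correlations), and a subset of taxa carries a group mean shift on the
  log scale (differential taxa);
* a study-of-origin batch effect applied to the controls as an additive
  location shift plus a multiplicative scale on the latent log scale;
* metabolite log-intensities linearly coupled to named taxa CLR values;
* 0-10 Likert symptom items produced by rounding and clipping a linear
  function of named (standardized log) metabolites, plus questionnaire
  item matrices for the four clinical instruments on their native scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .community import AbundanceTable
from .networks import clr_transform

__all__ = [
    "PlantedNetwork",
    "CohortConfig",
    "SyntheticCohort",
    "generate_planted_network",
    "simulate_counts",
    "generate_cohort",
    "write_cohort",
]

#: Magnitude range of off-diagonal precision entries on the planted support.
PRECISION_MAGNITUDE = (0.15, 0.35)
#: Diagonal-dominance margin added to each row's absolute off-diagonal sum.
DIAGONAL_MARGIN = 0.1


# ---------------------------------------------------------------------------
# planted network
# ---------------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """Ground-truth conditional-dependence structure over taxa.

    ``adjacency`` is the binary support, ``edge_signs`` the sign of the
    implied partial correlation (+1 = co-occurrence), and ``precision``
    the symmetric positive-definite matrix realizing it. A positive
    partial correlation corresponds to a *negative* off-diagonal
    precision entry.
    """

    taxa_ids: list[str]
    adjacency: np.ndarray
    edge_signs: np.ndarray
    precision: np.ndarray

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency[np.triu_indices(self.n_taxa, 1)].sum())

    def edge_list(self) -> list[tuple[str, str, int]]:
        iu = np.triu_indices(self.n_taxa, 1)
        return [(self.taxa_ids[i], self.taxa_ids[j], int(self.edge_signs[i, j]))
                for i, j in zip(*iu) if self.adjacency[i, j]]

    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


def _taxon_ids(n: int) -> list[str]:
    return [f"Taxon_{i:03d}" for i in range(n)]


def _assemble_precision(n: int, edges: list[tuple[int, int]], signs: dict[tuple[int, int], int],
                        magnitudes: dict[tuple[int, int], float],
                        margin: float = DIAGONAL_MARGIN) -> np.ndarray:
    """Build a diagonally dominant precision matrix from a signed edge set.

    The raw matrix (off-diagonal magnitudes on the support, diagonal =
    row-wise absolute sum + margin) is rescaled as ``D @ omega @ D`` so
    that the implied latent covariance has unit variances. The rescaling
    preserves support, signs, positive definiteness and every partial
    correlation; without it, weakly connected taxa would carry latent
    variances up to ``1/margin`` and dominate the softmax compositions.
    """
    omega = np.zeros((n, n))
    for (i, j) in edges:
        val = -signs[(i, j)] * magnitudes[(i, j)]  # sign flip: precision vs partial corr
        omega[i, j] = omega[j, i] = val
    np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + margin)
    d = np.sqrt(np.diag(np.linalg.inv(omega)))
    return omega * np.outer(d, d)


def generate_planted_network(n_taxa: int, n_edges: int, frac_positive: float = 0.9,
                             seed: int | None = None) -> PlantedNetwork:
    """Random planted network with a guaranteed positive-definite precision.

    Exactly ``n_edges`` edges are drawn uniformly among the
    ``n_taxa*(n_taxa-1)/2`` pairs; ``round(frac_positive * n_edges)``
    carry sign +1. Off-diagonal magnitudes are uniform in
    ``PRECISION_MAGNITUDE`` and the diagonal is the row-wise absolute sum
    plus ``DIAGONAL_MARGIN``, which forces strict diagonal dominance and
    hence positive definiteness.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be positive")
    max_edges = n_taxa * (n_taxa - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}] for {n_taxa} taxa")
    if not 0 <= frac_positive <= 1:
        raise ValueError("frac_positive must be a proportion")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(range(n_taxa), 2))
    chosen = [pairs[k] for k in rng.choice(len(pairs), size=n_edges, replace=False)]
    n_pos = int(round(frac_positive * n_edges))
    sign_draw = np.array([1] * n_pos + [-1] * (n_edges - n_pos))
    rng.shuffle(sign_draw)
    signs = {e: int(s) for e, s in zip(chosen, sign_draw)}
    mags = {e: float(rng.uniform(*PRECISION_MAGNITUDE)) for e in chosen}

    adjacency = np.zeros((n_taxa, n_taxa), dtype=int)
    edge_signs = np.zeros((n_taxa, n_taxa), dtype=int)
    for (i, j) in chosen:
        adjacency[i, j] = adjacency[j, i] = 1
        edge_signs[i, j] = edge_signs[j, i] = signs[(i, j)]
    precision = _assemble_precision(n_taxa, chosen, signs, mags)
    return PlantedNetwork(taxa_ids=_taxon_ids(n_taxa), adjacency=adjacency,
                          edge_signs=edge_signs, precision=precision)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _latent_draw(network: PlantedNetwork, n_samples: int, base: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    cov = network.covariance()
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "planted precision matrix is singular or not positive definite") from exc
    z = rng.standard_normal((n_samples, network.n_taxa))
    return base + z @ chol.T


def _softmax(latent: np.ndarray) -> np.ndarray:
    shifted = latent - latent.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def simulate_counts(network: PlantedNetwork, n_samples: int, depth: int,
                    base_log_abundances, seed: int | None = None) -> AbundanceTable:
    """Logistic-normal-multinomial counts under a planted network.

    Latent log-abundances are multivariate normal with mean
    ``base_log_abundances`` and covariance ``inv(precision)``;
    compositions are their softmax; counts are multinomial draws at
    ``depth`` reads per sample (rows of the returned table are taxa).
    """
    base = np.asarray(base_log_abundances, dtype=float)
    if base.shape != (network.n_taxa,):
        raise ValueError("base_log_abundances must have one entry per taxon")
    rng = np.random.default_rng(seed)
    latent = _latent_draw(network, n_samples, base, rng)
    comp = _softmax(latent)
    counts = np.vstack([rng.multinomial(depth, row) for row in comp])
    samples = [f"S{i:03d}" for i in range(n_samples)]
    data = pd.DataFrame(counts.T, index=network.taxa_ids, columns=samples)
    return AbundanceTable(data=data, taxonomy=_default_taxonomy(network.taxa_ids))


def _default_taxonomy(taxa: list[str]) -> pd.Series:
    lineages = [
        f"k__Bacteria|p__Phylum{i % 5:02d}|c__Class{i % 5:02d}|o__Order{i % 10:02d}"
        f"|f__Family{i % 10:02d}|g__Genus{i // 5:02d}|s__{t}"
        for i, t in enumerate(taxa)
    ]
    return pd.Series(lineages, index=taxa)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated cohort: 25 low-grade and 14 high-grade
    symptom patients (one study, batch A) merged with 48 asymptomatic
    treated controls (second study, batch B).
    """

    n_low: int = 25
    n_high: int = 14
    n_tcd: int = 48
    n_taxa: int = 50
    n_backbone_edges: int = 60
    n_differential_pairs: int = 6
    frac_positive: float = 0.9
    depth: int = 10000
    base_log_sd: float = 1.0
    n_differential_taxa: int = 9
    differential_taxon_shift: float = 1.0
    # batch effect (latent log scale); "study" nests batch in study of origin,
    # "crossed" alternates batches within groups (identifiable design)
    batch_mode: str = "study"
    batch_shift: float = 0.5          # additive, in units of latent SD
    batch_scale: float = 1.2          # multiplicative on centered latents
    # metabolome
    n_metabolites: int = 30
    n_coupled_metabolites: int = 10
    metabolite_coupling: float = 1.0
    metabolite_noise_sd: float = 1.0
    metabolite_couplings: dict[str, list[tuple[str, float]]] | None = None
    # symptoms (0-10 items)
    n_symptom_items: int = 10
    n_coupled_symptoms: int = 8
    symptom_coupling: float = 0.8
    symptom_noise_sd: float = 1.5
    symptom_baseline: float = 2.0
    symptom_group_shift: float = 2.0  # additive latent shift for the high group
    symptom_couplings: dict[str, list[tuple[str, float]]] | None = None
    # clinical variables
    n_inflammation_markers: int = 12
    n_differential_markers: int = 6
    marker_effect: float = 1.0        # standardized high-vs-low shift
    questionnaire_group_shift: float = 2.0  # symptom-instrument latent shift

    def group_sizes(self) -> dict[str, int]:
        return {"low": self.n_low, "high": self.n_high, "tCD": self.n_tcd}


@dataclass
class SyntheticCohort:
    """Generated tables plus the complete ground truth."""

    abundance: AbundanceTable
    metabolites: pd.DataFrame            # samples x metabolites, intensities
    symptoms: pd.DataFrame               # samples x items, integers 0-10
    questionnaire_items: dict[str, pd.DataFrame]
    clinical: pd.DataFrame               # samples x continuous clinical variables
    batch_labels: pd.Series
    true_groups: pd.Series
    truth: dict

    def metadata(self) -> pd.DataFrame:
        """Flat per-sample metadata table (group, batch, items, clinical)."""
        parts = [pd.DataFrame({"group": self.true_groups, "batch": self.batch_labels}),
                 self.clinical, self.symptoms]
        parts += list(self.questionnaire_items.values())
        return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _group_networks(cfg: CohortConfig, rng: np.random.Generator
                    ) -> tuple[dict[str, PlantedNetwork], list[tuple[int, int]]]:
    """Backbone shared by all groups; low/high differ on designated pairs."""
    n = cfg.n_taxa
    pairs = list(combinations(range(n), 2))
    idx = rng.choice(len(pairs), size=cfg.n_backbone_edges + cfg.n_differential_pairs,
                     replace=False)
    backbone = [pairs[k] for k in idx[:cfg.n_backbone_edges]]
    diff_pairs = [pairs[k] for k in idx[cfg.n_backbone_edges:]]

    n_pos = int(round(cfg.frac_positive * cfg.n_backbone_edges))
    sign_draw = np.array([1] * n_pos + [-1] * (cfg.n_backbone_edges - n_pos))
    rng.shuffle(sign_draw)
    signs = {e: int(s) for e, s in zip(backbone, sign_draw)}
    mags = {e: float(rng.uniform(*PRECISION_MAGNITUDE)) for e in backbone + diff_pairs}

    def build(extra: dict[tuple[int, int], int]) -> PlantedNetwork:
        all_signs = {**signs, **extra}
        edges = list(all_signs)
        adjacency = np.zeros((n, n), dtype=int)
        edge_signs = np.zeros((n, n), dtype=int)
        for (i, j), s in all_signs.items():
            adjacency[i, j] = adjacency[j, i] = 1
            edge_signs[i, j] = edge_signs[j, i] = s
        precision = _assemble_precision(n, edges, all_signs, mags)
        return PlantedNetwork(taxa_ids=_taxon_ids(n), adjacency=adjacency,
                              edge_signs=edge_signs, precision=precision)

    # differential pairs: positive association in "low"; in "high" the first
    # half flips sign and the second half is absent entirely
    low_extra = {e: 1 for e in diff_pairs}
    half = len(diff_pairs) // 2
    high_extra = {e: -1 for e in diff_pairs[:half]}
    nets = {"low": build(low_extra), "high": build(high_extra), "tCD": build({})}
    return nets, diff_pairs


def _sample_ids(cfg: CohortConfig) -> dict[str, list[str]]:
    out, k = {}, 0
    for g, n in cfg.group_sizes().items():
        out[g] = [f"S{k + i:03d}" for i in range(n)]
        k += n
    return out


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None
                    ) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    See the module docstring for the generative model. All randomness is
    derived from ``seed``; identical (config, seed) gives bit-identical
    output.
    """
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    (rng_net, rng_counts, rng_metab, rng_sympt, rng_clin, rng_quest) = [
        np.random.default_rng(s) for s in ss.spawn(6)]

    nets, diff_pairs = _group_networks(cfg, rng_net)
    taxa = nets["low"].taxa_ids
    ids = _sample_ids(cfg)
    samples = [s for g in ids for s in ids[g]]
    groups = pd.Series({s: g for g in ids for s in ids[g]}, name="group")[samples]

    # base log abundances; differential taxa shifted in the high group
    base = rng_counts.normal(0.0, cfg.base_log_sd, cfg.n_taxa)
    diff_taxa_idx = rng_counts.choice(cfg.n_taxa, size=cfg.n_differential_taxa, replace=False)
    shift_signs = np.where(np.arange(cfg.n_differential_taxa) % 2 == 0, 1.0, -1.0)
    base_by_group = {g: base.copy() for g in ids}
    base_by_group["high"][diff_taxa_idx] += shift_signs * cfg.differential_taxon_shift

    # batches
    if cfg.batch_mode == "study":
        batch = pd.Series({s: ("B" if g == "tCD" else "A")
                           for g in ids for s in ids[g]}, name="batch")[samples]
    elif cfg.batch_mode == "crossed":
        batch = pd.Series({s: ("A" if i % 2 == 0 else "B")
                           for g in ids for i, s in enumerate(ids[g])}, name="batch")[samples]
    else:
        raise ValueError("batch_mode must be 'study' or 'crossed'")

    # latent draws and counts, group by group; batch B gets a per-taxon
    # location shift (a shift common to all taxa would cancel in the
    # softmax composition) plus a scale inflation of the centered latents
    batch_delta = rng_counts.normal(0.0, cfg.batch_shift, cfg.n_taxa)
    count_blocks = []
    for g in ids:
        if not ids[g]:  # a group may be configured with zero samples
            continue
        net = nets[g]
        latent = _latent_draw(net, len(ids[g]), base_by_group[g], rng_counts)
        sd = np.sqrt(np.diag(net.covariance()))
        in_b = np.array([batch[s] == "B" for s in ids[g]])
        if in_b.any():
            centered = latent[in_b] - base_by_group[g]
            latent[in_b] = (base_by_group[g] + centered * cfg.batch_scale
                            + batch_delta * sd)
        comp = _softmax(latent)
        counts = np.vstack([rng_counts.multinomial(cfg.depth, row) for row in comp])
        count_blocks.append(pd.DataFrame(counts, index=ids[g], columns=taxa))
    counts = pd.concat(count_blocks).loc[samples]
    abundance = AbundanceTable(data=counts.T, taxonomy=_default_taxonomy(taxa),
                               batch_of=batch, group_of=groups)

    # metabolites coupled to taxa CLR
    rel = counts.div(counts.sum(axis=1), axis=0)
    clr = clr_transform(rel)
    metab_ids = [f"M{m:03d}" for m in range(cfg.n_metabolites)]
    couplings = cfg.metabolite_couplings
    if couplings is None:
        couplings = {}
        diff_taxa = [taxa[i] for i in diff_taxa_idx]
        for m in range(cfg.n_coupled_metabolites):
            t = diff_taxa[m % len(diff_taxa)] if diff_taxa else taxa[m % len(taxa)]
            couplings[metab_ids[m]] = [(t, cfg.metabolite_coupling)]
    for m_id, terms in couplings.items():
        if m_id not in metab_ids:
            raise ValueError(f"coupling references unknown metabolite {m_id!r}")
        for t, _ in terms:
            if t not in taxa:
                raise ValueError(f"coupling references unknown taxon {t!r}")
    baseline = rng_metab.normal(10.0, 1.0, cfg.n_metabolites)
    log_int = np.tile(baseline, (len(samples), 1)) \
        + rng_metab.normal(0.0, cfg.metabolite_noise_sd, (len(samples), cfg.n_metabolites))
    for m_id, terms in couplings.items():
        col = metab_ids.index(m_id)
        for t, coef in terms:
            log_int[:, col] += coef * clr[t].to_numpy()
    metabolites = pd.DataFrame(np.exp(log_int), index=samples, columns=metab_ids)

    # symptoms: linear in standardized log metabolites, round-clip to 0-10
    item_ids = [f"symptom_{i:02d}" for i in range(cfg.n_symptom_items)]
    s_couplings = cfg.symptom_couplings
    coupled_metabs = list(couplings) or metab_ids
    if s_couplings is None:
        s_couplings = {}
        for i in range(min(cfg.n_coupled_symptoms, cfg.n_symptom_items)):
            m1 = coupled_metabs[i % len(coupled_metabs)]
            m2 = coupled_metabs[(i + 1) % len(coupled_metabs)]
            s_couplings[item_ids[i]] = [(m1, cfg.symptom_coupling),
                                        (m2, cfg.symptom_coupling)]
    for it, terms in s_couplings.items():
        if it not in item_ids:
            raise ValueError(f"coupling references unknown symptom item {it!r}")
        for m, _ in terms:
            if m not in metab_ids:
                raise ValueError(f"coupling references unknown metabolite {m!r}")
    zlog = np.log(metabolites.to_numpy())
    zlog = (zlog - zlog.mean(axis=0)) / np.where(zlog.std(axis=0) == 0, 1, zlog.std(axis=0))
    zlog = pd.DataFrame(zlog, index=samples, columns=metab_ids)
    is_high = (groups == "high").to_numpy()
    is_tcd = (groups == "tCD").to_numpy()
    latent_items = np.full((len(samples), cfg.n_symptom_items), cfg.symptom_baseline)
    latent_items[is_tcd] = 0.5  # asymptomatic controls
    latent_items[is_high] += cfg.symptom_group_shift
    for it, terms in s_couplings.items():
        col = item_ids.index(it)
        for m, coef in terms:
            latent_items[:, col] += coef * zlog[m].to_numpy()
    latent_items += rng_sympt.normal(0.0, cfg.symptom_noise_sd, latent_items.shape)
    symptoms = pd.DataFrame(np.clip(np.round(latent_items), 0, 10).astype(int),
                            index=samples, columns=item_ids)

    # continuous clinical variables: inflammation + anthropometry + diet
    # positive-valued marker panel (cytokine-like scale): Canberra distance
    # behaves poorly around zero, as do real assay floors
    clin = {}
    for k in range(cfg.n_inflammation_markers):
        x = rng_clin.normal(3.0, 1.0, len(samples))
        if k < cfg.n_differential_markers:
            x[is_high] += cfg.marker_effect
        clin[f"marker_{k:02d}"] = np.clip(x, 0.05, None)
    clin["age"] = rng_clin.normal(35, 10, len(samples)).clip(18, 65)
    clin["bmi"] = rng_clin.normal(22.6, 3.0, len(samples)).clip(16, 35)
    clin["weight"] = rng_clin.normal(61, 10, len(samples)).clip(40, 100)
    clin["height"] = rng_clin.normal(164, 8, len(samples))
    clin["waist"] = rng_clin.normal(75, 8, len(samples))
    for k, (mu, sdv) in enumerate([(2094, 530), (82, 20), (184, 60), (45, 8),
                                   (22, 7), (717, 250), (10.7, 3.5), (3.0, 3.0)]):
        clin[f"diet_{k:02d}"] = rng_clin.normal(mu, sdv, len(samples))
    clinical = pd.DataFrame(clin, index=samples)

    # questionnaire items on native scales
    quest = _questionnaires(cfg, samples, is_high, is_tcd, rng_quest)

    truth = {
        "seed": seed,
        "networks": {g: {"edges": nets[g].edge_list()} for g in nets},
        "differential_pairs": [(taxa[i], taxa[j]) for i, j in diff_pairs],
        "differential_taxa": [taxa[i] for i in diff_taxa_idx],
        "metabolite_couplings": {m: [[t, c] for t, c in v] for m, v in couplings.items()},
        "symptom_couplings": {s: [[m, c] for m, c in v] for s, v in s_couplings.items()},
        "planted_networks": nets,
    }
    return SyntheticCohort(abundance=abundance, metabolites=metabolites,
                           symptoms=symptoms, questionnaire_items=quest,
                           clinical=clinical, batch_labels=batch, true_groups=groups,
                           truth=truth)


def _questionnaires(cfg: CohortConfig, samples, is_high, is_tcd,
                    rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    n = len(samples)

    def items(prefix, k, lo, hi, base, shift_high, noise):
        latent = np.full((n, k), float(base))
        latent[is_tcd] = lo + 0.3 * (hi - lo)
        latent[is_high] += shift_high
        latent += rng.normal(0.0, noise, (n, k))
        vals = np.clip(np.round(latent), lo, hi).astype(int)
        cols = [f"{prefix}_{i:02d}" for i in range(1, k + 1)]
        return pd.DataFrame(vals, index=samples, columns=cols)

    g = cfg.questionnaire_group_shift
    return {
        "GSRS-CD": items("gsrs", 15, 0, 10, 3.0, g, 1.5),
        "CeD-Pro": items("cedpro", 10, 0, 10, 3.0, g, 1.5),
        "CD-QOL": items("cdqol", 20, 0, 5, 3.5, -g / 2, 1.0),
        "CDAT": items("cdat", 7, 1, 5, 1.7, 0.0, 0.8),
    }


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write the cohort to plain-text files.

    Emits a MetaPhlAn-style abundance TSV (taxonomy lineage in the first
    column), a metadata CSV, a metabolite intensity TSV, and the ground
    truth as JSON. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ab = cohort.abundance.to_relative()
    table = ab.data * 100.0  # MetaPhlAn-style percentage profile
    table.index = [cohort.abundance.taxonomy[t] for t in table.index]
    table.index.name = "clade_name"
    paths = {
        "abundance": outdir / "abundance.tsv",
        "metadata": outdir / "metadata.csv",
        "metabolites": outdir / "metabolites.tsv",
        "truth": outdir / "truth.json",
    }
    table.to_csv(paths["abundance"], sep="\t")
    cohort.metadata().to_csv(paths["metadata"], index_label="sample")
    cohort.metabolites.to_csv(paths["metabolites"], sep="\t", index_label="sample")
    truth = {k: v for k, v in cohort.truth.items() if k != "planted_networks"}
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
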