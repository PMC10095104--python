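"""Synthetic dual-species experiment generator.

Emulates, at the count level, the data regime of a humanized-mouse DSS
colitis study: bulk colon RNA that is ~500:1 mouse:human, with >90% of
detected genes being ortholog pairs whose conserved sequence yields reads
mapping equally well to both species.  Everything downstream of raw
sequencing is generated with known ground truth:

* two-pass count matrices (pass 1 discards shared reads, pass 2 counts
  them in both orthologs) for the splitter;
* tissue-marker genes (human-enriched "immune", mouse-enriched
  "intestine") plus GMT atlas stand-ins for provenance validation;
* a signed node-signature database with planted active nodes driving
  differential expression for the DE and node-inference stages;
* a random signed DAG with BEL-like labels for the network stage.

The generative model for shared reads: each species' true read total is
negative binomial (variance mu + phi mu^2); a binomial ``shared_fraction``
of each species' reads moves into a common shared pool S, which pass 2
adds identically to both orthologs.  This is the minimal per-pair model
under which the two-pass bookkeeping identity
``pass2 - pass1 = S`` holds exactly for both species.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ._rng import stream
from .config import GroundTruth, SimConfig
from .nodes import NodeSignatureDB
from .network import CausalGraph
from .provenance import TissueGeneSets
from .split import PassCounts

__all__ = [
    "simulate_two_pass_counts",
    "simulate_tissue_gene_sets",
    "simulate_node_signatures_and_de",
    "simulate_causal_graph",
]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with variance mu + phi mu^2 (Poisson when phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    # gamma-Poisson mixture keeps fractional means exact
    lam = rng.gamma(shape=r, scale=mean[pos] / r)
    out[pos] = rng.poisson(lam)
    return out


def _gene_names(cfg: SimConfig) -> Tuple[List[str], List[str], List[str], List[str]]:
    """HGNC-style upper-case human symbols, MGI-style capitalized mouse ones."""
    orth_hs = [f"GENE{i:04d}" for i in range(cfg.n_genes_orth)]
    orth_mm = [f"Gene{i:04d}" for i in range(cfg.n_genes_orth)]
    priv_hs = [f"HSONLY{i:03d}" for i in range(cfg.n_genes_private_hs)]
    priv_mm = [f"Mmonly{i:03d}" for i in range(cfg.n_genes_private_mm)]
    return orth_hs, orth_mm, priv_hs, priv_mm


def simulate_two_pass_counts(
    cfg: SimConfig,
) -> Tuple[PassCounts, PassCounts, pd.DataFrame, GroundTruth]:
    """Generate two-pass matrices for both species plus the ortholog table.

    Sample columns cover both treatment arms (ctl_*, trt_*).  Tissue-marker
    genes are planted here so the same matrices serve provenance checks:
    immune markers get ``tissue_boost`` on the human side, intestine
    markers on the mouse side.
    """
    rng = stream(cfg.seed, "counts")
    orth_hs, orth_mm, priv_hs, priv_mm = _gene_names(cfg)
    n_samples = 2 * cfg.n_samples_per_group
    samples = [f"ctl_{i + 1}" for i in range(cfg.n_samples_per_group)] + [
        f"trt_{i + 1}" for i in range(cfg.n_samples_per_group)
    ]

    if cfg.mean_depth / cfg.mixing_ratio * cfg.n_genes_orth < 1.0:
        warnings.warn(
            "expected total human signal rounds to zero at this depth/mixing ratio",
            UserWarning,
        )

    # per-gene relative expression levels (lognormal, unit mean scale)
    rel_orth = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes_orth)
    rel_phs = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes_private_hs)
    rel_pmm = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes_private_mm)

    # plant tissue markers among ortholog pairs: first half immune (human-
    # boosted), second half intestine (mouse-boosted)
    n_tissue = int(round(cfg.frac_tissue_genes * cfg.n_genes_orth))
    marker_idx = rng.choice(cfg.n_genes_orth, size=n_tissue, replace=False)
    immune_idx = np.sort(marker_idx[: n_tissue // 2])
    intestine_idx = np.sort(marker_idx[n_tissue // 2 :])
    boost_hs = np.ones(cfg.n_genes_orth)
    boost_mm = np.ones(cfg.n_genes_orth)
    boost_hs[immune_idx] = cfg.tissue_boost
    boost_mm[intestine_idx] = cfg.tissue_boost

    mu_mm = cfg.mean_depth * rel_orth * boost_mm
    mu_hs = cfg.mean_depth / cfg.mixing_ratio * rel_orth * boost_hs

    y_hs = _nb_draw(rng, np.tile(mu_hs[:, None], (1, n_samples)), cfg.nb_dispersion)
    y_mm = _nb_draw(rng, np.tile(mu_mm[:, None], (1, n_samples)), cfg.nb_dispersion)

    s_hs = rng.binomial(y_hs, cfg.shared_fraction)
    s_mm = rng.binomial(y_mm, cfg.shared_fraction)
    shared = s_hs + s_mm

    pass1_hs = y_hs - s_hs
    pass1_mm = y_mm - s_mm
    pass2_hs = pass1_hs + shared
    pass2_mm = pass1_mm + shared

    # private genes: no ortholog, no shared pool; pass1 == pass2
    mu_priv_hs = cfg.mean_depth / cfg.mixing_ratio * rel_phs
    mu_priv_mm = cfg.mean_depth * rel_pmm
    yp_hs = _nb_draw(rng, np.tile(mu_priv_hs[:, None], (1, n_samples)), cfg.nb_dispersion)
    yp_mm = _nb_draw(rng, np.tile(mu_priv_mm[:, None], (1, n_samples)), cfg.nb_dispersion)

    def _mk(pass1, pass2, genes):
        idx = pd.Index(genes, name="gene")
        return (
            pd.DataFrame(pass1, index=idx, columns=samples),
            pd.DataFrame(pass2, index=idx, columns=samples),
        )

    p1h, p2h = _mk(np.vstack([pass1_hs, yp_hs]), np.vstack([pass2_hs, yp_hs]), orth_hs + priv_hs)
    p1m, p2m = _mk(np.vstack([pass1_mm, yp_mm]), np.vstack([pass2_mm, yp_mm]), orth_mm + priv_mm)
    hs = PassCounts(species="human", pass1=p1h, pass2=p2h)
    mm = PassCounts(species="mouse", pass1=p1m, pass2=p2m)
    orth = pd.DataFrame({"human": orth_hs, "mouse": orth_mm})

    truth = GroundTruth(
        species_of_origin={**{g: "human" for g in orth_hs + priv_hs}, **{g: "mouse" for g in orth_mm + priv_mm}},
        mixing_ratio=cfg.mixing_ratio,
        immune_genes=[orth_hs[i] for i in immune_idx],
        intestine_genes=[orth_mm[i] for i in intestine_idx],
    )
    return hs, mm, orth, truth


def simulate_tissue_gene_sets(
    cfg: SimConfig, truth: GroundTruth, n_decoys: int = 8
) -> Tuple[TissueGeneSets, TissueGeneSets, GroundTruth]:
    """Miniature atlas stand-ins: one true tissue set per species + decoys.

    The human collection carries an immune-cell set containing the planted
    human-enriched markers; the mouse collection an intestine set with the
    mouse-enriched markers.  Decoy sets are random ortholog genes.
    """
    rng = stream(cfg.seed, "tissue_sets")
    orth_hs, orth_mm, _, _ = _gene_names(cfg)

    def _decoys(universe: List[str], size: int) -> Dict[str, List[str]]:
        out = {}
        for i in range(n_decoys):
            picked = rng.choice(len(universe), size=size, replace=False)
            out[f"decoy_tissue_{i + 1}"] = sorted(universe[j] for j in picked)
        return out

    size = max(5, len(truth.immune_genes))
    human_sets = {"immune_cells": sorted(truth.immune_genes), **_decoys(orth_hs, size)}
    mouse_sets = {"intestine": sorted(truth.intestine_genes), **_decoys(orth_mm, size)}
    labels = {"immune_cells": "immune", "intestine": "intestine"}
    labels.update({f"decoy_tissue_{i + 1}": "decoy" for i in range(n_decoys)})
    truth.tissue_labels = labels
    return (
        TissueGeneSets(name="Human_Gene_Atlas_synthetic", sets=human_sets),
        TissueGeneSets(name="Mouse_Gene_Atlas_synthetic", sets=mouse_sets),
        truth,
    )


def simulate_node_signatures_and_de(
    cfg: SimConfig,
) -> Tuple[NodeSignatureDB, pd.DataFrame, List[str], GroundTruth]:
    """Signature database + matched mouse count matrices with planted effects.

    Builds ``n_nodes`` signatures of ``genes_per_node`` signed genes drawn
    without replacement per node (overlap across nodes allowed); marks
    ``frac_active_nodes`` of them active with direction +/-1 and injects
    ``effect_size_lfc * activity * d_g`` into the true log2 fold change of
    each signature gene.  Returns ``(db, counts, groups, truth)`` where
    ``counts`` is a mouse genes x samples matrix ready for the DE stage.
    """
    rng = stream(cfg.seed, "signatures")
    _, orth_mm, _, priv_mm = _gene_names(cfg)
    genes = orth_mm + priv_mm
    if cfg.genes_per_node > len(genes):
        raise ValueError(
            f"genes_per_node={cfg.genes_per_node} exceeds the {len(genes)}-gene universe"
        )

    node_ids = [f"act(p(MGI:Node{i:03d}))" for i in range(cfg.n_nodes)]
    signatures: Dict[str, List[Tuple[str, int]]] = {}
    for nid in node_ids:
        idx = rng.choice(len(genes), size=cfg.genes_per_node, replace=False)
        dirs = rng.choice([1, -1], size=cfg.genes_per_node)
        signatures[nid] = [(genes[j], int(d)) for j, d in zip(idx, dirs)]
    db = NodeSignatureDB(signatures=signatures)

    n_active = int(round(cfg.frac_active_nodes * cfg.n_nodes))
    active_idx = rng.choice(cfg.n_nodes, size=n_active, replace=False)
    activity = {nid: 0 for nid in node_ids}
    for j in active_idx:
        activity[node_ids[j]] = int(rng.choice([1, -1]))

    # planted true lfc: sum of node contributions (consistent with d_g)
    true_lfc = {g: 0.0 for g in genes}
    for nid in node_ids:
        a = activity[nid]
        if a == 0:
            continue
        for g, d in signatures[nid]:
            true_lfc[g] += cfg.effect_size_lfc * a * d

    # count matrices: control mean mu_g, treatment mean mu_g * 2^lfc
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    mu_ctl = cfg.mean_depth * rel
    fold = np.array([2.0 ** np.clip(true_lfc[g], -8, 8) for g in genes])
    mu_trt = mu_ctl * fold
    n = cfg.n_samples_per_group
    counts_ctl = _nb_draw(rng, np.tile(mu_ctl[:, None], (1, n)), cfg.nb_dispersion)
    counts_trt = _nb_draw(rng, np.tile(mu_trt[:, None], (1, n)), cfg.nb_dispersion)
    samples = [f"ctl_{i + 1}" for i in range(n)] + [f"trt_{i + 1}" for i in range(n)]
    counts = pd.DataFrame(
        np.hstack([counts_ctl, counts_trt]), index=pd.Index(genes, name="gene"), columns=samples
    )
    groups = ["control"] * n + ["treatment"] * n

    truth = GroundTruth(
        mixing_ratio=cfg.mixing_ratio,
        node_activity=activity,
        true_lfc=true_lfc,
    )
    # invariant: every planted active node carries >=1 gene into the effect model
    for nid, a in activity.items():
        if a != 0:
            assert any(true_lfc[g] != 0 for g, _ in signatures[nid])
    return db, counts, groups, truth


def simulate_causal_graph(n_nodes: int, edge_density: float, seed: int) -> CausalGraph:
    """Random signed DAG with BEL-like labels under a fixed topological order.

    Each ordered pair (i < j) becomes an edge with probability
    ``edge_density`` and a uniform random sign.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must lie in (0, 1]")
    rng = stream(seed, "graph")
    labels = [f"act(p(MGI:Node{i:03d}))" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_density:
                sign = int(rng.choice([1, -1]))
                edges.append((labels[i], sign, labels[j]))
    return CausalGraph(edges=edges, nodes=labels)


def consistent_graph_from_truth(
    truth: GroundTruth, edge_density: float, seed: int
) -> CausalGraph:
    """A DAG over the planted nodes whose edge signs are causally consistent
    with the planted activities wherever both endpoints are active."""
    nodes = sorted(truth.node_activity)
    rng = stream(seed, "graph_truth")
    edges = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if rng.random() >= edge_density:
                continue
            du, dv = truth.node_activity[u], truth.node_activity[v]
            if du != 0 and dv != 0:
                sign = du * dv  # dir(u) * sign == dir(v) holds
            else:
                sign = int(rng.choice([1, -1]))
            edges.append((u, sign, v))
    return CausalGraph(edges=edges, nodes=nodes)
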