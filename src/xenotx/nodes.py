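"""Directional node-activity ("strength") inference.

A node is a molecular entity — a protein activity, a complex, a process —
whose own activity is not measured but whose downstream transcriptional
footprint is: a signature of mRNAs with an expected regulation direction
(+1 if the node's activation increases the transcript, -1 if it
decreases it).  The strength score of a node is the threshold-free signed
mean of the differential-expression statistics of its measured signature
genes::

    S = (1 / |G|) * sum_{g in G} d_g * t_g

Positive S infers node upregulation.  Significance comes from a
gene-label permutation null: the statistic vector is shuffled over the
measured-gene universe and every node rescored per shuffle, giving a
two-sided add-one permutation p, BH-adjusted across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import stream

__all__ = [
    "NodeSignatureDB",
    "strength_score",
    "permutation_null",
    "bh_adjust",
    "call_nodes",
    "NodeActivityModel",
    "NodeActivityResults",
]

MIN_GENES_DEFAULT = 3


@dataclass
class NodeSignatureDB:
    """Per node, the list of (gene symbol, expected direction in {+1, -1})."""

    signatures: Dict[str, List[Tuple[str, int]]]

    def __post_init__(self) -> None:
        for node, sig in self.signatures.items():
            genes = [g for g, _ in sig]
            if len(set(genes)) != len(genes):
                raise ValueError(f"node {node!r}: duplicate gene in signature")
            for g, d in sig:
                if d not in (1, -1):
                    raise ValueError(f"node {node!r}: direction must be +1/-1, got {d}")

    def __len__(self) -> int:
        return len(self.signatures)

    def nodes(self) -> List[str]:
        return list(self.signatures)


def strength_score(
    signature: Sequence[Tuple[str, int]],
    stats: pd.Series,
    min_genes: int = MIN_GENES_DEFAULT,
) -> Tuple[Optional[float], int]:
    """Signed-mean strength score of one signature against gene statistics.

    Unmeasured signature genes are dropped; returns ``(S, n_measured)``
    with ``S=None`` when fewer than ``min_genes`` genes are measured
    (insufficient signature).
    """
    measured = [(g, d) for g, d in signature if g in stats.index]
    if len(measured) < min_genes:
        return None, len(measured)
    s = float(np.mean([d * stats[g] for g, d in measured]))
    return s, len(measured)


def _signature_matrix(db: NodeSignatureDB, genes: pd.Index, min_genes: int):
    """Node x gene direction matrix scaled by 1/|G|, plus bookkeeping."""
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows, idx_lists, dir_lists, n_measured = [], [], [], []
    for node, sig in db.signatures.items():
        idx = [gene_pos[g] for g, _ in sig if g in gene_pos]
        dirs = [d for g, d in sig if g in gene_pos]
        rows.append(node)
        idx_lists.append(np.array(idx, dtype=np.intp))
        dir_lists.append(np.array(dirs, dtype=float))
        n_measured.append(len(idx))
    D = np.zeros((len(rows), len(genes)))
    usable = np.array([n >= min_genes for n in n_measured])
    for i, (idx, dirs) in enumerate(zip(idx_lists, dir_lists)):
        if usable[i]:
            D[i, idx] = dirs / len(idx)
    return rows, D, usable, np.array(n_measured)


def permutation_null(
    db: NodeSignatureDB,
    stats: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    min_genes: int = MIN_GENES_DEFAULT,
    chunk: int = 2_000,
) -> pd.DataFrame:
    """Gene-label permutation p-values for every node.

    One shared permutation stream scores all nodes per shuffle, so the
    null is consistent across nodes.  Two-sided add-one estimator:
    p = (1 + #{|S*| >= |S_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = stream(seed, "permutation")
    t = stats.to_numpy(dtype=float)
    nodes, D, usable, n_measured = _signature_matrix(db, stats.index, min_genes)
    s_obs = D @ t
    exceed = np.zeros(len(nodes))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.empty((len(t), b))
        for j in range(b):
            perms[:, j] = rng.permutation(t)
        s_null = D @ perms  # nodes x b
        exceed += (np.abs(s_null) >= np.abs(s_obs)[:, None] - 1e-12).sum(axis=1)
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "score": np.where(usable, s_obs, np.nan),
            "p": np.where(usable, p, np.nan),
            "n_genes": n_measured,
            "flag": np.where(usable, "", "insufficient_signature"),
        },
        index=pd.Index(nodes, name="node"),
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_nodes(
    db: NodeSignatureDB,
    stats: pd.Series,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    min_genes: int = MIN_GENES_DEFAULT,
) -> pd.DataFrame:
    """Score -> permutation p -> BH -> significance at adjusted p < alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if len(db) == 0:
        raise ValueError("empty signature database")
    table = permutation_null(db, stats, n_perm=n_perm, seed=seed, min_genes=min_genes)
    usable = table["flag"] == ""
    p_adj = np.full(len(table), np.nan)
    if usable.any():
        p_adj[usable.to_numpy()] = bh_adjust(table.loc[usable, "p"].to_numpy())
    table["p_adj"] = p_adj
    table["direction"] = np.sign(table["score"]).fillna(0).astype(int)
    table["significant"] = (table["p_adj"] < alpha).fillna(False)
    return table[["score", "direction", "p", "p_adj", "n_genes", "significant", "flag"]]


class NodeActivityModel:
    """Node-activity inference model over a DE statistic vector.

    Parameters
    ----------
    db
        Signed node-signature database.
    stats
        Per-gene signed DE statistic (e.g. ``DEResults.stats``).
    min_genes
        Minimum measured signature genes for a node to be scored.
    """

    def __init__(self, db: NodeSignatureDB, stats: pd.Series, min_genes: int = MIN_GENES_DEFAULT):
        if len(db) == 0:
            raise ValueError("empty signature database")
        self.db = db
        self.stats = stats
        self.min_genes = min_genes

    def fit(self, alpha: float = 0.05, n_perm: int = 10_000, seed: int = 0) -> "NodeActivityResults":
        table = call_nodes(
            self.db, self.stats, alpha=alpha, n_perm=n_perm, seed=seed, min_genes=self.min_genes
        )
        return NodeActivityResults(model=self, alpha=alpha, n_perm=n_perm, seed=seed, table=table)


@dataclass
class NodeActivityResults:
    """Per-node calls: score, direction, permutation p, BH-adjusted p."""

    model: NodeActivityModel
    alpha: float
    n_perm: int
    seed: int
    table: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def directions(self) -> Mapping[str, int]:
        """node -> inferred direction for significant nodes (for annotation)."""
        sig = self.significant
        return dict(zip(sig.index, sig["direction"].astype(int)))

    def summary(self, n: int = 15) -> pd.DataFrame:
        ordered = self.table.sort_values(["p_adj", "p"], kind="mergesort", na_position="last")
        return ordered.head(n)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<NodeActivityResults nodes={len(self.table)} "
            f"significant={int(self.table['significant'].sum())} alpha={self.alpha}>"
        )
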