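"""Species-provenance validation via log-ratio tails and over-representation.

If the disambiguation worked, the genes whose human counts dominate their
mouse ortholog should look like immune-cell genes (the engrafted human
compartment) and the mouse-dominated genes like intestinal genes.  The
check ranks ortholog pairs by the log10 ratio of mean human to mean mouse
actual counts, takes the top-k and bottom-k tails, and tests each tissue
gene set for over-representation in each tail with a one-sided
hypergeometric test, BH-adjusted within collection x tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .split import ResolvedCounts

logger = logging.getLogger(__name__)

__all__ = ["TissueGeneSets", "TailReport", "log_ratio", "tail_genes", "overrepresentation"]


@dataclass
class TissueGeneSets:
    """A named collection of tissue-specific gene sets (GMT-backed)."""

    name: str
    sets: Dict[str, List[str]]

    def __post_init__(self) -> None:
        for sname, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sname!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {sname!r} has duplicate genes")


@dataclass
class TailReport:
    """Log-ratio vector, the two tails, and per-set enrichment per tail."""

    log_ratio: pd.Series
    top: List[str]
    bottom: List[str]
    enrichment: pd.DataFrame  # columns: collection, tail, set, overlap, set_size, p, p_adj, flag

    def min_padj_set(self, collection: str, tail: str) -> str:
        sub = self.enrichment[
            (self.enrichment["collection"] == collection) & (self.enrichment["tail"] == tail)
        ]
        sub = sub.sort_values(["p_adj", "p", "set"], kind="mergesort")
        return str(sub.iloc[0]["set"])


def log_ratio(
    hs_actual: ResolvedCounts,
    mm_actual: ResolvedCounts,
    orth: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-ortholog-pair log10 of (mean human + c) / (mean mouse + c).

    Indexed by human gene symbol.  ``pseudocount`` must be positive.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    present = orth["human"].isin(hs_actual.genes) & orth["mouse"].isin(mm_actual.genes)
    orth = orth[present]
    if orth.empty:
        raise ValueError("no ortholog pairs present in both matrices")
    hs_mean = hs_actual.actual.loc[orth["human"]].mean(axis=1).to_numpy()
    mm_mean = mm_actual.actual.loc[orth["mouse"]].mean(axis=1).to_numpy()
    r = np.log10((hs_mean + pseudocount) / (mm_mean + pseudocount))
    return pd.Series(r, index=pd.Index(orth["human"], name="gene"))


def tail_genes(r: pd.Series, k: int) -> Tuple[List[str], List[str]]:
    """The k largest and k smallest genes by log ratio.

    Ties break by gene symbol so the tails are deterministic; if ``2k``
    exceeds the number of genes both tails truncate to ``floor(n/2)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(r)
    if 2 * k > n:
        k_eff = n // 2
        logger.warning("2k=%d exceeds %d genes; tails truncated to %d", 2 * k, n, k_eff)
        k = k_eff
    df = pd.DataFrame({"r": r.values, "gene": r.index})
    top = df.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")["gene"]
    bottom = df.sort_values(["r", "gene"], ascending=[True, True], kind="mergesort")["gene"]
    top_k = list(top.iloc[:k])
    bottom_k = [g for g in bottom if g not in set(top_k)][:k]
    return top_k, bottom_k


def overrepresentation(
    tail: Sequence[str],
    sets: TissueGeneSets,
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in a tail.

    p = P[X >= overlap] with X ~ Hypergeom(N=|universe|, K=|set in universe|,
    n=|tail|); BH adjustment across the collection's sets.  A set with no
    universe overlap gets p = 1 and a ``no_universe_overlap`` flag.
    """
    uni = set(universe)
    tail_set = set(tail)
    if not tail_set <= uni:
        raise ValueError("tail must be a subset of the universe")
    N, n = len(uni), len(tail_set)
    rows = []
    for sname in sets.sets:
        members = set(sets.sets[sname]) & uni
        K = len(members)
        obs = len(members & tail_set)
        if K == 0:
            p, flag = 1.0, "no_universe_overlap"
        else:
            p, flag = float(hypergeom.sf(obs - 1, N, K, n)), ""
        rows.append({"set": sname, "overlap": obs, "set_size": K, "p": p, "flag": flag})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1] if len(df) else []
    return df[["set", "overlap", "set_size", "p", "p_adj", "flag"]]


def validate_provenance(
    hs_actual: ResolvedCounts,
    mm_actual: ResolvedCounts,
    orth: pd.DataFrame,
    collections: Sequence[TissueGeneSets],
    k: int = 1000,
    pseudocount: float = 0.5,
) -> TailReport:
    """Full tail/over-representation report over one or more collections.

    The universe is every ortholog pair with nonzero total actual counts,
    identified by human symbol; mouse-collection sets are expected to be
    given on the same (human-symbol) key via the ortholog table upstream,
    or on mouse symbols which are translated here.
    """
    present = orth[orth["human"].isin(hs_actual.genes) & orth["mouse"].isin(mm_actual.genes)]
    totals = (
        hs_actual.actual.loc[present["human"]].sum(axis=1).to_numpy()
        + mm_actual.actual.loc[present["mouse"]].sum(axis=1).to_numpy()
    )
    keep = totals > 0
    universe = list(present["human"][keep])
    mm2hs = dict(zip(present["mouse"], present["human"]))

    r = log_ratio(hs_actual, mm_actual, present[keep], pseudocount=pseudocount)
    top, bottom = tail_genes(r, k)

    frames = []
    for coll in collections:
        # translate mouse symbols onto the human-symbol universe key
        translated = {
            sname: sorted({mm2hs.get(g, g) for g in genes})
            for sname, genes in coll.sets.items()
        }
        tcoll = TissueGeneSets(name=coll.name, sets=translated)
        for tail_name, tail in (("top", top), ("bottom", bottom)):
            df = overrepresentation(tail, tcoll, universe)
            df.insert(0, "collection", coll.name)
            df.insert(1, "tail", tail_name)
            frames.append(df)
    enrichment = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return TailReport(log_ratio=r, top=top, bottom=bottom, enrichment=enrichment)
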