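"""Two-pass ortholog read-count disambiguation.

Bulk RNA from a humanized-mouse colon mixes mouse transcripts with a trace
of human immune-cell transcripts.  Reads from conserved regions of an
ortholog pair map equally well to both genomes.  The two-pass counting
scheme quantifies each gene twice: pass 1 discards those "shared" reads,
pass 2 counts them in both orthologs.  For a human gene with specific
count ``n_hs1`` (pass 1), two-pass count ``n_hs2`` and mouse-ortholog
specific count ``n_mm1``, the shared reads are split by the estimated
human fraction::

    n_shared = n_hs2 - n_hs1
    alpha_hs = n_hs1 / (n_hs1 + n_mm1)
    n_hs_actual = n_hs1 + alpha_hs * n_shared

and symmetrically for the mouse gene with ``alpha_mm = 1 - alpha_hs``.

Degenerate cases are repaired, not propagated: a shared increment that
comes out negative is clamped to zero (flag ``clamped_shared``), and an
alpha with zero denominator falls back to the symmetric prior 0.5 (flag
``degenerate_alpha``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Tuple

import numpy as np
import pandas as pd

from .io import PathLike, read_count_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PassCounts",
    "ResolvedCounts",
    "split_shared_reads",
    "resolve_matrix",
    "read_pass_counts",
]

Species = Literal["human", "mouse"]


@dataclass
class PassCounts:
    """Pass-1 (shared discarded) and pass-2 (shared double-counted) matrices."""

    species: Species
    pass1: pd.DataFrame
    pass2: pd.DataFrame
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ValueError(f"species must be 'human' or 'mouse', got {self.species!r}")
        if not self.pass1.index.equals(self.pass2.index) or not self.pass1.columns.equals(self.pass2.columns):
            raise ValueError("pass1 and pass2 must share identical gene and sample ordering")
        # pass2 < pass1 is impossible under the two-pass definition; repair upward.
        bad = self.pass2.values < self.pass1.values
        if bad.any():
            self.n_clamped = int(bad.sum())
            logger.warning(
                "%s: %d cells had pass2 < pass1; shared reads clamped to 0", self.species, self.n_clamped
            )
            self.pass2 = pd.DataFrame(
                np.maximum(self.pass2.values, self.pass1.values),
                index=self.pass2.index,
                columns=self.pass2.columns,
            )

    @property
    def genes(self) -> pd.Index:
        return self.pass1.index

    @property
    def samples(self) -> pd.Index:
        return self.pass1.columns


@dataclass
class ResolvedCounts:
    """Disambiguated ("actual") counts with per-entry alphas and repair flags.

    ``alpha`` is NaN for private (non-ortholog) genes; ``flags`` marks
    ``degenerate_alpha`` and ``clamped_shared`` entries.
    """

    species: Species
    actual: pd.DataFrame
    alpha: pd.DataFrame
    flags: Dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.actual.index

    @property
    def samples(self) -> pd.Index:
        return self.actual.columns


def split_shared_reads(
    n_hs1: float, n_mm1: float, n_hs2: float
) -> Tuple[float, float, Dict[str, bool]]:
    """Split one gene/sample's shared reads by the estimated human fraction.

    Parameters are the pass-1 human count, pass-1 mouse-ortholog count and
    pass-2 human count.  Returns ``(alpha_hs, n_hs_actual, flags)``.
    """
    for name, v in (("n_hs1", n_hs1), ("n_mm1", n_mm1), ("n_hs2", n_hs2)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    flags = {"degenerate_alpha": False, "clamped_shared": False}
    shared = n_hs2 - n_hs1
    if shared < 0:
        shared = 0.0
        flags["clamped_shared"] = True
    denom = n_hs1 + n_mm1
    if denom == 0:
        alpha = 0.5
        if shared > 0:
            flags["degenerate_alpha"] = True
    else:
        alpha = n_hs1 / denom
    return float(alpha), float(n_hs1 + alpha * shared), flags


def _vector_split(p1_self, p2_self, p1_other):
    """Vectorized splitter over ortholog-pair blocks (genes x samples)."""
    shared = p2_self - p1_self
    clamped = shared < 0
    shared = np.where(clamped, 0.0, shared)
    denom = p1_self + p1_other
    degenerate = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(degenerate, 0.5, p1_self / np.where(degenerate, 1.0, denom))
    actual = p1_self + alpha * shared
    degenerate = degenerate & (shared > 0)
    return alpha, actual, clamped, degenerate


def resolve_matrix(
    hs: PassCounts,
    mm: PassCounts,
    orth: pd.DataFrame,
    rounding: Literal["none", "floor", "stochastic"] = "none",
    alpha_mode: Literal["per-sample", "pooled"] = "per-sample",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ResolvedCounts, ResolvedCounts]:
    """Disambiguate full count matrices for both species.

    Each ortholog pair's shared reads are split per sample (or from counts
    pooled across samples with ``alpha_mode="pooled"``); private genes pass
    through with ``actual = pass2`` and alpha undefined.  Gene order is
    preserved.  ``rounding`` optionally integerizes the fractional actual
    counts (``floor`` or ``stochastic``; the latter needs ``rng``).
    """
    if hs.species != "human" or mm.species != "mouse":
        raise ValueError("resolve_matrix expects (human PassCounts, mouse PassCounts)")
    if list(hs.samples) != list(mm.samples):
        raise ValueError(
            f"sample IDs differ between species: {list(hs.samples)} vs {list(mm.samples)}"
        )

    orth = orth.copy()
    orth["human"] = orth["human"].str.strip()
    orth["mouse"] = orth["mouse"].str.strip()
    for col in ("human", "mouse"):
        if orth[col].duplicated().any():
            raise ValueError("ortholog table is not one-to-one")

    present = orth["human"].isin(hs.genes) & orth["mouse"].isin(mm.genes)
    n_missing = int((~present).sum())
    if n_missing:
        logger.warning("%d ortholog pairs absent from a count matrix; skipped", n_missing)
    orth = orth[present]

    out = {}
    for this, other, self_col, other_col in (
        (hs, mm, "human", "mouse"),
        (mm, hs, "mouse", "human"),
    ):
        genes_self = orth[self_col].to_numpy()
        genes_other = orth[other_col].to_numpy()
        p1_self = this.pass1.loc[genes_self].to_numpy(dtype=float)
        p2_self = this.pass2.loc[genes_self].to_numpy(dtype=float)
        p1_other = other.pass1.loc[genes_other].to_numpy(dtype=float)

        if alpha_mode == "pooled":
            shared = np.maximum(p2_self - p1_self, 0.0)
            clamped = (p2_self - p1_self) < 0
            tot_self = p1_self.sum(axis=1, keepdims=True)
            tot_other = p1_other.sum(axis=1, keepdims=True)
            denom = tot_self + tot_other
            degenerate0 = denom == 0
            with np.errstate(invalid="ignore", divide="ignore"):
                alpha = np.where(degenerate0, 0.5, tot_self / np.where(degenerate0, 1.0, denom))
            alpha = np.broadcast_to(alpha, p1_self.shape).copy()
            actual = p1_self + alpha * shared
            degenerate = np.broadcast_to(degenerate0, p1_self.shape) & (shared > 0)
        elif alpha_mode == "per-sample":
            alpha, actual, clamped, degenerate = _vector_split(p1_self, p2_self, p1_other)
        else:
            raise ValueError(f"unknown alpha_mode {alpha_mode!r}")

        # assemble full matrices in original gene order; private genes pass through
        actual_full = this.pass2.astype(float).copy()
        alpha_full = pd.DataFrame(np.nan, index=this.genes, columns=this.samples)
        flag_clamped = pd.DataFrame(False, index=this.genes, columns=this.samples)
        flag_degen = pd.DataFrame(False, index=this.genes, columns=this.samples)
        actual_full.loc[genes_self] = actual
        alpha_full.loc[genes_self] = alpha
        flag_clamped.loc[genes_self] = clamped
        flag_degen.loc[genes_self] = degenerate

        vals = actual_full.to_numpy()
        if rounding == "floor":
            vals = np.floor(vals)
        elif rounding == "stochastic":
            if rng is None:
                raise ValueError("stochastic rounding requires an rng")
            frac = vals - np.floor(vals)
            vals = np.floor(vals) + (rng.random(vals.shape) < frac)
        elif rounding != "none":
            raise ValueError(f"unknown rounding mode {rounding!r}")
        actual_full = pd.DataFrame(vals, index=this.genes, columns=this.samples)

        out[this.species] = ResolvedCounts(
            species=this.species,
            actual=actual_full,
            alpha=alpha_full,
            flags={"clamped_shared": flag_clamped, "degenerate_alpha": flag_degen},
        )
    return out["human"], out["mouse"]


def read_pass_counts(path_pass1: PathLike, path_pass2: PathLike, species: Species) -> PassCounts:
    """Load and validate a species' two-pass matrices from TSV files."""
    p1 = read_count_matrix(path_pass1)
    p2 = read_count_matrix(path_pass2)
    if p1.shape != p2.shape:
        raise ValueError(f"dimension mismatch: pass1 {p1.shape} vs pass2 {p2.shape}")
    if list(p1.index) != list(p2.index) or list(p1.columns) != list(p2.columns):
        raise ValueError("pass1 and pass2 gene/sample labels differ")
    for name, df in (("pass1", p1), ("pass2", p2)):
        vals = df.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"{name}: raw pass counts must be integers")
    return PassCounts(species=species, pass1=p1, pass2=p2)
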