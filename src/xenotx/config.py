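"""Simulation configuration and ground-truth containers.

The simulator emulates the data regime of a humanized-mouse colitis
experiment: colon RNA is an unequal mixture of mouse (intestinal tissue)
and engrafted human (immune cell) transcripts, with mouse RNA roughly
500-fold more abundant, and the large majority of detected genes being
human-mouse ortholog pairs whose conserved regions produce reads that map
equally well to either species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

__all__ = ["SimConfig", "GroundTruth"]


@dataclass
class SimConfig:
    """Parameters of the synthetic dual-species experiment.

    Parameters
    ----------
    n_genes_orth
        Number of human-mouse ortholog pairs.
    n_genes_private_hs, n_genes_private_mm
        Species-private genes (no ortholog, hence no shared reads).
    n_samples_per_group
        Samples per treatment arm (two arms: treatment vs control).
    mixing_ratio
        Expected mouse:human total-RNA abundance.  Default 500, the
        regime of a humanized-mouse colon where human immune-cell RNA is
        a trace component of bulk intestinal RNA.
    shared_fraction
        Expected fraction of an ortholog pair's reads that map equally
        well to both species (conserved exonic sequence).
    mean_depth
        Expected reads per mouse gene (the abundant species).
    nb_dispersion
        Negative-binomial dispersion phi; variance = mu + phi * mu**2.
    n_nodes, genes_per_node, frac_active_nodes, effect_size_lfc
        Node-signature database shape and the planted perturbation:
        ``frac_active_nodes`` of the nodes are active with direction +/-1
        and inject ``effect_size_lfc`` (log2 units, signed per gene by its
        expected regulation direction) into their signature genes.
    frac_tissue_genes
        Fraction of ortholog pairs planted as tissue markers: half
        immune-specific (human-enriched), half intestine-specific
        (mouse-enriched), used by provenance validation.
    tissue_boost
        Multiplicative expression boost of a tissue-marker gene in its
        own species.
    seed
        Master seed; all stage streams derive from it.
    """

    n_genes_orth: int = 1800
    n_genes_private_hs: int = 100
    n_genes_private_mm: int = 100
    n_samples_per_group: int = 10
    mixing_ratio: float = 500.0
    shared_fraction: float = 0.2
    mean_depth: float = 200.0
    nb_dispersion: float = 0.1
    n_nodes: int = 200
    genes_per_node: int = 20
    frac_active_nodes: float = 0.2
    effect_size_lfc: float = 2.0
    frac_tissue_genes: float = 0.1
    tissue_boost: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes_orth",
            "n_genes_private_hs",
            "n_genes_private_mm",
            "n_samples_per_group",
            "n_nodes",
            "genes_per_node",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_genes_orth <= 0:
            raise ValueError("n_genes_orth must be positive")
        if self.n_samples_per_group <= 0:
            raise ValueError("n_samples_per_group must be positive")
        if self.mixing_ratio <= 0:
            raise ValueError("mixing_ratio must be positive")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if not 0.0 <= self.frac_active_nodes <= 1.0:
            raise ValueError("frac_active_nodes must lie in [0, 1]")
        if not 0.0 <= self.frac_tissue_genes <= 1.0:
            raise ValueError("frac_tissue_genes must lie in [0, 1]")

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "SimConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery-based testing.

    Attributes
    ----------
    species_of_origin
        gene symbol -> "human" | "mouse" (ortholog pairs are recorded
        under both symbols).
    mixing_ratio
        The true mouse:human abundance ratio used.
    tissue_labels
        gene-set name -> tissue identity ("immune" | "intestine" | "decoy").
    node_activity
        node id -> -1 | 0 | +1 planted activity.
    true_lfc
        gene symbol -> planted log2 fold change (treatment vs control).
    """

    species_of_origin: Dict[str, str] = field(default_factory=dict)
    mixing_ratio: float = 0.0
    tissue_labels: Dict[str, str] = field(default_factory=dict)
    node_activity: Dict[str, int] = field(default_factory=dict)
    true_lfc: Dict[str, float] = field(default_factory=dict)
    immune_genes: List[str] = field(default_factory=list)
    intestine_genes: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "GroundTruth":
        return cls(**d)
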