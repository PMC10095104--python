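# xenotx

Dual-species RNA-seq disambiguation and causal-network node-activity
inference for xenograft / humanized-mouse transcriptomics.

Bulk RNA from a tissue that mixes two species — e.g. the colon of a
mouse with an engrafted human immune system, where mouse RNA outweighs
human RNA ~500:1 — produces reads that map equally well to both members
of a human–mouse ortholog pair. `xenotx` implements the full inference
chain from two-pass counts to a filtered causal network:

1. **Splitting** (`xenotx.split`): each gene is counted twice — pass 1
   discards reads shared between orthologs, pass 2 counts them in both.
   The shared reads `n_shared = n_hs,2 − n_hs,1` are apportioned by the
   species fraction estimated from the specific counts,

       alpha_hs = n_hs,1 / (n_hs,1 + n_mm,1),
       n_hs,actual = n_hs,1 + alpha_hs · n_shared,

   and symmetrically for the mouse ortholog.
2. **Provenance validation** (`xenotx.provenance`): the tails of the
   per-pair `log10(mean_hs / mean_mm)` distribution are tested for
   tissue gene-set over-representation (one-sided hypergeometric, BH
   adjusted) — human-dominated genes should look immune, mouse-dominated
   genes intestinal.
3. **Differential expression** (`xenotx.diffexp`): TMM normalization and
   a common-dispersion negative-binomial likelihood-ratio test, built to
   accept the splitter's fractional counts.
4. **Node inference** (`xenotx.nodes`): for a node with signed mRNA
   signature {(g, d_g)}, the threshold-free strength score
   `S = (1/|G|) Σ d_g t_g` over the signed DE statistics, with a
   gene-label permutation null and BH adjustment across nodes.
5. **Causal network** (`xenotx.network`): significant node directions
   are stamped onto a signed graph of BEL-like labels; an edge
   `u →(s) v` is causally consistent iff `dir(u) · s = dir(v)`, and
   inconsistent edges are removed before subgraph extraction.

A synthetic-data module (`xenotx.simulate`) generates every input with
known ground truth — species mixing, tissue identities, planted active
nodes, causal graphs — so each stage has a recovery-based test surface.

## Worked example

```python
from xenotx import (SimConfig, simulate_two_pass_counts, resolve_matrix,
                    simulate_node_signatures_and_de, NegativeBinomialDE,
                    NodeActivityModel)

cfg = SimConfig(n_genes_orth=1000, n_genes_private_hs=50,
                n_genes_private_mm=50, n_samples_per_group=5, seed=1)
hs, mm, orth, truth = simulate_two_pass_counts(cfg)
r_hs, r_mm = resolve_matrix(hs, mm, orth)
print(r_mm.actual.values.sum() / r_hs.actual.values.sum())
# 461.6692124808555   <- recovered mouse:human abundance (planted: 500)

db, counts, groups, node_truth = simulate_node_signatures_and_de(
    SimConfig(n_nodes=200, frac_active_nodes=0.2, effect_size_lfc=2.0,
              n_samples_per_group=5, seed=1))
res = NegativeBinomialDE(counts, groups, contrast=("treatment", "control")).fit()
print(res)
# <DEResults contrast='treatment vs control' genes=1900 dispersion=0.1021 p<0.05: 671>

calls = NodeActivityModel(db, res.stats).fit(n_perm=10_000, seed=1)
print(calls)
# <NodeActivityResults nodes=200 significant=45 alpha=0.05>
```

The first number is the mouse:human abundance ratio re-estimated from
the disambiguated matrices — within 8% of the planted 500:1 mixing. The
DE fit recovers the simulation's dispersion (0.1) and flags the genes
perturbed by the 40 planted active nodes; the node model then calls 45
nodes significant at adjusted p < 0.05, and their inferred directions
are checked against the planted up/down labels in the test suite.

The same chain is scriptable end to end (`simulate → split → validate →
de → infer → map`):

```bash
xenotx simulate --out sim --seed 1
xenotx split --hs-pass1 sim/hs_pass1.tsv --hs-pass2 sim/hs_pass2.tsv \
             --mm-pass1 sim/mm_pass1.tsv --mm-pass2 sim/mm_pass2.tsv \
             --orthologs sim/orthologs.tsv --out split
xenotx de --counts sim/de_counts.tsv --samples sim/samples.tsv \
          --contrast treatment:control --out de.tsv
xenotx infer --stats de.tsv --signatures sim/signatures.gmt \
             --seed 1 --out nodes.tsv
xenotx map --graph sim/graph.sif --calls nodes.tsv --radius 2 --out net
```

All file formats are plain text (TSV matrices, GMT and a signed-GMT
dialect, SIF-like graphs, JSON reports); outputs under one seed are
byte-identical across runs.

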