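# Methods

`xenotx` implements the transcriptomic inference chain for dual-species
(xenograft / humanized-mouse) bulk RNA-seq: disambiguation of read counts
between human and mouse orthologs, validation of species provenance,
differential expression, directional node-activity inference against
signed gene signatures, and causal-consistency filtering of a signed
biological network. This note records the models, the assumptions behind
them, and the design choices made where the design was genuinely open.

## 1. Two-pass ortholog read splitting (`xenotx.split`)

**Setting.** Colon tissue from a mouse with an engrafted human immune
system yields mixed RNA: mouse transcripts from intestinal tissue, human
transcripts from immune cells, at roughly 500:1 mouse:human abundance.
Reads from conserved regions of an ortholog pair align equally well to
both reference transcriptomes. Counting is done twice: **pass 1**
discards those shared reads (species-specific counts `n_hs,1`, `n_mm,1`),
**pass 2** counts them in *both* orthologs (`n_hs,2`, `n_mm,2`).

**Model.** The shared reads `n_shared = n_hs,2 − n_hs,1` are apportioned
by the species fraction estimated from the specific counts:

    alpha_hs   = n_hs,1 / (n_hs,1 + n_mm,1)
    n_hs,actual = n_hs,1 + alpha_hs * n_shared

and symmetrically for the mouse gene with `alpha_mm = 1 − alpha_hs` and
`n_mm,shared = n_mm,2 − n_mm,1`. When both shared increments are equal
(the generative model guarantees this; real two-pass counting should
too), the decomposition conserves reads exactly:
`actual_hs + actual_mm = n_hs,1 + n_mm,1 + shared`.

**Numerical/degenerate choices.**

- `alpha` is computed **per gene, per sample** by default. The formulas
  carry no sample index, so per-sample is the finest-grained reading and
  avoids cross-sample leakage; a `pooled` mode (alphas from counts summed
  over samples) is available for low-depth data.
- Zero denominator (`n_hs,1 = n_mm,1 = 0` with shared reads present):
  `alpha = 0.5` with a `degenerate_alpha` flag. A symmetric prior avoids
  species bias; the flag preserves auditability.
- `pass2 < pass1` is impossible under the definition of the two passes;
  such cells are treated as upstream artifacts — the shared increment is
  clamped to 0 with a `clamped_shared` flag (at file load, the pass-2
  cell is raised to the pass-1 value and the repair counted).
- Actual counts are kept as **reals** (the formula yields fractional
  values); rounding (`floor` | `stochastic`) is opt-in. The DE stage is
  built to accept fractional counts.
- Gene symbols are matched case-sensitively after whitespace trimming;
  the HGNC (upper-case) vs MGI (capitalized) convention is preserved and
  the one-to-one ortholog table is the single source of cross-species
  identity. Many-to-many homology relations must be resolved before
  input; tables with duplicated symbols are rejected.

## 2. Species-provenance validation (`xenotx.provenance`)

For each ortholog pair, `r_g = log10((mean_hs + c) / (mean_mm + c))`
with pseudocount `c = 0.5` (means over samples of the resolved counts).
The top-k and bottom-k genes by `r_g` (default k = 1000; ties broken
lexicographically so the tails are deterministic and disjoint) are tested
for over-representation of tissue gene sets: if the disambiguation
worked, the human-dominated tail is enriched for immune-cell genes and
the mouse-dominated tail for intestinal genes.

The over-representation statistic is the one-sided hypergeometric upper
tail, `p = P[X ≥ overlap]` with `X ~ Hypergeom(N = |universe|,
K = |set ∩ universe|, n = |tail|)` — the standard, closed-form,
enumeration-testable choice. The universe is every ortholog pair with
nonzero total resolved counts. Benjamini–Hochberg adjustment is applied
within each collection × tail. Sets with zero universe overlap get
`p = 1` and a flag. Both tail orientations are always reported, so the
human/mouse vs mouse/human ratio convention is moot.

## 3. Differential expression (`xenotx.diffexp`)

A deliberately small two-group count pipeline:

- **Normalization.** Library size plus trimmed mean of M-values (TMM):
  reference sample = the one whose 75th-percentile scaled count is
  closest to the mean of those percentiles; M-values doubly trimmed (30%
  on M, 5% on A, rank-based, two-sided) and averaged with inverse
  delta-method variance weights; factors renormalized to geometric
  mean 1.
- **Dispersion.** One common negative-binomial dispersion φ (variance
  μ + φμ²), estimated by pooled method of moments on counts scaled to a
  common effective library size: `φ = Σ(v − m) / Σ m²` over genes and
  groups, clamped at 0. No tagwise or trended shrinkage — the statistic
  feeds a rank/permutation-based node scorer, which needs a signed,
  roughly calibrated gene ranking rather than exact per-gene inference.
- **Test.** Per-gene likelihood-ratio test of equal group means. Group
  relative abundances are fitted by Newton iteration on the NB score
  equation `Σ_j (y_j − μ_j)/(1 + φ μ_j) = 0` with `μ_j = L_j q`
  (`L_j` = effective library size), and `2ΔlogL` is referred to
  chi-square(1). The LR test handles the splitter's fractional counts,
  which exact integer tests would not. Signed statistic
  `t_g = sign(lfc) · sqrt(LR)`; `lfc` is log2 of group mean normalized
  counts with pseudocount 0.5. All-zero genes get `(lfc 0, p 1)` and a
  flag. Positive `lfc` = higher in treatment (e.g. "nicotine+DSS vs
  DSS"-style contrasts).

Calibration is verified by simulation in the test suite: under a 2000
gene null at n = 10 per group the empirical type-I error at α = 0.05
falls in [0.03, 0.07] and the p-values pass a KS uniformity check.
Numerical equality with any particular published RNA-seq tool is a
non-goal.

## 4. Node-activity inference (`xenotx.nodes`)

A *node* is a molecular entity (protein activity, complex, process)
whose transcriptional footprint is a signature of mRNAs with expected
regulation directions `d_g ∈ {+1, −1}`. The **strength score** is the
threshold-free signed mean over measured signature genes:

    S = (1/|G|) Σ_{g∈G} d_g t_g

with `t_g` the signed DE statistic; `S > 0` infers upregulation. This
signed-mean statistic is this package's canonical definition (the
simplest threshold-free directional enrichment statistic consistent with
the approach it follows); the scorer is a small pluggable surface should
alternatives be wanted. Nodes with fewer than 3 measured signature genes
are skipped with an `insufficient_signature` flag.

**Null.** Gene-label permutation: the statistic vector is shuffled over
the measured-gene universe and *all* nodes are rescored per shuffle (one
shared stream, so the null is consistent across nodes). Two-sided
add-one estimator `p = (1 + #{|S*| ≥ |S_obs|}) / (n_perm + 1)`, default
`n_perm = 10000`, minimum attainable p = 1/(n_perm+1). A gene-label
(rather than sample) permutation is used because the scorer sees only a
single DE table. BH adjustment across nodes; significance at adjusted
p < 0.05; direction is reported separately from the two-sided p, so up-
and down-regulated nodes come out of one analysis.

## 5. Causal network filtering (`xenotx.network`)

Nodes carry BEL-like labels (`act(p(MGI:Tlr2))`,
`bp(PMIBP:wound healing)`); a minimal parser extracts (outer function,
namespace, entity) and flags unknown functions as pass-through — full
BEL parsing is out of scope. Edges are signed: `increases` (+1) /
`decreases` (−1); `directlyIncreases`-style synonyms normalize onto
these two. Self-loops are rejected; opposite-sign parallel edges are
kept but recorded.

Significant node calls stamp directions onto graph labels (exact string
match after whitespace canonicalization; an explicit call→label mapping
may be supplied, and one call resolving to two labels is an error). Edge
`u →(s) v` between two measured nodes is **consistent** iff
`dir(u) · s = dir(v)`; inconsistent edges are removed and logged. Edges
touching unmeasured nodes keep status *undetermined* and are retained —
removing them would silently disconnect reported paths. The filter is
idempotent by construction. Subgraph extraction takes all nodes within
undirected BFS distance ≤ radius of the anchors, with induced
consistent/undetermined edges, in deterministic order. Graphs merged
from several sub-models are merged by label identity.

## 6. Synthetic data (`xenotx.simulate`)

The generator works at the count level — no read-level FASTQ simulation
or alignment — because that is the level the splitting formulas operate
on.

**Two-pass counts.** Per ortholog pair, a lognormal(0, 1) relative
expression level scales a mouse mean of `mean_depth` and a human mean of
`mean_depth / mixing_ratio`; counts are negative binomial via a
gamma-Poisson mixture (variance μ + φμ²; a single common φ, matching the
DE model). A binomial `shared_fraction` of each species' reads moves
into a common pool S; pass 1 keeps the species-specific remainders and
pass 2 adds S identically to both orthologs. This identical-pool model
is the minimal one under which the bookkeeping identity
`pass2 − pass1 = S` holds exactly for both species; the variance model
of real shared-read counts is unknown, and this assumption is flagged as
such. Private genes get no shared pool. A fraction of ortholog pairs are
planted as tissue markers — immune markers boosted `tissue_boost`-fold
on the human side, intestine markers on the mouse side — and miniature
atlas stand-ins (one true set per species plus random decoy sets,
labelled synthetic in their names) are emitted for the provenance stage.

**Signatures and DE effects.** `n_nodes` signatures of `genes_per_node`
signed genes each (drawn without replacement per node, overlap across
nodes allowed); `frac_active_nodes` are active with direction ±1, and
each active node adds `effect_size_lfc × activity × d_g` to its
signature genes' true log2 fold changes (so injected effects always
agree with the expected direction). Matched control/treatment count
matrices are emitted so the DE stage runs end-to-end.

**Causal graphs.** Random DAGs under a fixed topological order with
uniform random edge signs; a truth-consistent variant assigns
`sign = dir(u)·dir(v)` between active nodes so planted annotations
survive the consistency filter, exercising the recovery path.

**Defaults as study conditions.** `mixing_ratio = 500` (the ~1:500
human:mouse abundance regime), 1800 ortholog pairs + 100 private genes
per species (>90% of detected genes orthologous),
`n_samples_per_group = 10` (the per-arm cohort size of the acute phase),
`shared_fraction = 0.2`, `mean_depth = 200` reads/gene,
`nb_dispersion = 0.1`, 200 nodes × 20 genes, 20% active at
`effect_size_lfc = 2`. Depth, dispersion, signature size and shared
fraction are desk-scale realism choices for bulk RNA-seq where no
external value exists. Tests and the acceptance script scale gene and
sample counts down (stated per run in their code) while keeping these
ratios.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: alignment and mapping-quality artifacts
(shared reads here are symmetric and exactly double-counted; real
multi-mappers are not), GC/length biases, sample-level batch effects,
tag-wise dispersion heterogeneity, correlated genes within biological
pathways (signature genes are drawn independently), and many-to-many
homology. Recovery results bound what the method can do under its own
assumptions, not its field performance.

**Randomness.** All stages draw from named child streams
(`counts`, `tissue_sets`, `signatures`, `graph`, `permutation`) of one
master seed via `SeedSequence` spawn keys, so any stage can be
regenerated independently and every output is byte-reproducible.

## 7. Known limitations

- The common-dispersion LR test is mildly liberal at very small counts;
  the calibration checks run at depth ≥ 100.
- Pooled-alpha mode shares one alpha across samples and can bias
  per-sample actual counts when the mixing fraction varies by sample.
- The permutation null treats genes as exchangeable; correlated DE
  statistics (co-regulated genes) would make it anti-conservative.
- BEL labels are compared as canonicalized strings; semantically equal
  but textually different labels do not merge.
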