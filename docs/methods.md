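# Methods

This note documents the statistical and algorithmic choices behind
omicsforest: what each stage computes, the parameters that matter, what
the synthetic generator does and does not emulate, and the numerical
conventions.

## Quantification

**Gene-level TPM.** Transcript-level TPM is summed per gene through a
transcript→gene map; per-sample totals are conserved exactly. No length
re-normalization is applied — TPM is already length-corrected.

**NSAF.** Spectral counts are converted to normalized spectral abundance
factors: NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j) with L the protein length
in amino acids, so every sample sums to 1 (enforced to 1e-12). Proteins
detected in only one condition are retained with zeros in the other; the
downstream pseudocount keeps their fold changes finite, preserving
presence/absence signal. For fold-change computation the pipeline rescales
NSAF to parts-per-million so that the count-scale pseudocount of 1 is
proportionally small; without that rescaling a pseudocount of 1 would
crush fold changes computed on values that sum to 1 per sample.

## Differential abundance

log2FC = mean_KO log2(x + pc) − mean_WT log2(x + pc), pseudocount pc = 1
on all layers. The test is Welch's unequal-variance t on the same log2
scale with Welch–Satterthwaite degrees of freedom; BH step-up FDR within
each layer; significance = (FDR < α, strict) AND |log2FC| ≥ 1, with
α = 0.05. Degenerate zero-variance features follow a fixed convention:
p = 1 when the group means agree, p = 0 when they differ.

This test is a deliberately simple surrogate for a negative-binomial count
model. At three replicates per condition it has little power after
multiple-testing correction — an expected property, visible in the worked
example (single-digit significant calls despite 45 truly perturbed
features). The network stage is therefore driven by effect sizes rather
than significance calls (below), and externally computed differential
tables (e.g. from a dedicated count-model tool) can be imported anywhere a
statistics table is consumed, via the documented six-column TSV.

## Enrichment

**Preranked GSEA.** Features are ranked by log2FC (ties broken by id).
The enrichment score is the classical weighted running sum: at member
positions the sum gains |score|^q normalized over the members (default
q = 1), elsewhere it loses 1/(N − N_hits); ES is the extremum of largest
magnitude, signed, and the leading edge is the members at or before
(positive ES) / at or after (negative ES) the extremum. The null permutes
member positions with scores fixed; one shared null is drawn per set size.
The p-value is one-sided conditional on the sign of the observed ES:
p = (1 + #{same-sign null ES at least as extreme}) / (1 + #{same-sign
null ES}). Conditioning on sign keeps null p-values uniform — a two-sided
count against the full null would double the tail mass and make the test
anticonservative, which the calibration test (fraction of null p < 0.05
within [0.035, 0.065] at 1000 permutations) would catch. NES divides ES
by the mean |same-sign null ES|; FDR is BH across the tested sets. Set
size bounds default to [5, 500].

**Metabolite ORA.** Hypergeometric upper tail P(X ≥ overlap) of the
overlap between differential metabolites and each pathway, restricted to
measured metabolites as the universe; BH across pathways.

**Pathway clustering.** Enriched pathways become nodes of a similarity
graph with an edge when the Jaccard index of their significant members
reaches 0.5 (configurable); connected components of size ≥ 2 are clusters,
singletons stay unassigned. This reproduces the *shape* of
grouped-enrichment reports, not any proprietary grouping rule.

## Global network and prizes

Networks merge by node/edge union; a duplicate edge keeps the maximum
confidence; an id carrying different molecule types in the two inputs is
an error, because silent coercion would corrupt every downstream stage.
Costs are c(e) = 1 − confidence. Prizes: a node measured in ≥ 1 layer
receives max over layers of |log2FC|; unmeasured nodes receive 0.

Two prize filters exist. `significant_only` restricts prizes to features
with a positive significance call — principled, but at 3 + 3 replicates
the FDR gate removes nearly everything and the forest collapses. The
pipeline therefore defaults to an **effect-size floor**: prizes below
`prize_floor` = 1.0 (the same threshold as the significance fold-change
cut) are zeroed. Without any floor, estimation noise gives *every*
background node a prize of ~0.3–0.5, which exceeds typical edge costs
(mean 0.25), and the optimal forest then legitimately swallows most of a
well-connected network — a property of the objective, not a solver
defect. Two further contributors to background |log2FC| at desk scale are
worth knowing about: count noise at three replicates, and the TPM
composition shift (a strongly perturbed module moves per-sample totals,
offsetting all fold changes; the same phenomenon that motivates
median-of-ratios normalization in count models).

The hub penalty p'(v) = max(0, p(v) − μ·deg(v)), μ = 0.01, discourages
selection of high-degree nodes whose measured change may reflect their
connectivity rather than specific involvement. Clamping at zero keeps the
exclusion term unambiguous: a negative prize would reward dropping hubs
twice.

## PCSF solver

Minimize β·Σ_{v∉F} p'(v) + Σ_{e∈F} c(e) + ω·κ over forests F. Defaults
β = 1, ω = 2, μ = 0.01. On the synthetic conditions the solution is
insensitive to ω within [0.75, 2] (short cheap bridges always make
merging two trees cheaper than opening a second one), so ω mostly matters
on sparser, more expensive graphs.

The heuristic: (1) attach a virtual root to every positive-prize node
with an ω-cost edge; (2) grow Goemans–Williamson moats — every cluster
with remaining potential grows uniformly, edges become tight and merge
clusters, clusters die when their potential (β-scaled prize sum) is
exhausted; (3) keep the root's component and strong-prune it (exact
subtree DP: a child subtree is kept iff its net worth exceeds its
connecting edge; root children must beat ω); (4) polish to a fixed point
with deterministic moves: add a node via its cheapest edge or as a new
tree, remove any node (splitting its tree), add a two-hop pair, merge two
trees through an edge cheaper than ω, re-span the selected node set with
its optimal forest (cost-sorted Kruskal restricted to edges cheaper than
ω — exact for a fixed node set), and refit every tree to its best
connected subtree (rerooting DP, linear per tree). On instances ≤ 250
nodes an additional escape move removes one node — or a pair of nodes on
instances ≤ 60 — and re-spans, which eliminates optima where a low-prize
connector forces a costly topology. A second candidate solution built
from the minimum spanning tree of the rooted graph is polished the same
way and the better of the two is returned.

All iteration orders are sorted, so the solver is deterministic; the
config seed exists only for optional randomized tie-breaking, which is
off. On 2,400 random instances with ≤ 10 nodes the polished heuristic
matched the exhaustive optimum in 99.9% of cases with a worst observed
excess of 0.4%.

`brute_force_pcsf` enumerates all node subsets (≤ 15 nodes) and completes
each subset with the exact optimal spanning forest under reduced costs
c(e) − ω; it is the test oracle and is never called by the solver.

## Subnetworks

Community detection runs on the **induced solution graph** — all global
network edges among selected nodes — not on the forest edges alone: the
forest is a connectivity certificate, while the induced graph carries the
topology that community structure should reflect (solution graphs
routinely have several times more edges than nodes). The algorithm is
greedy modularity agglomeration (Clauset–Newman–Moore) on sorted node and
edge lists, making the partition deterministic for a given graph; seeded
Louvain is available behind a flag. The pipeline uses modularity
resolution 0.5 (the package-level default of `detect_communities` remains
1.0): on hundred-node solution graphs default-resolution agglomeration
yields many ~10-node fragments, too small for over-representation tests
to have power against a 500-gene universe, whereas γ = 0.5 produces
pathway-sized communities of a few dozen nodes.

Prize density D(S) = Σ_{v∈S} p(v) / (|S|/N) with N the global network
size; with uniform prizes p it equals p·N for every subnetwork, so the
statistic is scale-free in subnetwork size and rewards concentration of
prize, not bulk. Each subnetwork's gene nodes are ORA-tested against the
gene universe **of the global network** (not the genome): the question is
whether the forest concentrated known pathways relative to what it could
have selected. BH runs within each subnetwork; the best pathway FDR is
the filter statistic (the cutoff 0.05, strict) and surviving subnetworks
are ranked by density, ties by prize sum then id.

## Synthetic data generator

The generator emulates the *structure* of a knockout multi-omics study:

* **Network** — preferential attachment from a seed path of `attach_m`
  nodes (gene edge count (n−m)·m + m − 1, connected by construction);
  metabolites attach to 1–3 uniform genes; confidences U(0.5, 1).
* **Planted truth** — k disjoint connected modules grown by BFS that
  visits lowest-degree neighbors first, placing modules in the network
  periphery; id-ordered expansion would pull every module into the
  high-degree core, making them topologically indistinct, which is not
  what a perturbed pathway looks like. Module nodes draw
  log2FC = ±N(signal_mean, signal_sd) with one sign per module
  (signal_sd = 0.4, a realistic within-pathway spread); background nodes
  draw N(0, noise_sd).
* **Layers** — transcript counts NegBin(mean = base·2^(lfc·KO),
  dispersion 0.1; base LogNormal(5, 1.5), 1–3 isoforms per gene) scaled
  to TPM; protein spectral counts Poisson for a random 40% of genes
  (mirroring real proteome coverage being far below the transcriptome);
  metabolite intensities LogNormal with σ = 0.3 for every metabolite
  node. 3 + 3 replicates by default. Everything is a pure function of the
  seed.

What it does **not** emulate: library-size and batch effects, count
overdispersion heterogeneity, shared-peptide protein inference, missing
values not-at-random, metabolite identification ambiguity, and any
correlation between network degree and expression level. Passing the
recovery benchmark therefore demonstrates that the pipeline's stages
compose correctly and that the ranking finds planted signal at realistic
noise — not that the defaults are tuned for any particular real platform.

Each planted module doubles as a "true" pathway in the generated GMT
(metabolite members included), alongside size-matched random decoy sets,
so enrichment stages can be scored against truth.

## End-to-end benchmark

`omicsforest.benchmark.planted_recovery` runs the whole pipeline in
memory at the default study conditions (500 genes, 50 metabolites, three
15-node modules, signal_mean 2, noise_sd 0.3, 3 + 3 replicates) and
scores the fraction of planted nodes inside the top-3 ranked subnetworks.
Mean recall over ten seeds is ~0.8, falling to ~0.7 at signal_mean 1.2
and ~0.2 at 0.5 — the degradation curve is the point: recovery tracks
effect size, and half-unit fold changes are simply not recoverable at
three replicates.

## Numerical conventions

* Strict inequalities at decision boundaries: FDR < α, best-pathway
  FDR < cutoff, child kept iff worth > edge cost.
* Ties: feature ranking by id; subnetwork ranking by prize sum then id;
  brute-force optimum by fewer nodes then lexicographic ids.
* Floating-point comparisons inside the solver use an absolute epsilon of
  1e-12; objective round-trip is validated to 1e-9.
* All TSV output uses fixed float formatting; identical config + seed
  reproduce byte-identical outputs (asserted in the test suite).
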