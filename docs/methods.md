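# Methods

## Scope and model

The package implements a three-stage workflow for detecting
chemical-induced metabolic changes from transcriptomics integrated into a
genome-scale metabolic network (GSMN): (1) partial enumeration of
transcriptome-consistent condition-specific models, (2) differential
reaction-activity statistics between conditions, (3) graph-based
clustering and subnetwork extraction. The stages are independent: any
solutions × reactions binary matrix can enter stage 2, and any DAR list
can enter stage 3.

## Model preparation

Differentiated, non-proliferating cells (such as primary human
hepatocytes) do not replicate DNA, so the biomass reaction is rewritten
into a maintenance reaction: DNA-precursor coefficients are zeroed and
the remaining substrate coefficients are multiplied by S/S′ (S = total
absolute substrate mass before zeroing, S′ after), preserving the
"one unit of biomass" normalization. The rule is a configurable hook
(`prepare_maintenance_biomass(..., correction=...)`) so an alternative
renormalization can be substituted. The rewritten reaction's lower bound
is forced to 1 flux unit so every feasible state pays the maintenance
cost. Exchange reactions are left unconstrained.

## Expression integration

Percentile cutoffs (default 25/75) are computed per sample with numpy's
linear-interpolation percentile; comparisons are strict (`< P25`,
`> P75`), so genes tied exactly at a threshold remain neutral — the
conservative reading of "below"/"above". GPR evaluation is min over AND,
max over OR, with genes absent from the categorization (and empty GPRs)
counting 0. The evaluation is monotone in the leaf values, which the
property tests exploit.

## Consensus MILP and enumeration

Every reaction gets explicit activity indicators: a forward binary (plus
a backward binary when reversible, with at most one of the two set) and
exact linking constraints — indicator on implies |v| ≥ ε, both off
implies v = 0. The consensus objective counts a-priori active reactions
that are active plus a-priori inactive ones that are off. Making the
binarization explicit for *all* reactions (not only the core sets) means
each solution *is* a binary activity pattern, which is what the
enumeration strategies compare and what downstream statistics consume;
it also makes the optimality constraint exact (integer equality, no
tolerance).

The default activation threshold is ε = 1 with default bounds ±1000
(10⁻³ of the bound magnitude); a strict positive threshold is needed to
binarize "non-zero flux" numerically.

Enumeration:

* **reaction-enum** — for each reaction, re-solve with the reaction
  forced opposite to its baseline state; keep solutions attaining the
  unconstrained optimum; infeasible flips are skipped; the baseline is
  always included; duplicates removed in discovery order.
* **systematic sampling** — partition the ordered solution list into
  contiguous batches of ⌈1/fraction⌉ and draw one uniform solution per
  batch (seeded); keeps every stretch of the enumeration represented.
* **diversity-enum** — with the optimal score pinned as an equality
  constraint, repeatedly maximize the summed Hamming distance of the
  activity vector to all solutions found so far for that start; stop on
  revisits or after the iteration budget. The distance objective is the
  package's concrete realization of "gradually more different"
  exploration; no simulated-annealing schedule is used.

The MILP backend is GLPK through optlang (deterministic; tie-breaking
among equally optimal solutions is solver-dependent, so correctness
statements are about solution sets, never about which optimum comes
first). Replicates of a condition are enumerated independently, then
pooled and deduplicated. A returned pattern can be independently
re-checked for steady-state feasibility (`verify_pattern`), which solves
one LP per orientation assignment of active reversible reactions.

## DAR statistics

R2 = (f_ctrl − f_trt)² with exact rational frequencies. Perturbation
requires R2 strictly above the threshold (default 0.2). The baseline
noise of a reaction is the median of pairwise R2 over all unordered pairs
of control conditions in a vehicle/time group (≥ 2 controls required; the
caller does the grouping). The noise filter keeps a perturbed reaction
iff R2 ≥ 2 × noise — reactions exactly at the bound are kept, the literal
reading of filtering what is "less than" twice the noise. Direction is
the sign of f_trt − f_ctrl. The squared-difference statistic is preferred
over proportion tests because it is insensitive to the enumeration sample
size and robust to extreme frequencies.

Pathway over-representation uses a one-sided Fisher exact test per
pathway with Benjamini–Hochberg correction; artificial reactions
(sink/pool/exchange) are removed from both the DAR list and the universe
by default, since keeping them visibly distorts enrichments — a flag-free
argument (`artificial=set()`) restores the unfiltered variant. The
specificity ratio of a condition is the share of its DARs found in no
other condition.

## Reaction graph and subnetworks

Edges connect a producing reaction to a consuming one through a shared
non-side metabolite; reversible reactions contribute both orientations,
and a connection with a reversible partner is recorded in both directions
(the distance stage uses the undirected view, where the convention is
immaterial). Excluded reactions (defaults: blocked by LP flux
variability, never active in the provided solution sets, and artificial
single-metabolite boundary reactions) are dropped with their incident
edges.

Distances are unweighted shortest paths on the undirected view (the
directed graph is kept for export). Clustering is Ward linkage applied
directly to the path-distance matrix — Ward nominally assumes Euclidean
distances; applying it to path distances is a deliberate
faithful-reproduction choice. Isolated query reactions are removed before
clustering; any remaining infinite entry is replaced by the largest
finite distance plus one (with a warning) so the linkage stays defined.
The number of clusters is an explicit parameter (a dendrogram cut that
practitioners choose by inspection).

Steiner subnetworks follow the metric-closure 2-approximation: complete
closure over terminals weighted by path distance, its MST, expansion of
closure edges into real shortest paths, a spanning tree of the induced
subgraph, and pruning of non-terminal leaves. All tie-breaks (BFS
neighbor order, MST edge order, path reconstruction) are lexicographic on
reaction ids, making the extraction deterministic. Coverage = DAR nodes /
all nodes of the subnetwork.

Exports are node/edge TSV tables and a GraphML of the bipartite
reaction–metabolite subgraph (side compounds removed), suitable for any
interactive network viewer.

## Synthetic data

The generators emulate the workflow's three input kinds:

* **Toy networks** (chain, diamond, star, random-branched; ≤ 30
  reactions) are mass-balanced 1:1 conversion networks with boundary
  exchanges, optional reversibility and GPRs drawn from a synthetic gene
  pool. The diamond's uptake/sink capacity (1.5) is deliberately below
  twice the default activation threshold so its two branches are mutually
  exclusive: the optimal set under active uptake+sink is exactly the two
  branch choices, a ground truth small enough for exhaustive oracles.
* **Planted-shift solution matrices** draw each reaction's activity as
  independent Bernoulli columns at specified frequencies; the truth table
  records which planted shifts exceed the R2 threshold in expectation.
  Real enumeration output is not column-independent (activity patterns
  are coupled through stoichiometry), so these matrices validate the
  statistics, not the enumeration.
* **Synthetic z-scores** realize requested core sets through the GPRs by
  pushing the implicated genes outside the interquartile range and
  padding with neutral filler genes; the construction is verified by
  running the categorization and GPR evaluation on its own output.

What passing tests on these fixtures show: the statistics, filters and
graph algorithms behave exactly as specified on inputs with known ground
truth. What they do not show: recovery rates on real toxicogenomic data,
where expression calls are noisy, GPRs incomplete and the enumeration a
partial sample of an astronomically degenerate optimum.

## Problem sizes and numerical choices

Test and example problems use toy networks of 3–50 reactions, exhaustive
pattern oracles up to 2¹² patterns, Steiner brute force up to 12 nodes,
and planted-shift matrices up to 10,000 solutions — sizes chosen so every
claim is verifiable against an independent brute-force computation.
Frequencies and R2 are exact rationals of small integers; MILP activity
values are read from the binaries (no flux-threshold rounding); LP
feasibility checks use HiGHS via scipy.

## Known limitations

* GLPK is slower than commercial MILP solvers; genome-scale enumeration
  (thousands of solutions on a 7,785-reaction network) is out of desk
  range, which is why correctness is established on exhaustively
  checkable fixtures.
* Only the summed-Hamming diversity objective is implemented; other
  enumeration variants (integer cuts, maximal-distance variants) are not.
* Ward on path distances and the 2-approximate Steiner tree are faithful
  choices, not optimal ones; community detection and exact Steiner
  solvers are deliberate non-goals.
* The baseline-noise filter needs at least two control conditions per
  vehicle/time group; with a single control the noise is undefined and
  the filter cannot run.
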