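# Methods

This note documents the models and procedures implemented in `unicorn`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the design decisions taken where more than
one reasonable construction exists.

## Ontology representation and similarity

An ontology is a single-namespace rooted DAG; edges point from child term
to parent (`is_a` and `part_of` are both retained, obsolete terms are
dropped, alternative ids resolve to primary ids). A gene annotated to a
term is annotated to every ancestor, so annotation sets are closed upward
once and reused. A term's *level* is the length of the shortest directed
path to the namespace root, with the root at level 1 — the usual
convention for DAGs with multiple parents. Training sub-trees are rooted
at terms of levels 2–5: deep enough to be informative, shallow enough to
leave a coherent held-out part.

Gene-pair similarity within a training part is the normalized simplified
Resnik score

    s(g_a, g_b) = log(|G_tot| / |G_LCA|) / log(|G_tot|)

with G_LCA the gene set of the common-ancestor term with maximal
information content (equivalently, minimal annotated-gene count) and G_tot
the training genes. The normalization makes scores comparable across
training parts of different sizes; logarithm base cancels. Pairs with no
common ancestor inside the training sub-tree (possible only for malformed
inputs, since all training genes share the training root) score 0. The
similarity threshold t_s defaults to 0.3 (unitless, on the normalized
scale); pairs at or above it are called semantically similar.

## Edge filtering (t_w)

For each network, f(w) is the fraction of semantically similar pairs among
training-pair edges with weight ≥ w. Candidate thresholds are the distinct
training-edge weights scanned in descending order; t_w is the smallest
candidate with f(w) ≥ 0.5, so that as many relevant edges as possible are
retained. If f fails to increase for 5 consecutive reductions (the
`patience` knob) before any candidate satisfies the requirement, the scan
stops and the weight in effect before the stall is used, flagged as a
fallback. Only training-pair edges vote; the resulting threshold then
filters every edge. The pipeline additionally refuses to let a degenerate
fallback destroy a network: if fewer than two training edges survive, the
network is used unfiltered (warned), and dropped from integration only if
even that leaves fewer than two training edges.

## Discretization

An order-preserving discretization partitions the weight-sorted training
edges into contiguous levels that never split groups of equal weight. The
objective is the discordance

    D(M) = #{ {p, q} : d(level_p, level_q) ≠ d(s_p, s_q) }

over unordered pairs of training edges, with d the three-valued direction
function. Unordered counting is used; the indicator is symmetric, so
ordered counting would merely double every value.

The search starts from a random partition into k = 200 levels (cut points
drawn uniformly among the equal-weight block boundaries) and proposes
moves that shift 1–5 pairs from the top or bottom of a random level into
the adjacent level, re-proposing any draw that would split an equal-weight
block or walk off the ends. Improving moves are always accepted;
non-improving moves with probability min{0.1/iteration, 0.001}. The run
lasts 10,000 iterations with 5 restarts (restart count is a free choice;
"several" is enough for the instance sizes here) and the best partition
ever seen is returned. The objective is updated incrementally per move —
only pairs involving moved edges change — and a full recount validates the
incremental value in the tests.

Merging to 10–20 levels guards the later fit against over-fitting. The
merge criterion is greedy: the adjacent pair whose merge least increases
discordance goes first (ties: smaller combined size, then the lower pair).
Non-training edges are binned by half-open intervals anchored at the
minimum training-edge weight of each level, clamped at the extremes, and
every edge receives its level's mean original weight.

## Integration

The design matrix M has one row per training pair and one column per
merged level of each network; the entry is the pair's discretized weight
if it occupies that level, else 0 (also 0 throughout a network's block if
the pair has no edge there). `fit_integration` maximizes PCC(M a, s) in
closed form — ordinary least squares of the centred s on the centred
columns, the single-response case of canonical correlation analysis — with
a tiny ridge only for rank-deficient designs. Coefficients are reported at
unit Euclidean norm with the sign making the correlation non-negative;
PCC is scale-invariant, so the normalization is presentational.

The pipeline's default solver is `fit_integration_monotone`, which
constrains each network's per-level products a_j·w_j (the effective
integrated contribution of level j) to be nondecreasing in the level,
fitted by backfitting with isotonic regression. The rationale: the
discretization step guarantees that larger original weights never map to
lower levels, and the downstream DAG inference consumes *ranks*; an
unconstrained per-level fit on a small training set (tens of edges per
network against 10–20 free coefficients) produces non-monotone products
that invert that order and measurably degrade held-out ranking. The
monotone fit is a projection of the same objective onto the
order-respecting cone and approaches the unconstrained optimum as training
data grow. The unconstrained solver remains available
(`PipelineConfig.solver = "ols"`). Both solvers assume each design column
carries one constant value (the level's representative weight), which is
what `build_design_matrix` produces. Negative coefficients are permitted
in the unconstrained solver; integrated weights are min-max rescaled to
[0, 1] before DAG inference (configurable).

The equal-importance baseline (`summation`) min-max scales each filtered
network and adds them, skipping discretization and the fit.

## DAG inference

Starting from one singleton term per gene, a threshold sweeps the distinct
integrated edge weights in descending order. At threshold t, edges with
weight ≥ t − α are present. Top-level terms are pairwise compatible when
the subgraph induced by their combined gene set has edge density
≥ 1 − β; maximal cliques of this compatibility graph (Bron–Kerbosch with
pivoting via networkx) whose full union also reaches the density bound
become new terms, parents of their members. β is thus the tolerated
fraction of missing edges inside a term (default 0.5), α a noise margin on
edge inclusion (swept over {0, 0.05, 0.1, 0.2, 0.3} by default, in
rescaled-weight units, spanning high-precision to high-recall regimes).
Candidate groups are processed largest union first with lexicographic
tie-breaks, so the output is deterministic. A candidate whose gene set
duplicates an existing term attaches its members under that term instead
of creating a copy. Outputs always satisfy: acyclic link graph, each
child's gene set a strict subset of each parent's, leaves are single
genes. With α = β = 0 on an ultrametric network the procedure provably
recovers exactly the planted clusters. This is an implementation of the
clique-extraction idea as specified for this pipeline, not a bit-level
port of any external tool.

## Alignment and evaluation

Terms are matched across two DAGs by intrinsic similarity only — the
Jaccard index of their (propagated) gene sets — never by their position in
the hierarchy, so that the training part cannot leak into the evaluation
through shared neighbours. Matching is greedy in descending score (ties:
smaller inferred gene set, then lexicographic), subject to one-to-one use
of every term and to a no-crisscross rule (two matches may not invert
ancestor/descendant order between the DAGs). Because matching proceeds
downward in score, the matches above any cutoff are unaffected by
candidates below it; the null distribution therefore prunes cheaply. The
score cutoff realizes a 5 % FDR: with a null built from 100 gene-label
permutations of the first DAG, the cutoff is the smallest observed match
score c with (mean null matches ≥ c) / (observed matches ≥ c) ≤ 0.05.

Evaluation against the reference: an ontology O_G' is inferred from all
genes, a second ontology O_T' from the training genes alone; O_G' terms
aligned to O_T' are flagged training-derived. Hit counts O_G'–O_G matches
whose reference term lies outside the training sub-tree and whose inferred
term is not flagged; precision divides by the unflagged inferred terms,
recall by the reference terms outside the training sub-tree, F is their
harmonic mean. Singleton inferred terms (bare genes) and reference terms
annotating fewer than two genes are excluded from alignment and from the
denominators — they carry no grouping information.

## Synthetic worlds

`generate_ontology` plants a complete branching tree (optionally with
extra parents, making a true DAG) and spreads genes round-robin over the
leaves. `generate_networks` derives each network from the true pair
similarity through a monotone transform — identity, square, exponential
rescale, or a binary threshold — plus additive Gaussian noise (clipped to
[0, 1]) and uniform edge dropout. The binary network goes through a
diffusion kernel, exp(−τL) on the normalized Laplacian per connected
component (τ = 1), rescaled by its maximum off-diagonal entry into (0, 1]
and sparsified below 1e-6 — so more directly and indirectly connected
pairs score higher.

Defaults: 60 genes, depth 4, branching 3, dropout 0.3, and three networks
with noise 0.45 (identity), 0.2 (square) and 0.3 (binary). The noise
levels deliberately differ: heterogeneous real networks are unequally
informative about any given sub-ontology, and that inequality is precisely
what makes learned integration preferable to equal-weight summation; a
world in which every network is equally informative would make the
comparison between the two uninformative by construction.

What the generator does *not* emulate: realistic degree distributions,
motif structure, correlated noise between networks, annotation
incompleteness, or multi-namespace ontologies. Passing tests on these
worlds demonstrate that the machinery behaves as specified under
controlled signal/noise, not that real networks meet the assumptions.

## Problem sizes and numerics

The test and acceptance runs use 32–60-gene worlds, training parts of
20–24 genes (~300 training pairs), three networks, 10,000 search
iterations × 5 restarts, α grid of five values and 100 permutations per
alignment — sizes chosen so a complete run finishes in minutes on a
laptop-class CPU while every phenomenon of interest (filter learning,
discretization, fit, inference, alignment) is exercised end to end.
Stochastic components (search, permutation nulls) draw from seeds derived
deterministically from one pipeline seed via `numpy` seed sequences, so
reruns are byte-identical.

Known limitations: the discretization search is a heuristic — optimality
is verified only on enumerable instances; the FDR calibration is
permutation-based and inherits Monte-Carlo error; the DAG-inference sweep
restricts merges to current top-level terms, so multiple parenthood arises
only through duplicate-set attachment; and alignment scores ties are
broken lexicographically, which is arbitrary but deterministic.
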