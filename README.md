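# unicorn

Semi-supervised inference of gene-ontology sub-trees from heterogeneous
molecular networks.

## The problem

Biological ontologies such as the Gene Ontology organize terms (gene sets
with a shared function, process or location) in a rooted DAG, with genes
annotated upward to every ancestor term. Molecular networks — co-expression,
functional association, physical interaction — carry enough signal to infer
parts of such hierarchies automatically, but each network reports edge
weights on its own scale, with its own noise, and with unequal relevance to
any particular sub-ontology. Purely unsupervised inference cannot exploit
the parts of the ontology that are already well curated.

`unicorn` treats a chosen sub-tree of an existing ontology as a **training
part** and learns from it how to prepare and combine the networks before
inferring new terms:

1. **Training sub-trees** — every term between the 2nd and 5th level of the
   reference DAG roots a candidate training sub-tree.
2. **Similarity** — each pair of training genes g_a, g_b gets a normalized
   simplified-Resnik similarity
   `s(g_a, g_b) = −log(|G_LCA|/|G_tot|) / −log(1/|G_tot|)`,
   where G_LCA is the gene set of their most informative common-ancestor
   term and G_tot the training gene set. Pairs with `s ≥ t_s = 0.3` are
   *semantically similar*.
3. **Filtering** — each network keeps edges with weight at least t_w, the
   smallest threshold at which ≥ 50 % of the retained training edges are
   semantically similar (with an early stop when the fraction stalls).
4. **Discretization** — each network's weights are mapped to ordered levels
   minimizing the *discordance* — the number of training-pair pairs whose
   order by level disagrees with their order by similarity — under the
   constraint that the original weight order is preserved. The search is a
   stochastic local search with an annealing-style acceptance schedule,
   restarted from random partitions; neighbouring levels are then merged to
   10–20 per network.
5. **Integration** — a design matrix M (training pairs × pooled levels)
   holds each pair's discretized weight in its level column. Coefficients
   `a` maximizing `PCC(M a, s)` (a single-response special case of
   canonical correlation analysis, solved in closed form by least squares)
   combine all networks into one integrated network.
6. **DAG inference** — a clique-extraction sweep: descending a similarity
   threshold, groups of current top-level terms whose combined gene set is
   a near-clique (edge density ≥ 1 − β, with an α margin on edge inclusion)
   merge into new parent terms, yielding a DAG of candidate terms.
7. **Evaluation** — inferred terms are aligned to reference terms by
   intrinsic (gene-set Jaccard) similarity only, greedily, under one-to-one
   and no-crisscross constraints with a permutation-calibrated 5 % FDR
   cutoff. Hit / precision / recall / F are computed on the held-out part
   of the ontology, excluding terms attributable to the training part.

A synthetic-data module generates planted ontologies and noisy
heterogeneous networks with known ground truth, so the full pipeline is
testable without any downloads.

## Worked example

```python
import unicorn as u
from unicorn.pipeline import PipelineConfig, run_pipeline

world = u.generate_world(n_genes=60, depth=4, branching=3, seed=1)
table = run_pipeline(
    world.dag, world.annotations, world.networks,
    config=PipelineConfig(seed=1),
    training_roots=["S:0000002"],
    arms=("unicorn", "summation"),
)
print(table.groupby("method")["f_measure"].mean())
```

```
method
summation    0.315806
unicorn      0.375666
Name: f_measure, dtype: float64
```

The world plants a 40-term ontology over 60 genes and derives three
networks from it (identity, squared and binary-thresholded transforms of
the true pair similarity, each with noise and dropout; the binary one is
weighted by a diffusion kernel). Training on the sub-tree rooted at
`S:0000002`, the learned integration reaches a higher held-out F-measure
(averaged over the α grid 0–0.3) than the equal-weight summation of the
same filtered networks.

The same run is available from the shell:

```sh
unicorn simulate --outdir world --seed 1 --n-genes 60 --depth 4 --branching 3
unicorn run-all --ontology world/ontology.obo --annotations world/annotations.tsv \
    --network coexpr=world/network_coexpr.tsv \
    --network funcnet=world/network_funcnet.tsv \
    --network physical=world/network_physical.tsv \
    --training-root S:0000002 --outdir results --seed 1
```

`unicorn --help` lists the stage-by-stage subcommands (`filter`,
`discretize`, `integrate`, `infer`, `align`, `evaluate`, `benchmark`).

## Scope notes

The DAG-inference module implements the clique-extraction procedure as
characterized for this pipeline — β as the tolerated fraction of missing
edges in a term's subgraph and α as a margin on edge inclusion — not a
bit-identical port of any external implementation. See `docs/methods.md`
for the model details, parameter defaults and known limitations.
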