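"""End-to-end orchestration: filter, discretize, integrate, infer, evaluate.

Runs the whole semi-supervised pipeline for one or more training sub-trees
and a grid of DAG-inference stringencies (alpha), producing per-run
held-out metrics.  Two comparison arms mirror the method's evaluation
protocol: a simple-summation integration (equal network importance, no
discretization) and single-network inference.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import GeneSetDAG, align, evaluate, flag_training_derived
from .clixo import InferredDAG, infer_dag
from .discretizer import (
    DiscretizationMap,
    SearchParams,
    apply_discretization,
    merge_levels,
    search_discretization,
)
from .integrator import (
    build_design_matrix,
    fit_integration,
    fit_integration_monotone,
    integrate_networks,
)
from .netfilter import FilterResult, learn_threshold
from .netio import WeightedNetwork, diffusion_kernel, write_network
from .ontology import (
    AnnotationSet,
    OntologyDAG,
    TrainingSet,
    select_training_subtrees,
    training_pair_similarities,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "TrainingArtifacts", "run_pipeline", "run_benchmark_summation"]

ALPHA_GRID_DEFAULT = (0.0, 0.05, 0.1, 0.2, 0.3)

METRIC_COLUMNS = [
    "method",
    "training_root",
    "alpha",
    "n_inferred_terms",
    "n_training_derived",
    "hit",
    "precision",
    "recall",
    "f_measure",
]


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place."""

    t_s: float = 0.3
    filter_patience: int = 5
    search: SearchParams = field(default_factory=SearchParams)
    merge_min: int = 10
    merge_max: int = 20
    alpha_grid: tuple[float, ...] = ALPHA_GRID_DEFAULT
    beta: float = 0.5
    fdr: float = 0.05
    n_perm: int = 100
    diffusion_tau: float = 1.0
    rescale_integrated: bool = True
    min_training_genes: int = 4
    solver: str = "monotone"  # "monotone" (order-preserving products) or "ols"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_grid:
            raise ValueError("alpha grid must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainingArtifacts:
    """Everything learned for one training sub-tree."""

    training: TrainingSet
    filters: list[FilterResult]
    maps: list[DiscretizationMap]
    coefficients: object
    integrated: WeightedNetwork


def prepare_networks(
    networks: Sequence[WeightedNetwork],
    annotations: AnnotationSet,
    tau: float = 1.0,
) -> list[WeightedNetwork]:
    """Restrict networks to annotated genes; kernel-weight binary ones."""
    universe = annotations.genes
    out: list[WeightedNetwork] = []
    for net in networks:
        net = net.subset_genes(universe)
        if net.weights and all(w == 1.0 for w in net.weights.values()):
            logger.info("network %s is binary: applying diffusion kernel", net.name)
            net = diffusion_kernel(net, tau=tau)
        out.append(net)
    return out


def learn_integration(
    networks: Sequence[WeightedNetwork],
    training: TrainingSet,
    config: PipelineConfig,
) -> TrainingArtifacts:
    """Steps 3-5 for one training sub-tree: filter, discretize, integrate."""
    filters: list[FilterResult] = []
    discretized: list[tuple[WeightedNetwork, DiscretizationMap]] = []
    for i, net in enumerate(networks):
        fres = learn_threshold(net, training, patience=config.filter_patience)
        retained = fres.retained_network
        tr_weights = {
            p: retained.weights[p] for p in training.pairs if p in retained.weights
        }
        if len(tr_weights) < 2:
            # degenerate fallback threshold (e.g. no similar training pair at
            # all): keep the network unfiltered rather than losing it
            logger.warning(
                "network %s: threshold %.4g retains %d training edges; "
                "keeping the network unfiltered",
                net.name, fres.t_w, len(tr_weights),
            )
            retained = net
            tr_weights = {
                p: net.weights[p] for p in training.pairs if p in net.weights
            }
            fres = FilterResult(
                t_w=float("-inf"),
                retained_network=net,
                training_fraction_similar=fres.training_fraction_similar,
                fallback_used=True,
                n_edges_before=len(net),
                n_edges_after=len(net),
            )
            if len(tr_weights) < 2:
                logger.warning(
                    "network %s has <2 training edges; excluded from integration",
                    net.name,
                )
                continue
        filters.append(fres)
        params = SearchParams(
            k=config.search.k,
            max_iterations=config.search.max_iterations,
            restarts=config.search.restarts,
            seed=_derive_seed(config.seed, "discretize", i),
            max_block=config.search.max_block,
        )
        dmap = search_discretization(tr_weights, training, params)
        dmap = merge_levels(dmap, config.merge_min, config.merge_max)
        discretized.append((retained, dmap))
    if not discretized:
        raise ValueError("no network retains >= 2 training-pair edges")
    design = build_design_matrix(discretized, training)
    s = np.array([training.similarity[p] for p in training.pairs])
    if config.solver == "monotone":
        coef = fit_integration_monotone(design, s)
    elif config.solver == "ols":
        coef = fit_integration(design, s)
    else:
        raise ValueError(f"unknown solver {config.solver!r}")
    integrated = integrate_networks(
        discretized, coef, rescale=config.rescale_integrated
    )
    return TrainingArtifacts(
        training=training,
        filters=filters,
        maps=[m for _, m in discretized],
        coefficients=coef,
        integrated=integrated,
    )


def summation_integration(
    networks: Sequence[WeightedNetwork],
    filters: Sequence[FilterResult] | None = None,
) -> WeightedNetwork:
    """Equal-importance benchmark: min-max scale each network and add.

    When filter results are given, each network is first thresholded at
    its learned t_w (the benchmark replaces only the discretization and
    correlation-maximizing steps).
    """
    nets = [f.retained_network for f in filters] if filters is not None else networks
    combined: dict[tuple[str, str], float] = {}
    for net in nets:
        net = net.rescaled()
        for p, w in net.weights.items():
            combined[p] = combined.get(p, 0.0) + w
    return WeightedNetwork(combined, name="summation").rescaled()


def _derive_seed(base: int, label: str, index: int = 0) -> int:
    tag = zlib.crc32(label.encode()) % (2**31)
    h = np.random.SeedSequence([base, tag, index])
    return int(h.generate_state(1)[0] % (2**31))


def _evaluate_arm(
    method: str,
    integrated: WeightedNetwork,
    training: TrainingSet,
    reference: GeneSetDAG,
    subtree_terms: set[str],
    config: PipelineConfig,
    training_root: str,
) -> list[dict]:
    """Infer O_G' and O_T' for each alpha, align and score the held-out part."""
    rows: list[dict] = []
    training_genes = training.genes
    train_net = integrated.subset_genes(training_genes)
    for alpha in config.alpha_grid:
        o_g_prime = infer_dag(integrated, alpha=alpha, beta=config.beta)
        view_g = GeneSetDAG.from_inferred(o_g_prime)
        if train_net.weights:
            o_t_prime = infer_dag(train_net, alpha=alpha, beta=config.beta)
            view_t = GeneSetDAG.from_inferred(o_t_prime)
            align_t = align(
                view_g,
                view_t,
                fdr=config.fdr,
                n_perm=config.n_perm,
                seed=_derive_seed(config.seed, f"{method}-align-t", int(alpha * 1000)),
            )
            derived = flag_training_derived(align_t)
        else:
            derived = set()
        align_g = align(
            view_g,
            reference,
            fdr=config.fdr,
            n_perm=config.n_perm,
            seed=_derive_seed(config.seed, f"{method}-align-g", int(alpha * 1000)),
        )
        metrics = evaluate(
            align_g,
            o_g_terms=reference.term_genes.keys(),
            o_t_terms=subtree_terms,
            training_derived=derived,
            inferred_term_count=len(view_g.term_genes),
        )
        rows.append(
            {
                "method": method,
                "training_root": training_root,
                "alpha": alpha,
                "n_inferred_terms": len(view_g.term_genes),
                "n_training_derived": len(derived),
                "hit": metrics.hit,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "f_measure": metrics.f_measure,
            }
        )
    return rows


def _training_roots(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    config: PipelineConfig,
    training_roots: Iterable[str] | None,
) -> list[str]:
    if training_roots is not None:
        return list(training_roots)
    roots = []
    for t in select_training_subtrees(dag):
        genes = annotations.genes_annotated_to(dag.subtree_terms(t))
        held_out = annotations.genes - genes
        if len(genes) >= config.min_training_genes and held_out:
            roots.append(t)
    return roots


def run_pipeline(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    networks: Sequence[WeightedNetwork],
    config: PipelineConfig | None = None,
    training_roots: Iterable[str] | None = None,
    outdir: str | Path | None = None,
    arms: Sequence[str] = ("unicorn",),
) -> pd.DataFrame:
    """Run the full pipeline and return one metric row per arm x root x alpha.

    ``arms`` selects the methods to run: ``unicorn`` (learned
    integration), ``summation`` (equal-weight benchmark) and/or
    ``single`` (one arm per input network).  With ``outdir``, all
    intermediate artifacts and a manifest are written as tab-separated /
    JSON text.
    """
    config = config or PipelineConfig()
    prepared = prepare_networks(networks, annotations, tau=config.diffusion_tau)
    reference = GeneSetDAG.from_ontology(dag, annotations)
    roots = _training_roots(dag, annotations, config, training_roots)
    if not roots:
        raise ValueError("no usable training sub-tree (too few annotated genes?)")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for root in roots:
        subtree = dag.subtree_terms(root)
        training = training_pair_similarities(dag, root, annotations, t_s=config.t_s)
        if len(set(training.similarity.values())) < 2:
            # e.g. a leaf-level sub-tree where every pair shares one LCA:
            # nothing to supervise with
            logger.warning("training root %s: constant similarities; skipped", root)
            continue
        arts = learn_integration(prepared, training, config)
        if "unicorn" in arms:
            rows += _evaluate_arm(
                "unicorn", arts.integrated, training, reference, subtree, config, root
            )
        if "summation" in arms:
            summed = summation_integration(prepared, arts.filters)
            rows += _evaluate_arm(
                "summation", summed, training, reference, subtree, config, root
            )
        if "single" in arms:
            for net in prepared:
                rows += _evaluate_arm(
                    f"single:{net.name}",
                    net.rescaled(),
                    training,
                    reference,
                    subtree,
                    config,
                    root,
                )
        if out is not None:
            _write_artifacts(out, root, arts, config)
    if not rows:
        raise ValueError("no training root produced results")
    table = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    if out is not None:
        table.to_csv(out / "metrics.tsv", sep="\t", index=False)
        summary = (
            table.groupby(["method", "training_root"])["f_measure"]
            .mean()
            .reset_index()
            .rename(columns={"f_measure": "mean_f_measure"})
        )
        summary.to_csv(out / "summary_f_by_method.tsv", sep="\t", index=False)
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "training_roots": roots,
            "networks": [n.name for n in networks],
            "arms": list(arms),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def run_benchmark_summation(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    networks: Sequence[WeightedNetwork],
    config: PipelineConfig | None = None,
    training_roots: Iterable[str] | None = None,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Comparison arms only: simple summation plus each single network."""
    return run_pipeline(
        dag,
        annotations,
        networks,
        config=config,
        training_roots=training_roots,
        outdir=outdir,
        arms=("summation", "single"),
    )


def _write_artifacts(
    out: Path, root: str, arts: TrainingArtifacts, config: PipelineConfig
) -> None:
    tag = root.replace(":", "_")
    sub = out / f"root_{tag}"
    sub.mkdir(exist_ok=True)
    write_network(arts.integrated, sub / "integrated_network.tsv")
    (sub / "coefficients.tsv").write_text(arts.coefficients.report() + "\n")
    with open(sub / "filter_report.tsv", "w") as fh:
        fh.write("network\tt_w\tedges_before\tedges_after\tfrac_similar\tfallback\n")
        for fres in arts.filters:
            fh.write(fres.report_row() + "\n")
    for i, dmap in enumerate(arts.maps):
        name = arts.filters[i].retained_network.name or f"net{i}"
        (sub / f"discretization_{name}.tsv").write_text(dmap.report() + "\n")
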