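"""End-to-end analysis pipeline: data -> network -> clusters -> phenotype.

Configured by a :class:`PipelineConfig` (YAML-serialisable), the pipeline
simulates or loads an expression matrix and phenotype, infers the
co-expression network (partial correlations by default, a simple-correlation
"relevance network" as comparison mode), computes node-importance metrics,
clusters the network over the method/parameter grids, selects the best
partition by modularity, and runs the phenotype spatial analysis.  All
stochastic stages are seeded from the single config seed; identical configs
give byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .clustering import Partition, clustering_grid, select_best_partition
from .ggm import (
    EdgeSet,
    PartialCorrelationEstimate,
    PhenotypeCorr,
    bootstrap_partial_correlations,
    edge_significance,
    phenotype_partial_correlations,
)
from .io import (
    read_expression,
    read_phenotype,
    write_edge_list,
    write_expression,
    write_graphml,
    write_json,
    write_node_table,
    write_phenotype,
)
from .network import (
    GeneNetwork,
    build_network,
    default_betweenness_threshold,
    default_degree_threshold,
    density,
    node_metrics,
    select_high_betweenness,
    select_hubs,
)
from .spatial import MoranResult, all_cluster_tests, moran_permutation_test
from .synthetic import ExpressionMatrix, PhenotypeVector, simulate_study

__all__ = [
    "PipelineConfig",
    "ResultsBundle",
    "PipelineError",
    "run_pipeline",
    "simple_correlation_edges",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run (YAML-serialisable)."""

    # exactly one of the two input blocks must be provided
    simulation: dict | None = None
    input: dict | None = None

    n_bootstrap: int = 4000
    bootstrap_size: int = 20
    significance_cutoff: float = 0.2
    network_mode: str = "partial"  # or "simple"

    k_range: tuple[int, int] = (4, 12)
    som_grid_range: tuple[int, int] = (2, 4)
    heat_betas: tuple[float, ...] = (0.1, 1.0, 10.0)
    annealing_grid: tuple[float, ...] = (10.0, 100.0, 1000.0, 10_000.0, 100_000.0)
    n_sweeps: int = 200
    n_restarts: int = 5
    som_epochs: int = 30

    degree_threshold: int | None = None  # None -> percentile default
    betweenness_threshold: float | None = None
    degree_percentile: float = 92.5
    betweenness_percentile: float = 90.0

    n_permutations: int = 999
    moran_alternative: str = "greater"
    weight_scheme: str = "row_standardized"
    influence_rule: str = "4_over_n"
    influence_value: float | None = None
    cluster_test_level: float = 0.01

    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input is None):
            raise ValueError("exactly one of 'simulation' or 'input' must be given")
        if self.network_mode not in ("partial", "simple"):
            raise ValueError("network_mode must be 'partial' or 'simple'")
        if not (0 < self.significance_cutoff < 1):
            raise ValueError("significance_cutoff must lie in (0, 1)")
        if self.bootstrap_size < 2 or self.n_bootstrap < 1:
            raise ValueError("invalid bootstrap parameters")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if not (0 < self.cluster_test_level < 1):
            raise ValueError("cluster_test_level must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("k_range", "som_grid_range", "heat_betas", "annealing_grid"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key in ("k_range", "som_grid_range", "heat_betas", "annealing_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def simple_correlation_edges(X: ExpressionMatrix, cutoff: float = 0.2) -> EdgeSet:
    """Relevance-network edges from marginal Pearson correlations.

    The same empirical-null mixture / local-fdr machinery used for partial
    correlations is applied to the plain correlation coefficients.
    """
    corr = np.corrcoef(X.values)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    est = PartialCorrelationEstimate(matrix=corr, gene_ids=list(X.gene_ids))
    return edge_significance(est, cutoff=cutoff)


@dataclass
class ResultsBundle:
    """Everything one pipeline run produces."""

    expression: ExpressionMatrix
    phenotype: PhenotypeVector | None
    edges: EdgeSet
    network: GeneNetwork
    node_table: pd.DataFrame
    partitions: pd.DataFrame
    best_partition: Partition
    phenotype_pcor: PhenotypeCorr | None
    moran: MoranResult | None
    cluster_tests: list
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression(self.expression, out / "expression.tsv")
        if self.phenotype is not None:
            write_phenotype(self.phenotype, out / "phenotype.tsv")
        write_edge_list(self.edges, out / "edges.tsv")
        write_graphml(self.network, out / "network.graphml", self.edges)
        write_node_table(self.node_table, out / "node_table.tsv")
        self.partitions.to_csv(out / "partitions.tsv", sep="\t", index=False)
        results: dict = {"provenance": self.provenance}
        if self.moran is not None:
            results["moran"] = {
                "I": self.moran.I,
                "expected_I": self.moran.expected_I,
                "p_value": self.moran.p_value,
                "n_permutations": self.moran.n_permutations,
                "alternative": self.moran.alternative,
                "weight_scheme": self.moran.weight_scheme,
                "influential": list(self.moran.influential),
            }
        if self.cluster_tests:
            results["cluster_tests"] = [
                {
                    "cluster": t.cluster,
                    "mean_abs_inside": t.mean_abs_inside,
                    "mean_abs_outside": t.mean_abs_outside,
                    "t_statistic": t.t_statistic,
                    "p_value": t.p_value,
                    "level": t.level,
                    "significant": t.significant,
                }
                for t in self.cluster_tests
            ]
        write_json(results, out / "results.json")


def _load_data(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, PhenotypeVector | None, dict]:
    if config.simulation is not None:
        sim = dict(config.simulation)
        sim.setdefault("seed", config.seed)
        truth, expr, pheno = simulate_study(**sim)
        truth_info = {
            "true_partition": truth.true_partition,
            "phenotype_module": truth.phenotype_module,
        }
        return expr, pheno, truth_info
    paths = dict(config.input)
    expr = read_expression(paths["expression"])
    pheno = read_phenotype(paths["phenotype"]) if paths.get("phenotype") else None
    return expr, pheno, {}


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> ResultsBundle:
    """Execute the full analysis; write outputs to ``out_dir`` when given.

    On a stage failure the outputs produced so far are flushed to
    ``out_dir`` before a :class:`PipelineError` naming the stage is raised.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(8) >> 1
    t0 = time.perf_counter()
    stage = "load_data"
    partial_outputs: dict = {}

    def tick(name: str) -> None:
        nonlocal stage
        logger.info("stage %-18s done at %6.1fs", stage, time.perf_counter() - t0)
        stage = name

    try:
        X, y, truth_info = _load_data(config)
        partial_outputs["expression"] = X

        tick("edge_inference")
        if config.network_mode == "partial":
            pcor = bootstrap_partial_correlations(
                X,
                n_bootstrap=config.n_bootstrap,
                bootstrap_size=config.bootstrap_size,
                seed=int(seeds[0]),
            )
            edges = edge_significance(pcor, cutoff=config.significance_cutoff)
        else:
            edges = simple_correlation_edges(X, cutoff=config.significance_cutoff)

        tick("network_build")
        G = build_network(edges, X.gene_ids)
        metrics = node_metrics(G)
        deg_thresh = (
            config.degree_threshold
            if config.degree_threshold is not None
            else default_degree_threshold(metrics, config.degree_percentile)
        )
        bet_thresh = (
            config.betweenness_threshold
            if config.betweenness_threshold is not None
            else default_betweenness_threshold(metrics, config.betweenness_percentile)
        )
        hubs = set(select_hubs(metrics, deg_thresh))
        high_betw = set(select_high_betweenness(metrics, bet_thresh))

        tick("clustering")
        candidates = clustering_grid(
            G,
            k_range=config.k_range,
            som_grid_range=config.som_grid_range,
            heat_betas=config.heat_betas,
            annealing_grid=config.annealing_grid,
            n_sweeps=config.n_sweeps,
            n_restarts=config.n_restarts,
            som_epochs=config.som_epochs,
            seed=int(seeds[1]),
        )
        best = select_best_partition(G, candidates)
        partitions = pd.DataFrame(
            {
                "method": [c.method for c in candidates],
                "params": [json.dumps(c.params, sort_keys=True, default=str) for c in candidates],
                "n_clusters": [c.n_clusters for c in candidates],
                "modularity": [c.modularity for c in candidates],
                "selected": [c is best for c in candidates],
            }
        )

        pheno_pcor = None
        moran = None
        cluster_tests: list = []
        if y is not None:
            tick("phenotype_pcor")
            pheno_pcor = phenotype_partial_correlations(
                X,
                y,
                n_bootstrap=config.n_bootstrap,
                bootstrap_size=config.bootstrap_size,
                seed=int(seeds[2]),
            )
            tick("moran")
            rho_values = pheno_pcor.to_series()
            if G.n_edges == 0 or rho_values.nunique() <= 1:
                logger.warning(
                    "Moran stage skipped: network has no edges or constant attribute"
                )
                moran = None
            else:
                moran = moran_permutation_test(
                    G,
                    rho_values,
                    n_permutations=config.n_permutations,
                    seed=int(seeds[3]),
                    alternative=config.moran_alternative,
                    weight_scheme=config.weight_scheme,
                    influence_rule=config.influence_rule,
                    influence_value=config.influence_value,
                )
            tick("cluster_tests")
            from .spatial import cluster_phenotype_test

            sizes = best.sizes()
            n_genes = len(X.gene_ids)
            cluster_tests = [
                cluster_phenotype_test(
                    pheno_pcor, best, c, level=config.cluster_test_level
                )
                for c in sorted(sizes)
                if sizes[c] >= 2 and n_genes - sizes[c] >= 2
            ]

        tick("assemble")
        influential = set(moran.influential) if moran is not None else set()
        node_table = pd.DataFrame(
            {
                "degree": [metrics.degree[g] for g in X.gene_ids],
                "betweenness": [metrics.betweenness[g] for g in X.gene_ids],
                "hub": [g in hubs for g in X.gene_ids],
                "high_betweenness": [g in high_betw for g in X.gene_ids],
                "cluster": [best.assignment[g] for g in X.gene_ids],
            },
            index=X.gene_ids,
        )
        if pheno_pcor is not None:
            rho = pheno_pcor.to_series()
            node_table["pcor_phenotype"] = rho.reindex(X.gene_ids)
            node_table["abs_pcor_phenotype"] = node_table["pcor_phenotype"].abs()
            node_table["influential"] = [g in influential for g in X.gene_ids]
            node_table["moran_quadrant"] = [
                moran.quadrant[g] if moran is not None else "isolated"
                for g in X.gene_ids
            ]
        if truth_info:
            node_table["true_module"] = [
                truth_info["true_partition"][g] for g in X.gene_ids
            ]

        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "network_mode": config.network_mode,
            "degree_threshold": int(deg_thresh),
            "betweenness_threshold": float(bet_thresh),
            "significance_cutoff": config.significance_cutoff,
            "influence_rule": config.influence_rule,
            "cluster_test_level": config.cluster_test_level,
            "density_ordered_pairs": density(G, "ordered_pairs"),
            "n_edges": G.n_edges,
            "versions": {
                "coexnet": _pkg_version,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        if truth_info:
            provenance["phenotype_module"] = truth_info["phenotype_module"]

        bundle = ResultsBundle(
            expression=X,
            phenotype=y,
            edges=edges,
            network=G,
            node_table=node_table,
            partitions=partitions,
            best_partition=best,
            phenotype_pcor=pheno_pcor,
            moran=moran,
            cluster_tests=cluster_tests,
            provenance=provenance,
        )
        tick("write")
        if out_dir is not None:
            bundle.write(out_dir)
        tick("done")
        return bundle
    except PipelineError:
        raise
    except Exception as exc:
        if out_dir is not None and partial_outputs:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            if "expression" in partial_outputs:
                write_expression(partial_outputs["expression"], out / "expression.tsv")
        raise PipelineError(stage, exc) from exc
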