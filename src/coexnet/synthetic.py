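"""Synthetic expression data from a known Gaussian graphical model.

Every downstream stage of the package (partial-correlation inference, edge
calling, clustering, phenotype spatial statistics) can be validated against
ground truth only if the data come from a model whose conditional-independence
graph, module structure and phenotype coupling are known exactly.  This module
plants that truth: a sparse block precision matrix with modules, multivariate
normal expression draws, and a quantitative phenotype driven linearly by the
mean expression of one module.

The default shape mirrors a microarray study of eQTL-controlled transcripts
in pig muscle: 272 genes in 7 modules (sizes 33, 44, 58, 28, 41, 28, 40),
56 animals, and a pH-like phenotype tied to one module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "STUDY_MODULE_SIZES",
    "STUDY_N_GENES",
    "STUDY_N_SAMPLES",
    "SyntheticTruth",
    "ExpressionMatrix",
    "PhenotypeVector",
    "make_precision_matrix",
    "sample_expression",
    "attach_phenotype",
    "simulate_study",
]

#: Module sizes of the reference study's seven co-expression clusters.
STUDY_MODULE_SIZES = (33, 44, 58, 28, 41, 28, 40)
STUDY_N_GENES = sum(STUDY_MODULE_SIZES)  # 272
STUDY_N_SAMPLES = 56

# Diagonal-dominance margin: smallest eigenvalue of the repaired precision
# matrix is bounded below by this value (Gershgorin).
_DOMINANCE_MARGIN = 0.1


@dataclass
class ExpressionMatrix:
    """Gene expression values, genes as rows, samples as columns."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PhenotypeVector:
    """One quantitative phenotype value per sample."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.sample_ids):
            raise ValueError("phenotype length must equal number of samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth of a planted Gaussian graphical model.

    Attributes
    ----------
    precision
        Symmetric positive-definite precision (inverse covariance) matrix.
        Its off-diagonal support is the true conditional-independence graph.
    true_partition
        Gene id -> module label (1..K).
    phenotype_module
        Label of the module that drives the phenotype.
    phenotype_coefficients
        Per-gene regression weight of the phenotype on expression; nonzero
        only inside ``phenotype_module``.  Filled in by :func:`attach_phenotype`.
    noise_sd
        Standard deviation of the phenotype noise (set by
        :func:`attach_phenotype`).
    """

    precision: np.ndarray
    true_partition: dict[str, int]
    phenotype_module: int = 1
    phenotype_coefficients: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        P = np.asarray(self.precision, dtype=float)
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("precision matrix must be symmetric")
        eigmin = np.linalg.eigvalsh(P).min()
        if eigmin <= 0:
            raise ValueError(f"precision matrix not positive definite (min eig {eigmin:g})")
        self.precision = P

    @property
    def gene_ids(self) -> list[str]:
        return list(self.true_partition)

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def true_partial_correlations(self) -> np.ndarray:
        """Partial correlations implied by the precision matrix."""
        d = np.sqrt(np.diag(self.precision))
        rho = -self.precision / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        return rho

    def support(self) -> np.ndarray:
        """Boolean adjacency of the true conditional-independence graph."""
        off = self.precision.copy()
        np.fill_diagonal(off, 0.0)
        return off != 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "precision": self.precision.tolist(),
            "true_partition": self.true_partition,
            "phenotype_module": self.phenotype_module,
            "phenotype_coefficients": self.phenotype_coefficients,
            "noise_sd": self.noise_sd,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            precision=np.asarray(payload["precision"], dtype=float),
            true_partition={k: int(v) for k, v in payload["true_partition"].items()},
            phenotype_module=int(payload["phenotype_module"]),
            phenotype_coefficients={
                k: float(v) for k, v in payload["phenotype_coefficients"].items()
            },
            noise_sd=float(payload["noise_sd"]),
        )


def _gene_ids(p: int) -> list[str]:
    width = max(3, len(str(p)))
    return [f"g{i + 1:0{width}d}" for i in range(p)]


def _sample_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]


def make_precision_matrix(
    p: int = STUDY_N_GENES,
    module_sizes: list[int] | tuple[int, ...] = STUDY_MODULE_SIZES,
    within_density: float = 0.1,
    within_strength: float = -0.6,
    inter_module_edges: int = 20,
    seed: int = 0,
    phenotype_module: int | None = None,
) -> SyntheticTruth:
    """Build a sparse block precision matrix with planted modules.

    Off-diagonal entries equal to ``within_strength`` are placed at a random
    fraction ``within_density`` of the within-module positions (symmetric),
    plus ``inter_module_edges`` uniformly sampled between-module positions.
    Positive definiteness is enforced by diagonal dominance: each diagonal
    entry is the sum of the absolute off-diagonal entries in its row plus a
    fixed margin, so every eigenvalue is at least the margin.

    Parameters
    ----------
    p
        Number of genes.
    module_sizes
        Sizes of the planted modules; must sum to ``p`` and each be >= 2.
    within_density
        Fraction of within-module pairs that receive an edge, in (0, 1].
    within_strength
        Value placed at selected off-diagonal precision entries
        (|value| < 1).  The implied partial correlation has the opposite
        sign (rho_ij = -P_ij / sqrt(P_ii P_jj)), so the negative default
        plants positively co-expressed modules whose marginal correlations
        compound, as in real expression modules.
    inter_module_edges
        Number of between-module edges, sampled uniformly.
    seed
        Seed for the placement of edges.
    phenotype_module
        Module label (1-based) later used to drive the phenotype; by
        default the fourth module (mirroring the study's phenotype-linked
        cluster), or the last one when fewer than four modules exist.
    """
    module_sizes = list(module_sizes)
    if p < 2:
        raise ValueError("p must be >= 2")
    if sum(module_sizes) != p:
        raise ValueError(
            f"module sizes {module_sizes} sum to {sum(module_sizes)}, expected p={p}"
        )
    if any(s < 2 for s in module_sizes):
        raise ValueError("every module must contain at least 2 genes")
    if not (0 < within_density <= 1):
        raise ValueError("within_density must be in (0, 1]")
    if not abs(within_strength) < 1:
        raise ValueError("|within_strength| must be < 1")
    if phenotype_module is None:
        phenotype_module = min(4, len(module_sizes))
    if not (1 <= phenotype_module <= len(module_sizes)):
        raise ValueError("phenotype_module must index one of the modules")

    rng = np.random.default_rng(seed)
    gene_ids = _gene_ids(p)
    labels = np.repeat(np.arange(1, len(module_sizes) + 1), module_sizes)

    P = np.zeros((p, p))
    # Within-module support: sample pairs independently at within_density.
    start = 0
    for size in module_sizes:
        idx = np.arange(start, start + size)
        iu, ju = np.triu_indices(size, k=1)
        if within_density >= 1.0:
            keep = np.ones(len(iu), dtype=bool)
        else:
            keep = rng.random(len(iu)) < within_density
        P[idx[iu[keep]], idx[ju[keep]]] = within_strength
        start += size

    # Between-module support: uniform sample without replacement.
    if inter_module_edges > 0:
        iu, ju = np.triu_indices(p, k=1)
        between = labels[iu] != labels[ju]
        pool = np.flatnonzero(between)
        if inter_module_edges > len(pool):
            raise ValueError("inter_module_edges exceeds number of between-module pairs")
        chosen = rng.choice(pool, size=inter_module_edges, replace=False)
        P[iu[chosen], ju[chosen]] = within_strength

    P = P + P.T
    row_abs = np.abs(P).sum(axis=1)
    np.fill_diagonal(P, row_abs + _DOMINANCE_MARGIN)

    eigmin = np.linalg.eigvalsh(P).min()
    if eigmin <= 0:  # unreachable by construction; guards the invariant
        raise AssertionError(f"diagonal-dominance repair failed (min eig {eigmin:g})")

    return SyntheticTruth(
        precision=P,
        true_partition=dict(zip(gene_ids, (int(l) for l in labels))),
        phenotype_module=phenotype_module,
    )


def sample_expression(
    truth: SyntheticTruth, n: int = STUDY_N_SAMPLES, seed: int = 0
) -> ExpressionMatrix:
    """Draw ``n`` i.i.d. multivariate normal samples from the planted model.

    The covariance is the inverse of ``truth.precision``; genes are rows.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    cov = truth.covariance
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise np.linalg.LinAlgError("precision matrix is not invertible") from exc
    rng = np.random.default_rng(seed)
    p = cov.shape[0]
    z = rng.standard_normal((n, p))
    values = (z @ chol.T).T  # genes x samples
    return ExpressionMatrix(values=values, gene_ids=truth.gene_ids, sample_ids=_sample_ids(n))


def attach_phenotype(
    expr: ExpressionMatrix,
    truth: SyntheticTruth,
    effect_size: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> PhenotypeVector:
    """Generate a phenotype linearly driven by the phenotype module.

    ``y_s = effect_size * mean_{g in module}(expr[g, s]) + eps_s`` with
    ``eps_s ~ N(0, noise_sd^2)``.  The per-gene coefficients
    (``effect_size / module size`` inside the module, 0 outside) are recorded
    on ``truth``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    module = truth.phenotype_module
    members = [g for g, lab in truth.true_partition.items() if lab == module]
    if not members:
        raise ValueError(f"phenotype module {module} has no genes")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = [gene_index[g] for g in members]
    module_mean = expr.values[rows].mean(axis=0)
    rng = np.random.default_rng(seed)
    y = effect_size * module_mean + rng.normal(0.0, noise_sd, size=expr.n_samples)
    coef = effect_size / len(members)
    truth.phenotype_coefficients = {
        g: (coef if g in set(members) else 0.0) for g in expr.gene_ids
    }
    truth.noise_sd = float(noise_sd)
    return PhenotypeVector(values=y, sample_ids=list(expr.sample_ids))


def simulate_study(
    p: int = STUDY_N_GENES,
    module_sizes: list[int] | tuple[int, ...] = STUDY_MODULE_SIZES,
    n: int = STUDY_N_SAMPLES,
    within_density: float = 0.1,
    within_strength: float = -0.6,
    inter_module_edges: int = 20,
    effect_size: float = 1.0,
    noise_sd: float = 0.2,
    phenotype_module: int | None = None,
    seed: int = 0,
) -> tuple[SyntheticTruth, ExpressionMatrix, PhenotypeVector]:
    """One-call study-shaped simulation (truth, expression, phenotype).

    Independent seeds for structure, expression and phenotype noise are
    derived from ``seed`` through a seed sequence, so any single seed below
    2**31 reproduces the whole dataset.
    """
    s_struct, s_expr, s_pheno = np.random.SeedSequence(seed).generate_state(3) >> 1
    truth = make_precision_matrix(
        p=p,
        module_sizes=module_sizes,
        within_density=within_density,
        within_strength=within_strength,
        inter_module_edges=inter_module_edges,
        seed=int(s_struct),
        phenotype_module=phenotype_module,
    )
    expr = sample_expression(truth, n=n, seed=int(s_expr))
    pheno = attach_phenotype(
        expr, truth, effect_size=effect_size, noise_sd=noise_sd, seed=int(s_pheno)
    )
    return truth, expr, pheno
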