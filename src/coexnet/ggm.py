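"""Gaussian-graphical-model inference of a partial-correlation network.

With far fewer samples than genes the empirical covariance is singular, so
partial correlations (the scaled negative entries of the inverse covariance)
cannot be read off directly.  The estimator implemented here follows the
small-n large-p recipe standard in co-expression analysis:

1. shrink the empirical covariance toward its diagonal, with an analytic
   variance-minimising shrinkage intensity, so it is always invertible;
2. aggregate over bootstrap resamples of the animals/samples (default 4,000
   resamples of size 20) for robustness;
3. call significant edges with an empirical-null mixture: the null density of
   a sample (partial) correlation, ``f0(r) proportional to
   (1-r^2)^((kappa-3)/2)``, plus a uniform alternative, fitted by maximum
   likelihood; each gene pair gets a local false-discovery score and pairs
   scoring at or below the cutoff (default 0.2) become network edges.

The same machinery, applied to the expression matrix augmented with the
phenotype as an extra variable, yields per-gene partial correlations with the
phenotype.

The statsmodels-style entry point is :class:`CoexpressionGGM` whose ``fit``
returns a :class:`GGMResults`; the stage functions are also usable directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import ExpressionMatrix, PhenotypeVector

__all__ = [
    "ShrunkCovariance",
    "PartialCorrelationEstimate",
    "EdgeSet",
    "PhenotypeCorr",
    "shrink_covariance",
    "partial_correlations",
    "bootstrap_partial_correlations",
    "edge_significance",
    "phenotype_partial_correlations",
    "CoexpressionGGM",
    "GGMResults",
]

logger = logging.getLogger(__name__)

PHENOTYPE_ID = "__phenotype__"


@dataclass
class ShrunkCovariance:
    """Covariance shrunk toward its diagonal: (1-lambda) S + lambda diag(S)."""

    matrix: np.ndarray
    shrinkage_intensity: float
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("shrunk covariance must be symmetric")
        if not (0.0 <= self.shrinkage_intensity <= 1.0):
            raise ValueError("shrinkage intensity must lie in [0, 1]")
        self.matrix = 0.5 * (M + M.T)


@dataclass
class PartialCorrelationEstimate:
    """Symmetric matrix of pairwise partial correlations with unit diagonal."""

    matrix: np.ndarray
    gene_ids: list[str]
    n_bootstrap: int = 0
    bootstrap_size: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("partial-correlation matrix must be symmetric")
        R = 0.5 * (R + R.T)
        if np.any(np.abs(R) > 1 + 1e-9):
            raise ValueError("partial correlations must lie in [-1, 1]")
        R = np.clip(R, -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
        self.matrix = R

    def offdiagonal_values(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu, ju]


@dataclass
class EdgeSet:
    """Significant edges: (gene_i, gene_j, partial correlation, local-fdr score)."""

    edges: list[tuple[str, str, float, float]]
    significance_cutoff: float
    method: str = "local_fdr"
    null_kappa: float = float("nan")
    null_proportion: float = float("nan")

    def __post_init__(self) -> None:
        seen = set()
        for i, j, _, _ in self.edges:
            if i == j:
                raise ValueError(f"self-loop on {i!r}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {i!r}-{j!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.edges)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["gene_a", "gene_b", "pcor", "score"]
        )


@dataclass
class PhenotypeCorr:
    """Per-gene partial correlation with the phenotype."""

    gene_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float).ravel()
        if len(self.rho) != len(self.gene_ids):
            raise ValueError("one partial correlation per gene required")
        if not np.all(np.isfinite(self.rho)):
            raise ValueError("phenotype partial correlations must be finite")
        if np.any(np.abs(self.rho) > 1 + 1e-9):
            raise ValueError("phenotype partial correlations must lie in [-1, 1]")
        self.rho = np.clip(self.rho, -1.0, 1.0)

    @property
    def abs_rho(self) -> np.ndarray:
        return np.abs(self.rho)

    def to_series(self) -> pd.Series:
        return pd.Series(self.rho, index=self.gene_ids, name="pcor_phenotype")


# ---------------------------------------------------------------------------
# Stage 1: shrinkage covariance


def _check_constant_genes(values: np.ndarray, gene_ids: list[str]) -> None:
    spread = values.max(axis=1) - values.min(axis=1)
    dead = np.flatnonzero(spread == 0.0)
    if dead.size:
        names = ", ".join(gene_ids[i] for i in dead[:5])
        raise ValueError(f"constant gene(s) with zero variance: {names}")


def _analytic_intensity(obs_by_var: np.ndarray) -> float:
    """Variance-minimising shrinkage intensity toward the diagonal target.

    lambda* = sum_{i!=j} Var-hat(s_ij) / sum_{i!=j} s_ij^2, clipped to [0,1],
    with the usual unbiased plug-in estimate of Var(s_ij) from the centered
    cross-products.
    """
    n = obs_by_var.shape[0]
    xc = obs_by_var - obs_by_var.mean(axis=0)
    S = (xc.T @ xc) / (n - 1)
    sq = xc**2
    sum_w2 = sq.T @ sq  # sum_k (x_ki x_kj)^2 of centered data
    sum_w = (n - 1) * S
    var_s = (n / (n - 1) ** 3) * (sum_w2 - sum_w**2 / n)
    mask = ~np.eye(S.shape[0], dtype=bool)
    denom = float((S[mask] ** 2).sum())
    if denom <= 0:
        return 1.0
    lam = float(var_s[mask].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def _shrink(values_var_by_obs: np.ndarray, intensity: float | None) -> tuple[np.ndarray, float]:
    xc = values_var_by_obs.T  # observations x variables
    n = xc.shape[0]
    S = np.cov(values_var_by_obs, ddof=1)
    S = np.atleast_2d(S)
    lam = _analytic_intensity(xc) if intensity is None else float(intensity)
    if not (0.0 <= lam <= 1.0):
        raise ValueError("shrinkage intensity must lie in [0, 1]")
    C = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return C, lam


def shrink_covariance(
    X: ExpressionMatrix, intensity: float | None = None
) -> ShrunkCovariance:
    """Shrink the empirical gene-gene covariance toward its diagonal.

    Returns ``(1-lambda) S + lambda diag(S)`` with ``S`` the empirical
    covariance across samples.  When ``intensity`` is None the analytic
    variance-minimising intensity is used (clipped to [0, 1]); this keeps
    the matrix invertible even with far fewer samples than genes.
    """
    if X.n_samples < 2:
        raise ValueError("at least 2 samples required")
    if X.n_genes < 2:
        raise ValueError("at least 2 genes required")
    _check_constant_genes(X.values, X.gene_ids)
    C, lam = _shrink(X.values, intensity)
    return ShrunkCovariance(matrix=C, shrinkage_intensity=lam, gene_ids=list(X.gene_ids))


# ---------------------------------------------------------------------------
# Stage 2: partial correlations


def _pcor_from_cov(C: np.ndarray) -> np.ndarray:
    try:
        omega = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance matrix is singular") from exc
    d = np.sqrt(np.diag(omega))
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise np.linalg.LinAlgError("inverse covariance has non-positive diagonal")
    rho = -omega / np.outer(d, d)
    rho = 0.5 * (rho + rho.T)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def partial_correlations(C: ShrunkCovariance) -> PartialCorrelationEstimate:
    """Partial correlations rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj).

    ``Omega`` is the inverse of the (shrunk) covariance; the diagonal is set
    to 1 by convention.
    """
    rho = _pcor_from_cov(C.matrix)
    gene_ids = C.gene_ids or [f"v{i}" for i in range(rho.shape[0])]
    return PartialCorrelationEstimate(matrix=rho, gene_ids=list(gene_ids))


# ---------------------------------------------------------------------------
# Stage 3: bootstrap aggregation


def _resample_indices(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """One bootstrap draw: ``size`` sample indices with replacement."""
    return rng.integers(0, n, size=size)


def bootstrap_partial_correlations(
    X: ExpressionMatrix,
    n_bootstrap: int = 4000,
    bootstrap_size: int = 20,
    seed: int = 0,
) -> PartialCorrelationEstimate:
    """Bootstrap-aggregated shrinkage partial correlations.

    Each replicate draws ``bootstrap_size`` samples with replacement,
    computes the shrunk covariance and its partial correlations, and the
    replicates are averaged elementwise.  Replicates in which some gene is
    constant are skipped (logged, not counted).  Columns are canonicalised
    by sample id before resampling, so the estimate does not depend on the
    order in which samples are stored; replicate ``r`` draws from an
    independent stream derived from ``(seed, r)``.
    """
    if bootstrap_size < 2:
        raise ValueError("bootstrap_size must be >= 2")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    order = np.argsort(np.asarray(X.sample_ids, dtype=object))
    values = X.values[:, order]
    n = values.shape[1]
    children = np.random.SeedSequence(seed).spawn(n_bootstrap)
    total = np.zeros((X.n_genes, X.n_genes))
    kept = 0
    skipped = 0
    for child in children:
        rng = np.random.default_rng(child)
        idx = _resample_indices(rng, n, bootstrap_size)
        sub = values[:, idx]
        if np.any(sub.max(axis=1) == sub.min(axis=1)):
            skipped += 1
            continue
        C, _ = _shrink(sub, None)
        total += _pcor_from_cov(C)
        kept += 1
    if skipped:
        logger.info("bootstrap: skipped %d degenerate replicate(s)", skipped)
    if kept == 0:
        raise RuntimeError("all bootstrap replicates degenerate (constant gene)")
    mean = total / kept
    np.fill_diagonal(mean, 1.0)
    return PartialCorrelationEstimate(
        matrix=mean,
        gene_ids=list(X.gene_ids),
        n_bootstrap=n_bootstrap,
        bootstrap_size=bootstrap_size,
    )


# ---------------------------------------------------------------------------
# Stage 4: edge significance (empirical-null mixture, local fdr)


def _null_logpdf(r: np.ndarray, a: float) -> np.ndarray:
    # r -> (r+1)/2 is Beta(a, a); a = (kappa - 1) / 2
    return stats.beta.logpdf((r + 1.0) / 2.0, a, a) - np.log(2.0)


def fit_null_mixture(values: np.ndarray) -> tuple[float, float]:
    """Empirical-null fit of ``eta0 * f0(r; kappa) + (1 - eta0) * Uniform(-1, 1)``.

    ``f0(r) propto (1 - r^2)^((kappa-3)/2)`` is the null density of a sample
    correlation with ``kappa`` effective degrees of freedom.  ``kappa`` is
    estimated by maximum likelihood on the central part of the distribution
    (|r| within 2.5 robust null standard deviations, i.e. on values treated
    as null), which keeps a concentrated alternative from inflating the
    null width; ``eta0`` follows by matching the observed central mass to
    the null probability of the central region.  Returns ``(eta0, kappa)``.
    """
    r = np.clip(np.asarray(values, dtype=float), -1 + 1e-12, 1 - 1e-12)
    n = r.size
    # robust initial null scale (null is centred at zero by construction)
    sd0 = float(np.median(np.abs(r))) / 0.6745
    if sd0 <= 0:
        return 1.0 - 1.0 / n, 1e6
    q = min(2.5 * sd0, 1 - 1e-9)
    central = r[np.abs(r) <= q]
    if central.size < 5:  # pathological: fall back to the plain scale match
        kappa = float(np.clip(1.0 / sd0**2, 3.0, 5e6))
        return 1.0 - 1.0 / n, kappa

    def p_central(a: float) -> float:
        hi = stats.beta.cdf((q + 1.0) / 2.0, a, a)
        lo = stats.beta.cdf((1.0 - q) / 2.0, a, a)
        return float(max(hi - lo, 1e-12))

    def nll(log_a: float) -> float:
        a = float(np.exp(log_a))
        ll = _null_logpdf(central, a).sum() - central.size * np.log(p_central(a))
        return -float(ll)

    a0 = np.log(max((1.0 / sd0**2 - 1.0) / 2.0, 0.52))
    res = optimize.minimize_scalar(
        nll, bounds=(np.log(0.51), np.log(5e6)), method="bounded",
        options={"xatol": 1e-6},
    )
    a = float(np.exp(res.x if np.isfinite(res.fun) else a0))
    kappa = 2.0 * a + 1.0
    eta0 = (central.size / n) / p_central(a)
    # at least one observation's worth of alternative mass so extreme
    # values can always be called
    eta0 = float(np.clip(eta0, 1e-4, 1.0 - 1.0 / n))
    return eta0, float(kappa)


def local_fdr_scores(values: np.ndarray, eta0: float, kappa: float) -> np.ndarray:
    """Posterior null probability of each value under the fitted mixture."""
    r = np.clip(np.asarray(values, dtype=float), -1 + 1e-12, 1 - 1e-12)
    a = (kappa - 1.0) / 2.0
    with np.errstate(over="ignore", under="ignore"):
        f0 = np.exp(_null_logpdf(r, a))
    f = eta0 * f0 + (1.0 - eta0) * 0.5
    return np.clip(eta0 * f0 / np.maximum(f, 1e-300), 0.0, 1.0)


def edge_significance(
    P: PartialCorrelationEstimate, cutoff: float = 0.2
) -> EdgeSet:
    """Call significant edges by local false-discovery scoring.

    Fits the two-component empirical-null mixture to the off-diagonal
    partial correlations and retains pairs whose local-fdr score is at most
    ``cutoff``.  With fewer than 10 pairs the mixture cannot be fitted and an
    absolute-value quantile threshold is used instead (with a warning).
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    p = P.matrix.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    r = P.matrix[iu, ju]
    if r.size == 0:
        return EdgeSet(edges=[], significance_cutoff=cutoff)
    if np.all(r == 0.0):
        return EdgeSet(edges=[], significance_cutoff=cutoff)
    if r.size < 10:
        warnings.warn(
            "fewer than 10 gene pairs: falling back to absolute-value "
            "quantile thresholding instead of the mixture fit",
            stacklevel=2,
        )
        thresh = np.quantile(np.abs(r), 1.0 - cutoff)
        keep = np.abs(r) >= thresh
        scores = 1.0 - np.abs(r)
        method = "quantile_fallback"
        eta0 = kappa = float("nan")
    else:
        eta0, kappa = fit_null_mixture(r)
        scores = local_fdr_scores(r, eta0, kappa)
        keep = scores <= cutoff
        method = "local_fdr"
    ids = P.gene_ids
    edges = [
        (ids[i], ids[j], float(rho), float(s))
        for i, j, rho, s in zip(iu[keep], ju[keep], r[keep], scores[keep])
    ]
    return EdgeSet(
        edges=edges,
        significance_cutoff=cutoff,
        method=method,
        null_kappa=kappa,
        null_proportion=eta0,
    )


# ---------------------------------------------------------------------------
# Stage 5: gene-phenotype partial correlations


def phenotype_partial_correlations(
    X: ExpressionMatrix,
    y: PhenotypeVector,
    n_bootstrap: int = 4000,
    bootstrap_size: int = 20,
    seed: int = 0,
) -> PhenotypeCorr:
    """Partial correlation of each gene with the phenotype.

    The phenotype is appended as a (p+1)-th variable and the bootstrap
    shrinkage estimator is run on the augmented matrix; the returned vector
    is the phenotype row restricted to the genes.
    """
    if set(X.sample_ids) != set(y.sample_ids):
        missing = sorted(set(X.sample_ids) ^ set(y.sample_ids))
        raise ValueError(f"sample ids of expression and phenotype differ: {missing}")
    pos = {s: k for k, s in enumerate(y.sample_ids)}
    y_aligned = y.values[[pos[s] for s in X.sample_ids]]
    if PHENOTYPE_ID in X.gene_ids:
        raise ValueError(f"gene id {PHENOTYPE_ID!r} is reserved")
    aug = ExpressionMatrix(
        values=np.vstack([X.values, y_aligned[None, :]]),
        gene_ids=list(X.gene_ids) + [PHENOTYPE_ID],
        sample_ids=list(X.sample_ids),
    )
    est = bootstrap_partial_correlations(
        aug, n_bootstrap=n_bootstrap, bootstrap_size=bootstrap_size, seed=seed
    )
    rho = est.matrix[-1, :-1]
    if not np.all(np.isfinite(rho)):  # contract: never silently NaN
        raise FloatingPointError("phenotype partial correlations are not finite")
    return PhenotypeCorr(gene_ids=list(X.gene_ids), rho=rho)


# ---------------------------------------------------------------------------
# Model / Results facade


class CoexpressionGGM:
    """Gaussian graphical model of gene co-expression, statsmodels-style.

    Parameters
    ----------
    expression
        Genes-by-samples expression matrix.
    phenotype
        Optional quantitative phenotype aligned with the samples; when
        given, ``fit`` also estimates per-gene phenotype partial
        correlations.
    """

    def __init__(
        self, expression: ExpressionMatrix, phenotype: PhenotypeVector | None = None
    ):
        self.expression = expression
        self.phenotype = phenotype

    @classmethod
    def from_dataframe(
        cls, expression: pd.DataFrame, phenotype: pd.Series | None = None
    ) -> "CoexpressionGGM":
        """Build from a genes-by-samples DataFrame (and optional phenotype Series)."""
        X = ExpressionMatrix(
            values=expression.to_numpy(dtype=float),
            gene_ids=[str(g) for g in expression.index],
            sample_ids=[str(s) for s in expression.columns],
        )
        y = None
        if phenotype is not None:
            y = PhenotypeVector(
                values=phenotype.to_numpy(dtype=float),
                sample_ids=[str(s) for s in phenotype.index],
            )
        return cls(X, y)

    def fit(
        self,
        n_bootstrap: int = 4000,
        bootstrap_size: int = 20,
        significance_cutoff: float = 0.2,
        seed: int = 0,
    ) -> "GGMResults":
        """Run the bootstrap shrinkage estimator and call significant edges."""
        pcor = bootstrap_partial_correlations(
            self.expression,
            n_bootstrap=n_bootstrap,
            bootstrap_size=bootstrap_size,
            seed=seed,
        )
        edges = edge_significance(pcor, cutoff=significance_cutoff)
        pheno_corr = None
        if self.phenotype is not None:
            pheno_corr = phenotype_partial_correlations(
                self.expression,
                self.phenotype,
                n_bootstrap=n_bootstrap,
                bootstrap_size=bootstrap_size,
                seed=seed + 1,
            )
        return GGMResults(
            model=self, pcor=pcor, edges=edges, phenotype_pcor=pheno_corr, seed=seed
        )


@dataclass
class GGMResults:
    """Fitted co-expression GGM: estimates, significant edges, diagnostics."""

    model: CoexpressionGGM
    pcor: PartialCorrelationEstimate
    edges: EdgeSet
    phenotype_pcor: PhenotypeCorr | None = None
    seed: int = 0
    _network: object = field(default=None, repr=False)

    def network(self):
        """The undirected co-expression network over all genes (cached)."""
        if self._network is None:
            from .network import build_network

            self._network = build_network(self.edges, self.model.expression.gene_ids)
        return self._network

    def summary(self) -> str:
        from .network import density

        X = self.model.expression
        G = self.network()
        m = G.n_edges
        lines = [
            "Co-expression Gaussian graphical model",
            "=" * 48,
            f"genes:                 {X.n_genes}",
            f"samples:               {X.n_samples}",
            f"bootstrap replicates:  {self.pcor.n_bootstrap} (size {self.pcor.bootstrap_size})",
            f"significance cutoff:   {self.edges.significance_cutoff} (local fdr)",
            f"null proportion eta0:  {self.edges.null_proportion:.3f}",
            f"null kappa:            {self.edges.null_kappa:.1f}",
            f"edges retained:        {m}",
            f"density (ordered):     {100 * density(G, 'ordered_pairs'):.1f}%"
            if X.n_genes >= 2
            else "",
            f"phenotype attached:    {self.phenotype_pcor is not None}",
        ]
        return "\n".join(filter(None, lines))
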