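"""Relating network structure to a phenotype with spatial statistics.

The per-gene (partial) correlation with the phenotype is treated as an
attribute living on the network's nodes, and the network plays the role of
the spatial neighbourhood structure.  Moran's I measures whether neighbours
carry similar attribute values; its significance is assessed by randomly
permuting the attribute over the nodes.  The Moran scatterplot (attribute vs.
mean attribute of the neighbours) classifies genes into H-H/H-L/L-H/L-L
quadrants, and Cook's distance on the scatterplot's least-squares line flags
influential genes.  A Welch t-test per cluster compares the mean absolute
phenotype correlation inside a cluster to the rest of the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .clustering import Partition
from .ggm import PhenotypeCorr
from .network import GeneNetwork

__all__ = [
    "MoranResult",
    "ClusterPhenotypeTest",
    "morans_I",
    "moran_permutation_test",
    "moran_plot",
    "influential_nodes",
    "cluster_phenotype_test",
    "all_cluster_tests",
    "MoranTest",
]

QUADRANTS = ("H-H", "H-L", "L-H", "L-L", "isolated")


def _as_vector(G: GeneNetwork, x) -> np.ndarray:
    if isinstance(x, dict):
        missing = [n for n in G.nodes if n not in x]
        if missing:
            raise ValueError(f"attribute missing for nodes: {missing[:5]}")
        v = np.array([float(x[n]) for n in G.nodes])
    elif isinstance(x, pd.Series):
        v = x.reindex(G.nodes).to_numpy(dtype=float)
    else:
        v = np.asarray(x, dtype=float).ravel()
        if len(v) != G.n_nodes:
            raise ValueError("attribute length must equal number of nodes")
    if not np.all(np.isfinite(v)):
        raise ValueError("attribute must be finite")
    return v


def _weights(G: GeneNetwork, weight_scheme: str) -> np.ndarray:
    A = G.adjacency_matrix()
    if weight_scheme == "binary":
        return A
    if weight_scheme == "row_standardized":
        rowsum = A.sum(axis=1)
        W = np.divide(A, rowsum[:, None], out=np.zeros_like(A), where=rowsum[:, None] > 0)
        return W
    raise ValueError(f"unknown weight scheme {weight_scheme!r}")


def morans_I(G: GeneNetwork, x, weight_scheme: str = "row_standardized") -> float:
    """Moran's I of a node attribute on the network.

    ``I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``
    with ``w_ij`` taken from the adjacency (row-standardized by default) and
    ``S0 = sum_ij w_ij``.  Isolated nodes contribute only to the mean and the
    denominator.  Under random permutation of ``x`` the expectation is
    ``-1/(n-1)``.
    """
    v = _as_vector(G, x)
    if G.n_edges == 0:
        raise ValueError("Moran's I requires at least one edge")
    if np.ptp(v) == 0:
        raise ValueError("Moran's I is undefined for a constant attribute")
    W = _weights(G, weight_scheme)
    S0 = W.sum()
    xc = v - v.mean()
    return float(G.n_nodes / S0 * (xc @ W @ xc) / (xc @ xc))


def moran_plot(G: GeneNetwork, x) -> tuple[dict[str, float], dict[str, str]]:
    """Spatial lag (mean attribute over neighbours) and Moran quadrants.

    A node is "H" on the attribute axis when its value exceeds the overall
    mean, and "H" on the lag axis when its lag exceeds the mean lag over
    non-isolated nodes; isolated nodes are labelled ``"isolated"``.
    """
    v = _as_vector(G, x)
    nodes = G.nodes
    lag: dict[str, float] = {}
    index = {n: i for i, n in enumerate(nodes)}
    for n in nodes:
        nb = G.neighbors(n)
        lag[n] = float(np.mean([v[index[u]] for u in nb])) if nb else float("nan")
    xbar = v.mean()
    finite_lags = [w for w in lag.values() if np.isfinite(w)]
    lag_mean = float(np.mean(finite_lags)) if finite_lags else float("nan")
    quadrant: dict[str, str] = {}
    for n in nodes:
        if not np.isfinite(lag[n]):
            quadrant[n] = "isolated"
        elif v[index[n]] > xbar:
            quadrant[n] = "H-H" if lag[n] > lag_mean else "H-L"
        else:
            quadrant[n] = "L-H" if lag[n] > lag_mean else "L-L"
    return lag, quadrant


def _cooks_distances(G: GeneNetwork, x) -> tuple[list[str], np.ndarray]:
    """Cook's distance of each non-isolated node on the lag ~ x regression."""
    v = _as_vector(G, x)
    lag, _ = moran_plot(G, x)
    nodes = [n for n in G.nodes if np.isfinite(lag[n])]
    if len(nodes) < 3:
        raise ValueError("influence requires at least 3 non-isolated nodes")
    index = {n: i for i, n in enumerate(G.nodes)}
    xv = np.array([v[index[n]] for n in nodes])
    yv = np.array([lag[n] for n in nodes])
    if np.ptp(xv) == 0:
        raise ValueError("degenerate regression: attribute has zero variance")
    fit = sm.OLS(yv, sm.add_constant(xv)).fit()
    cooks = fit.get_influence().cooks_distance[0]
    return nodes, np.asarray(cooks)


def influential_nodes(
    G: GeneNetwork,
    x,
    threshold_rule: str = "4_over_n",
    threshold_value: float | None = None,
) -> list[str]:
    """Genes with outsized influence on the Moran scatterplot regression.

    Fits ordinary least squares of the spatial lag on the attribute and
    flags nodes whose Cook's distance exceeds ``4/n`` (default rule, ``n``
    the number of non-isolated nodes) or an absolute ``threshold_value``.
    """
    nodes, cooks = _cooks_distances(G, x)
    if threshold_rule == "4_over_n":
        thresh = 4.0 / len(nodes)
    elif threshold_rule == "absolute":
        if threshold_value is None:
            raise ValueError("threshold_value required for the absolute rule")
        thresh = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    flagged = [n for n, c in zip(nodes, cooks) if c > thresh]
    return sorted(flagged, key=lambda n: -cooks[nodes.index(n)])


@dataclass
class MoranResult:
    """Moran's I with permutation inference and influence diagnostics."""

    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    lag: dict[str, float]
    quadrant: dict[str, str]
    influence: dict[str, float]
    influential: list[str]
    weight_scheme: str = "row_standardized"
    alternative: str = "greater"
    perm_values: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")
        if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("permutation p-value below its attainable lower bound")

    def summary(self) -> str:
        counts = {q: 0 for q in QUADRANTS}
        for q in self.quadrant.values():
            counts[q] += 1
        lines = [
            "Moran's I permutation test",
            "=" * 40,
            f"I:                {self.I:.6f}",
            f"E[I] (perm.):     {self.expected_I:.6f}",
            f"p-value:          {self.p_value:.6g} ({self.alternative}, "
            f"{self.n_permutations} permutations)",
            f"weights:          {self.weight_scheme}",
            "quadrants:        "
            + ", ".join(f"{q}: {counts[q]}" for q in QUADRANTS if counts[q]),
            f"influential:      {len(self.influential)} node(s)",
        ]
        return "\n".join(lines)


def moran_permutation_test(
    G: GeneNetwork,
    x,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    weight_scheme: str = "row_standardized",
    influence_rule: str = "4_over_n",
    influence_value: float | None = None,
) -> MoranResult:
    """Permutation test of Moran's I, plus Moran-plot diagnostics.

    The attribute is permuted uniformly over the nodes;
    ``p = (1 + #{I_perm >= I_obs}) / (n_permutations + 1)`` for the
    one-sided "greater" alternative (two-sided compares distances from the
    permutation expectation ``-1/(n-1)``).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    v = _as_vector(G, x)
    n = G.n_nodes
    I_obs = morans_I(G, v, weight_scheme)
    W = _weights(G, weight_scheme)
    S0 = W.sum()
    xc = v - v.mean()
    denom = float(xc @ xc)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    E = xc[perms]  # B x n, centered values permuted
    I_perm = (n / S0) * np.einsum("bi,ij,bj->b", E, W, E, optimize=True) / denom
    expected = -1.0 / (n - 1)
    if alternative == "greater":
        exceed = int(np.count_nonzero(I_perm >= I_obs))
    else:
        exceed = int(np.count_nonzero(np.abs(I_perm - expected) >= abs(I_obs - expected)))
    p = (1 + exceed) / (n_permutations + 1)

    lag, quadrant = moran_plot(G, v)
    try:
        nodes_ni, cooks = _cooks_distances(G, v)
        influence = dict(zip(nodes_ni, (float(c) for c in cooks)))
        influential = influential_nodes(
            G, v, threshold_rule=influence_rule, threshold_value=influence_value
        )
    except ValueError as exc:
        # too few non-isolated nodes or a degenerate scatter: the test result
        # stands, influence diagnostics are simply unavailable
        warnings.warn(f"influence diagnostics skipped: {exc}", stacklevel=2)
        influence = {}
        influential = []
    return MoranResult(
        I=I_obs,
        expected_I=expected,
        p_value=p,
        n_permutations=n_permutations,
        lag=lag,
        quadrant=quadrant,
        influence=influence,
        influential=influential,
        weight_scheme=weight_scheme,
        alternative=alternative,
        perm_values=I_perm,
    )


class MoranTest:
    """Model-style wrapper: spatial autocorrelation of an attribute on a network."""

    def __init__(self, G: GeneNetwork, x, weight_scheme: str = "row_standardized"):
        self.G = G
        self.x = x
        self.weight_scheme = weight_scheme

    def fit(
        self, n_permutations: int = 999, seed: int = 0, alternative: str = "greater"
    ) -> MoranResult:
        return moran_permutation_test(
            self.G,
            self.x,
            n_permutations=n_permutations,
            seed=seed,
            alternative=alternative,
            weight_scheme=self.weight_scheme,
        )


# ---------------------------------------------------------------------------
# Per-cluster phenotype association


@dataclass
class ClusterPhenotypeTest:
    """Welch t-test of mean |rho| inside one cluster vs. the rest."""

    cluster: int
    mean_abs_inside: float
    mean_abs_outside: float
    t_statistic: float
    p_value: float
    level: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def cluster_phenotype_test(
    rho: PhenotypeCorr,
    P: Partition,
    cluster: int,
    level: float = 0.01,
    alternative: str = "greater",
) -> ClusterPhenotypeTest:
    """Does one cluster carry systematically stronger phenotype correlations?

    Two-sample Welch (unequal-variance) t-test on the absolute phenotype
    partial correlations of the genes inside the cluster against all other
    genes; significant when ``p <= level`` (default 1%).  The default
    alternative is one-sided ("greater"): the scientific question is whether
    a cluster is *more* strongly tied to the phenotype than the rest, and a
    two-sided test would also flag clusters that merely look weak next to
    the strong one.
    """
    if cluster not in set(P.assignment.values()):
        raise ValueError(f"cluster {cluster} not present in the partition")
    labels = np.array([P.assignment[g] for g in rho.gene_ids])
    inside = rho.abs_rho[labels == cluster]
    outside = rho.abs_rho[labels != cluster]
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("both groups need at least 2 genes")
    t, p = stats.ttest_ind(inside, outside, equal_var=False, alternative=alternative)
    return ClusterPhenotypeTest(
        cluster=cluster,
        mean_abs_inside=float(inside.mean()),
        mean_abs_outside=float(outside.mean()),
        t_statistic=float(t),
        p_value=float(p),
        level=level,
        significant=bool(p <= level),
    )


def all_cluster_tests(
    rho: PhenotypeCorr, P: Partition, level: float = 0.01, alternative: str = "greater"
) -> list[ClusterPhenotypeTest]:
    """Run the per-cluster phenotype test for every cluster label."""
    return [
        cluster_phenotype_test(rho, P, c, level=level, alternative=alternative)
        for c in sorted(set(P.assignment.values()))
    ]
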