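"""Node clustering of the co-expression network.

Three families of methods are provided, mirroring common practice for module
detection in biological networks:

* modularity optimization by simulated annealing (single-node label moves,
  geometric inverse-temperature ramp, greedy polish), where the modularity
  Q compares within-cluster edges to a degree-preserving null model;
* kernel k-means on a graph kernel (heat kernel ``exp(-beta L)`` or
  commute-time kernel ``L^+``), which relates to spectral clustering;
* batch kernel self-organizing maps on a small 2-D grid of prototypes.

Candidates from all methods and parameter grids are compared on their
modularity, and the best partition is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import GeneNetwork

__all__ = [
    "Partition",
    "KernelMatrix",
    "modularity",
    "modularity_pairwise",
    "anneal_modularity",
    "heat_kernel",
    "commute_time_kernel",
    "kernel_kmeans",
    "kernel_som",
    "select_best_partition",
    "clustering_grid",
]


@dataclass
class Partition:
    """A hard clustering of the network nodes.

    Labels are contiguous integers starting at 1.
    """

    assignment: dict[str, int]
    n_clusters: int
    modularity: float = float("nan")
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if labels != set(range(1, self.n_clusters + 1)):
            raise ValueError(
                f"labels must be contiguous 1..{self.n_clusters}, got {sorted(labels)}"
            )
        if not (np.isnan(self.modularity) or -1.0 <= self.modularity <= 1.0):
            raise ValueError("modularity must lie in [-1, 1]")

    @classmethod
    def from_labels(
        cls,
        nodes: list[str],
        labels: np.ndarray | list[int],
        method: str = "",
        params: dict | None = None,
        modularity: float = float("nan"),
    ) -> "Partition":
        """Build a partition, renumbering labels by first appearance in node order."""
        labels = list(labels)
        if len(labels) != len(nodes):
            raise ValueError("one label per node required")
        remap: dict[int, int] = {}
        assignment = {}
        for node, lab in zip(nodes, labels):
            if lab not in remap:
                remap[lab] = len(remap) + 1
            assignment[node] = remap[lab]
        return cls(
            assignment=assignment,
            n_clusters=len(remap),
            modularity=modularity,
            method=method,
            params=dict(params or {}),
        )

    def labels_for(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.assignment[n] for n in nodes], dtype=int)

    def members(self, label: int) -> list[str]:
        return [n for n, lab in self.assignment.items() if lab == label]

    def sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lab in self.assignment.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


@dataclass
class KernelMatrix:
    """Symmetric PSD node-similarity kernel on the network."""

    matrix: np.ndarray
    kernel_name: str
    node_ids: list[str]
    parameter: float | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel matrix must be symmetric")
        K = 0.5 * (K + K.T)
        eigmin = float(np.linalg.eigvalsh(K).min())
        if eigmin < -1e-8:
            raise ValueError(f"kernel matrix not PSD (min eigenvalue {eigmin:g})")
        self.matrix = K


# ---------------------------------------------------------------------------
# Modularity


def _partition_stats(
    G: GeneNetwork, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Within-cluster edge counts e_c and total degrees D_c per label value."""
    nodes = G.nodes
    index = {n: i for i, n in enumerate(nodes)}
    n_labels = labels.max() + 1
    e = np.zeros(n_labels)
    D = np.zeros(n_labels)
    deg = G.degree()
    for n in nodes:
        D[labels[index[n]]] += deg[n]
    for a, b in G.graph.edges:
        la, lb = labels[index[a]], labels[index[b]]
        if la == lb:
            e[la] += 1
    return e, D, G.n_edges


def modularity(G: GeneNetwork, P: Partition) -> float:
    """Newman modularity Q = sum_c [ e_c/m - (D_c/(2m))^2 ].

    ``e_c`` is the number of within-cluster edges and ``D_c`` the total
    degree of cluster ``c``; higher Q means edges concentrate inside
    clusters relative to a degree-preserving random graph.
    """
    if set(P.assignment) != set(G.nodes):
        raise ValueError("partition must cover exactly the network's nodes")
    m = G.n_edges
    if m == 0:
        raise ValueError("modularity is undefined on a graph with no edges")
    labels = P.labels_for(G.nodes)
    e, D, m = _partition_stats(G, labels)
    return float((e / m - (D / (2.0 * m)) ** 2).sum())


def modularity_pairwise(G: GeneNetwork, P: Partition) -> float:
    """Pairwise form of Q: sum over same-cluster ordered pairs (i, j),
    including i = j, of ``w_ij/(2m) - d_i d_j/(4 m^2)``.

    Kept as an independent algebraic route for cross-checking
    :func:`modularity`.
    """
    m = G.n_edges
    if m == 0:
        raise ValueError("modularity is undefined on a graph with no edges")
    A = G.adjacency_matrix()
    d = A.sum(axis=1)
    labels = P.labels_for(G.nodes)
    same = labels[:, None] == labels[None, :]
    Q = (A / (2.0 * m) - np.outer(d, d) / (4.0 * m**2))[same].sum()
    return float(Q)


# ---------------------------------------------------------------------------
# Simulated annealing


def _greedy_polish(
    labels: np.ndarray,
    nbrs: list[np.ndarray],
    deg: np.ndarray,
    m: int,
    D: np.ndarray,
    max_rounds: int = 100,
) -> np.ndarray:
    """Move nodes to the adjacent (or fresh) cluster that maximizes Q until stable."""
    p = len(labels)
    for _ in range(max_rounds):
        moved = False
        for v in range(p):
            a = labels[v]
            dv = deg[v]
            counts: dict[int, int] = {}
            for lab in labels[nbrs[v]]:
                counts[lab] = counts.get(lab, 0) + 1
            kva = counts.get(a, 0)
            # candidate targets: clusters of neighbours plus one fresh label
            best_gain = 1e-12
            best_b = -1
            fresh = len(D)
            for b in list(counts) + [fresh]:
                if b == a:
                    continue
                kvb = counts.get(b, 0)
                Db = D[b] if b < len(D) else 0.0
                gain = (kvb - kva) / m - dv * (Db - D[a] + dv) / (2.0 * m**2)
                if gain > best_gain:
                    best_gain, best_b = gain, b
            if best_b >= 0:
                if best_b == fresh:
                    D = np.append(D, 0.0)
                D[a] -= dv
                D[best_b] += dv
                labels[v] = best_b
                moved = True
        if not moved:
            break
    return labels


def anneal_modularity(
    G: GeneNetwork,
    n_init_clusters: int = 10,
    annealing_parameter: float = 100.0,
    n_sweeps: int = 200,
    seed: int = 0,
) -> Partition:
    """Maximize modularity by simulated annealing over single-node moves.

    Starts from a uniform random assignment into ``n_init_clusters`` labels.
    Each sweep proposes, for every node, a move to a label drawn uniformly
    from the current labels plus one fresh label; the move is accepted with
    probability ``min(1, exp(dQ * T_t))`` where the inverse temperature
    ``T_t`` rises geometrically from ``annealing_parameter`` to ten times
    that value over the sweeps.  The best partition seen is then polished
    with improving-only moves, so the result never scores below the
    initialization.  Empty labels are dropped and the rest renumbered.
    With ``n_sweeps=0`` the (renumbered) random initialization is returned
    unchanged.
    """
    if n_init_clusters < 2:
        raise ValueError("n_init_clusters must be >= 2")
    if annealing_parameter <= 0:
        raise ValueError("annealing_parameter must be > 0")
    m = G.n_edges
    if m == 0:
        raise ValueError("cannot cluster a graph with no edges")
    nodes = sorted(G.nodes)  # canonical order: result independent of storage order
    p = len(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    nbrs = [np.array([index[u] for u in G.neighbors(n)], dtype=int) for n in nodes]
    deg = np.array([len(a) for a in nbrs], dtype=float)

    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_init_clusters, size=p)

    def q_of(lab_arr: np.ndarray) -> float:
        e = np.zeros(lab_arr.max() + 1)
        D = np.zeros(lab_arr.max() + 1)
        for v in range(p):
            D[lab_arr[v]] += deg[v]
            same = lab_arr[nbrs[v]] == lab_arr[v]
            e[lab_arr[v]] += 0.5 * np.count_nonzero(same)
        return float((e / m - (D / (2.0 * m)) ** 2).sum())

    if n_sweeps == 0:
        part = Partition.from_labels(
            nodes,
            labels,
            method="modularity_annealing",
            params={
                "annealing_parameter": annealing_parameter,
                "n_sweeps": 0,
                "n_init_clusters": n_init_clusters,
                "seed": seed,
            },
        )
        part.modularity = modularity(G, part)
        return part

    max_labels = p + n_init_clusters + 1
    D = np.zeros(max_labels)
    for v in range(p):
        D[labels[v]] += deg[v]

    best_labels = labels.copy()
    best_q = q_of(labels)
    temps = annealing_parameter * 10.0 ** (
        np.arange(n_sweeps) / max(n_sweeps - 1, 1)
    )
    two_m2 = 2.0 * m**2
    for T in temps:
        order = rng.permutation(p)
        for v in order:
            a = labels[v]
            active = np.flatnonzero(D > 0)
            # fresh label: first empty slot
            empties = np.flatnonzero(D == 0)
            fresh = int(empties[0]) if empties.size else -1
            choices = list(active)
            if fresh >= 0:
                choices.append(fresh)
            b = choices[rng.integers(0, len(choices))]
            if b == a:
                continue
            nv = nbrs[v]
            lab_n = labels[nv]
            kva = int(np.count_nonzero(lab_n == a))
            kvb = int(np.count_nonzero(lab_n == b))
            dv = deg[v]
            gain = (kvb - kva) / m - dv * (D[b] - D[a] + dv) / two_m2
            if gain >= 0 or rng.random() < np.exp(gain * T):
                labels[v] = b
                D[a] -= dv
                D[b] += dv
        q = q_of(labels)
        if q > best_q:
            best_q = q
            best_labels = labels.copy()

    # greedy improving-only tail from the best state seen
    labels = best_labels
    D = np.zeros(int(labels.max()) + 1)
    for v in range(p):
        D[labels[v]] += deg[v]
    labels = _greedy_polish(labels, nbrs, deg, m, D)

    part = Partition.from_labels(
        nodes,
        labels,
        method="modularity_annealing",
        params={
            "annealing_parameter": annealing_parameter,
            "n_sweeps": n_sweeps,
            "n_init_clusters": n_init_clusters,
            "seed": seed,
        },
    )
    part.modularity = modularity(G, part)
    return part


# ---------------------------------------------------------------------------
# Graph kernels


def _laplacian(G: GeneNetwork) -> tuple[np.ndarray, list[str]]:
    nodes = sorted(G.nodes)  # canonical order: kernel independent of storage order
    A = nx.to_numpy_array(G.graph, nodelist=nodes)
    return np.diag(A.sum(axis=1)) - A, nodes


def heat_kernel(G: GeneNetwork, beta: float) -> KernelMatrix:
    """Diffusion (heat) kernel ``exp(-beta L)`` of the combinatorial Laplacian."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    L, nodes = _laplacian(G)
    w, V = np.linalg.eigh(L)
    K = (V * np.exp(-beta * w)) @ V.T
    return KernelMatrix(matrix=K, kernel_name="heat", node_ids=nodes, parameter=beta)


def commute_time_kernel(G: GeneNetwork) -> KernelMatrix:
    """Commute-time kernel: Moore-Penrose pseudo-inverse of the Laplacian."""
    comps = list(nx.connected_components(G.graph))
    if len(comps) != 1:
        raise ValueError(
            f"graph has {len(comps)} connected components; the commute-time "
            "kernel requires a connected graph — analyse components separately"
        )
    L, nodes = _laplacian(G)
    w, V = np.linalg.eigh(L)
    inv_w = np.where(w > 1e-10, 1.0 / np.where(w > 1e-10, w, 1.0), 0.0)
    K = (V * inv_w) @ V.T
    return KernelMatrix(matrix=K, kernel_name="commute_time", node_ids=nodes)


# ---------------------------------------------------------------------------
# Kernel k-means


def _kernel_distances(K: np.ndarray, members: list[np.ndarray]) -> np.ndarray:
    """Feature-space squared distances ||phi(i) - mu_c||^2 for all i, c."""
    p = K.shape[0]
    k = len(members)
    dist = np.tile(np.diag(K)[:, None], (1, k))
    for c, idx in enumerate(members):
        if idx.size == 0:
            dist[:, c] = np.inf
            continue
        dist[:, c] -= 2.0 * K[:, idx].mean(axis=1)
        dist[:, c] += K[np.ix_(idx, idx)].mean()
    return dist


def kernel_kmeans(
    K: KernelMatrix,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 100,
    _init_assignment: np.ndarray | None = None,
) -> Partition:
    """Lloyd's algorithm in the kernel feature space.

    Distances use the kernel trick
    ``||phi(i)-mu_c||^2 = K_ii - 2/|c| sum_{j in c} K_ij
    + 1/|c|^2 sum_{j,l in c} K_jl``; the best of ``n_restarts`` random
    initializations by within-cluster inertia is returned.  Empty clusters
    are re-seeded from the point farthest from its centroid.
    """
    km = K.matrix
    p = km.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p:
        raise ValueError(f"k={k} exceeds number of nodes {p}")
    ss = np.random.SeedSequence(seed).spawn(max(n_restarts, 1))
    best_labels = None
    best_inertia = np.inf
    restarts = 1 if _init_assignment is not None else n_restarts
    for r in range(restarts):
        rng = np.random.default_rng(ss[r])
        if _init_assignment is not None:
            labels = np.asarray(_init_assignment, dtype=int).copy()
        else:
            labels = rng.integers(0, k, size=p)
        for _ in range(max_iter):
            members = [np.flatnonzero(labels == c) for c in range(k)]
            dist = _kernel_distances(km, members)
            # re-seed empty clusters from the farthest point
            assigned = dist[np.arange(p), np.argmin(dist, axis=1)]
            for c in range(k):
                if members[c].size == 0:
                    far = int(np.argmax(assigned))
                    dist[far, :] = np.inf
                    dist[far, c] = 0.0
                    assigned[far] = 0.0
            new_labels = np.argmin(dist, axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        members = [np.flatnonzero(labels == c) for c in range(k)]
        dist = _kernel_distances(km, members)
        inertia = float(dist[np.arange(p), labels].sum())
        if inertia < best_inertia - 1e-12:
            best_inertia = inertia
            best_labels = labels.copy()
    return Partition.from_labels(
        K.node_ids,
        best_labels,
        method="kernel_kmeans",
        params={
            "k": k,
            "kernel": K.kernel_name,
            "kernel_parameter": K.parameter,
            "n_restarts": n_restarts,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Batch kernel SOM


def kernel_som(
    K: KernelMatrix,
    grid_rows: int,
    grid_cols: int,
    n_epochs: int = 30,
    seed: int = 0,
    initial_radius: float | None = None,
) -> Partition:
    """Batch self-organizing map in the kernel feature space.

    Prototypes live on a ``grid_rows x grid_cols`` grid and are convex
    combinations of kernel rows.  Each epoch assigns every node to its
    best-matching prototype and rebuilds prototypes with a Gaussian grid
    neighborhood whose radius shrinks linearly to zero over the epochs
    (``initial_radius=0`` disables the neighborhood, reducing the update to
    batch kernel k-means).  Non-empty prototypes become cluster labels.
    """
    km = K.matrix
    p = km.shape[0]
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    n_units = grid_rows * grid_cols
    if n_units > p:
        raise ValueError(f"grid of {n_units} units exceeds number of nodes {p}")
    rng = np.random.default_rng(seed)
    coords = np.array(
        [(r, c) for r in range(grid_rows) for c in range(grid_cols)], dtype=float
    )
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    gamma = np.zeros((n_units, p))
    init_pts = rng.choice(p, size=n_units, replace=False)
    gamma[np.arange(n_units), init_pts] = 1.0

    sigma0 = (
        max(grid_rows, grid_cols) / 2.0 if initial_radius is None else float(initial_radius)
    )
    diag = np.diag(km)

    def bmu(gamma_: np.ndarray) -> np.ndarray:
        cross = gamma_ @ km  # n_units x p
        quad = np.einsum("up,pq,uq->u", gamma_, km, gamma_)
        dist = diag[None, :] - 2.0 * cross + quad[:, None]
        return np.argmin(dist, axis=0)

    for t in range(n_epochs):
        sigma = sigma0 * (1.0 - t / n_epochs)
        winners = bmu(gamma)
        if sigma > 0:
            h = np.exp(-grid_d2[:, winners] / (2.0 * sigma**2))  # n_units x p
        else:
            h = (np.arange(n_units)[:, None] == winners[None, :]).astype(float)
        sums = h.sum(axis=1)
        nonempty = sums > 0
        gamma[nonempty] = h[nonempty] / sums[nonempty, None]
        # prototypes with no mass keep their previous position

    final = bmu(gamma)
    return Partition.from_labels(
        K.node_ids,
        final,
        method="kernel_som",
        params={
            "grid": (grid_rows, grid_cols),
            "kernel": K.kernel_name,
            "kernel_parameter": K.parameter,
            "n_epochs": n_epochs,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Model selection


def select_best_partition(G: GeneNetwork, candidates: list[Partition]) -> Partition:
    """Pick the candidate with the highest (recomputed) modularity.

    Ties are broken by fewer clusters, then lexicographically by method name.
    """
    if not candidates:
        raise ValueError("no candidate partitions supplied")
    scored = []
    for part in candidates:
        q = modularity(G, part)
        part.modularity = q
        scored.append((-q, part.n_clusters, part.method, part))
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


def clustering_grid(
    G: GeneNetwork,
    k_range: tuple[int, int] = (4, 12),
    som_grid_range: tuple[int, int] = (2, 4),
    heat_betas: tuple[float, ...] = (0.1, 1.0, 10.0),
    annealing_grid: tuple[float, ...] = (10.0, 100.0, 1000.0, 10_000.0, 100_000.0),
    n_sweeps: int = 200,
    n_restarts: int = 5,
    som_epochs: int = 30,
    seed: int = 0,
) -> list[Partition]:
    """All candidate partitions over the default parameter grids.

    Annealing runs once per annealing parameter (exponential grid 10..1e5);
    kernel k-means sweeps k over ``k_range`` and kernel SOM square grids
    over ``som_grid_range`` for each kernel (heat at each beta, plus
    commute-time when the graph is connected).
    """
    candidates: list[Partition] = []
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s >> 1) for s in ss.generate_state(4096))
    for a_param in annealing_grid:
        candidates.append(
            anneal_modularity(
                G, annealing_parameter=a_param, n_sweeps=n_sweeps, seed=next(seeds)
            )
        )
    kernels = [heat_kernel(G, b) for b in heat_betas]
    if len(list(nx.connected_components(G.graph))) == 1:
        kernels.append(commute_time_kernel(G))
    for K in kernels:
        for k in range(k_range[0], k_range[1] + 1):
            candidates.append(
                kernel_kmeans(K, k, n_restarts=n_restarts, seed=next(seeds))
            )
        for g in range(som_grid_range[0], som_grid_range[1] + 1):
            candidates.append(
                kernel_som(K, g, g, n_epochs=som_epochs, seed=next(seeds))
            )
    return candidates
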