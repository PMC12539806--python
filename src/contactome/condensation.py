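"""Diffusion condensation of adjacency profiles with modularity tracking.

Each neuron starts as a point whose coordinates are its adjacency profile
(its row of the contact matrix).  Every iteration builds a Gaussian affinity
over the current cluster centers with an adaptively chosen bandwidth, row
normalizes it into a diffusion operator, smooths the centers by one diffusion
step, and merges centers closer than a fixed threshold epsilon.  Merging uses
connected components of the epsilon-proximity graph, so the cluster hierarchy
is a sequence of nested coarsenings ending in a single cluster.  Weighted
modularity of each iteration's partition, always evaluated on the original
adjacency graph, identifies the iteration whose clusters define the strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from contactome.adjacency import AdjacencyMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DataMatrix:
    """Current cluster centers with their member-sets.

    ``row_labels`` are frozensets of original neuron labels (initially
    singletons); ``coords`` row i is the current center of cluster i.
    """

    row_labels: list[frozenset]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.row_labels):
            raise ValueError("coords shape does not match row labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")

    @property
    def n(self) -> int:
        return len(self.row_labels)


@dataclass
class AffinityMatrix:
    values: np.ndarray
    sigma: float


@dataclass
class DiffusionOperator:
    values: np.ndarray

    def __post_init__(self) -> None:
        rs = self.values.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("diffusion operator rows must sum to 1")
        if np.any(self.values < 0):
            raise ValueError("diffusion operator entries must be >= 0")


@dataclass(frozen=True)
class CondensationParams:
    """Tunables of the condensation loop.

    epsilon_divisor: the merge threshold is the largest coordinate range
    after the first diffusion step divided by this (default 10,000).
    sigma_rule: adaptive bandwidth policy; 'knn' (default) = median
    distance to the k-th nearest neighbor among current centers (k = 5,
    the usual adaptive-kernel scale in diffusion-map methods), 'median' =
    median nonzero pairwise distance.  The local knn scale keeps the
    kernel contrast high enough that well-separated groups condense
    internally before any cross-group merge.
    initial_affinity: 'gaussian' (default) builds the first affinity from the
    adjacency-profile geometry like every later iteration; 'adjacency' seeds
    the first diffusion operator from the row-normalized contact matrix
    itself.
    """

    epsilon_divisor: float = 10_000.0
    sigma_rule: str = "knn"
    knn_k: int = 5
    max_iterations: int = 1000
    merge_rule: str = "connected-components"
    initial_affinity: str = "gaussian"

    def __post_init__(self) -> None:
        if self.epsilon_divisor <= 0:
            raise ValueError("epsilon_divisor must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.sigma_rule not in ("knn", "median"):
            raise ValueError(f"unknown sigma rule {self.sigma_rule!r}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.initial_affinity not in ("gaussian", "adjacency"):
            raise ValueError(f"unknown initial_affinity {self.initial_affinity!r}")


@dataclass
class IterationRecord:
    assignment: dict  # original neuron label -> cluster id (int)
    centers: np.ndarray
    n_clusters: int
    modularity: float
    sigma: float


@dataclass
class CondensationTrace:
    labels: list  # original neuron labels, fixed order
    iterations: list[IterationRecord] = field(default_factory=list)
    epsilon: float = float("nan")
    converged: bool = False

    def assignment_vector(self, it: int) -> np.ndarray:
        """Cluster ids per original neuron (trace label order) at iteration it."""
        a = self.iterations[it].assignment
        return np.array([a[lab] for lab in self.labels], dtype=int)

    def modularities(self) -> np.ndarray:
        return np.array([rec.modularity for rec in self.iterations])


@dataclass
class StrataResult:
    partition: dict  # neuron label -> stratum id
    iteration_index: int
    modularity: float

    @property
    def n_strata(self) -> int:
        return len(set(self.partition.values()))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def gaussian_affinity(coords: np.ndarray, sigma: float) -> AffinityMatrix:
    """A_ij = exp(-d(xi, xj)^2 / (2 sigma^2)) with Euclidean d."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d2 = squareform(pdist(coords, metric="sqeuclidean")) if coords.shape[0] > 1 \
        else np.zeros((1, 1))
    return AffinityMatrix(values=np.exp(-d2 / (2.0 * sigma ** 2)), sigma=sigma)


def adaptive_sigma(
    coords: np.ndarray,
    last_sigma: float | None = None,
    rule: str = "knn",
    k: int = 5,
) -> float:
    """Adaptive Gaussian bandwidth for the current cluster centers.

    'knn' (default): the median, over centers, of the Euclidean distance to
    the k-th nearest other center (k capped at n - 1).  This local scale is
    the usual adaptive-kernel choice in diffusion-map methods and preserves
    kernel contrast between near and far neighborhoods as the point set
    condenses.  'median': the median nonzero pairwise distance (a global
    scale).  When the chosen statistic is zero the last positive bandwidth
    is reused (the affinity is all-ones either way).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if n < 2:
        raise ValueError("adaptive sigma needs at least 2 rows")
    d = squareform(pdist(coords))
    if rule == "knn":
        kk = min(k, n - 1)
        knn_d = np.sort(d, axis=1)[:, kk]  # column 0 is the self distance
        sigma = float(np.median(knn_d))
    elif rule == "median":
        flat = d[np.triu_indices(n, k=1)]
        nz = flat[flat > 0]
        sigma = float(np.median(nz)) if nz.size else 0.0
    else:
        raise ValueError(f"unknown sigma rule {rule!r}")
    if sigma <= 0:
        if last_sigma is None or last_sigma <= 0:
            raise ValueError("all distances zero and no previous sigma to reuse")
        return last_sigma
    return sigma


def diffusion_operator(A: AffinityMatrix | np.ndarray) -> DiffusionOperator:
    """Row-stochastic P = D^-1 A."""
    vals = A.values if isinstance(A, AffinityMatrix) else np.asarray(A, float)
    rs = vals.sum(axis=1)
    bad = np.where(rs <= 0)[0]
    if bad.size:
        raise ValueError(f"zero row sum at row {bad[0]}")
    return DiffusionOperator(values=vals / rs[:, None])


def diffuse(P: DiffusionOperator, X: DataMatrix) -> DataMatrix:
    """One diffusion step Y = P X; labels unchanged."""
    if P.values.shape[1] != X.coords.shape[0]:
        raise ValueError("operator and data dimensions do not conform")
    return DataMatrix(row_labels=list(X.row_labels), coords=P.values @ X.coords)


def compute_epsilon(coords: np.ndarray, divisor: float = 10_000.0) -> float:
    """Merge threshold: largest coordinate-wise range divided by the divisor.

    Equivalently (and provably) the maximum pairwise Chebyshev distance
    divided by the divisor.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    ranges = coords.max(axis=0) - coords.min(axis=0)
    eps = float(ranges.max()) / divisor
    if eps <= 0:
        raise ValueError("degenerate input: all rows identical")
    return eps


def condense_step(Y: DataMatrix, epsilon: float) -> tuple[np.ndarray, DataMatrix]:
    """Merge centers closer than epsilon (transitively) and average them.

    Returns the partition over current rows (component index per row) and the
    condensed data matrix whose member-sets are unions and whose centers are
    unweighted means of the merged centers.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    n = Y.n
    if n == 1:
        return np.zeros(1, dtype=int), Y
    d = squareform(pdist(Y.coords))
    adj = csr_matrix(d < epsilon)
    k, comp = connected_components(adj, directed=False)
    new_labels: list[frozenset] = []
    centers = np.zeros((k, Y.coords.shape[1]))
    for j in range(k):
        members = np.where(comp == j)[0]
        merged = frozenset().union(*(Y.row_labels[i] for i in members))
        new_labels.append(merged)
        centers[j] = Y.coords[members].mean(axis=0)
    return comp, DataMatrix(row_labels=new_labels, coords=centers)


def modularity(assignment: dict | np.ndarray, A0: AdjacencyMatrix) -> float:
    """Weighted modularity of a partition on the original adjacency graph.

    e = (1/2m) sum_ij (A_ij - d_i d_j / 2m) delta(pi(i), pi(j)), with
    d_i the weighted degree and m half the total weight.
    """
    A = A0.values
    if isinstance(assignment, dict):
        comm = np.array([assignment[lab] for lab in A0.labels])
    else:
        comm = np.asarray(assignment)
        if comm.shape[0] != A0.n:
            raise ValueError("assignment does not cover all labels")
    deg = A.sum(axis=1)
    two_m = deg.sum()
    if two_m <= 0:
        raise ValueError("graph has no edge weight")
    score = 0.0
    for c in np.unique(comm):
        idx = comm == c
        score += A[np.ix_(idx, idx)].sum() / two_m
        score -= (deg[idx].sum() / two_m) ** 2
    return float(score)


def run_condensation(
    A0: AdjacencyMatrix, params: CondensationParams | None = None
) -> CondensationTrace:
    """Full diffusion-condensation run over adjacency profiles.

    The initial coordinates are the rows of the adjacency matrix.  Each
    iteration recomputes the bandwidth adaptively on the current centers,
    diffuses them once, and merges within the fixed threshold epsilon
    (computed after the first diffusion step).  The partition over original
    neurons and its modularity against the original graph are recorded per
    iteration; the loop stops at a single cluster or at the iteration cap.
    """
    if params is None:
        params = CondensationParams()
    if A0.n < 2:
        raise ValueError("condensation needs at least 2 neurons")

    X = DataMatrix(
        row_labels=[frozenset([lab]) for lab in A0.labels],
        coords=A0.values.copy(),
    )
    trace = CondensationTrace(labels=list(A0.labels))
    epsilon = None
    sigma = None

    for it in range(params.max_iterations):
        if params.initial_affinity == "adjacency" and it == 0:
            sigma = float("nan")
            P = diffusion_operator(A0.values)
        else:
            sigma = adaptive_sigma(
                X.coords, last_sigma=sigma, rule=params.sigma_rule, k=params.knn_k
            )
            A = gaussian_affinity(X.coords, sigma)
            P = diffusion_operator(A)
        Y = diffuse(P, X)
        if epsilon is None:
            epsilon = compute_epsilon(Y.coords, params.epsilon_divisor)
            trace.epsilon = epsilon
        _, X = condense_step(Y, epsilon)

        assignment = {}
        for cid, members in enumerate(X.row_labels):
            for lab in members:
                assignment[lab] = cid
        trace.iterations.append(
            IterationRecord(
                assignment=assignment,
                centers=X.coords.copy(),
                n_clusters=X.n,
                modularity=modularity(assignment, A0),
                sigma=sigma if sigma == sigma else float("nan"),
            )
        )
        if X.n == 1:
            trace.converged = True
            break

    if not trace.converged:
        log.warning(
            "DC_NOT_CONVERGED hit max_iterations=%d with %d clusters remaining",
            params.max_iterations,
            trace.iterations[-1].n_clusters,
        )
    return trace


def select_strata(trace: CondensationTrace) -> StrataResult:
    """Partition at the highest-modularity iteration (earliest on ties)."""
    if not trace.iterations:
        raise ValueError("empty trace")
    mods = trace.modularities()
    best = int(np.argmax(mods))  # argmax returns the first maximum
    rec = trace.iterations[best]
    return StrataResult(
        partition=dict(rec.assignment),
        iteration_index=best,
        modularity=float(mods[best]),
    )


def sankey_flows(trace: CondensationTrace) -> pd.DataFrame:
    """Neuron flow between clusters of consecutive iterations.

    One row per (iteration, source cluster, target cluster) with the number
    of neurons flowing; flows out of each source sum to its size.
    """
    rows = []
    for t in range(len(trace.iterations) - 1):
        a = trace.assignment_vector(t)
        b = trace.assignment_vector(t + 1)
        for (src, dst), cnt in pd.crosstab(a, b).stack().items():
            if cnt > 0:
                rows.append(
                    {"iteration": t, "source": int(src), "target": int(dst),
                     "n_neurons": int(cnt)}
                )
    return pd.DataFrame(rows, columns=["iteration", "source", "target", "n_neurons"])
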