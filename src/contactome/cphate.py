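"""C-PHATE: block connectivity over all condensation iterations + 3-D embedding.

Every cluster of every condensation iteration (including the singleton
neurons at iteration 0) becomes one node.  Within-iteration affinities are
the original adjacency summed over cluster members, symmetrically normalized
into kernel matrices that sit on the diagonal of a large block connectivity
matrix; consecutive iterations are tied by transition-probability blocks
weighted w1 (lag 1) and w2 (lag 2).  A PHATE-family potential-distance
embedding of the connectivity matrix places all nodes in 3-D, so condensation
trajectories can be followed from single neurons to the final cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from contactome.adjacency import AdjacencyMatrix
from contactome.condensation import CondensationTrace, select_strata

log = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Row-stochastic k_t x k_{t+1} matrix of cluster membership flow."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("negative transition probability")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")


@dataclass
class ConnectivityMatrix:
    values: np.ndarray
    node_index: dict  # (iteration, cluster id) -> row
    lag_weights: tuple[float, float] = (100.0, 30.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    coords: np.ndarray  # N x 3
    node_index: dict
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Levels: iteration-0 singletons + every trace iteration
# ---------------------------------------------------------------------------

def _levels(trace: CondensationTrace) -> list[np.ndarray]:
    """Assignment vectors per level; level 0 = singleton neurons."""
    if not trace.iterations:
        raise ValueError("trace has no iterations")
    n = len(trace.labels)
    levels = [np.arange(n, dtype=int)]
    for t in range(len(trace.iterations)):
        levels.append(trace.assignment_vector(t))
    return levels


def _cluster_ids(assign: np.ndarray) -> np.ndarray:
    return np.unique(assign)


def cluster_affinity(assign: np.ndarray, A0: AdjacencyMatrix) -> np.ndarray:
    """Cluster-level affinity: block sums of the original adjacency.

    A_t[i, j] = sum of A0 over members of cluster i x members of cluster j.
    Total weight is conserved under this coarse-graining.
    """
    ids = _cluster_ids(assign)
    M = np.zeros((len(ids), A0.n))
    for k, c in enumerate(ids):
        M[k] = A0.values[assign == c].sum(axis=0)
    out = np.zeros((len(ids), len(ids)))
    for k, c in enumerate(ids):
        out[:, k] = M[:, assign == c].sum(axis=1)
    return out


def symmetric_kernel(A_t: np.ndarray) -> np.ndarray:
    """K = D^(-1/2) A D^(-1/2); requires positive row sums."""
    A_t = np.asarray(A_t, dtype=float)
    d = A_t.sum(axis=1)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise ValueError(f"zero row sum at row {bad[0]}")
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_t * inv_sqrt[:, None] * inv_sqrt[None, :]


def transition_probabilities(
    assign_t: np.ndarray, assign_t1: np.ndarray
) -> TransitionMatrix:
    """P[i, j] = fraction of cluster i's neurons that land in cluster j.

    Requires the later assignment to coarsen the earlier one (merge-only
    dynamics), which makes every row a point mass.
    """
    assign_t = np.asarray(assign_t)
    assign_t1 = np.asarray(assign_t1)
    if assign_t.shape != assign_t1.shape:
        raise ValueError("assignments cover different neuron sets")
    ids_t = _cluster_ids(assign_t)
    ids_t1 = _cluster_ids(assign_t1)
    col = {c: j for j, c in enumerate(ids_t1)}
    P = np.zeros((len(ids_t), len(ids_t1)))
    for i, c in enumerate(ids_t):
        members = assign_t == c
        targets = np.unique(assign_t1[members])
        if len(targets) > 1:
            raise ValueError(
                f"assignments are not nested: cluster {c} splits into {targets}"
            )
        counts = np.bincount(
            [col[t] for t in assign_t1[members]], minlength=len(ids_t1)
        )
        P[i] = counts / members.sum()
    return TransitionMatrix(values=P)


def build_connectivity(
    trace: CondensationTrace,
    A0: AdjacencyMatrix,
    lag_weights: tuple[float, float] = (100.0, 30.0),
) -> ConnectivityMatrix:
    """Assemble the symmetric block connectivity matrix across all levels.

    Diagonal blocks are the per-level kernels; (t, t+1) blocks carry
    w1 x transition probabilities and (t, t+2) blocks w2 x the composed
    two-step transitions, mirrored by transposition for symmetry.
    """
    w1, w2 = lag_weights
    levels = _levels(trace)
    sizes = [len(_cluster_ids(a)) for a in levels]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    N = int(offsets[-1])
    C = np.zeros((N, N))

    node_index: dict = {}
    for t, assign in enumerate(levels):
        for k, c in enumerate(_cluster_ids(assign)):
            node_index[(t, int(c))] = int(offsets[t] + k)

    kernels = [symmetric_kernel(cluster_affinity(a, A0)) for a in levels]
    for t, K in enumerate(kernels):
        sl = slice(offsets[t], offsets[t + 1])
        C[sl, sl] = K

    trans = [
        transition_probabilities(levels[t], levels[t + 1]).values
        for t in range(len(levels) - 1)
    ]
    for t, P in enumerate(trans):
        r = slice(offsets[t], offsets[t + 1])
        c = slice(offsets[t + 1], offsets[t + 2])
        C[r, c] += w1 * P
        C[c, r] += w1 * P.T
    for t in range(len(trans) - 1):
        P2 = trans[t] @ trans[t + 1]
        r = slice(offsets[t], offsets[t + 1])
        c = slice(offsets[t + 2], offsets[t + 3])
        C[r, c] += w2 * P2
        C[c, r] += w2 * P2.T

    return ConnectivityMatrix(values=C, node_index=node_index, lag_weights=(w1, w2))


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def potential_embedding(
    affinity: np.ndarray, n_components: int = 3, diffusion_time: int = 50,
    seed: int = 1,
) -> np.ndarray:
    """PHATE-family potential-distance embedding of a symmetric affinity.

    Row normalizes the affinity into a Markov operator, powers it to the
    diffusion time, takes -log potentials, and embeds their pairwise
    Euclidean distances by classical multidimensional scaling.  Fully
    deterministic: eigenvector signs are fixed by convention, so the seed
    only tags the run.
    """
    A = np.asarray(affinity, dtype=float)
    rs = A.sum(axis=1)
    if np.any(rs <= 0):
        raise ValueError("affinity has a zero row sum")
    P = A / rs[:, None]
    Pt = np.linalg.matrix_power(P, int(diffusion_time))
    U = -np.log(Pt + 1e-7)
    # classical MDS on potential distances
    from scipy.spatial.distance import pdist, squareform

    sq = squareform(pdist(U, metric="sqeuclidean"))
    n = sq.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ sq @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n_components]
    w_top = np.clip(w[order], 0.0, None)
    Y = V[:, order] * np.sqrt(w_top)[None, :]
    # deterministic sign convention: largest-magnitude entry positive
    for j in range(Y.shape[1]):
        col = Y[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            Y[:, j] = -col
    return Y


def embed(
    C: ConnectivityMatrix,
    diffusion_time: int = 50,
    seed: int = 1,
    backend=None,
) -> Embedding:
    """3-D embedding of all iteration-clusters from the connectivity matrix.

    ``backend`` may be any callable ``(affinity, n_components, diffusion_time,
    seed) -> coords`` implementing a PHATE-family embedding; the built-in
    potential-distance backend is used by default.
    """
    if backend is None:
        backend = potential_embedding
    coords = np.asarray(
        backend(C.values, n_components=3, diffusion_time=diffusion_time, seed=seed)
    )
    if coords.shape != (C.n, 3) or not np.all(np.isfinite(coords)):
        raise ValueError("embedding backend returned invalid coordinates")
    return Embedding(
        coords=coords,
        node_index=dict(C.node_index),
        params={"diffusion_time": diffusion_time, "seed": seed,
                "lag_weights": C.lag_weights},
    )


def export_cphate(
    embedding: Embedding, trace: CondensationTrace
) -> pd.DataFrame:
    """Node table: iteration, cluster, members, x/y/z, stratum of the node.

    The stratum column carries the max-modularity stratum id of the cluster
    that contains the node's members at the selected iteration.
    """
    strata = select_strata(trace)
    levels = _levels(trace)
    labels = np.asarray(trace.labels, dtype=object)
    rows = []
    for t, assign in enumerate(levels):
        for c in _cluster_ids(assign):
            members = labels[assign == c]
            idx = embedding.node_index[(t, int(c))]
            x, y, z = embedding.coords[idx]
            # nodes at or before the max-modularity iteration lie inside one
            # stratum; coarser nodes spanning several strata are marked -1
            member_strata = {strata.partition[m] for m in members}
            stratum = member_strata.pop() if len(member_strata) == 1 else -1
            rows.append(
                {
                    "iteration": t,
                    "cluster": int(c),
                    "members": ";".join(str(m) for m in members),
                    "n_members": len(members),
                    "x": float(x),
                    "y": float(y),
                    "z": float(z),
                    "stratum": int(stratum),
                }
            )
    return pd.DataFrame(rows)
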