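"""Per-subject graph construction and normalized propagation operators.

A subject's brain graph is built by thresholding a connectivity matrix
(functional connectivity for multimodal runs, structural connectivity
for SC-only runs) and keeping the k strongest connections of every
region.  The adjacency is binary — edge weighting is delegated entirely
to the learnable mask of the model — and the graph convolution uses the
symmetric-normalized augmented adjacency D̃^{-1/2} (A + I) D̃^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BrainGraph",
    "build_adjacency",
    "normalize_adjacency",
    "graph_laplacian",
    "make_node_features",
]

DEFAULT_TOP_K = 30
DEFAULT_EDGE_THRESHOLD = 0.001


@dataclass
class BrainGraph:
    """Binary adjacency plus derived operators and node features.

    ``norm_adjacency`` is D̃^{-1/2} Ã D̃^{-1/2} with Ã = A + I;
    ``laplacian`` is the combinatorial Laplacian D - A of the
    self-loop-free adjacency (used by the manifold regularizer).
    """

    adjacency: np.ndarray
    node_features: np.ndarray
    norm_adjacency: np.ndarray = field(init=False)
    laplacian: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.trace(a) != 0:
            raise ValueError("adjacency must have zero diagonal")
        if self.node_features.shape[0] != a.shape[0]:
            raise ValueError("node_features row count must equal node count")
        self.adjacency = a
        self.norm_adjacency = normalize_adjacency(a)
        self.laplacian = graph_laplacian(a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def build_adjacency(
    conn: np.ndarray,
    k: int = DEFAULT_TOP_K,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> np.ndarray:
    """Binary adjacency from a connectivity matrix by per-node top-k.

    For every node, its k largest-valued incident connections that
    exceed ``threshold`` are selected (fewer when fewer exist).  An
    edge is present when either endpoint selected it, which preserves
    each node's strongest connections.  Ties at the k-th value break
    toward the lower ROI index for determinism.  Values are compared
    as signed (algebraically largest wins).
    """
    conn = np.asarray(conn, dtype=float)
    if conn.shape[0] != conn.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(conn, conn.T):
        raise ValueError("connectivity matrix must be symmetric")
    if k < 1:
        raise ValueError("k must be at least 1")
    q = conn.shape[0]
    adj = np.zeros((q, q), dtype=float)
    idx = np.arange(q)
    for i in range(q):
        row = conn[i].copy()
        candidates = idx[(idx != i) & (row > threshold)]
        if candidates.size == 0:
            continue
        # stable sort on (-value, index): ties go to the lower index
        order = candidates[np.lexsort((candidates, -row[candidates]))]
        chosen = order[:k]
        adj[i, chosen] = 1.0
        adj[chosen, i] = 1.0  # OR-symmetrization
    return adj


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization of the self-loop-augmented adjacency."""
    a = np.asarray(adjacency, dtype=float)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)


def graph_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Combinatorial Laplacian D - A (row sums zero)."""
    a = np.asarray(adjacency, dtype=float)
    return np.diag(a.sum(axis=1)) - a


def make_node_features(
    fc: np.ndarray | None,
    sc: np.ndarray | None,
    mode: str,
) -> np.ndarray:
    """Nodal feature matrix for the requested modality combination.

    Node i's feature vector is its FC row (``fc_only``), its SC row
    (``sc_only``) or the FC row followed by the SC row (``fc_sc``),
    giving d_in = Q or 2Q.
    """
    if mode == "fc_only":
        if fc is None:
            raise ValueError("fc_only mode requires an FC matrix")
        return np.asarray(fc, dtype=float).copy()
    if mode == "sc_only":
        if sc is None:
            raise ValueError("sc_only mode requires an SC matrix")
        return np.asarray(sc, dtype=float).copy()
    if mode == "fc_sc":
        if fc is None or sc is None:
            raise ValueError("fc_sc mode requires both FC and SC")
        fc = np.asarray(fc, dtype=float)
        sc = np.asarray(sc, dtype=float)
        if fc.shape[0] != sc.shape[0]:
            raise ValueError("FC and SC disagree on ROI count")
        return np.hstack([fc, sc])
    raise ValueError(f"unknown mode {mode!r}; expected fc_only, sc_only or fc_sc")
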