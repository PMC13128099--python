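"""Directed patient graph (DPG) construction and magnetic-Laplacian algebra.

Nodes are enhanced encounter windows. Two kinds of directed edges exist:
within-patient edges between consecutive windows (always present, so each
patient's progression is linked through a path), and similarity edges from
each node to its top-k Jaccard neighbors over the whole node set. Every edge
is oriented from the chronologically earlier node to the later one (ties
broken deterministically by node order), and carries the elapsed time in
days as its weight.

Direction is exposed to spectral methods through the magnetic Laplacian
L(q) = I − D_s^{-1/2} H(q) D_s^{-1/2}, with H(q) = A_s ⊙ exp(i·2πq(A−Aᵀ)),
A_s = (A+Aᵀ)/2 on 0/1 connectivity: a complex Hermitian matrix whose phase
encodes edge direction. At q=0 it reduces to the symmetrized normalized
Laplacian; q=0.25 gives maximal direction sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .featurize import FeaturizedCohort


def jaccard(u, v) -> float:
    """Jaccard similarity |u∧v| / |u∨v| of two equal-length binary vectors.

    Defined as 0 when both vectors are all-zero.
    """
    u = np.asarray(u).astype(bool)
    v = np.asarray(v).astype(bool)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    union = np.logical_or(u, v).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(u, v).sum() / union)


@dataclass
class ProgressionGraph:
    """Directed graph over all enhanced encounters of a cohort."""

    node_table: pd.DataFrame   # node_id, patient_id, window_index, date
    X: np.ndarray              # (n_nodes, F) binary node features
    labels: np.ndarray         # (n_nodes,) next-window state, -1 unlabeled
    states: np.ndarray         # (n_nodes,) own-window state
    src: np.ndarray            # edge sources
    dst: np.ndarray            # edge destinations
    elapsed_days: np.ndarray   # edge weights (days, >= 0)
    k: int
    feature_names: list

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def patient_ids(self) -> np.ndarray:
        return self.node_table["patient_id"].to_numpy()

    def adjacency(self, weighting: str = "binary",
                  tau: float = 365.0) -> sp.csr_matrix:
        """Directed adjacency; 'binary' 0/1 or 'exp_decay' exp(−Δdays/τ)."""
        if weighting == "binary":
            data = np.ones(self.n_edges)
        elif weighting == "elapsed":
            data = self.elapsed_days.astype(float)
        elif weighting == "exp_decay":
            data = np.exp(-self.elapsed_days / tau)
        else:
            raise ValueError(f"unknown weighting '{weighting}'")
        n = self.n_nodes
        return sp.csr_matrix((data, (self.src, self.dst)), shape=(n, n))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            zip(self.src.tolist(), self.dst.tolist(),
                self.elapsed_days.tolist()), weight="elapsed_days")
        return g

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"src_node_id": self.src, "dst_node_id": self.dst,
                      "elapsed_days": self.elapsed_days}
                     ).to_csv(d / "edges.csv", index=False)
        self.node_table.to_csv(d / "nodes.csv", index=False)


def _pairwise_topk(B: np.ndarray, k: int, chunk: int = 2048) -> np.ndarray:
    """Top-k Jaccard neighbors per row of a binary matrix (self excluded).

    Exact pairwise computation; ties broken by ascending node index, which
    equals (patient_id, window_index) order by construction.
    """
    n = B.shape[0]
    Bf = B.astype(np.float32)
    row_sums = Bf.sum(axis=1)
    out = np.empty((n, k), dtype=np.int64)
    kk = min(k + 32, n - 1)  # slack absorbs ties at the k-th boundary
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        inter = Bf[lo:hi] @ Bf.T                      # |u ∧ v|
        union = row_sums[lo:hi, None] + row_sums[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / union, 0.0)
        sim[np.arange(hi - lo), np.arange(lo, hi)] = -1.0  # exclude self
        cand = np.argpartition(-sim, kk - 1, axis=1)[:, :kk]
        cand_sim = np.take_along_axis(sim, cand, axis=1)
        order = np.lexsort((cand, -cand_sim), axis=1)[:, :k]
        out[lo:hi] = np.take_along_axis(cand, order, axis=1)
    return out


def build_dpg(feat: FeaturizedCohort, k: int = 25) -> ProgressionGraph:
    """Build the directed patient graph from featurized windows.

    For each node, its top-k Jaccard neighbors (over all nodes, own-patient
    nodes included) contribute candidate edges oriented earlier→later;
    consecutive within-patient windows are always connected. Duplicate edges
    are collapsed; self-loops never occur. The whole construction is
    deterministic: rebuilding from the same input yields the same edge list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows, X_parts, label_parts, state_parts = [], [], [], []
    node_id = 0
    for pid in feat.patients:
        pw = feat.windows[pid]
        for w in range(pw.n_windows):
            rows.append((node_id, pid, w, pw.window_starts[w]))
            node_id += 1
        X_parts.append(pw.X)
        label_parts.append(pw.labels)
        state_parts.append(pw.states)
    node_table = pd.DataFrame(rows, columns=["node_id", "patient_id",
                                             "window_index", "date"])
    X = np.vstack(X_parts)
    labels = np.concatenate(label_parts)
    states = np.concatenate(state_parts)
    n = X.shape[0]
    if k >= n:
        import warnings

        warnings.warn(f"k={k} >= number of nodes {n}; clamping to {n - 1}")
        k = n - 1

    dates = node_table["date"].to_numpy()
    day_number = (node_table["date"] - node_table["date"].min()
                  ).dt.days.to_numpy()

    neighbors = _pairwise_topk(X, k)
    src_list, dst_list = [], []
    node_idx = np.repeat(np.arange(n), k)
    nbr_idx = neighbors.ravel()
    # orient earlier -> later; same-date ties by node order (patient, window)
    earlier_first = (day_number[node_idx] < day_number[nbr_idx]) | (
        (day_number[node_idx] == day_number[nbr_idx]) & (node_idx < nbr_idx))
    src_sim = np.where(earlier_first, node_idx, nbr_idx)
    dst_sim = np.where(earlier_first, nbr_idx, node_idx)
    src_list.append(src_sim)
    dst_list.append(dst_sim)

    # within-patient consecutive-window chain
    same_patient = (node_table["patient_id"].to_numpy()[:-1]
                    == node_table["patient_id"].to_numpy()[1:])
    chain_src = np.flatnonzero(same_patient)
    src_list.append(chain_src)
    dst_list.append(chain_src + 1)

    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    keep = src != dst
    src, dst = src[keep], dst[keep]
    # deduplicate deterministically
    key = src.astype(np.int64) * n + dst
    order = np.argsort(key, kind="stable")
    key, src, dst = key[order], src[order], dst[order]
    uniq = np.ones(len(key), dtype=bool)
    uniq[1:] = key[1:] != key[:-1]
    src, dst = src[uniq], dst[uniq]
    elapsed = (day_number[dst] - day_number[src]).astype(np.int64)
    assert (elapsed >= 0).all(), "chronology violated"
    _ = dates  # dates retained in node_table

    return ProgressionGraph(node_table=node_table, X=X, labels=labels,
                            states=states, src=src, dst=dst,
                            elapsed_days=elapsed, k=k,
                            feature_names=list(feat.feature_space.names))


def _phase_modulate(A_s: sp.csr_matrix, conn: sp.spmatrix,
                    q: float) -> sp.csr_matrix:
    """H = A_s ⊙ exp(i·2πq·(conn − connᵀ)), computed sparsely.

    The phase Θ is supported on a subset of A_s's pattern, so
    H = A_s + A_s ⊙ (exp(iΘ) − 1) stays sparse and exact.
    """
    theta = (2.0 * np.pi * q * (conn - conn.T)).tocsr()
    theta.eliminate_zeros()
    E = theta.copy().astype(complex)
    E.data = np.exp(1j * theta.data) - 1.0
    return (A_s.astype(complex) + A_s.multiply(E)).tocsr()


@dataclass
class MagneticLaplacian:
    """Normalized magnetic Laplacian of a directed graph."""

    q: float
    L: sp.csr_matrix          # complex, Hermitian
    H: sp.csr_matrix          # phase-modulated symmetrized adjacency
    deg: np.ndarray           # symmetrized degrees


def magnetic_laplacian(graph, q: float = 0.25) -> MagneticLaplacian:
    """Magnetic Laplacian L(q) = I − D_s^{-1/2} H(q) D_s^{-1/2}.

    ``graph`` may be a ProgressionGraph or any scipy sparse / dense directed
    0/1 adjacency matrix. H(q) = A_s ⊙ exp(i·2πq·(A−Aᵀ)) with
    A_s = (A+Aᵀ)/2 on binary connectivity. Hermitian by construction, with a
    real spectrum contained in [0, 2]. Isolated nodes contribute a diagonal
    1 (their normalized degree term vanishes).
    """
    if not 0.0 <= q <= 0.25:
        raise ValueError(f"q must lie in [0, 0.25], got {q}")
    if isinstance(graph, ProgressionGraph):
        A = graph.adjacency("binary")
    else:
        A = sp.csr_matrix(graph)
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    A = (A > 0).astype(float)
    A.setdiag(0)
    A.eliminate_zeros()
    A_s = ((A + A.T) / 2.0).tocsr()
    H = _phase_modulate(A_s, A, q)
    deg = np.asarray(A_s.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    Dinv = sp.diags(dinv)
    L = sp.identity(A.shape[0], dtype=complex, format="csr") \
        - Dinv @ H @ Dinv
    return MagneticLaplacian(q=q, L=L.tocsr(), H=H.tocsr(), deg=deg)


def propagation_matrix(graph, q: float = 0.25,
                       weighting: str = "binary",
                       tau: float = 365.0) -> sp.csr_matrix:
    """Self-loop-augmented magnetic propagation operator for convolutions.

    P = D̃^{-1/2} (Ã_s ⊙ exp(iΘ)) D̃^{-1/2} with Ã_s = A_s + I. At q=0 and
    binary weighting this is the familiar renormalized GCN operator on the
    symmetrized graph. ``weighting='exp_decay'`` feeds exp(−Δdays/τ) edge
    magnitudes into A before symmetrization.
    """
    if isinstance(graph, ProgressionGraph):
        A = graph.adjacency(weighting, tau=tau)
    else:
        A = sp.csr_matrix(graph).astype(float)
    A.setdiag(0)
    A.eliminate_zeros()
    n = A.shape[0]
    conn = (A > 0).astype(float)
    A_s = ((A + A.T) / 2.0 + sp.identity(n)).tocsr()
    H = _phase_modulate(A_s, conn, q)
    deg = np.asarray(A_s.sum(axis=1)).ravel().real
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    Dinv = sp.diags(dinv)
    return (Dinv @ H @ Dinv).tocsr()
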