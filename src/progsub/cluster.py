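"""DTW time-series k-means over per-patient embedding sequences.

Patients have embedding sequences of unequal length (one learned vector per
90-day window), so similarity is measured by dynamic time warping with
pointwise Euclidean distance: the minimal cumulative cost over monotone
warping paths with unit steps {(1,0),(0,1),(1,1)}, boundary-aligned at both
ends. K-means alternates nearest-centroid assignment with DTW barycenter
averaging (DBA) centroid updates and minimizes

    J = Σ_i Σ_{j in C_i} DTW(H_j, μ_i).

Cluster validity uses the silhouette score and Davies–Bouldin index, both
under DTW; a clustering is conventionally deemed acceptable at SS > 0.25
and DBI < 1. Stability is assessed by refitting on 90% subsamples and
comparing full-cohort nearest-centroid assignments against the full-sample
solution with per-cluster Jaccard agreement after Hungarian label matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

try:  # optional JIT acceleration of the DP recursion
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]


@_njit(cache=False)
def _dtw_table(cost):  # pragma: no cover - exercised via dtw()
    n, m = cost.shape
    D = np.empty((n, m))
    D[0, 0] = cost[0, 0]
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
    for i in range(1, n):
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost[i, j] + best
    return D


def _as_seq(S) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] == 0:
        raise ValueError("empty sequence")
    return S


def dtw(S, S2, return_path: bool = False):
    """DTW distance between two sequences of d-dimensional points.

    Returns the minimal cumulative Euclidean cost over all admissible
    warping paths; with ``return_path=True`` also returns one optimal path
    as a list of (i, j) index pairs satisfying the boundary, monotonicity
    and unit-step conditions.
    """
    S, S2 = _as_seq(S), _as_seq(S2)
    if S.shape[1] != S2.shape[1]:
        raise ValueError("sequence dimensions differ")
    cost = cdist(S, S2)
    D = _dtw_table(cost)
    dist = float(D[-1, -1])
    if not return_path:
        return dist
    i, j = S.shape[0] - 1, S2.shape[0] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            steps = ((D[i - 1, j - 1], i - 1, j - 1),
                     (D[i - 1, j], i - 1, j),
                     (D[i, j - 1], i, j - 1))
            _, i, j = min(steps)
        path.append((i, j))
    path.reverse()
    return dist, path


def scale_sequences(sequences) -> list:
    """Per-dimension mean/variance scaling across all time points.

    Standard preprocessing for DTW k-means on learned multivariate series:
    outcome-trained embeddings put very unequal variance on different
    dimensions, and unscaled Euclidean pointwise distances would be
    dominated by the few largest ones. Constant dimensions are left at zero.
    """
    seqs = [_as_seq(s) for s in sequences]
    allpts = np.vstack(seqs)
    mu = allpts.mean(axis=0)
    sd = allpts.std(axis=0)
    sd[sd == 0] = 1.0
    return [(s - mu) / sd for s in seqs]


def whiten_embeddings(embeddings: np.ndarray) -> np.ndarray:
    """Decorrelate and equalize the variance of embedding dimensions.

    Outcome-trained node embeddings concentrate most of their variance in a
    few directions aligned with the supervised task; whitening (PCA scores
    scaled to unit variance) gives every component of the learned
    representation equal footing before distances are computed, in the
    spirit of all-but-the-top post-processing of learned embeddings.
    """
    E = np.asarray(embeddings, dtype=float)
    E0 = E - E.mean(axis=0)
    U, S, _ = np.linalg.svd(E0, full_matrices=False)
    keep = S > S[0] * 1e-12
    return U[:, keep] * np.sqrt(len(E0))


def patient_subspace(embeddings: np.ndarray, patient_ids,
                     n_components: int | None = None) -> np.ndarray:
    """Project whitened embeddings onto the between-patient subspace.

    Two-level (multilevel) PCA: node embeddings are whitened, patient mean
    embeddings are computed, and nodes are projected onto the leading
    principal directions of the *patient-mean* variation. Progression
    subphenotypes are patient-level structure; window-to-window variation
    within a patient is mostly encounter noise and state dynamics, so
    restricting distances to the between-patient subspace raises the
    signal-to-noise of the subsequent DTW clustering. Default dimension:
    a quarter of the embedding width (at least 4).
    """
    W = whiten_embeddings(embeddings)
    pid = np.asarray(patient_ids)
    if n_components is None:
        n_components = max(4, W.shape[1] // 4)
    n_components = min(n_components, W.shape[1])
    means = np.stack([W[pid == p].mean(axis=0)
                      for p in dict.fromkeys(pid.tolist())])
    means -= means.mean(axis=0)
    _, _, Vt = np.linalg.svd(means, full_matrices=False)
    return W @ Vt[:n_components].T


def pairwise_dtw(sequences) -> np.ndarray:
    """Symmetric matrix of DTW distances between all sequence pairs."""
    seqs = [_as_seq(s) for s in sequences]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw(seqs[i], seqs[j])
    return D


def _resample(seq: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of a sequence to a fixed length."""
    seq = _as_seq(seq)
    if seq.shape[0] == length:
        return seq.copy()
    src = np.linspace(0.0, 1.0, seq.shape[0])
    tgt = np.linspace(0.0, 1.0, length)
    return np.stack([np.interp(tgt, src, seq[:, d])
                     for d in range(seq.shape[1])], axis=1)


def dba(sequences, init: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """DTW barycenter averaging: centroid update for k-means under DTW."""
    centroid = _as_seq(init).copy()
    for _ in range(n_iter):
        sums = np.zeros_like(centroid)
        counts = np.zeros(centroid.shape[0])
        for seq in sequences:
            seq = _as_seq(seq)
            _, path = dtw(centroid, seq, return_path=True)
            for i, j in path:
                sums[i] += seq[j]
                counts[i] += 1
        new = sums / np.maximum(counts, 1.0)[:, None]
        if np.allclose(new, centroid, atol=1e-10):
            break
        centroid = new
    return centroid


@dataclass
class ClusterModel:
    """Fitted DTW k-means: centroids, assignments and validity scores."""

    K: int
    centroids: list
    assignments: np.ndarray
    objective: float                  # J at convergence
    objective_history: list = field(default_factory=list)
    silhouette: float | None = None
    davies_bouldin: float | None = None
    patient_ids: list | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = (self.patient_ids if self.patient_ids is not None
               else list(range(len(self.assignments))))
        return pd.DataFrame({"patient_id": ids, "cluster": self.assignments})


def _assign(seqs, centroids) -> tuple:
    d = np.array([[dtw(s, c) for c in centroids] for s in seqs])
    labels = d.argmin(axis=1)
    return labels, float(d[np.arange(len(seqs)), labels].sum())


def _kmeanspp_init(seqs, K, rng) -> list:
    idx = [int(rng.integers(len(seqs)))]
    d2 = np.array([dtw(s, seqs[idx[0]]) for s in seqs]) ** 2
    for _ in range(K - 1):
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(len(seqs), 1 / len(seqs))
        nxt = int(rng.choice(len(seqs), p=probs))
        idx.append(nxt)
        d2 = np.minimum(d2, np.array([dtw(s, seqs[nxt])
                                      for s in seqs]) ** 2)
    return idx


def ts_kmeans(sequences, K: int, seed: int = 0, n_init: int = 5,
              max_iter: int = 15, patient_ids=None) -> ClusterModel:
    """Time-series k-means under DTW with DBA centroid updates.

    k-means++-style seeding, ``n_init`` restarts, centroids of fixed length
    equal to the median sequence length. The objective J is non-increasing
    across iterations within a restart (a non-improving update terminates
    the restart); an emptied cluster is re-seeded from the sequence farthest
    from its centroid.
    """
    seqs = [_as_seq(s) for s in sequences]
    if K < 1 or K > len(seqs):
        raise ValueError(f"K must lie in [1, {len(seqs)}]")
    rng = np.random.default_rng(seed)
    cent_len = int(np.median([s.shape[0] for s in seqs]))

    best = None
    for _ in range(n_init):
        init_idx = _kmeanspp_init(seqs, K, rng)
        centroids = [_resample(seqs[i], cent_len) for i in init_idx]
        labels, J = _assign(seqs, centroids)
        history = [J]
        for _ in range(max_iter):
            new_centroids = []
            for k in range(K):
                members = [seqs[i] for i in np.flatnonzero(labels == k)]
                if not members:  # re-seed from the farthest sequence
                    far = int(np.argmax([dtw(s, centroids[labels[i]])
                                         for i, s in enumerate(seqs)]))
                    new_centroids.append(_resample(seqs[far], cent_len))
                else:
                    new_centroids.append(dba(members, centroids[k]))
            new_labels, new_J = _assign(seqs, new_centroids)
            if new_J > J - 1e-10:   # keep J monotone non-increasing
                if new_J < J:
                    centroids, labels, J = new_centroids, new_labels, new_J
                    history.append(J)
                break
            centroids, labels, J = new_centroids, new_labels, new_J
            history.append(J)
        if best is None or J < best.objective:
            best = ClusterModel(K=K, centroids=centroids,
                                assignments=labels, objective=J,
                                objective_history=history,
                                patient_ids=list(patient_ids)
                                if patient_ids is not None else None)
    return best


def assign_to_centroids(sequences, centroids) -> np.ndarray:
    labels, _ = _assign([_as_seq(s) for s in sequences], centroids)
    return labels


def silhouette_dtw(sequences, assignments, D: np.ndarray | None = None):
    """Mean silhouette (b−a)/max(a,b) on DTW distances, in [−1, 1].

    Returns NaN (with a warning) when undefined, e.g. a single cluster or
    only singleton clusters.
    """
    labels = np.asarray(assignments)
    if D is None:
        D = pairwise_dtw(sequences)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts == 1).all():
        warnings.warn("silhouette undefined for this clustering")
        return float("nan")
    return float(silhouette_score(D, labels, metric="precomputed"))


def dbi_dtw(sequences, model: ClusterModel) -> float:
    """Davies–Bouldin index under DTW: mean_i max_{j≠i} (σ_i+σ_j)/Δ_ij.

    σ_i is the mean DTW distance of cluster i's members to its centroid and
    Δ_ij the DTW distance between centroids. Coincident centroids yield an
    infinite ratio (flagged with a warning).
    """
    seqs = [_as_seq(s) for s in sequences]
    K = model.K
    sigma = np.zeros(K)
    for k in range(K):
        members = np.flatnonzero(model.assignments == k)
        if len(members):
            sigma[k] = np.mean([dtw(seqs[i], model.centroids[k])
                                for i in members])
    ratios = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            delta = dtw(model.centroids[i], model.centroids[j])
            if delta == 0:
                warnings.warn("coincident centroids: DBI diverges")
                r = np.inf
            else:
                r = (sigma[i] + sigma[j]) / delta
            ratios[i, j] = ratios[j, i] = r
    np.fill_diagonal(ratios, -np.inf)
    return float(np.mean(ratios.max(axis=1)))


def select_k(sequences, k_range=range(2, 11), seed: int = 0,
             n_init: int = 5, D: np.ndarray | None = None) -> pd.DataFrame:
    """Scan K and report J, SS, DBI and the SS>0.25 ∧ DBI<1 acceptability.

    The final choice of K is left to the caller; this table is the
    quantitative half of that decision.
    """
    seqs = [_as_seq(s) for s in sequences]
    if D is None:
        D = pairwise_dtw(seqs)
    rows = []
    for K in k_range:
        model = ts_kmeans(seqs, K, seed=seed, n_init=n_init)
        ss = silhouette_dtw(seqs, model.assignments, D=D)
        dbi = dbi_dtw(seqs, model)
        rows.append({"K": K, "J": model.objective, "SS": ss, "DBI": dbi,
                     "acceptable": bool(ss > 0.25 and dbi < 1.0)})
    return pd.DataFrame(rows)


def _match_clusters(ref_labels, labels, K) -> np.ndarray:
    """Hungarian matching of cluster ids by assignment overlap counts."""
    overlap = np.zeros((K, K))
    for a, b in zip(ref_labels, labels):
        overlap[a, b] += 1
    row, col = linear_sum_assignment(-overlap)
    mapping = np.arange(K)
    mapping[col] = row
    return mapping


def bootstrap_stability(sequences, K: int, full_model: ClusterModel | None
                        = None, n_iter: int = 100, frac: float = 0.9,
                        seed: int = 0, n_init: int = 3,
                        D: np.ndarray | None = None) -> dict:
    """Cluster-stability bootstrap against the full-sample solution.

    Each iteration refits k-means on a ``frac`` subsample, assigns *all*
    sequences to the subsample centroids, Hungarian-matches cluster labels
    to the full-sample solution, and records per-cluster Jaccard agreement
    of the member sets plus SS and DBI of the induced clustering.
    """
    seqs = [_as_seq(s) for s in sequences]
    n = len(seqs)
    rng = np.random.default_rng(seed)
    if full_model is None:
        full_model = ts_kmeans(seqs, K, seed=seed, n_init=max(n_init, 5))
    if D is None:
        D = pairwise_dtw(seqs)
    ref = full_model.assignments
    per_iter = []
    for it in range(n_iter):
        m = max(K, int(round(frac * n)))
        sub = rng.choice(n, size=m, replace=False)
        sub_model = ts_kmeans([seqs[i] for i in sub], K,
                              seed=int(rng.integers(2 ** 31)), n_init=n_init)
        labels = assign_to_centroids(seqs, sub_model.centroids)
        mapping = _match_clusters(ref, labels, K)
        matched_centroids = [None] * K
        for b in range(K):
            matched_centroids[mapping[b]] = sub_model.centroids[b]
        labels = mapping[labels]
        jacc = []
        for k in range(K):
            a, b = set(np.flatnonzero(ref == k)), \
                set(np.flatnonzero(labels == k))
            union = a | b
            jacc.append(len(a & b) / len(union) if union else 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ss = silhouette_dtw(seqs, labels, D=D)
            dbi = dbi_dtw(seqs, ClusterModel(
                K=K, centroids=matched_centroids, assignments=labels,
                objective=float("nan")))
        per_iter.append({"iteration": it, "jaccard_mean": float(np.mean(jacc)),
                         "jaccard_per_cluster": jacc, "SS": ss, "DBI": dbi})
    table = pd.DataFrame(per_iter)
    return {
        "per_iteration": table,
        "jaccard_mean": float(table["jaccard_mean"].mean()),
        "jaccard_sd": float(table["jaccard_mean"].std(ddof=1))
        if n_iter > 1 else float("nan"),
        "SS_mean": float(table["SS"].mean()),
        "SS_sd": float(table["SS"].std(ddof=1)) if n_iter > 1
        else float("nan"),
        "DBI_mean": float(table["DBI"].mean()),
        "DBI_sd": float(table["DBI"].std(ddof=1)) if n_iter > 1
        else float("nan"),
        "full_model": full_model,
    }


def embedding_sequences(graph, embeddings: np.ndarray) -> tuple:
    """Group node embeddings into chronological per-patient sequences H^n."""
    pids = graph.patient_ids()
    order = np.asarray(graph.node_table["window_index"])
    out_ids, out_seqs = [], []
    for pid in dict.fromkeys(pids):  # preserve node order
        mask = pids == pid
        idx = np.flatnonzero(mask)[np.argsort(order[mask], kind="stable")]
        out_ids.append(pid)
        out_seqs.append(np.asarray(embeddings, dtype=float)[idx])
    return out_ids, out_seqs
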