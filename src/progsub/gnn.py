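"""Outcome-oriented representation learning on the directed patient graph.

A two-layer graph encoder plus a fully connected softmax head predicts each
window's next-window state (PreMCI / MCI / AD); the prediction loss trains
the whole model end-to-end, so the learned node embeddings h_v are oriented
toward progression outcomes. Four encoder variants are provided:

* ``magnet`` — spectral convolution with the magnetic Laplacian's
  phase-modulated propagation operator; the complex signal is carried as
  separate real/imaginary channels with shared real weights and the head
  consumes their concatenation. The only variant that sees edge direction.
* ``gcn`` — renormalized graph convolution on the symmetrized graph.
* ``sage`` — GraphSAGE with mean aggregation on the symmetrized graph.
* ``gat`` — single-head additive attention on the symmetrized graph.

Training is full-graph (transductive) with patient-level 70/10/20 masks:
no patient contributes nodes to more than one of train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import confusion_matrix, roc_auc_score

from . import _autograd as ag
from .dpg import ProgressionGraph, propagation_matrix

N_CLASSES = 3

VARIANTS = ("magnet", "gcn", "gat", "sage")


@dataclass
class EncoderConfig:
    variant: str = "magnet"
    embedding_dim: int = 32
    hidden_dim: int = 64
    loss: str = "focal"              # "focal" or "cross_entropy"
    focal_gamma: float = 2.0
    label_smoothing: float = 0.0     # caps optimal logit magnitudes
    learning_rate: float = 1e-2
    epochs: int = 100
    patience: int = 20
    q: float = 0.25                  # magnetic charge, magnet variant only
    edge_weighting: str = "binary"   # "binary" or "exp_decay"
    tau: float = 365.0
    train_frac: float = 0.7
    val_frac: float = 0.1
    seed: int = 0

    def validate(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if self.variant == "magnet" and self.embedding_dim % 2:
            raise ValueError("magnet embedding_dim must be even (real||imag)")
        if self.loss not in ("focal", "cross_entropy"):
            raise ValueError("loss must be 'focal' or 'cross_entropy'")


def focal_loss(probabilities, labels, gamma: float) -> float:
    """Mean focal loss −(1−p_true)^γ·log(p_true) over samples.

    ``probabilities`` are rows of class probabilities; γ=0 recovers
    cross-entropy exactly. Zero probabilities are clipped at 1e−12.
    """
    probs = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p_true = np.clip(probs[np.arange(len(labels)), labels], 1e-12, 1.0)
    return float(np.mean(-((1.0 - p_true) ** gamma) * np.log(p_true)))


# ---------------------------------------------------------------------------
# encoders


def _symmetrize(A: sp.spmatrix) -> sp.csr_matrix:
    A = sp.csr_matrix(A).astype(float)
    A.setdiag(0)
    A.eliminate_zeros()
    S = A.maximum(A.T)
    return S.tocsr()


class _EncoderBase:
    """Two graph layers; subclasses define propagation."""

    def __init__(self, A: sp.spmatrix, X: np.ndarray, cfg: EncoderConfig):
        self.cfg = cfg
        self.X = np.asarray(X, dtype=float)
        self.n, self.in_dim = self.X.shape
        rng = np.random.default_rng(cfg.seed)
        self._init(A, rng)
        self.head_W = ag.glorot(rng, cfg.embedding_dim, N_CLASSES)
        self.head_b = ag.zeros(1, N_CLASSES)

    def parameters(self) -> list:
        return self._params + [self.head_W, self.head_b]

    def forward(self):
        emb = self._embed(ag.Tensor(self.X))
        logits = emb @ self.head_W + self.head_b
        return emb, logits


class MagNetEncoder(_EncoderBase):
    def _init(self, A, rng):
        cfg = self.cfg
        P = propagation_matrix(A, q=cfg.q)
        self.Pr, self.Pi = P.real.tocsr(), P.imag.tocsr()
        self.PrT, self.PiT = self.Pr.T.tocsr(), self.Pi.T.tocsr()
        half = cfg.embedding_dim // 2
        self.W1 = ag.glorot(rng, self.in_dim, cfg.hidden_dim)
        self.b1 = ag.zeros(1, cfg.hidden_dim)
        self.W2 = ag.glorot(rng, cfg.hidden_dim, half)
        self.b2 = ag.zeros(1, half)
        self._params = [self.W1, self.b1, self.W2, self.b2]

    def _cprop(self, xr, xi):
        rr = ag.spmm(self.Pr, xr, self.PrT) - ag.spmm(self.Pi, xi, self.PiT)
        ri = ag.spmm(self.Pr, xi, self.PrT) + ag.spmm(self.Pi, xr, self.PiT)
        return rr, ri

    def _embed(self, X):
        zr, zi = self._cprop(X, ag.Tensor(np.zeros_like(X.data)))
        zr = ag.relu(zr @ self.W1 + self.b1)
        zi = ag.relu(zi @ self.W1 + self.b1)
        zr, zi = self._cprop(zr, zi)
        zr = zr @ self.W2 + self.b2
        zi = zi @ self.W2 + self.b2
        return ag.concat([zr, zi], axis=1)


class GCNEncoder(_EncoderBase):
    def _init(self, A, rng):
        cfg = self.cfg
        self.P = propagation_matrix(_symmetrize(A), q=0.0).real.tocsr()
        self.PT = self.P.T.tocsr()
        self.W1 = ag.glorot(rng, self.in_dim, cfg.hidden_dim)
        self.b1 = ag.zeros(1, cfg.hidden_dim)
        self.W2 = ag.glorot(rng, cfg.hidden_dim, cfg.embedding_dim)
        self.b2 = ag.zeros(1, cfg.embedding_dim)
        self._params = [self.W1, self.b1, self.W2, self.b2]

    def _embed(self, X):
        h = ag.relu(ag.spmm(self.P, X, self.PT) @ self.W1 + self.b1)
        return ag.spmm(self.P, h, self.PT) @ self.W2 + self.b2


class SAGEEncoder(_EncoderBase):
    def _init(self, A, rng):
        cfg = self.cfg
        S = _symmetrize(A)
        deg = np.asarray(S.sum(axis=1)).ravel()
        self.M = (sp.diags(1.0 / np.maximum(deg, 1.0)) @ S).tocsr()
        self.MT = self.M.T.tocsr()  # mean aggregator and its adjoint
        d = (self.in_dim, cfg.hidden_dim, cfg.embedding_dim)
        self.Wself1 = ag.glorot(rng, d[0], d[1])
        self.Wnb1 = ag.glorot(rng, d[0], d[1])
        self.b1 = ag.zeros(1, d[1])
        self.Wself2 = ag.glorot(rng, d[1], d[2])
        self.Wnb2 = ag.glorot(rng, d[1], d[2])
        self.b2 = ag.zeros(1, d[2])
        self._params = [self.Wself1, self.Wnb1, self.b1,
                        self.Wself2, self.Wnb2, self.b2]

    def _embed(self, X):
        h = ag.relu(X @ self.Wself1 + ag.spmm(self.M, X, self.MT)
                    @ self.Wnb1 + self.b1)
        return (h @ self.Wself2 + ag.spmm(self.M, h, self.MT) @ self.Wnb2
                + self.b2)


class GATEncoder(_EncoderBase):
    def _init(self, A, rng):
        cfg = self.cfg
        S = _symmetrize(A) + sp.identity(self.X.shape[0])
        coo = S.tocoo()
        self.e_src, self.e_dst = coo.row, coo.col
        d = (self.in_dim, cfg.hidden_dim, cfg.embedding_dim)
        self.W1 = ag.glorot(rng, d[0], d[1])
        self.a1s = ag.glorot(rng, d[1], 1)
        self.a1d = ag.glorot(rng, d[1], 1)
        self.W2 = ag.glorot(rng, d[1], d[2])
        self.a2s = ag.glorot(rng, d[2], 1)
        self.a2d = ag.glorot(rng, d[2], 1)
        self._params = [self.W1, self.a1s, self.a1d,
                        self.W2, self.a2s, self.a2d]

    def _attend(self, X, W, a_s, a_d):
        Z = X @ W
        zs = ag.gather_rows(Z, self.e_src)
        zd = ag.gather_rows(Z, self.e_dst)
        e = ag.leaky_relu(zs @ a_s + zd @ a_d)
        # segment softmax over incoming edges of each destination node;
        # the per-segment max is a constant shift (softmax is shift-invariant)
        emax = np.full(self.n, -np.inf)
        np.maximum.at(emax, self.e_dst, e.data.ravel())
        ee = ag.exp(e - emax[self.e_dst, None])
        denom = ag.segment_sum(ee, self.e_dst, self.n)
        alpha = ee * ag.pow_const(ag.gather_rows(denom, self.e_dst), -1.0)
        return ag.segment_sum(alpha * zs, self.e_dst, self.n)

    def _embed(self, X):
        h = ag.relu(self._attend(X, self.W1, self.a1s, self.a1d))
        return self._attend(h, self.W2, self.a2s, self.a2d)


_ENCODERS = {"magnet": MagNetEncoder, "gcn": GCNEncoder,
             "sage": SAGEEncoder, "gat": GATEncoder}


def make_encoder(A, X, cfg: EncoderConfig) -> _EncoderBase:
    cfg.validate()
    return _ENCODERS[cfg.variant](A, X, cfg)


# ---------------------------------------------------------------------------
# patient-level splitting, training, evaluation


@dataclass
class PatientSplit:
    train_patients: set
    val_patients: set
    test_patients: set

    def masks(self, graph: ProgressionGraph):
        pids = graph.patient_ids()
        labeled = graph.labels >= 0
        return {
            "train": labeled & np.isin(pids, list(self.train_patients)),
            "val": labeled & np.isin(pids, list(self.val_patients)),
            "test": labeled & np.isin(pids, list(self.test_patients)),
        }


def split_patients(patient_ids, train_frac=0.7, val_frac=0.1,
                   seed=0) -> PatientSplit:
    """Random patient-level split; every node of a patient stays together."""
    pids = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(pids)
    n = len(pids)
    n_train = int(round(train_frac * n))
    n_val = int(round(val_frac * n))
    return PatientSplit(train_patients=set(pids[:n_train]),
                        val_patients=set(pids[n_train:n_train + n_val]),
                        test_patients=set(pids[n_train + n_val:]))


def _masked_loss(logits, labels_onehot_masked, n_masked, cfg, mask=None):
    logp = ag.log_softmax(logits)
    eps = cfg.label_smoothing
    if eps > 0.0 and mask is not None:
        # smoothed targets on masked rows only; off-mask rows stay zero
        Y = labels_onehot_masked.data
        Y_s = np.where(mask[:, None], Y * (1.0 - eps) + eps / N_CLASSES, 0.0)
        return (-1.0 / n_masked) * (logp * ag.Tensor(Y_s)).sum()
    lt = (logp * labels_onehot_masked).sum(axis=1)   # log p_true, 0 off-mask
    if cfg.loss == "cross_entropy" or cfg.focal_gamma == 0.0:
        return (-1.0 / n_masked) * lt.sum()
    p = ag.exp(lt)  # off-mask rows contribute (1-1)^γ·0 = 0
    mod = ag.pow_const(1.0 - p + 1e-12, cfg.focal_gamma)
    return (-1.0 / n_masked) * (mod * lt).sum()


@dataclass
class TrainResult:
    encoder: _EncoderBase
    cfg: EncoderConfig
    split: PatientSplit
    history: list = field(default_factory=list)
    best_epoch: int = -1

    def embeddings(self) -> np.ndarray:
        """Learned node embeddings h_v (side-effect-free extraction)."""
        emb, _ = self.encoder.forward()
        return emb.data.copy()

    def predict_proba(self) -> np.ndarray:
        _, logits = self.encoder.forward()
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def _onehot_masked(labels, mask):
    Y = np.zeros((len(labels), N_CLASSES))
    idx = np.flatnonzero(mask)
    Y[idx, labels[idx]] = 1.0
    return Y


def train(graph: ProgressionGraph, cfg: EncoderConfig,
          split: PatientSplit | None = None,
          labels: np.ndarray | None = None) -> TrainResult:
    """Train an encoder end-to-end on next-window state prediction.

    The best checkpoint by validation loss is restored before returning.
    ``labels`` overrides the graph's labels (used for shuffled-label nulls).
    """
    cfg.validate()
    labels = graph.labels if labels is None else np.asarray(labels)
    if split is None:
        split = split_patients(graph.patient_ids(), cfg.train_frac,
                               cfg.val_frac, seed=cfg.seed)
    masks = split.masks(graph)
    if not masks["train"].any():
        raise ValueError("no labeled training nodes")
    Y_train = _onehot_masked(labels, masks["train"])
    Y_val = _onehot_masked(labels, masks["val"])
    n_train = int(masks["train"].sum())
    n_val = max(int(masks["val"].sum()), 1)

    A = graph.adjacency(cfg.edge_weighting, tau=cfg.tau)
    enc = make_encoder(A, graph.X, cfg)
    opt = ag.Adam(enc.parameters(), lr=cfg.learning_rate)
    result = TrainResult(encoder=enc, cfg=cfg, split=split)

    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        _, logits = enc.forward()
        loss = _masked_loss(logits, ag.Tensor(Y_train), n_train, cfg,
                            mask=masks["train"])
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {loss.data}")
        if masks["val"].any():
            val_loss = float(_masked_loss(logits, ag.Tensor(Y_val),
                                          n_val, cfg,
                                          mask=masks["val"]).data)
        else:
            val_loss = float(loss.data)
        result.history.append((float(loss.data), val_loss))
        # checkpoint the parameters that *produced* this validation loss
        if val_loss < best_val - 1e-9:
            best_val, since_best = val_loss, 0
            best_state = [p.data.copy() for p in enc.parameters()]
            result.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        loss.backward()
        opt.step()
    if best_state is not None:
        for p, d in zip(enc.parameters(), best_state):
            p.data = d
    return result


def evaluate(result: TrainResult, graph: ProgressionGraph,
             which: str = "test", labels: np.ndarray | None = None) -> dict:
    """One-vs-rest AUROC, sensitivity, specificity, precision per class.

    A class absent from the split yields NaN metrics (flagged via the
    ``undefined`` list) rather than a silent zero. ``macro_auroc`` averages
    over the defined classes.
    """
    labels = graph.labels if labels is None else np.asarray(labels)
    mask = result.split.masks(graph)[which]
    probs = result.predict_proba()[mask]
    y = labels[mask]
    pred = probs.argmax(axis=1)
    cm = confusion_matrix(y, pred, labels=list(range(N_CLASSES)))
    out = {"n": int(mask.sum()), "per_class": {}, "undefined": []}
    aurocs = []
    for c in range(N_CLASSES):
        pos = y == c
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = cm.sum() - tp - fn - fp
        m = {}
        if pos.any() and (~pos).any():
            m["auroc"] = float(roc_auc_score(pos, probs[:, c]))
            aurocs.append(m["auroc"])
        else:
            m["auroc"] = float("nan")
            out["undefined"].append(c)
        m["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
        m["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
        m["precision"] = tp / (tp + fp) if (tp + fp) else float("nan")
        out["per_class"][c] = m
    out["macro_auroc"] = float(np.mean(aurocs)) if aurocs else float("nan")
    out["accuracy"] = float((pred == y).mean()) if len(y) else float("nan")
    return out


def cross_validate(graph: ProgressionGraph, cfg: EncoderConfig,
                   n_folds: int = 10) -> list:
    """Patient-level k-fold evaluation; returns one metrics dict per fold."""
    pids = sorted(set(graph.patient_ids()))
    rng = np.random.default_rng(cfg.seed)
    rng.shuffle(pids)
    folds = np.array_split(np.asarray(pids), n_folds)
    reports = []
    for i, test_pids in enumerate(folds):
        rest = [p for p in pids if p not in set(test_pids.tolist())]
        n_val = max(1, len(rest) // 8)
        split = PatientSplit(train_patients=set(rest[n_val:]),
                             val_patients=set(rest[:n_val]),
                             test_patients=set(test_pids.tolist()))
        res = train(graph, replace(cfg, seed=cfg.seed + i), split=split)
        reports.append(evaluate(res, graph, "test"))
    return reports
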