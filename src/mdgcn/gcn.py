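"""Graph convolutional network over MDP nodes, implemented in numpy.

The propagation rule is the renormalised graph convolution

    H^{l+1} = sigma( D~^{-1/2} (A + I) D~^{-1/2} H^l W^l )

followed by a dense head mapping the last hidden layer to a single logit;
association scores are sigmoid-mapped logits.  Training minimises binary
cross-entropy over the train-role nodes, either on the full graph or on
edge-sampled induced subgraphs with the sampler's bias corrections: each
node's loss is weighted by ``1 / lambda_v`` (capped) and each aggregation
term ``(u, v)`` inside a subgraph is divided by ``alpha_{u,v}``.

The network is small (two convolution layers by default), so a hand-written
backward pass plus Adam keeps the whole pipeline dependency-light and
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .pair_graph import MDPNodeTable, PairGraph
from .sampler import (
    EdgeProbabilityTable,
    NormalizationCoefficients,
    sample_subgraph,
)
from .similarity import InputError

__all__ = [
    "GCNConfig",
    "TrainedModel",
    "normalized_adjacency",
    "gcn_layer",
    "train",
    "predict_scores",
]

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass
class GCNConfig:
    """Hyperparameters of the classifier.

    ``hidden`` are the widths of the graph-convolution layers; the dense head
    always maps the last width to one logit.  ``edges_per_batch`` defaults to
    ``n_edges // batches_per_epoch`` at train time.
    """

    hidden: tuple[int, ...] = (128, 64)
    activation: str = "relu"
    dropout: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 200
    batches_per_epoch: int = 20
    edges_per_batch: int | None = None
    lambda_cap: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise InputError(f"unknown activation {self.activation!r}")
        if not self.hidden:
            raise InputError("need at least one convolution layer")
        if not 0.0 <= self.dropout < 1.0:
            raise InputError("dropout must be in [0, 1)")


@dataclass
class TrainedModel:
    """Weights, training history and the config snapshot of a fitted GCN."""

    conv_weights: list[np.ndarray]
    out_weight: np.ndarray
    out_bias: float
    config: GCNConfig
    loss_history: list[float] = field(default_factory=list)
    input_dim: int = 0

    def save(self, path) -> None:
        """Checkpoint to a single .npz archive; round-trips bit-exactly."""
        cfg = asdict(self.config)
        cfg["hidden"] = list(cfg["hidden"])
        arrays = {f"conv_{i}": w for i, w in enumerate(self.conv_weights)}
        np.savez(
            path,
            out_weight=self.out_weight,
            out_bias=np.array(self.out_bias),
            loss_history=np.array(self.loss_history),
            meta=np.frombuffer(
                json.dumps({"config": cfg, "input_dim": self.input_dim}).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            cfg = meta["config"]
            cfg["hidden"] = tuple(cfg["hidden"])
            n_conv = sum(1 for k in z.files if k.startswith("conv_"))
            return cls(
                conv_weights=[z[f"conv_{i}"] for i in range(n_conv)],
                out_weight=z["out_weight"],
                out_bias=float(z["out_bias"]),
                config=GCNConfig(**cfg),
                loss_history=z["loss_history"].tolist(),
                input_dim=meta["input_dim"],
            )


# ---------------------------------------------------------------------------
# propagation primitives
# ---------------------------------------------------------------------------


def normalized_adjacency(graph: PairGraph) -> sp.csr_matrix:
    """Renormalised adjacency D~^{-1/2} (A + I) D~^{-1/2} (binary A)."""
    if graph.n_nodes < 1:
        raise InputError("empty graph")
    a_tilde = graph.adjacency() + sp.eye(graph.n_nodes, format="csr")
    return _sym_normalize(a_tilde)


def _sym_normalize(a_tilde: sp.spmatrix) -> sp.csr_matrix:
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    pos = deg > 0
    inv_sqrt[pos] = 1.0 / np.sqrt(deg[pos])
    d = sp.diags(inv_sqrt)
    return (d @ a_tilde @ d).tocsr()


def gcn_layer(h: np.ndarray, a_norm, w: np.ndarray, activation="identity") -> np.ndarray:
    """One convolution: activation(A_norm @ H @ W)."""
    act = _ACTIVATIONS[activation][0] if isinstance(activation, str) else activation
    h = np.asarray(h, dtype=float)
    w = np.asarray(w, dtype=float)
    if h.shape[1] != w.shape[0]:
        raise InputError(f"shape mismatch: H is {h.shape}, W is {w.shape}")
    return act(a_norm @ (h @ w))


def _subgraph_adjacency(
    graph: PairGraph,
    nodes: np.ndarray,
    induced_edges: np.ndarray,
    coeffs: NormalizationCoefficients | None,
) -> sp.csr_matrix:
    """Renormalised adjacency of an induced subgraph with alpha correction."""
    local = {int(g): i for i, g in enumerate(nodes)}
    n = len(nodes)
    if len(induced_edges):
        u = np.array([local[int(x)] for x in induced_edges[:, 0]])
        v = np.array([local[int(x)] for x in induced_edges[:, 1]])
        w = np.ones(len(u))
        if coeffs is not None:
            alpha = np.asarray(
                coeffs.alpha[induced_edges[:, 0], induced_edges[:, 1]]
            ).ravel()
            w = np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), 1.0)
        a = sp.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(n, n),
        ).tocsr()
    else:
        a = sp.csr_matrix((n, n))
    return _sym_normalize(a + sp.eye(n, format="csr"))


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _forward(a_norm, x, model_params, act_name, dropout=0.0, rng=None):
    """Forward pass; returns logits and the caches needed for backprop."""
    act, _ = _ACTIVATIONS[act_name]
    conv_ws, w_out, b_out = model_params
    caches = []
    h = x
    for w in conv_ws:
        ah = a_norm @ h           # aggregate then transform
        z = ah @ w
        hn = act(z)
        mask = None
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(hn.shape) >= dropout) / (1.0 - dropout)
            hn = hn * mask
        caches.append((h, ah, z, mask))
        h = hn
    logits = h @ w_out + b_out
    return logits.ravel(), h, caches


def _backward(a_norm, logits, h_last, caches, model_params, act_name, dz):
    """Gradients of a weighted-BCE loss given dL/dlogits = dz."""
    _, dact = _ACTIVATIONS[act_name]
    conv_ws, w_out, _ = model_params
    g_out = h_last.T @ dz[:, None]
    g_bias = float(dz.sum())
    dh = dz[:, None] @ w_out.T
    g_convs = [None] * len(conv_ws)
    for i in range(len(conv_ws) - 1, -1, -1):
        h_in, ah, z, mask = caches[i]
        if mask is not None:
            dh = dh * mask
        dzl = dh * dact(z)
        g_convs[i] = ah.T @ dzl
        if i > 0:
            dh = a_norm @ (dzl @ conv_ws[i].T)  # a_norm is symmetric
    return g_convs, g_out, g_bias


def _bce_and_grad(logits, y, weights):
    """Weighted binary cross-entropy (weights sum-normalised) and dL/dlogits."""
    wsum = weights.sum()
    if wsum <= 0:
        return 0.0, np.zeros_like(logits)
    w = weights / wsum
    # stable log(1 + exp(-|z|)) formulation
    zy = logits * (2 * y - 1)
    losses = np.logaddexp(0.0, -zy)
    p = 1.0 / (1.0 + np.exp(-logits))
    return float((w * losses).sum()), w * (p - y)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        if self.lr == 0.0:
            return
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------


def train(
    config: GCNConfig,
    graph: PairGraph,
    nodes: MDPNodeTable,
    sampler: tuple[EdgeProbabilityTable, NormalizationCoefficients] | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """Fit the GCN on the train-role nodes of the graph.

    With ``sampler`` set (probability table + normalization coefficients),
    each epoch draws ``batches_per_epoch`` edge-sampled subgraphs and applies
    one lambda-weighted update per subgraph; without it, one full-graph update
    per epoch.  The recorded per-epoch loss is the full-graph, dropout-free
    mean BCE over train nodes, so the history is comparable across modes and
    identical for identical seeds.
    """
    if seed is None:
        seed = config.seed
    x = np.asarray(nodes.features, dtype=float)
    train_mask = nodes.train_mask()
    y_all = nodes.labels.astype(float)
    y_train = y_all[train_mask]
    if len(np.unique(y_train)) < 2:
        raise InputError("training nodes must contain both classes")

    rng = np.random.default_rng(seed)
    dims = [x.shape[1], *config.hidden]
    conv_ws = [_glorot(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
    w_out = _glorot(rng, dims[-1], 1)
    b_out = np.zeros(1)
    params = [*conv_ws, w_out, b_out]
    opt = _Adam(params, config.learning_rate)

    a_full = normalized_adjacency(graph)
    m_edges = config.edges_per_batch or max(1, graph.n_edges // config.batches_per_epoch)

    probs = coeffs = None
    lam_w = None
    if sampler is not None:
        probs, coeffs = sampler
        lam_w = np.zeros(graph.n_nodes)
        pos = coeffs.lam > 0
        lam_w[pos] = np.minimum(1.0 / coeffs.lam[pos], config.lambda_cap)

    history: list[float] = []
    for epoch in range(config.epochs):
        if sampler is None:
            weights = train_mask.astype(float)
            logits, h_last, caches = _forward(
                a_full, x, (conv_ws, w_out, float(b_out[0])),
                config.activation, config.dropout, rng,
            )
            _, dz = _bce_and_grad(logits, y_all, weights)
            g_convs, g_out, g_b = _backward(
                a_full, logits, h_last, caches,
                (conv_ws, w_out, None), config.activation, dz,
            )
            _apply_update(opt, params, conv_ws, w_out, b_out,
                          g_convs, g_out, g_b, config.weight_decay)
        else:
            batch_seeds = rng.integers(0, 2**31 - 1, size=config.batches_per_epoch)
            for bs in batch_seeds:
                sub = sample_subgraph(graph, probs, m_edges, int(bs))
                a_sub = _subgraph_adjacency(graph, sub.nodes, sub.induced_edges, coeffs)
                xs = x[sub.nodes]
                ys = y_all[sub.nodes]
                weights = (train_mask[sub.nodes]).astype(float) * lam_w[sub.nodes]
                if weights.sum() == 0:
                    continue
                logits, h_last, caches = _forward(
                    a_sub, xs, (conv_ws, w_out, float(b_out[0])),
                    config.activation, config.dropout, rng,
                )
                _, dz = _bce_and_grad(logits, ys, weights)
                g_convs, g_out, g_b = _backward(
                    a_sub, logits, h_last, caches,
                    (conv_ws, w_out, None), config.activation, dz,
                )
                _apply_update(opt, params, conv_ws, w_out, b_out,
                              g_convs, g_out, g_b, config.weight_decay)

        logits, _, _ = _forward(
            a_full, x, (conv_ws, w_out, float(b_out[0])), config.activation
        )
        loss, _ = _bce_and_grad(logits, y_all, train_mask.astype(float))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        history.append(loss)

    return TrainedModel(
        conv_weights=conv_ws,
        out_weight=w_out,
        out_bias=float(b_out[0]),
        config=config,
        loss_history=history,
        input_dim=x.shape[1],
    )


def _apply_update(opt, params, conv_ws, w_out, b_out, g_convs, g_out, g_b, wd):
    grads = [g + wd * w for g, w in zip(g_convs, conv_ws)]
    grads.append(g_out + wd * w_out)
    grads.append(np.array([g_b]))
    opt.step(params, grads)


def predict_scores(
    model: TrainedModel,
    graph: PairGraph,
    nodes: MDPNodeTable,
    node_ids=None,
) -> np.ndarray:
    """Sigmoid association scores from a full-graph forward pass (no sampling)."""
    x = np.asarray(nodes.features, dtype=float)
    if x.shape[1] != model.input_dim:
        raise InputError(
            f"feature length {x.shape[1]} differs from model input {model.input_dim}"
        )
    a_full = normalized_adjacency(graph)
    logits, _, _ = _forward(
        a_full, x, (model.conv_weights, model.out_weight, model.out_bias),
        model.config.activation,
    )
    scores = 1.0 / (1.0 + np.exp(-logits))
    if node_ids is None:
        return scores
    node_ids = np.asarray(node_ids)
    if len(node_ids) and (node_ids.min() < 0 or node_ids.max() >= len(nodes)):
        bad = node_ids[(node_ids < 0) | (node_ids >= len(nodes))][0]
        raise InputError(f"unknown node id {bad}")
    return scores[node_ids]
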