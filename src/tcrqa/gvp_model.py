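"""GVP-GNN DockQ regressor: architecture, pair-MSE loss, cross-validated training.

The network embeds node and edge features into hidden scalar/vector tracks,
applies a fixed number of GVP message-passing layers, mean-pools the final
node scalars per graph and maps them through a small fully connected head
(dropout on the FC layers only) with a sigmoid output, so predictions live
in [0, 1] like DockQ itself.

Training minimizes a pair MSE: two candidates of the same target are scored
jointly and the loss adds a term on the *difference* of their qualities,
discouraging the network from keying on features that are constant within a
target (e.g. sequence) rather than on docking geometry:

    L = MSE(y1, p1) + MSE(y2, p2) + MSE(y1 - y2, p1 - p2)

Two 5-fold cross-validated ensembles are trained: one on the full DockQ
range and one restricted to poses with DockQ >= 0.5, giving 10 networks in
total; downstream consensus scoring lives in :mod:`tcrqa.scoring`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .featurize import ComplexGraph
from .nn.autodiff import Tensor, gather, segment_mean
from .nn.gvp import GVP, GVPConvLayer, Linear
from .nn.gvp import Module as _Module

__all__ = [
    "ModelConfig",
    "GVPRegressor",
    "EnsembleSpec",
    "pair_mse_loss",
    "forward",
    "train_cv",
    "collate",
    "predict_many",
    "save_ensemble",
    "load_ensemble",
    "OUTPUT_CLAMP_EPS",
]

OUTPUT_CLAMP_EPS = 1e-4  # predictions are clamped to [eps, 1] before harmonic means


@dataclass(frozen=True)
class ModelConfig:
    conv_layers: int = 3
    node_scalar_dim: int = 50
    node_vector_dim: int = 8
    edge_scalar_dim: int = 50
    edge_vector_dim: int = 8
    dropout: float = 0.5
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 42
    node_in_scalar: int = 30    # input feature widths (542 with embeddings)
    node_in_vector: int = 3
    edge_in_scalar: int = 32
    edge_in_vector: int = 1


class GVPRegressor(_Module):
    """DockQ regressor over a (possibly batched) ComplexGraph."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.embed_node = GVP(c.node_in_scalar, c.node_in_vector,
                              c.node_scalar_dim, c.node_vector_dim, rng)
        self.embed_edge = GVP(c.edge_in_scalar, c.edge_in_vector,
                              c.edge_scalar_dim, c.edge_vector_dim, rng)
        self.layers = [
            GVPConvLayer(c.node_scalar_dim, c.node_vector_dim,
                         c.edge_scalar_dim, c.edge_vector_dim, rng)
            for _ in range(c.conv_layers)
        ]
        self.fc1 = Linear(c.node_scalar_dim, c.node_scalar_dim, rng)
        self.fc2 = Linear(c.node_scalar_dim, 1, rng)
        self._drop_rng = np.random.default_rng(config.seed + 7919)

    def forward_batch(self, batch, training=False) -> Tensor:
        ns = Tensor(batch["node_scalar"])
        nv = Tensor(batch["node_vector"])
        es = Tensor(batch["edge_scalar"])
        ev = Tensor(batch["edge_vector"])
        ns, nv = self.embed_node(ns, nv)
        es, ev = self.embed_edge(es, ev)
        for layer in self.layers:
            ns, nv = layer(ns, nv, batch["edge_index"], es, ev)
        pooled = segment_mean(ns, batch["graph_ids"], batch["n_graphs"])
        h = self.fc1(pooled).relu().dropout(self.config.dropout, self._drop_rng, training)
        out = self.fc2(h).sigmoid()
        return _squeeze_last(out)

    def predict(self, graphs) -> np.ndarray:
        """Deterministic inference (dropout off), clamped to [eps, 1]."""
        preds = self.forward_batch(collate(graphs), training=False).data
        return np.clip(preds, OUTPUT_CLAMP_EPS, 1.0)


def _squeeze_last(t: Tensor) -> Tensor:
    out = Tensor(t.data[:, 0], parents=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum(g[:, None])
    out._backward = bw
    return out


def collate(graphs):
    """Disjoint-union batching of ComplexGraphs (edge indices offset per graph)."""
    graphs = list(graphs)
    offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
    edge_index = np.concatenate(
        [g.edge_index + offsets[i] for i, g in enumerate(graphs)], axis=1)
    graph_ids = np.concatenate(
        [np.full(g.n_nodes, i, dtype=np.int64) for i, g in enumerate(graphs)])
    return {
        "node_scalar": np.concatenate([g.node_scalar for g in graphs]),
        "node_vector": np.concatenate([g.node_vector for g in graphs]),
        "edge_index": edge_index,
        "edge_scalar": np.concatenate([g.edge_scalar for g in graphs]),
        "edge_vector": np.concatenate([g.edge_vector for g in graphs]),
        "graph_ids": graph_ids,
        "n_graphs": len(graphs),
        "y": np.array([np.nan if g.target_dockq is None else g.target_dockq
                       for g in graphs]),
    }


def forward(graph: ComplexGraph, network: GVPRegressor) -> float:
    """Predicted DockQ of one graph under one trained network."""
    return float(network.predict([graph])[0])


def pair_mse_loss(y1_true, y1_pred, y2_true, y2_pred) -> float:
    """Pair MSE: per-member MSEs plus an MSE on the within-pair difference."""
    arrs = [np.atleast_1d(np.asarray(a, float))
            for a in (y1_true, y1_pred, y2_true, y2_pred)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("pair members must have identical lengths")
    a_t, a_p, b_t, b_p = arrs
    return float(np.mean((a_t - a_p) ** 2) + np.mean((b_t - b_p) ** 2)
                 + np.mean(((a_t - b_t) - (a_p - b_p)) ** 2))


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            g = g + self.wd * p.data  # coupled L2, torch-Adam style
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from lr0 to 0 over the training run."""
    return 0.5 * lr0 * (1.0 + np.cos(np.pi * epoch / max(1, total_epochs)))


# ---------------------------------------------------------------------------
# cross-validated training
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """The 10-network ensemble: 5 CV folds x {full DockQ range, DockQ >= 0.5}."""
    fold_models_full: list = field(default_factory=list)
    fold_models_high: list = field(default_factory=list)

    def __post_init__(self):
        for group in (self.fold_models_full, self.fold_models_high):
            if group and len(group) != 5:
                raise ValueError("each ensemble half needs exactly 5 networks")


def _sample_pair_batch(rng, by_target, batch_size):
    """Sample ``batch_size`` within-target candidate pairs; returns graph list
    ordered (pair0_a, pair0_b, pair1_a, ...)."""
    targets = list(by_target)
    weights = np.array([len(by_target[t]) for t in targets], float)
    weights /= weights.sum()
    out = []
    for _ in range(batch_size):
        t = targets[rng.choice(len(targets), p=weights)]
        pool = by_target[t]
        i = int(rng.integers(len(pool)))
        j = int(rng.integers(len(pool) - 1))
        if j >= i:
            j += 1
        out.append(pool[i])
        out.append(pool[j])
    return out


def _pair_loss_tensor(preds: Tensor, y: np.ndarray) -> Tensor:
    even = np.arange(0, len(y), 2)
    odd = np.arange(1, len(y), 2)
    pa, pb = gather(_as_column(preds), even), gather(_as_column(preds), odd)
    ya, yb = Tensor(y[even, None]), Tensor(y[odd, None])
    da = ya - pa
    db = yb - pb
    dd = (ya - yb) - (pa - pb)
    return (da * da).mean() + (db * db).mean() + (dd * dd).mean()


def _as_column(t: Tensor) -> Tensor:
    out = Tensor(t.data[:, None], parents=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum(g[:, 0])
    out._backward = bw
    return out


def train_network(graphs, config: ModelConfig, seed_offset=0, log=None):
    """Train one GVP-GNN on within-target pair batches; returns the network."""
    by_target = {}
    for g in graphs:
        if g.target_dockq is None:
            raise ValueError(f"graph {g.candidate_id} lacks target_dockq")
        by_target.setdefault(g.target_id, []).append(g)
    by_target = {t: p for t, p in by_target.items() if len(p) >= 2}
    if not by_target:
        raise ValueError("no target with >= 2 candidates; cannot form pairs")

    net_cfg = ModelConfig(**{**asdict(config), "seed": config.seed + seed_offset})
    net = GVPRegressor(net_cfg)
    params = net.params()
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 100003 * (seed_offset + 1))

    n_graphs = sum(len(p) for p in by_target.values())
    steps = max(1, int(np.ceil(n_graphs / (2 * config.batch_size))) * 2)
    history = []
    for epoch in range(config.epochs):
        opt.lr = cosine_lr(config.lr, epoch, config.epochs)
        losses = []
        for _ in range(steps):
            batch_graphs = _sample_pair_batch(rng, by_target, config.batch_size)
            batch = collate(batch_graphs)
            preds = net.forward_batch(batch, training=True)
            loss = _pair_loss_tensor(preds, batch["y"])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        if log is not None:
            log.append({"epoch": epoch, "loss": history[-1]})
    net.history = history
    return net


def train_cv(dataset, partitions, config: ModelConfig, subset="full"):
    """Train one ensemble half: one network per held-out fold.

    ``partitions`` maps target_id -> fold in {0..4}. For ``subset='high'``
    training graphs are restricted to target_dockq >= 0.5.
    """
    if subset not in ("full", "high"):
        raise ValueError(f"unknown subset {subset!r}")
    folds = sorted(set(partitions.values()))
    if folds != [0, 1, 2, 3, 4]:
        raise ValueError(f"expected folds 0..4, got {folds}")
    dataset = list(dataset)
    for g in dataset:
        if g.target_id not in partitions:
            raise ValueError(f"target {g.target_id} not in partition assignment")
    models = []
    for fold in range(5):
        train_graphs = [g for g in dataset if partitions[g.target_id] != fold]
        if subset == "high":
            train_graphs = [g for g in train_graphs
                            if g.target_dockq is not None and g.target_dockq >= 0.5]
        if not {g.target_id for g in train_graphs}:
            raise ValueError(f"fold {fold}: no training targets")
        net = train_network(train_graphs, config, seed_offset=fold)
        net.fold = fold
        models.append(net)
    return models


def predict_many(networks, graphs) -> np.ndarray:
    """(n_networks, n_graphs) matrix of clamped predictions."""
    return np.stack([net.predict(graphs) for net in networks])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_ensemble(networks, path):
    arrays, metas = {}, []
    for i, net in enumerate(networks):
        for j, p in enumerate(net.params()):
            arrays[f"net{i}_p{j}"] = p.data
        metas.append({"config": asdict(net.config), "fold": getattr(net, "fold", i)})
    arrays["meta_json"] = np.frombuffer(json.dumps(metas).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_ensemble(path):
    z = np.load(path, allow_pickle=False)
    metas = json.loads(bytes(z["meta_json"]).decode())
    nets = []
    for i, meta in enumerate(metas):
        net = GVPRegressor(ModelConfig(**meta["config"]))
        net.fold = meta["fold"]
        for j, p in enumerate(net.params()):
            p.data = z[f"net{i}_p{j}"]
        nets.append(net)
    return nets
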