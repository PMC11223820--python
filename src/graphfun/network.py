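"""Edge-featured graph attention trunk with global-node updates and task heads.

One message-passing layer performs, in order:

1. scaled-dot attention over each node's neighbourhood including the node
   itself, with edge features added to the keys:
   ``w_ji = (W_Q h_i)^T (W_K h_j + W_E e_ji) / sqrt(d)``, softmax-normalised
   over ``N(i) + {i}``; the self term has no edge, so ``e_ii`` is the zero
   vector and contributes ``W_K h_i`` only;
2. residual node update ``h_i <- h_i + sum_j alpha_ji (W_V h_j + W_E e_ji)``;
3. residual edge update ``e_ji <- e_ji + MLP(h_j || e_ji || h_i)`` with a
   two-layer perceptron on the updated node states;
4. a global-node update: the mean of a learned projection of the node states
   gates a shared additive correction of every node.

Residue-level heads are per-task linear+sigmoid maps of the final node
states; the protein-level head pools node states with learned softmax
attention before its linear+sigmoid output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import ProteinGraph
from .structio import PredictionResult


@dataclass
class GNNConfig:
    hidden: int = 128
    n_layers: int = 4
    activation: str = "gelu"
    use_global: bool = True
    residue_tasks: tuple = ()
    protein_labels: tuple = ()

    def __post_init__(self):
        self.residue_tasks = tuple(self.residue_tasks)
        self.protein_labels = tuple(self.protein_labels)
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.activation not in ad.ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


def _xavier(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / (fan_in + fan_out))


class GNNModel:
    """Learnable state: input projections, per-layer trunk weights, task heads.

    Parameters live in a flat name -> Tensor dict so the optimiser, the
    checkpoint format and the tests can address them individually.
    """

    def __init__(self, node_dim: int, edge_dim: int, config: GNNConfig, seed: int = 0):
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden
        p = {}
        p["node_in.W"] = _xavier(rng, node_dim, h)
        p["node_in.b"] = np.zeros(h)
        p["edge_in.W"] = _xavier(rng, edge_dim, h)
        p["edge_in.b"] = np.zeros(h)
        for l in range(config.n_layers):
            for w in ("WQ", "WK", "WV", "WE"):
                p[f"layer{l}.{w}"] = _xavier(rng, h, h)
            p[f"layer{l}.mlp.W1"] = _xavier(rng, 3 * h, h)
            p[f"layer{l}.mlp.b1"] = np.zeros(h)
            p[f"layer{l}.mlp.W2"] = _xavier(rng, h, h)
            p[f"layer{l}.mlp.b2"] = np.zeros(h)
            if config.use_global:
                p[f"layer{l}.glob.P"] = _xavier(rng, h, h)
                p[f"layer{l}.glob.bP"] = np.zeros(h)
                p[f"layer{l}.glob.U"] = _xavier(rng, h, h)
                p[f"layer{l}.glob.bU"] = np.zeros(h)
                p[f"layer{l}.glob.V"] = _xavier(rng, h, h)
                p[f"layer{l}.glob.bV"] = np.zeros(h)
        for task in config.residue_tasks:
            p[f"head.res.{task}.w"] = _xavier(rng, h, 1)
            p[f"head.res.{task}.b"] = np.zeros(1)
        if config.protein_labels:
            p["head.prot.att"] = _xavier(rng, h, 1)
            p["head.prot.W"] = _xavier(rng, h, len(config.protein_labels))
            p["head.prot.b"] = np.zeros(len(config.protein_labels))
        self.params = {k: ad.parameter(v) for k, v in p.items()}

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict:
        return {k: t.value.copy() for k, t in self.params.items()}

    def load_state_arrays(self, arrays: dict) -> None:
        for k, t in self.params.items():
            if arrays[k].shape != t.value.shape:
                raise ValueError(f"shape mismatch for parameter {k}")
            t.value = np.array(arrays[k], dtype=float)

    def save(self, path) -> None:
        meta = {
            "node_dim": self.node_dim, "edge_dim": self.edge_dim,
            "config": asdict(self.config),
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.state_arrays())

    @classmethod
    def load(cls, path) -> "GNNModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = meta["config"]
            cfg["residue_tasks"] = tuple(cfg["residue_tasks"])
            cfg["protein_labels"] = tuple(cfg["protein_labels"])
            model = cls(meta["node_dim"], meta["edge_dim"], GNNConfig(**cfg))
            model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        return model

    # -- forward -----------------------------------------------------------
    def forward(self, graph: ProteinGraph):
        """Returns (final node states, residue score dict, protein score Tensor
        or None).  Deterministic given parameters and graph."""
        h, e = trunk_forward(graph, self)
        res = residue_scores(h, self)
        prot = protein_scores(h, self) if self.config.protein_labels else None
        return h, res, prot

    def predict(self, graph: ProteinGraph) -> PredictionResult:
        _, res, prot = self.forward(graph)
        result = PredictionResult(protein_id=graph.meta.get("protein_id", "?"))
        result.residue_scores = {t: s.value.ravel().copy() for t, s in res.items()}
        if prot is not None:
            vals = prot.value.ravel()
            result.protein_scores = {
                lbl: float(v) for lbl, v in zip(self.config.protein_labels, vals)
            }
        return result


def attention_weights(h: Tensor, e: Tensor, model: GNNModel, layer: int, graph: ProteinGraph):
    """Normalised attention coefficients over N(i) + {i} for every node.

    Returns (alpha, seg, e_proj): ``alpha`` is a 1-D tensor aligned with the
    augmented edge list (all graph edges followed by the n self terms),
    ``seg`` the target node of each entry, and ``e_proj`` the W_E-projected
    edge features (reused by the node update).
    """
    p = model.params
    n = graph.n_nodes
    src = graph.edges[:, 0]
    dst = graph.edges[:, 1]
    d = float(model.config.hidden)
    q = h @ p[f"layer{layer}.WQ"]
    k = h @ p[f"layer{layer}.WK"]
    e_proj = e @ p[f"layer{layer}.WE"]
    logits_e = ad.tsum(ad.gather(q, dst) * (ad.gather(k, src) + e_proj), axis=1)
    logits_s = ad.tsum(q * k, axis=1)
    logits = ad.concat([logits_e, logits_s], axis=0) * (1.0 / np.sqrt(d))
    if not np.all(np.isfinite(logits.value)):
        raise FloatingPointError("non-finite attention logits")
    seg = np.concatenate([dst, np.arange(n)])
    alpha = ad.segment_softmax(logits, seg, n)
    return alpha, seg, e_proj


def node_update(h: Tensor, e: Tensor, alpha: Tensor, e_proj: Tensor,
                model: GNNModel, layer: int, graph: ProteinGraph) -> Tensor:
    """Residual attention-weighted aggregation (the self term carries no edge
    feature)."""
    p = model.params
    n = graph.n_nodes
    n_e = graph.n_edges
    src = graph.edges[:, 0]
    dst = graph.edges[:, 1]
    v = h @ p[f"layer{layer}.WV"]
    a_e = ad.reshape(ad.gather(alpha, np.arange(n_e)), (n_e, 1))
    a_s = ad.reshape(ad.gather(alpha, np.arange(n_e, n_e + n)), (n, 1))
    msg = (ad.gather(v, src) + e_proj) * a_e
    agg = ad.segment_sum(msg, dst, n) + v * a_s
    return h + agg


def edge_update(h_new: Tensor, e: Tensor, model: GNNModel, layer: int,
                graph: ProteinGraph) -> Tensor:
    """Residual two-layer MLP on (h_j || e_ji || h_i) using updated node states."""
    p = model.params
    act = ad.ACTIVATIONS[model.config.activation]
    src = graph.edges[:, 0]
    dst = graph.edges[:, 1]
    cat = ad.concat([ad.gather(h_new, src), e, ad.gather(h_new, dst)], axis=1)
    hidden = act(cat @ p[f"layer{layer}.mlp.W1"] + p[f"layer{layer}.mlp.b1"])
    return e + (hidden @ p[f"layer{layer}.mlp.W2"] + p[f"layer{layer}.mlp.b2"])


def global_node_update(h: Tensor, model: GNNModel, layer: int):
    """Mean-project-gate global node: g = mean_i proj(h_i);
    h_i <- h_i + sigmoid(U g) * (V g).  Returns (updated h, g)."""
    if h.value.shape[0] == 0:
        raise ValueError("empty graph")
    p = model.params
    g = ad.tmean(h @ p[f"layer{layer}.glob.P"] + p[f"layer{layer}.glob.bP"],
                 axis=0, keepdims=True)
    gate = ad.sigmoid(g @ p[f"layer{layer}.glob.U"] + p[f"layer{layer}.glob.bU"])
    val = g @ p[f"layer{layer}.glob.V"] + p[f"layer{layer}.glob.bV"]
    return h + gate * val, g


def trunk_forward(graph: ProteinGraph, model: GNNModel):
    """Input projections followed by the full layer stack; returns the final
    node and edge states."""
    p = model.params
    if graph.node_features.shape[1] != model.node_dim:
        raise ValueError("node feature dimension does not match model input")
    if graph.edge_features.shape[1] != model.edge_dim:
        raise ValueError("edge feature dimension does not match model input")
    h = Tensor(graph.node_features) @ p["node_in.W"] + p["node_in.b"]
    e = Tensor(graph.edge_features) @ p["edge_in.W"] + p["edge_in.b"]
    for l in range(model.config.n_layers):
        alpha, _, e_proj = attention_weights(h, e, model, l, graph)
        h = node_update(h, e, alpha, e_proj, model, l, graph)
        e = edge_update(h, e, model, l, graph)
        if model.config.use_global:
            h, _ = global_node_update(h, model, l)
    return h, e


def residue_scores(h: Tensor, model: GNNModel) -> dict:
    """Per-residue sigmoid scores, one (n, 1) tensor per configured task."""
    p = model.params
    return {
        task: ad.sigmoid(h @ p[f"head.res.{task}.w"] + p[f"head.res.{task}.b"])
        for task in model.config.residue_tasks
    }


def protein_scores(h: Tensor, model: GNNModel) -> Tensor:
    """Attention-pooled protein-level sigmoid scores, shape (1, n_labels)."""
    if h.value.shape[0] == 0:
        raise ValueError("empty graph")
    p = model.params
    a = ad.softmax_1d(h @ p["head.prot.att"])
    pooled = ad.tsum(a * h, axis=0, keepdims=True)
    return ad.sigmoid(pooled @ p["head.prot.W"] + p["head.prot.b"])
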