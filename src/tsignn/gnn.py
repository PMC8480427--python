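"""GraphSAGE-style message passing with edge embeddings on the joint graph.

The network learns embeddings for observation nodes, feature nodes and edges
of the joint bipartite graph, then predicts the (scaled) value of every
(observation, feature) pair with an edge-level regression head. Per layer l:

    message  m_{j->i} = ReLU(W_l . [h_j, e_ij])
    aggregate        = mean over neighbors j of i       (zero if isolated)
    node     h_i     = ReLU(Q_l . [h_i_prev, aggregate])
    edge     e_ij    = ReLU(P_l . [e_ij_prev, h_i, h_j])

Feature nodes start from the one-hot of their feature index; observation nodes
from the all-ones constant of the same width; edges from their scalar scaled
value. Stored edges are undirected but messages flow both ways. Training
minimizes MSE between head predictions and the true scaled values over the
observed edges only, with a fraction of edges dropped from message passing
each epoch (redrawn per epoch) while remaining prediction targets.

Defaults follow the published configuration: 3 layers, 64 hidden units, mean
aggregation, ReLU, Adam at learning rate 0.001, 2000 epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .graph import JointBipartiteGraph
from .series import TemporalSeries
from .windowing import collapse_to_series

AGGREGATORS = ("mean",)  # pluggable; only mean is shipped


@dataclass
class ImputerConfig:
    """Hyperparameters of the imputation network.

    ``edge_dropout_rate`` is the per-epoch fraction of observed edges removed
    from message passing (they remain loss targets); 0 disables dropout.
    """

    n_layers: int = 3
    hidden_dim: int = 64
    aggregation: str = "mean"
    epochs: int = 2000
    learning_rate: float = 1e-3
    edge_dropout_rate: float = 0.3
    grad_clip: float | None = None
    seed: int = 0
    dtype: str = "float32"  # training precision; float64 available

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("need positive layer count and hidden dim")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.edge_dropout_rate < 1:
            raise ValueError("edge dropout rate must be in [0, 1)")
        if self.aggregation not in AGGREGATORS:
            raise ValueError(
                f"aggregation {self.aggregation!r} not available; "
                f"shipped aggregators: {AGGREGATORS}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")


def split_seeds(master_seed: int, n: int = 3) -> list[int]:
    """Derive independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def init_parameters(n_features: int, config: ImputerConfig,
                    rng: np.random.Generator) -> dict[str, ad.Tensor]:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) init for every transform."""
    params: dict[str, ad.Tensor] = {}

    dtype = np.dtype(config.dtype)

    def lin(name: str, fan_in: int, fan_out: int) -> None:
        k = 1.0 / np.sqrt(fan_in)
        params[f"{name}_w"] = ad.parameter(
            rng.uniform(-k, k, (fan_in, fan_out)).astype(dtype))
        params[f"{name}_b"] = ad.parameter(
            rng.uniform(-k, k, fan_out).astype(dtype))

    h = config.hidden_dim
    d_node, d_edge = n_features, 1
    for l in range(config.n_layers):
        lin(f"msg{l}", d_node + d_edge, h)       # W_l
        lin(f"node{l}", d_node + h, h)           # Q_l
        lin(f"edge{l}", d_edge + 2 * h, h)       # P_l
        d_node, d_edge = h, h
    lin("head0", 2 * h, h)
    lin("head1", h, 1)
    return params


def _mean_aggregator(dst: np.ndarray, n_nodes: int, n_msgs: int,
                     dtype=np.float64) -> sp.csr_matrix:
    """Sparse (n_nodes x n_msgs) matrix averaging messages by destination."""
    counts = np.bincount(dst, minlength=n_nodes).astype(dtype)
    weights = (1.0 / counts[dst]).astype(dtype)
    return sp.csr_matrix((weights, (dst, np.arange(n_msgs))),
                         shape=(n_nodes, n_msgs))


def forward_pass(graph: JointBipartiteGraph, params: dict[str, ad.Tensor],
                 config: ImputerConfig,
                 keep: np.ndarray | None = None) -> tuple[ad.Tensor, ad.Tensor]:
    """Run message passing; returns (node embeddings, edge embeddings).

    Node embeddings are stacked observation-first: rows 0..m-1 are observation
    nodes, rows m..m+n-1 are feature nodes. ``keep`` optionally restricts
    message passing to a subset of edge indices (edge dropout).
    """
    m, n = graph.n_observation_nodes, graph.n_feature_nodes
    if keep is None:
        keep = np.arange(graph.n_edges)
    u = graph.edge_obs[keep]
    v = graph.edge_feat[keep] + m
    p = len(keep)
    # both directions share the undirected edge embedding
    src = np.concatenate([u, v])
    dst = np.concatenate([v, u])
    eid = np.concatenate([np.arange(p), np.arange(p)])
    dtype = np.dtype(config.dtype)
    agg_matrix = _mean_aggregator(dst, m + n, 2 * p, dtype)
    # gradient-scatter matrices are index-only and shared across layers
    sc_src = ad.make_scatter(src, m + n, dtype)
    sc_eid = ad.make_scatter(eid, p, dtype)
    sc_u = ad.make_scatter(u, m + n, dtype)
    sc_v = ad.make_scatter(v, m + n, dtype)

    h = ad.constant(np.vstack([graph.observation_init(), graph.feature_init()]),
                    dtype=dtype)
    e = ad.constant(graph.edge_values[keep][:, None], dtype=dtype)

    for l in range(config.n_layers):
        msg_in = ad.concat([ad.gather(h, src, sc_src), ad.gather(e, eid, sc_eid)])
        msg = ad.relu(ad.linear(msg_in, params[f"msg{l}_w"], params[f"msg{l}_b"]))
        agg = ad.spmm(agg_matrix, msg)
        h = ad.relu(ad.linear(ad.concat([h, agg]),
                              params[f"node{l}_w"], params[f"node{l}_b"]))
        edge_in = ad.concat([e, ad.gather(h, u, sc_u), ad.gather(h, v, sc_v)])
        e = ad.relu(ad.linear(edge_in, params[f"edge{l}_w"], params[f"edge{l}_b"]))
    return h, e


def predict_edges(node_emb: ad.Tensor, params: dict[str, ad.Tensor],
                  obs_idx: np.ndarray, feat_idx: np.ndarray,
                  n_observation_nodes: int,
                  scatters: tuple | None = None) -> ad.Tensor:
    """Edge-level head: MLP(concat(h_u, h_v)) -> scalar per pair."""
    if np.any(obs_idx >= n_observation_nodes) or np.any(obs_idx < 0):
        raise ValueError("unknown observation node id")
    sc_u, sc_v = scatters if scatters is not None else (None, None)
    z = ad.concat([ad.gather(node_emb, obs_idx, sc_u),
                   ad.gather(node_emb, feat_idx + n_observation_nodes, sc_v)])
    hidden = ad.relu(ad.linear(z, params["head0_w"], params["head0_b"]))
    return ad.linear(hidden, params["head1_w"], params["head1_b"])


@dataclass
class TrainedImputer:
    """Trained parameters plus the loss trace and config snapshot."""

    params: dict[str, ad.Tensor]
    config: ImputerConfig
    loss_trace: list[float]
    n_features: int

    def save(self, directory) -> None:
        """Checkpoint: one .npz of parameter arrays + a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "parameters.npz",
                 **{k: t.data for k, t in self.params.items()})
        with open(directory / "training_log.csv", "w") as fh:
            fh.write("epoch,train_mse\n")
            fh.writelines(f"{i},{v!r}\n" for i, v in enumerate(self.loss_trace))
        manifest = {"config": asdict(self.config),
                    "n_features": self.n_features,
                    "loss_trace": self.loss_trace}
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, directory) -> "TrainedImputer":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        arrays = np.load(directory / "parameters.npz")
        params = {k: ad.parameter(arrays[k]) for k in arrays.files}
        return cls(params, ImputerConfig(**manifest["config"]),
                   manifest["loss_trace"], manifest["n_features"])


def train(graph: JointBipartiteGraph, config: ImputerConfig) -> TrainedImputer:
    """Full-batch training on observed edges with per-epoch edge dropout."""
    if graph.n_edges < 1:
        raise ValueError("graph has no observed edges to train on")
    init_seed, dropout_seed, _ = split_seeds(config.seed)
    rng_init = np.random.default_rng(init_seed)
    rng_drop = np.random.default_rng(dropout_seed)
    params = init_parameters(graph.n_feature_nodes, config, rng_init)
    optimizer = ad.Adam(params.values(), lr=config.learning_rate)
    targets = graph.edge_values
    n_nodes = graph.n_observation_nodes + graph.n_feature_nodes
    dtype = np.dtype(config.dtype)
    head_scatters = (
        ad.make_scatter(graph.edge_obs, n_nodes, dtype),
        ad.make_scatter(graph.edge_feat + graph.n_observation_nodes,
                        n_nodes, dtype))
    trace: list[float] = []
    for epoch in range(config.epochs):
        if config.edge_dropout_rate > 0:
            kept = rng_drop.random(graph.n_edges) >= config.edge_dropout_rate
            if not kept.any():
                kept[rng_drop.integers(graph.n_edges)] = True
            keep = np.nonzero(kept)[0]
        else:
            keep = None
        optimizer.zero_grad()
        node_emb, _ = forward_pass(graph, params, config, keep)
        pred = predict_edges(node_emb, params, graph.edge_obs,
                             graph.edge_feat, graph.n_observation_nodes,
                             scatters=head_scatters)
        loss = ad.mse(pred, targets[:, None])
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}; "
                "try a lower learning rate or enable grad_clip")
        loss.backward()
        optimizer.step(config.grad_clip)
        trace.append(value)
    return TrainedImputer(params, config, trace, graph.n_feature_nodes)


@dataclass
class ImputationResult:
    """Predicted values for every cell of the flat design matrix."""

    predicted: np.ndarray            # (M, F), observed cells passed through
    observed_mask: np.ndarray        # (M, F) bool, True where a training edge
    collapsed: TemporalSeries | None = None


def impute(model: TrainedImputer, graph: JointBipartiteGraph,
           source: TemporalSeries | None = None,
           reducer: str = "mean", chunk: int = 200_000) -> ImputationResult:
    """Predict all M x F cells; observed cells keep their known values.

    Inductive use is supported: the graph may differ from the training graph
    as long as the feature schema (count and order) matches. When ``source``
    is given the flat predictions are collapsed back to a series.
    """
    if graph.n_feature_nodes != model.n_features:
        raise ValueError(
            f"feature schema mismatch: model expects {model.n_features} "
            f"features, graph has {graph.n_feature_nodes}")
    m, n = graph.n_observation_nodes, graph.n_feature_nodes
    node_emb, _ = forward_pass(graph, model.params, model.config)
    node_data = ad.constant(node_emb.data)   # cut the tape before the head
    obs_all = np.repeat(np.arange(m), n)
    feat_all = np.tile(np.arange(n), m)
    preds = np.empty(m * n)
    for lo in range(0, m * n, chunk):
        hi = min(lo + chunk, m * n)
        out = predict_edges(node_data, model.params,
                            obs_all[lo:hi], feat_all[lo:hi], m)
        preds[lo:hi] = out.data[:, 0]
    predicted = preds.reshape(m, n)
    observed = np.zeros((m, n), dtype=bool)
    observed[graph.edge_obs, graph.edge_feat] = True
    predicted[observed] = graph.edge_values  # observed passthrough
    if not np.all(np.isfinite(predicted)):
        raise RuntimeError("non-finite imputed values")
    collapsed = None
    if source is not None:
        flat = graph.flat
        imputed_flat = type(flat)(predicted, flat.sequence_length,
                                  flat.source_shape, flat.source_rows,
                                  flat.entity_ids)
        collapsed = collapse_to_series(imputed_flat, source, reducer,
                                       uncovered="fallback")
    return ImputationResult(predicted, observed, collapsed)
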