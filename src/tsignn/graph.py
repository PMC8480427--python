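"""Joint bipartite graph construction and the size estimator.

Observation nodes are the rows of the window-flattened design matrix, feature
nodes are the columns, and each *observed* cell contributes one attributed
edge carrying its scaled value. No observation-observation or feature-feature
edges exist: temporal order lives entirely in how the observation-node set was
built, which is what makes the graph "joint" bipartite.

The number of trainable edges in the fully observed case is

    size = (T - L) * L * F

(windows times steps times features), and a nonnegative threshold gates
training: a model whose estimated size exceeds the budget is refused unless
overridden. A size of four million or less is practical on a laptop-class
machine, hence the default threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .windowing import FlatDesignMatrix

DEFAULT_THRESHOLD = 4_000_000

CONTINUOUS = "continuous"


@dataclass(frozen=True)
class SizeEstimate:
    """Estimated trainable-edge count checked against a budget threshold."""

    size: int
    threshold: int
    within_budget: bool

    def __str__(self) -> str:  # used by the CLI
        verdict = "within budget" if self.within_budget else "OVER BUDGET"
        return f"size {self.size} vs threshold {self.threshold}: {verdict}"


@dataclass
class JointBipartiteGraph:
    """Bipartite graph of observation rows vs features with valued edges.

    Edge arrays are parallel: edge i joins observation node ``edge_obs[i]`` to
    feature node ``edge_feat[i]`` and carries scaled value ``edge_values[i]``.
    Feature nodes are indexed 0..n-1 within their own role; message passing
    treats every stored edge as bidirectional.
    """

    n_observation_nodes: int
    n_feature_nodes: int
    edge_obs: np.ndarray          # (p,) int
    edge_feat: np.ndarray         # (p,) int
    edge_values: np.ndarray       # (p,) float
    edge_kinds: list[str]         # per-feature tags, indexed by feature node
    flat: FlatDesignMatrix        # provenance carried through

    @property
    def n_edges(self) -> int:
        return len(self.edge_values)

    def observation_init(self) -> np.ndarray:
        """Initial observation-node embeddings: constant all-ones, dim F."""
        return np.ones((self.n_observation_nodes, self.n_feature_nodes))

    def feature_init(self) -> np.ndarray:
        """Initial feature-node embeddings: one-hot of the feature index."""
        return np.eye(self.n_feature_nodes)


def estimate_size(observations: int, sequence_length: int, features: int,
                  threshold: int = DEFAULT_THRESHOLD) -> SizeEstimate:
    """Trainable-edge count of a fully observed model: (T - L) * L * F.

    ``within_budget`` is True when size <= threshold (inclusive).
    """
    t, l, f = int(observations), int(sequence_length), int(features)
    if l < 1 or f < 1:
        raise ValueError("need sequence_length >= 1 and features >= 1")
    if t <= l:
        raise ValueError(
            f"observations ({t}) must exceed sequence length ({l})")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    size = (t - l) * l * f
    return SizeEstimate(size, int(threshold), size <= threshold)


def check_budget(observations: int, sequence_length: int, features: int,
                 threshold: int = DEFAULT_THRESHOLD) -> SizeEstimate:
    """Alias of :func:`estimate_size`; the CLI hard-gates on the result."""
    return estimate_size(observations, sequence_length, features, threshold)


def build_graph(flat: FlatDesignMatrix,
                feature_kinds: list[str] | None = None) -> JointBipartiteGraph:
    """Build the joint bipartite graph from a (scaled) flat design matrix.

    One observation node per flat row, one feature node per column, one edge
    per observed (non-NaN) cell carrying the scaled value. Node and edge ids
    are deterministic functions of (row, feature).
    """
    values = flat.values
    m, n = values.shape
    kinds = list(feature_kinds) if feature_kinds else [CONTINUOUS] * n
    if len(kinds) != n:
        raise ValueError("feature_kinds length must equal feature count")
    obs_idx, feat_idx = np.nonzero(~np.isnan(values))
    if len(obs_idx) == 0:
        raise ValueError("empty graph: no observed cells")
    edge_values = values[obs_idx, feat_idx]
    if not np.all(np.isfinite(edge_values)):
        raise ValueError("edge values must be finite")
    return JointBipartiteGraph(m, n, obs_idx.astype(np.int64),
                               feat_idx.astype(np.int64),
                               edge_values.astype(float), kinds, flat)


# ---------------------------------------------------------------------------
# serialization: edge-list text + JSON sidecar


def save_graph(graph: JointBipartiteGraph, edge_path, sidecar_path,
               feature_names: list[str] | None = None,
               seed: int | None = None) -> None:
    """Write `u,v,value` edge list plus a JSON sidecar with shapes/metadata."""
    with open(edge_path, "w") as fh:
        fh.write("obs_node,feature_node,value\n")
        for u, v, x in zip(graph.edge_obs, graph.edge_feat, graph.edge_values):
            fh.write(f"{u},{v},{x!r}\n")
    sidecar = {
        "n_observation_nodes": graph.n_observation_nodes,
        "n_feature_nodes": graph.n_feature_nodes,
        "n_edges": graph.n_edges,
        "sequence_length": graph.flat.sequence_length,
        "source_shape": list(graph.flat.source_shape),
        "feature_kinds": graph.edge_kinds,
        "feature_names": feature_names,
        "seed": seed,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2) + "\n")
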