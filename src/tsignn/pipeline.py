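"""End-to-end imputation pipelines: windows -> graph -> train -> collapse.

Two variants share all machinery:

* the joint-bipartite (windowed) pipeline, where observation nodes are rows
  of the sliding-window-flattened matrix and carry sequence information;
* a non-windowed variant, where each source row is its own observation node —
  the plain bipartite construction a static graph imputer would use. It is
  the natural ablation of the windowing step.

Both expect the input series already normalized (see
:func:`tsignn.evaluation.normalize`); masked/missing cells are NaN.
"""

from __future__ import annotations

import numpy as np

from .gnn import ImputerConfig, TrainedImputer, impute, train
from .graph import build_graph
from .series import EntitySeriesCollection, TemporalSeries
from .windowing import (FlatDesignMatrix, collapse_collection, cut_windows,
                        flatten, window_collection)


def flat_from_series(series: TemporalSeries,
                     sequence_length: int | None) -> FlatDesignMatrix:
    """Windowed flat matrix, or the trivial row-per-node matrix when L is None."""
    if sequence_length is None:
        t, f = series.values.shape
        return FlatDesignMatrix(series.values.copy(), 1, (t, f), np.arange(t))
    return flatten(cut_windows(series, sequence_length))


def impute_series(scaled_masked: TemporalSeries,
                  sequence_length: int | None,
                  config: ImputerConfig | None = None,
                  reducer: str = "mean"
                  ) -> tuple[TemporalSeries, TrainedImputer]:
    """Train on the observed cells of one series and fill its missing cells.

    ``sequence_length=None`` selects the non-windowed (plain bipartite)
    construction. Returns the completed series and the trained model.
    """
    config = config or ImputerConfig()
    flat = flat_from_series(scaled_masked, sequence_length)
    graph = build_graph(flat, scaled_masked.feature_kinds)
    model = train(graph, config)
    result = impute(model, graph, source=scaled_masked, reducer=reducer)
    return result.collapsed, model


def impute_collection(scaled_masked: EntitySeriesCollection,
                      sequence_length: int,
                      config: ImputerConfig | None = None,
                      reducer: str = "mean"
                      ) -> tuple[EntitySeriesCollection, TrainedImputer]:
    """Joint training over all entities of an irregular collection."""
    config = config or ImputerConfig()
    flat = window_collection(scaled_masked, sequence_length)
    graph = build_graph(flat, scaled_masked.feature_kinds)
    model = train(graph, config)
    result = impute(model, graph)
    imputed_flat = FlatDesignMatrix(result.predicted, flat.sequence_length,
                                    flat.source_shape, flat.source_rows,
                                    flat.entity_ids)
    return collapse_collection(imputed_flat, scaled_masked, reducer), model


def graph_imputer(sequence_length: int | None,
                  config: ImputerConfig | None = None):
    """Adapter for the experiment grid: (scaled series, seed) -> imputed.

    Each call reseeds the config with the grid seed so the mask seed and the
    network seed stay coupled per cell.
    """
    base = config or ImputerConfig()

    def run(scaled_masked: TemporalSeries, seed: int) -> TemporalSeries:
        cfg = ImputerConfig(**{**base.__dict__, "seed": seed})
        imputed, _ = impute_series(scaled_masked, sequence_length, cfg)
        return imputed

    return run
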