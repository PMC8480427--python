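"""Sliding-window cut, 3D->2D flattening, exact restore, and sequence length.

The joint-bipartite-graph construction encodes temporal order by cutting a
T x F series into length-L sliding windows (stride 1) and flattening the
resulting W x L x F array row-major over (window, step) into an M x F design
matrix with M = W * L. Each row of that matrix becomes one observation node.
The flattening is exactly invertible, which is what lets sequence information
survive the trip into a bipartite graph and back.

Window count follows the convention W = T - L (not the usual T - L + 1):
windows start at t = 0 .. T-L-1, so a 4120 x 6 series cut at L = 21 yields
4099 windows and an 86079 x 6 design matrix. Every source row is still
covered: row T-1 appears (only) as the final step of the last window.

Because stride is 1, each source cell appears in up to L windows;
:func:`collapse_to_series` reconciles the multiple imputed copies of a cell
back to a single value (mean by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .series import EntitySeriesCollection, TemporalSeries

PAD_ROW = -1  # provenance marker for front-padded steps of short entities

_REDUCERS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean,
    "median": np.median,
    "first": lambda a: a[0],
}


@dataclass
class WindowedTensor:
    """W x L x F array of sliding windows plus provenance to the source."""

    values: np.ndarray               # (W, L, F)
    window_starts: np.ndarray        # (W,) source row of each window's step 0
    sequence_length: int
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        w, l, f = self.values.shape
        if l != self.sequence_length:
            raise ValueError("middle axis must equal sequence_length")
        if len(self.window_starts) != w:
            raise ValueError("window_starts length must equal window count")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class FlatDesignMatrix:
    """M x F design matrix, M = W*L, with full per-row provenance.

    Row k corresponds to window ``k // L``, step ``k % L``; ``source_rows[k]``
    is the row of the original series it copies (``PAD_ROW`` for padding).
    """

    values: np.ndarray               # (M, F)
    sequence_length: int
    source_shape: tuple[int, int]
    source_rows: np.ndarray          # (M,) int
    entity_ids: np.ndarray | None = None  # (M,) object, for collections

    def __post_init__(self) -> None:
        m = self.values.shape[0]
        if m % self.sequence_length != 0:
            raise ValueError("row count not divisible by sequence length")
        if len(self.source_rows) != m:
            raise ValueError("provenance length must equal row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def row_provenance(self) -> list[tuple[int, int, int]]:
        """(window, step, source row) for every flat row."""
        l = self.sequence_length
        return [(k // l, k % l, int(self.source_rows[k]))
                for k in range(self.n_rows)]


def cut_windows(series: TemporalSeries, sequence_length: int) -> WindowedTensor:
    """Cut a series into W = T - L sliding windows of length L, stride 1.

    Missing cells are carried through unchanged. Raises if the series is not
    strictly longer than the window.
    """
    t = series.n_timesteps
    l = int(sequence_length)
    if l < 1:
        raise ValueError("sequence length must be a positive integer")
    if l >= t:
        raise ValueError(
            f"series shorter than sequence length (T={t}, L={l}); "
            "need T > L"
        )
    w = t - l
    starts = np.arange(w)
    # windows[w] = rows [w, w+L) of the source
    windows = np.lib.stride_tricks.sliding_window_view(
        series.values, (l,), axis=0
    )[:w]                                        # (w, F, L)
    values = np.ascontiguousarray(np.swapaxes(windows, 1, 2))
    return WindowedTensor(values, starts, l, (t, series.n_features))


def flatten(windowed: WindowedTensor) -> FlatDesignMatrix:
    """Reshape (W, L, F) row-major over (window, step) into (W*L, F)."""
    w, l, f = windowed.values.shape
    flat = windowed.values.reshape(w * l, f)
    steps = np.tile(np.arange(l), w)
    src = np.repeat(windowed.window_starts, l) + steps
    return FlatDesignMatrix(flat.copy(), l, windowed.source_shape, src)


def restore(flat: FlatDesignMatrix) -> WindowedTensor:
    """Exact inverse of :func:`flatten` (bit-identical values)."""
    m, f = flat.values.shape
    l = flat.sequence_length
    if m % l != 0:
        raise ValueError("row count not divisible by sequence length")
    w = m // l
    values = flat.values.reshape(w, l, f).copy()
    starts = flat.source_rows.reshape(w, l)[:, 0]
    return WindowedTensor(values, starts.copy(), l, flat.source_shape)


def collapse_to_series(flat_imputed: FlatDesignMatrix, source: TemporalSeries,
                       reducer: str = "mean",
                       uncovered: str = "error") -> TemporalSeries:
    """Reconcile the window-copies of each source cell to a single value.

    Every source cell appears in up to L flattened rows; for each (t, f) the
    reducer (mean by default) is applied over all imputed copies. Padded rows
    are ignored.

    With W = T - L windows starting at row 0, the final source row belongs to
    no window. ``uncovered="error"`` (default) raises for any row with no
    copies; ``uncovered="fallback"`` fills such rows from the source where
    observed and from the per-feature mean of the imputed copies otherwise.
    """
    if reducer not in _REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}; use one of {sorted(_REDUCERS)}")
    if uncovered not in ("error", "fallback"):
        raise ValueError("uncovered must be 'error' or 'fallback'")
    reduce = _REDUCERS[reducer]
    t, f = source.values.shape
    out = np.empty((t, f), dtype=float)
    src = flat_imputed.source_rows
    order = np.argsort(src, kind="stable")
    sorted_src = src[order]
    bounds = np.searchsorted(sorted_src, np.arange(t + 1))
    column_means = flat_imputed.values.mean(axis=0)
    for row in range(t):
        lo, hi = bounds[row], bounds[row + 1]
        if lo == hi:
            if uncovered == "error":
                raise ValueError(f"row not represented in any window: {row}")
            observed = ~np.isnan(source.values[row])
            out[row] = np.where(observed, source.values[row], column_means)
            continue
        copies = flat_imputed.values[order[lo:hi]]
        out[row] = [reduce(copies[:, j]) for j in range(f)]
    return TemporalSeries(out, list(source.feature_names),
                          list(source.feature_kinds),
                          np.asarray(source.time_index).copy(),
                          source.entity_id)


def determine_sequence_length(collection: EntitySeriesCollection,
                              min_length: int = 9) -> int:
    """Average per-entity length, rounded, over entities of length >= min_length.

    The returned value doubles as the per-entity maximum (truncation cap) for
    irregular data: the cap equals the average sequence length.
    Rounds half away from zero.
    """
    lengths = [n for n in collection.lengths().values() if n >= min_length]
    if not lengths:
        raise ValueError(
            f"no entity meets the minimum sequence length {min_length}"
        )
    mean = sum(lengths) / len(lengths)
    return int(math.floor(mean + 0.5))


def window_collection(collection: EntitySeriesCollection,
                      sequence_length: int) -> FlatDesignMatrix:
    """Window every entity and stack the flattened blocks into one matrix.

    Entities longer than the cap keep their most recent ``L + 1`` rows (so each
    contributes at least one window); entities with T <= L contribute a single
    window front-padded with missing cells. Padded steps carry NaN and
    ``PAD_ROW`` provenance, so they generate no graph edges.
    """
    l = int(sequence_length)
    if l < 1:
        raise ValueError("sequence length must be a positive integer")
    blocks, src_rows, ents = [], [], []
    f = len(collection.feature_names)
    for eid, s in collection:
        t = s.n_timesteps
        if t > l:
            sub = s if t == l + 1 else TemporalSeries(
                s.values[t - (l + 1):], s.feature_names, s.feature_kinds,
                entity_id=eid)
            offset = 0 if t == l + 1 else t - (l + 1)
            flat = flatten(cut_windows(sub, l))
            blocks.append(flat.values)
            src_rows.append(flat.source_rows + offset)
        else:
            pad = l - t
            vals = np.vstack([np.full((pad, f), np.nan), s.values])
            blocks.append(vals)
            src_rows.append(np.concatenate([np.full(pad, PAD_ROW, dtype=int),
                                            np.arange(t)]))
        ents.append(np.full(len(src_rows[-1]), eid, dtype=object))
    values = np.vstack(blocks)
    return FlatDesignMatrix(values, l, (values.shape[0], f),
                            np.concatenate(src_rows),
                            entity_ids=np.concatenate(ents))


def collapse_collection(flat_imputed: FlatDesignMatrix,
                        collection: EntitySeriesCollection,
                        reducer: str = "mean") -> EntitySeriesCollection:
    """Per-entity :func:`collapse_to_series` over a stacked flat matrix.

    Source rows dropped by truncation keep their original values.
    """
    if flat_imputed.entity_ids is None:
        raise ValueError("flat matrix has no entity provenance")
    out: dict[str, TemporalSeries] = {}
    for eid, s in collection:
        sel = flat_imputed.entity_ids == eid
        pad_free = sel & (flat_imputed.source_rows != PAD_ROW)
        vals = s.values.copy()
        sub_src = flat_imputed.source_rows[pad_free]
        sub_vals = flat_imputed.values[pad_free]
        reduce = _REDUCERS[reducer]
        for row in np.unique(sub_src):
            copies = sub_vals[sub_src == row]
            vals[row] = [reduce(copies[:, j]) for j in range(s.n_features)]
        # cells in rows no window covers (the final row of long entities)
        # fall back to the global per-feature mean of the imputed matrix
        still_missing = np.isnan(vals)
        if still_missing.any():
            fill = np.nanmean(flat_imputed.values, axis=0)
            vals[still_missing] = np.broadcast_to(fill, vals.shape)[still_missing]
        out[eid] = TemporalSeries(vals, s.feature_names, s.feature_kinds,
                                  np.asarray(s.time_index).copy(), eid)
    return EntitySeriesCollection(out, label_name=collection.label_name)
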