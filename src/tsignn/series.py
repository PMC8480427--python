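"""Temporal data containers and CSV ingest/egress.

Two shapes of input are supported:

* a *regular* single-entity series — a wide CSV with one row per timestep and
  one column per feature (optional leading ``time`` column), held as a
  :class:`TemporalSeries`;
* an *irregular* multi-entity collection — a long CSV with ``entity_id`` and
  ``time`` columns followed by features, held as an
  :class:`EntitySeriesCollection`.

Missing cells are represented as NaN throughout. Time indices are mapped to
0-based integer positions on ingest; the method operates on sequence position,
not wall-clock time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class TemporalSeries:
    """A T x F matrix of (possibly partially observed) feature values over time.

    Parameters
    ----------
    values
        Float matrix of shape (T, F); NaN marks a missing cell.
    feature_names
        Length-F column names.
    feature_kinds
        Per-feature tag, ``"continuous"`` or ``"categorical"``. Defaults to
        all continuous.
    time_index
        Strictly increasing positions, length T. Defaults to 0..T-1.
    entity_id
        Optional identifier when the series belongs to a collection.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str] = field(default_factory=list)
    time_index: np.ndarray | None = None
    entity_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (T, F) matrix")
        t, f = self.values.shape
        if t < 1 or f < 1:
            raise ValueError("need T >= 1 and F >= 1")
        if len(self.feature_names) != f:
            raise ValueError("feature_names length must equal F")
        if not self.feature_kinds:
            self.feature_kinds = [CONTINUOUS] * f
        if len(self.feature_kinds) != f:
            raise ValueError("feature_kinds length must equal F")
        for kind in self.feature_kinds:
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise ValueError(f"unknown feature kind {kind!r}")
        if self.time_index is None:
            self.time_index = np.arange(t)
        self.time_index = np.asarray(self.time_index)
        if len(self.time_index) != t:
            raise ValueError("time_index length must equal row count")
        if t > 1 and not np.all(np.diff(self.time_index.astype(float)) > 0):
            raise ValueError("time_index must be strictly increasing")

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (T, F) matrix, True where the cell is missing."""
        return np.isnan(self.values)

    def copy(self) -> "TemporalSeries":
        return replace(self, values=self.values.copy(),
                       time_index=np.asarray(self.time_index).copy())

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "time", np.asarray(self.time_index))
        return df


@dataclass
class EntitySeriesCollection:
    """A set of TemporalSeries keyed by entity id (irregular-sampling case).

    All member series share feature names and kinds; one feature may be
    designated the downstream prediction label.
    """

    series: dict[str, TemporalSeries]
    label_name: str | None = None

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("collection must contain at least one entity")
        names = None
        for eid, s in self.series.items():
            if names is None:
                names = (tuple(s.feature_names), tuple(s.feature_kinds))
            elif (tuple(s.feature_names), tuple(s.feature_kinds)) != names:
                raise ValueError(f"entity {eid!r} has mismatched feature schema")
        if self.label_name is not None and self.label_name not in names[0]:
            raise ValueError(f"label {self.label_name!r} is not a feature")

    @property
    def feature_names(self) -> list[str]:
        return list(next(iter(self.series.values())).feature_names)

    @property
    def feature_kinds(self) -> list[str]:
        return list(next(iter(self.series.values())).feature_kinds)

    @property
    def n_entities(self) -> int:
        return len(self.series)

    def lengths(self) -> dict[str, int]:
        return {eid: s.n_timesteps for eid, s in self.series.items()}

    def __iter__(self) -> Iterator[tuple[str, TemporalSeries]]:
        return iter(self.series.items())


# ---------------------------------------------------------------------------
# CSV ingest / egress


def read_wide_csv(path, feature_kinds: Mapping[str, str] | None = None) -> TemporalSeries:
    """Read a regular series: header of feature names, one row per timestep.

    An optional first column named ``time`` supplies the time axis; it is
    mapped to ordinal positions. Empty fields and ``NA`` are missing.
    """
    df = pd.read_csv(path, na_values=["NA"])
    if df.columns[0].lower() == "time":
        df = df.drop(columns=df.columns[0])
    names = [str(c) for c in df.columns]
    kinds = [
        (feature_kinds or {}).get(name, CONTINUOUS) for name in names
    ]
    return TemporalSeries(df.to_numpy(dtype=float), names, kinds)


def write_wide_csv(series: TemporalSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, na_rep="")


def read_long_csv(path, label_name: str | None = None,
                  feature_kinds: Mapping[str, str] | None = None) -> EntitySeriesCollection:
    """Read an irregular collection: columns ``entity_id``, ``time``, features."""
    df = pd.read_csv(path, na_values=["NA"])
    required = {"entity_id", "time"}
    if not required.issubset(df.columns):
        raise ValueError("long CSV must contain 'entity_id' and 'time' columns")
    feats = [c for c in df.columns if c not in required]
    kinds = [(feature_kinds or {}).get(name, CONTINUOUS) for name in feats]
    out: dict[str, TemporalSeries] = {}
    for eid, grp in df.groupby("entity_id", sort=True):
        grp = grp.sort_values("time")
        out[str(eid)] = TemporalSeries(
            grp[feats].to_numpy(dtype=float), list(feats), list(kinds),
            entity_id=str(eid),
        )
    return EntitySeriesCollection(out, label_name=label_name)


def write_long_csv(collection: EntitySeriesCollection, path) -> None:
    frames = []
    for eid, s in collection:
        df = s.to_frame()
        df.insert(0, "entity_id", eid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep="")
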