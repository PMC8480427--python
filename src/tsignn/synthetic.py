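"""Synthetic temporal datasets with known correlation structure.

The generator produces the two correlation axes a temporal imputer is meant
to exploit: *temporal autocorrelation*, via latent AR(1) factors
``x_t = phi * x_{t-1} + eps_t`` (innovation variance ``1 - phi**2`` so each
factor is stationary with unit variance), and *cross-feature correlation*,
via a factor loading matrix mapping the k latent factors to F observed
features plus independent observation noise. A downstream label with known
feature dependence (linear, optionally thresholded to binary) can be
appended, giving the congeniality protocol a ground truth.

Irregular multi-entity collections draw per-entity lengths from a discrete
uniform distribution; the defaults (minimum 9, range 9..21, mean 15 over 550
entities) mirror a de-identified ICU-style cohort with per-patient
sequence-length variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import (CATEGORICAL, CONTINUOUS, EntitySeriesCollection,
                     TemporalSeries)

LABEL = "label"


@dataclass
class LabelRule:
    """How the downstream label is built from the features.

    ``linear``: label = features @ coefficients + N(0, noise_sd).
    ``threshold_binary``: 1 where the linear score exceeds ``threshold``.
    """

    kind: str = "linear"
    coefficients: np.ndarray | None = None   # defaults to all-ones
    noise_sd: float = 0.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "threshold_binary"):
            raise ValueError(f"unknown label rule {self.kind!r}")


@dataclass
class SyntheticSpec:
    """Parameters of the generator; every draw is reproducible from seed."""

    n_timesteps: int = 300
    n_features: int = 5
    n_entities: int = 1
    n_factors: int = 2
    ar_coefficient: float = 0.8
    loading: np.ndarray | str | None = None  # matrix, "identity", or random
    noise_sd: float = 0.1
    label_rule: LabelRule | None = None
    length_min: int = 9
    length_max: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("AR coefficient must be in [0, 1) for stationarity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.length_min < 2:
            raise ValueError("minimum entity length must be >= 2")


def _loading_matrix(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.loading, str):
        if spec.loading != "identity":
            raise ValueError(f"unknown loading spec {spec.loading!r}")
        if spec.n_factors != spec.n_features:
            raise ValueError("identity loading needs n_factors == n_features")
        return np.eye(spec.n_features)
    if spec.loading is not None:
        lam = np.asarray(spec.loading, dtype=float)
        if lam.shape != (spec.n_features, spec.n_factors):
            raise ValueError("loading must be (n_features, n_factors)")
        return lam
    # random loadings, unit row norms: every feature mixes all factors
    lam = rng.normal(size=(spec.n_features, spec.n_factors))
    return lam / np.linalg.norm(lam, axis=1, keepdims=True)


def _simulate(spec: SyntheticSpec, rng: np.random.Generator,
              n_timesteps: int, entity_id: str | None) -> TemporalSeries:
    phi = spec.ar_coefficient
    k, f, t = spec.n_factors, spec.n_features, n_timesteps
    lam = _loading_matrix(spec, rng)
    innov_sd = np.sqrt(1.0 - phi ** 2)
    latent = np.empty((t, k))
    latent[0] = rng.normal(size=k)  # stationary start: unit variance
    for step in range(1, t):
        latent[step] = phi * latent[step - 1] + innov_sd * rng.normal(size=k)
    values = latent @ lam.T
    if spec.noise_sd > 0:
        values = values + spec.noise_sd * rng.normal(size=(t, f))
    names = [f"x{j}" for j in range(f)]
    kinds = [CONTINUOUS] * f
    if spec.label_rule is not None:
        rule = spec.label_rule
        coef = (np.ones(f) if rule.coefficients is None
                else np.asarray(rule.coefficients, dtype=float))
        score = values @ coef
        if rule.noise_sd > 0:
            score = score + rule.noise_sd * rng.normal(size=t)
        if rule.kind == "threshold_binary":
            score = (score > rule.threshold).astype(float)
            kinds = kinds + [CATEGORICAL]
        else:
            kinds = kinds + [CONTINUOUS]
        values = np.column_stack([values, score])
        names = names + [LABEL]
    return TemporalSeries(values, names, kinds, entity_id=entity_id)


def generate_regular(spec: SyntheticSpec) -> TemporalSeries:
    """One fully observed regular T x F series (plus label if configured)."""
    rng = np.random.default_rng(spec.seed)
    return _simulate(spec, rng, spec.n_timesteps, None)


def generate_irregular(spec: SyntheticSpec) -> EntitySeriesCollection:
    """A multi-entity collection with per-entity length variation.

    All entities share the loading matrix and generator parameters but have
    independent latent paths; lengths ~ uniform{length_min .. length_max}.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = rng.integers(spec.length_min, spec.length_max + 1,
                           size=spec.n_entities)
    series = {}
    for i, t in enumerate(lengths):
        eid = f"e{i:04d}"
        series[eid] = _simulate(spec, rng, int(t), eid)
    label = LABEL if spec.label_rule is not None else None
    return EntitySeriesCollection(series, label_name=label)


def desk_scale_spec(seed: int = 0, label: bool = True) -> SyntheticSpec:
    """The default desk-scale fixture: T=300, F=5, phi=0.8.

    With sequence length 10 its model size is (300-10)*10*5 = 14,500 —
    far under the 4M budget; it trains in minutes on one CPU.
    """
    rule = LabelRule("linear", noise_sd=0.1) if label else None
    return SyntheticSpec(n_timesteps=300, n_features=5, n_factors=2,
                         ar_coefficient=0.8, noise_sd=0.1,
                         label_rule=rule, seed=seed)
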