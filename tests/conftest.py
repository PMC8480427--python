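import numpy as np
import pytest

from tsignn import (ImputerConfig, LabelRule, SyntheticSpec, TemporalSeries,
                    apply_mcar_mask, build_graph, cut_windows, flatten,
                    generate_regular, normalize)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_series():
    """A 40 x 3 fully observed series with temporal structure."""
    spec = SyntheticSpec(n_timesteps=40, n_features=3, n_factors=2,
                         ar_coefficient=0.7, noise_sd=0.1, seed=7,
                         label_rule=LabelRule("linear", noise_sd=0.3))
    return generate_regular(spec)


@pytest.fixture(scope="session")
def masked_scaled(small_series):
    """(scaled masked series, scaled truth, mask) at a 30% MCAR rate."""
    masked, mask = apply_mcar_mask(small_series, 0.3, seed=11)
    scaled, stats = normalize(masked)
    truth, _ = normalize(small_series, stats)
    return scaled, truth, mask


@pytest.fixture(scope="session")
def tiny_graph(masked_scaled):
    scaled, _, _ = masked_scaled
    return build_graph(flatten(cut_windows(scaled, 5)), scaled.feature_kinds)


@pytest.fixture
def tiny_config():
    """Small, fast, double-precision config for numerical tests."""
    return ImputerConfig(n_layers=3, hidden_dim=8, epochs=5,
                         edge_dropout_rate=0.0, seed=3, dtype="float64")


def series_from(values, names=None) -> TemporalSeries:
    values = np.asarray(values, dtype=float)
    names = names or [f"x{j}" for j in range(values.shape[1])]
    return TemporalSeries(values, names)
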