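# Methods

## Model

`tsignn` treats imputation as edge-level regression on a bipartite graph.
For a T×F matrix cut at sequence length L, observation nodes are the
M = (T − L)·L rows of the window-flattened design matrix, feature nodes are
the F columns, and each observed cell contributes one undirected edge whose
attribute is the min–max-scaled value. Temporal order enters purely through
the construction of the observation-node set: consecutive windows share L − 1
source rows, so message passing over shared feature nodes lets window context
inform every prediction without observation–observation edges.

Message passing follows the modified-GraphSAGE scheme with edge embeddings.
With h⁰ the initial node states (feature node f: one-hot of f; observation
nodes: the all-ones vector of width F) and e⁰ the scalar edge value,
layer l computes

    m_{j→i} = ReLU(W_l [h_j ‖ e_ij])          (both directions of each edge)
    a_i     = mean_{j ∈ N(i)} m_{j→i}          (zero for isolated nodes)
    h_i     = ReLU(Q_l [h_i ‖ a_i])
    e_ij    = ReLU(P_l [e_ij ‖ h_i ‖ h_j])

and a two-layer MLP head on [h_u ‖ h_v] yields the predicted value of any
(observation, feature) pair. Training minimizes MSE over observed edges;
a per-epoch redrawn fraction of edges (default 0.3) is removed from message
passing while remaining prediction targets, which regularizes against copying
the edge attribute through the edge embedding. Because the message/update
transforms are shared across nodes, the model is inductive: it can impute a
graph built from rows never seen in training, provided the feature schema
matches.

The aggregator is a pluggable interface; only the (permutation-invariant)
mean is shipped. Sequence-sensitive aggregators such as LSTMs are a known
extension and deliberately out of scope.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| layers / hidden | 3 / 64 | the published configuration for this architecture family |
| optimizer / lr / epochs | Adam / 0.001 / 2000 | published configuration; desk-scale runs use 500 (see below) |
| edge dropout | 0.3 per epoch | reference value for the architecture this follows; redrawn each epoch |
| size threshold | 4,000,000 edges | (T−L)·L·F at or under this trains comfortably on a laptop-class CPU |
| normalization | per-feature min–max to [0,1], observed cells only | matches the 0.03–0.3 RMSE scale conventional for this protocol; z-scoring available |
| collapse reducer | mean over the ≤ L window copies | unbiased combination; median and first available |
| sequence length (irregular) | rounded mean entity length over entities of length ≥ 9, used also as truncation cap | the average-sequence-length rule for EHR-style cohorts |
| holdout | time-ordered 70:30 | avoids leakage between temporally adjacent rows; random split by flag |
| training precision | float32 | halves runtime; float64 by config for numerical tests |

Seeding: one master seed is split (via `numpy.random.SeedSequence`) into
initialization, dropout-stream, and mask seeds, all below 2³¹ and recorded in
run manifests; identical seeds give bit-identical runs on the same machine.

## Windowing conventions and the uncovered final row

Window count is W = T − L with stride 1 and starts 0 … T−L−1 (so the
4120-row, L = 21 reference shape yields exactly 4099 windows and an
86079-row design matrix). Under this convention the final source row belongs
to no window: the last window covers rows T−L−1 … T−2. `collapse_to_series`
therefore raises on uncovered rows by default, and the pipeline explicitly
opts into a fallback for that single row — the observed source value where
present, otherwise the per-feature mean of the imputed matrix. For irregular
collections, entities longer than the cap keep their most recent L + 1 rows;
entities with T ≤ L form a single window front-padded with missing cells,
which generate no edges.

## Evaluation protocol

Masking is MCAR: each observed cell is hidden independently with probability
0.3 or 0.6, *before* windowing, so all window copies of a cell share its
missingness. RMSE is computed over masked cells only, on the normalized
scale (model outputs are not rescaled or rounded). Congeniality fits a
nonlinear model (gradient-boosted regression trees) and a linear model (OLS)
of the label on the other features, on the identical 70:30 split, for the
original and the imputed data; the gap in test-set R² measures how well the
imputation preserved feature–label relationships and is exactly zero for
perfect imputation. The label column is protected from masking by default so
the gap reflects feature-imputation quality; both that choice and the
normalization of the label are configurable.

## Synthetic data

The generator produces k latent AR(1) factors x_t = φ x_{t−1} + ε_t with
innovation variance 1 − φ², mapped through a loading matrix (random
unit-row-norm by default) to F features plus independent observation noise,
and optionally a label that is a known linear (or thresholded-binary)
function of the features. This provides exactly the two correlation axes the
windowed graph is designed to exploit — temporal autocorrelation and
cross-feature correlation — with closed-form checks (lag-1 autocorrelation
φ, loading-implied covariance ΛΛᵀ + σ²I, population R² of the label model).

It does **not** emulate real-data features such as heavy-tailed marginals,
regime changes, seasonality, missingness that is informative (MAR/MNAR), or
cross-entity heterogeneity beyond independent latent paths. Passing tests on
this generator demonstrate that the implementation exploits temporal and
cross-feature structure when present; they do not certify performance on any
particular real dataset.

Desk-scale problem sizes are used throughout the test suite and the
acceptance script: the regular fixture is T = 300, five features plus a
protected label, L = 10 (model size 14,500 edges), trained for 500 epochs,
with medians over 3 seeds for stochastic comparisons; the irregular fixture
is 550 entities with lengths uniform on {9 … 21} (mean 15). These sizes were
chosen so a full evaluation grid trains in minutes on one CPU while leaving
the architecture and all other defaults identical to the full-scale
configuration.

## Numerical choices

- The network trains on a small reverse-mode autodiff core over numpy
  (`tsignn.autodiff`) with sparse-matrix neighborhood aggregation; gradients
  are validated against central finite differences in the test suite.
- Constant features scale to 0 with a warning (zero span).
- Isolated observation nodes (all cells missing in a row) receive a zero
  aggregate, not an error.
- Non-finite training loss aborts with a diagnostic; optional global
  gradient-norm clipping is off by default.
- Ties in `determine_sequence_length` round half away from zero.
- The threshold gate is inclusive (size ≤ threshold trains).

## Known limitations

- Full-batch training keeps the whole graph in memory; the threshold gate is
  the guard rail, and minibatched neighbor sampling is out of scope.
- Only MCAR masking is implemented; informative missingness mechanisms are
  future work.
- The windowed construction multiplies edge count by roughly L, so at low
  missing rates large inputs hit the budget quickly; at desk scale the
  advantage of windowing over the plain bipartite construction is directional
  (clear against mean imputation, modest against the non-windowed graph).
- Categorical features ride as {0,1}-valued continuous edges; no dedicated
  discrete head, and RMSE over mixed feature types inherits the usual bias.
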