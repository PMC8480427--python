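# tsignn — temporal-setting imputation with joint bipartite graph neural networks

Missing values are pervasive in multivariate time series — clinical
observations charted at irregular intervals, sensor feeds with dropouts,
financial histories with gaps. Graph-based imputers represent a data matrix
as a bipartite graph (observation nodes vs feature nodes, observed values as
attributed edges) and learn to predict the value of every
(observation, feature) pair, but the plain construction treats rows as
exchangeable and discards temporal order. `tsignn` implements the
*joint bipartite graph* remedy: the series is first cut into sliding windows
and flattened, so that sequence context is folded into the observation-node
set itself — no observation–observation edges are ever created, and the graph
remains properly bipartite.

The package is aimed at biostatisticians and ML practitioners who need a
temporal imputer plus a complete, reproducible evaluation harness (masking,
scoring, baselines, synthetic data) that runs on a laptop CPU.

## Method

Given a T×F series and sequence length L, the pipeline is:

1. **Window + flatten.** Cut into W = T − L sliding windows (stride 1) and
   reshape the W×L×F array row-major into an M×F design matrix, M = W·L.
   The reshape is exactly invertible, so sequence information survives.
2. **Graph.** Build G(V, E) with observation nodes u₁…u_m (one per flat row),
   feature nodes v₁…v_n, and one attributed edge per *observed* cell carrying
   its min–max-scaled value. Fully observed,

       |E| = (T − L) · L · F  ≤  threshold,

   and the estimator/threshold gate (default 4,000,000) refuses oversized
   models before training.
3. **GNN.** A 3-layer GraphSAGE-style network with edge embeddings
   (64 hidden units, mean aggregation, ReLU; Adam, lr 0.001, 2000 epochs by
   default). Per layer: message = ReLU(W·[h_j, e_ij]); mean-aggregate over
   neighbors; node update h_i = ReLU(Q·[h_i, agg]); edge update
   e_ij = ReLU(P·[e_ij, h_i, h_j]). An MLP head on [h_u, h_v] predicts every
   cell; training minimizes MSE on observed edges with per-epoch edge dropout.
4. **Collapse.** Each source cell appears in up to L windows; the imputed
   copies are reconciled (mean by default) back onto the original T×F grid,
   with observed values passed through untouched.

The evaluation harness reproduces the standard protocol: hide 30% or 60% of
cells completely at random, impute, report RMSE over masked cells on the
normalized scale, and check *congeniality* — R² of downstream predictors
(gradient-boosted trees and OLS, identical 70:30 holdout) on imputed vs
original data. Baselines: mean, linear/spline/cubic interpolation, KNN, and
the non-windowed plain-bipartite graph imputer as the ablation of the
windowing step.

## Worked example

```python
import numpy as np
from tsignn import (desk_scale_spec, generate_regular, apply_mcar_mask,
                    normalize, impute_series, baseline_impute, rmse_masked,
                    ImputerConfig, estimate_size)

print(estimate_size(4120, 21, 6))
# size 516474 vs threshold 4000000: within budget

series = generate_regular(desk_scale_spec(seed=0))        # 300 x (5+label)
masked, mask = apply_mcar_mask(series, 0.3, seed=0,
                               label_protected=True, label_name="label")
scaled, stats = normalize(masked)
truth, _ = normalize(series, stats)

imputed, model = impute_series(scaled, sequence_length=10,
                               config=ImputerConfig(epochs=500, seed=0))
print(round(rmse_masked(imputed, truth, mask), 4))        # 0.1199
print(round(rmse_masked(baseline_impute(scaled, "mean"), truth, mask), 4))
#                                                           0.1752
```

The two numbers are masked-cell RMSE on the [0, 1] scale: the windowed graph
imputer recovers the hidden 30% of cells with about a third less error than
mean imputation on this autocorrelated fixture.

The same pipeline is available from the shell:

```bash
tsignn size --obs 4120 --seq-len 21 --features 6
tsignn simulate --kind irregular --seed 1 --out data/
tsignn impute --input data.csv --seq-len auto --out completed.csv
tsignn evaluate --input data.csv --methods mean,knn,tsignn --label label \
       --out results.csv --report report.md
```

Every command writes a JSON manifest (seeds, config, input hash) sufficient
to reproduce the run.

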