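# allercast

Spatiotemporal graph-convolutional forecasting of daily allergic-disease
patient counts from regional PM10 concentrations.

Asthma, allergic rhinitis and atopic dermatitis wax and wane with air
pollution, season and what is happening in neighbouring districts. Given a
panel of daily patient counts per administrative district, district-level
PM10 concentrations and calendar covariates, `allercast` forecasts the next
1–14 days of counts per district. It is written for epidemiologists and
health-service planners who work with district-level surveillance extracts,
and for methodologists who want a transparent, dependency-light reference
implementation of this model family.

## The model

Districts form a graph G = (V, E): nodes are district centroids, edges join
k-nearest neighbours (great-circle distance, union-symmetrised). With node
attributes X_t (counts for the three diseases, PM10, year/month/day), the
forecasting task is

    <X_{t+1}, ..., X_{t+l_p}> = f(A, <X_{t-l_h+1}, ..., X_t>),  l_h = 14.

The core forecaster (MST-GCN) applies, for each day of the history window, a
stack of graph convolutions over the renormalised adjacency
Â = D̃^{-1/2}(A+I)D̃^{-1/2},

    H^(n) = ReLU( Â H^(n-1) θ^(n) + H^(n-1) θ_r^(n) ),

feeds the per-district embedding sequence into a gated recurrent unit shared
across districts, and emits all l_p future days through an affine readout.
Training minimises ‖Y − Ŷ‖² + λ‖θ‖² with Adam. Four baselines are included:
per-district seasonal ARIMA (default (1,0,1)(0,1,1)₁₄), GCN-only, GRU-only
and T-GCN. Performance is reported as RMSE, MAE, ACC = 1 − ‖Y−Ŷ‖_F/‖Y‖_F,
R² and explained variance on min-max-normalised targets.

The neural models are implemented directly on NumPy with a small
reverse-mode autodiff core — no deep-learning framework required.

Because the national health-insurance and air-quality extracts this kind of
analysis uses are application-gated, the package ships a synthetic generator
(`allercast.synthetic`) producing panels with the same statistical skeleton
— spatially correlated seasonal PM10 driving disease-specific lagged counts
that diffuse between neighbouring districts — with full ground truth for
recovery experiments. See `docs/methods.md` for the model, the generator
and every design decision.

## Worked example

```python
import allercast as ac

# a synthetic study: 20 districts, 2 years, known generative parameters
config = ac.SyntheticConfig(n_regions=20, n_days=730, seed=7, knn_k=3)
panel, regions, network, truth = ac.generate_dataset(config)
print(panel.values.shape, panel.feature_names)

# windows: 14-day history, 1-day-ahead target, chronological 70/10/20 split
windows = ac.prepare_windows(panel, l_h=14, l_p=1, target_features=["asthma"])

model_cfg = ac.ModelConfig(model_kind="mstgcn", gcn_hidden=16, gru_hidden=32, seed=0)
train_cfg = ac.TrainConfig(epochs=150, learning_rate=5e-3, patience=30, seed=0)
report = ac.train_and_evaluate(model_cfg, windows, network, train_cfg)
print(f"RMSE {report.rmse:.3f}  MAE {report.mae:.3f}  ACC {report.acc:.3f}  "
      f"R2 {report.r2:.3f}  var {report.var:.3f}")
```

Output:

```
(730, 20, 7) ['asthma', 'atopic_dermatitis', 'allergic_rhinitis', 'pm10', 'year', 'month', 'day']
RMSE 0.073  MAE 0.058  ACC 0.797  R2 0.647  var 0.647
```

The panel holds 730 days x 20 districts x 7 node attributes. The scores are
on the normalised scale: the model explains ~65% of the held-out variance
in daily asthma counts, with a mean absolute error of ~0.06 of the
feature's training-span range. The remainder is mostly the Poisson
observation noise the default generator puts on counts of this size
(baseline ≈ 60/day), which no forecaster can remove.

The same pipeline is scriptable from the shell:

```sh
allercast simulate --config cfg.yaml --out study/
allercast build-graph --regions study/regions.csv --k 5 --out study/graph/
allercast compare --panel study/panel.csv --regions study/regions.csv --out compare.csv
allercast ablate  --panel study/panel.csv --regions study/regions.csv --out ablate.csv
allercast horizon --panel study/panel.csv --regions study/regions.csv --out horizon.csv
```

`compare` runs the five-model x four-disease-set grid, `ablate` refits the
forecaster with and without the PM10 input, and `horizon` sweeps 1/7/14-day
forecasts.

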