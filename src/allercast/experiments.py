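"""End-to-end experiment protocols.

Three studies, all on the normalised target scale:

* model comparison — five forecasters x four disease sets (the three
  allergies singly, and all three jointly; the univariate seasonal ARIMA is
  skipped for the joint cell);
* PM10 ablation — the spatiotemporal forecaster with and without the PM10
  input column, identical seeds and schedules;
* horizon sweep — forecasts 1, 7 and 14 days ahead per disease set.

Each cell yields a :class:`~allercast.metrics.MetricReport`; failures are
recorded rather than aborting the grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import MetricReport, compute_metrics, average_reports
from .models import ModelConfig, SarimaSpec, make_model, sarima_rolling_forecast
from .network import DiseaseNetwork
from .preprocess import (
    DISEASES,
    PanelDataset,
    WindowSet,
    apply_minmax,
    chronological_split,
    fit_minmax,
    invert_minmax,
    make_windows,
)
from .train import TrainConfig, train

logger = logging.getLogger(__name__)

DISEASE_SETS = {
    "all": list(DISEASES),
    "asthma": ["asthma"],
    "atopic_dermatitis": ["atopic_dermatitis"],
    "allergic_rhinitis": ["allergic_rhinitis"],
}


@dataclass
class ExperimentResult:
    """Grid of metric reports keyed by (model, disease_set, horizon, variant)."""

    cells: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def add(self, key: tuple, report: MetricReport) -> None:
        self.cells[key] = report

    def fail(self, key: tuple, error: Exception) -> None:
        self.failures[key] = repr(error)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (model, disease_set, horizon, variant), rep in self.cells.items():
            rows.append(
                {
                    "model": model,
                    "disease_set": disease_set,
                    "horizon": horizon,
                    "variant": variant,
                    **{k: getattr(rep, k) for k in ("rmse", "mae", "acc", "r2", "var")},
                }
            )
        return pd.DataFrame(rows)

    def to_table(self, value: str = "r2") -> pd.DataFrame:
        """Pivot one score into the models x disease-sets layout."""
        df = self.to_frame()
        return df.pivot_table(index="model", columns="disease_set", values=value)


@dataclass
class SplitWindows:
    """Normalised train/val/test windows plus the shared scaler state."""

    train: WindowSet
    val: WindowSet
    test: WindowSet
    norm_state: object
    feature_names: list
    target_features: list


def prepare_windows(
    panel: PanelDataset,
    l_h: int,
    l_p: int,
    target_features: list,
    fractions: tuple = (0.7, 0.1, 0.2),
    drop_features: tuple = (),
) -> SplitWindows:
    """Chronological split, train-span min-max fit, and window slicing."""
    if drop_features:
        keep = [f for f in panel.feature_names if f not in set(drop_features)]
        panel = panel.select_features(keep)
    train_panel, val_panel, test_panel = chronological_split(panel, fractions)
    state = fit_minmax(train_panel)
    train_n = apply_minmax(train_panel, state)
    val_n = apply_minmax(val_panel, state)
    test_n = apply_minmax(test_panel, state)
    return SplitWindows(
        train=make_windows(train_n, l_h, l_p, target_features),
        val=make_windows(val_n, l_h, l_p, target_features),
        test=make_windows(test_n, l_h, l_p, target_features),
        norm_state=state,
        feature_names=list(panel.feature_names),
        target_features=list(target_features),
    )


def evaluate(model, test_windows: WindowSet, norm_state=None, target_idx=None) -> dict:
    """Score a trained model on held-out windows (normalised scale).

    Returns the report plus the denormalised predictions when the scaler
    state and target feature indices are provided.
    """
    pred = model.predict(test_windows.histories)
    report = compute_metrics(test_windows.targets, pred)
    out = {"report": report, "predictions": pred}
    if norm_state is not None and target_idx is not None:
        out["predictions_original_scale"] = invert_minmax(pred, norm_state, target_idx)
    return out


def train_and_evaluate(
    model_config: ModelConfig,
    windows: SplitWindows,
    network: DiseaseNetwork | None,
    train_config: TrainConfig,
) -> MetricReport:
    """Fit one neural forecaster and report test metrics."""
    n_features = windows.train.histories.shape[-1]
    d_out = windows.train.targets.shape[-1]
    cfg = replace(model_config, l_p=windows.train.l_p, l_h=windows.train.l_h, d_out=d_out)
    model = make_model(cfg, n_features, network)
    history = train(model, windows.train, windows.val, train_config)
    result = evaluate(model, windows.test)
    report = result["report"]
    report.metadata.update(
        model_kind=cfg.model_kind, l_p=cfg.l_p, seed=train_config.seed,
        val_mse=history["best_val_loss"],
    )
    return report


def sarima_cell(
    panel: PanelDataset,
    disease: str,
    l_h: int,
    l_p: int,
    spec: SarimaSpec | None = None,
    fractions: tuple = (0.7, 0.1, 0.2),
) -> MetricReport:
    """Per-region seasonal ARIMA over the same test days as the neural models.

    Each region's normalised series is fitted on the train+validation span
    extended by the first ``l_h`` test days (which the neural models consume
    as history only), then the remaining test days are forecast in blocks of
    ``l_p``.  Scores are computed per region and averaged; non-convergent
    regions are excluded with a warning.
    """
    spec = spec or SarimaSpec()
    train_panel, val_panel, test_panel = chronological_split(panel, fractions)
    state = fit_minmax(train_panel)
    fidx = panel.feature_index(disease)
    series = apply_minmax(panel, state).values[:, :, fidx]  # (T, N)
    n_train = train_panel.n_days + val_panel.n_days + l_h
    reports = []
    for i in range(panel.n_regions):
        try:
            preds = sarima_rolling_forecast(
                series[:n_train, i], series[n_train:, i], spec, horizon=l_p
            )
            reports.append(compute_metrics(series[n_train:, i], preds))
        except Exception as err:  # noqa: BLE001 - a failed region must not kill the grid
            logger.warning("SARIMA failed for region %s: %r", panel.region_ids[i], err)
    if not reports:
        raise RuntimeError("SARIMA failed on every region")
    return average_reports(
        reports, metadata={"model_kind": "sarima", "l_p": l_p, "spec": str(spec)}
    )


NEURAL_MODELS = ("gcn", "gru", "tgcn", "mstgcn")


def run_comparison(
    panel: PanelDataset,
    network: DiseaseNetwork,
    model_config: ModelConfig,
    train_config: TrainConfig,
    l_h: int = 14,
    l_p: int = 1,
    models: tuple = ("sarima",) + NEURAL_MODELS,
    disease_sets: dict | None = None,
) -> ExperimentResult:
    """Models x disease-sets grid; SARIMA is skipped for the joint cell."""
    disease_sets = disease_sets or DISEASE_SETS
    result = ExperimentResult()
    for set_name, targets in disease_sets.items():
        windows = prepare_windows(panel, l_h, l_p, targets)
        for model_kind in models:
            key = (model_kind, set_name, l_p, "full")
            if model_kind == "sarima":
                if len(targets) > 1:
                    continue  # univariate model: no joint-disease cell
                try:
                    result.add(key, sarima_cell(panel, targets[0], l_h, l_p))
                except Exception as err:  # noqa: BLE001
                    result.fail(key, err)
                continue
            try:
                cfg = replace(model_config, model_kind=model_kind)
                result.add(key, train_and_evaluate(cfg, windows, network, train_config))
            except Exception as err:  # noqa: BLE001
                logger.warning("cell %s failed: %r", key, err)
                result.fail(key, err)
    return result


def run_ablation_pm10(
    panel: PanelDataset,
    network: DiseaseNetwork,
    model_config: ModelConfig,
    train_config: TrainConfig,
    l_h: int = 14,
    l_p: int = 1,
    disease_sets: dict | None = None,
) -> ExperimentResult:
    """Paired fits with and without the PM10 input column, identical seeds."""
    disease_sets = disease_sets or DISEASE_SETS
    result = ExperimentResult()
    for set_name, targets in disease_sets.items():
        for variant, drop in (("with_pm10", ()), ("without_pm10", ("pm10",))):
            windows = prepare_windows(panel, l_h, l_p, targets, drop_features=drop)
            key = ("mstgcn", set_name, l_p, variant)
            try:
                result.add(
                    key, train_and_evaluate(model_config, windows, network, train_config)
                )
            except Exception as err:  # noqa: BLE001
                result.fail(key, err)
    return result


def run_horizon_sweep(
    panel: PanelDataset,
    network: DiseaseNetwork,
    model_config: ModelConfig,
    train_config: TrainConfig,
    l_h: int = 14,
    horizons: tuple = (1, 7, 14),
    disease_sets: dict | None = None,
) -> ExperimentResult:
    """One spatiotemporal fit per horizon per disease set."""
    disease_sets = disease_sets or DISEASE_SETS
    result = ExperimentResult()
    for set_name, targets in disease_sets.items():
        for l_p in horizons:
            windows = prepare_windows(panel, l_h, l_p, targets)
            key = ("mstgcn", set_name, l_p, "full")
            try:
                result.add(
                    key, train_and_evaluate(model_config, windows, network, train_config)
                )
            except Exception as err:  # noqa: BLE001
                result.fail(key, err)
    return result
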