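"""The five-score evaluation report used throughout the experiments.

On truth Y and prediction Y^ (any matching shapes, pooled elementwise):

    RMSE = sqrt(mean (Y - Y^)^2)
    MAE  = mean |Y - Y^|
    ACC  = 1 - ||Y - Y^||_F / ||Y||_F        (normalised-error score)
    R^2  = 1 - SSE / SStot
    var  = 1 - Var(Y - Y^) / Var(Y)          (explained variance)

ACC is the Frobenius-ratio form; the literal 1 - RMSE/||Y||_F variant is
scale-inconsistent (RMSE is a per-element average, the norm is not) but is
available via ``acc_literal=True`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass
class MetricReport:
    rmse: float
    mae: float
    acc: float
    r2: float
    var: float
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "metadata"}
        d.update(self.metadata)
        return d


def compute_metrics(
    y_true, y_pred, acc_literal: bool = False, metadata: dict | None = None
) -> MetricReport:
    """Pooled five-score report; arrays are flattened before scoring.

    A constant truth leaves R^2 and var undefined; they are reported as NaN
    with a warning.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yh.shape:
        raise ValueError("shape mismatch between truth and prediction")
    if y.size < 2:
        raise ValueError("need at least 2 elements")
    resid = y - yh
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    norm_y = float(np.linalg.norm(y))
    if acc_literal:
        acc = 1.0 - rmse / norm_y if norm_y > 0 else np.nan
    else:
        acc = 1.0 - float(np.linalg.norm(resid)) / norm_y if norm_y > 0 else np.nan
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant truth: R^2 and explained variance undefined")
        r2 = np.nan
        var = np.nan
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        var = 1.0 - float(np.var(resid)) / float(np.var(y))
    return MetricReport(rmse, mae, acc, r2, var, metadata=dict(metadata or {}))


def average_reports(reports: list, metadata: dict | None = None) -> MetricReport:
    """Mean of each score across reports (NaN-aware), e.g. per-region SARIMA."""
    if not reports:
        raise ValueError("no reports to average")
    fields = ("rmse", "mae", "acc", "r2", "var")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = {f: float(np.nanmean([getattr(r, f) for r in reports])) for f in fields}
    return MetricReport(**means, metadata=dict(metadata or {}))
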