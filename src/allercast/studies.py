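"""Preset study conditions for the synthetic recovery experiments.

These fix the generative conditions under which the package demonstrates
that the spatiotemporal forecaster recovers planted structure:

* ``recovery`` — strong spatial signal: diffusion 0.4 between neighbouring
  regions, a PM10 lag kernel concentrated on lags 0-3, a rough PM10 field
  (10 km correlation length, so neighbouring regions carry genuinely
  distinct pollution histories), a sparse graph (k=2) and Gaussian count
  noise large enough (sd 15 on baselines 150-250) that neighbourhood
  information is worth having.
* ``decoupled`` — the same panel with the PM10 lag kernel zeroed: counts
  ignore pollution, so removing the PM10 input must not matter.
* ``no_spatial`` — spatial diffusion zeroed and independent PM10: graph
  layers cannot help.
* ``persistent`` — strongly autocorrelated PM10 (AR coefficient 0.98) and a
  broad lag kernel: the process stays predictable many days ahead, the
  regime in which multi-horizon accuracy should be stable.

The same presets drive the test suite and the acceptance script, so every
reported number comes from one set of frozen conditions.
"""

from __future__ import annotations

import numpy as np

from .models import ModelConfig
from .synthetic import DiseaseProfile, SyntheticConfig, _kernel, generate_dataset
from .train import TrainConfig

RECOVERY_LAG_KERNEL = {0: 1.0, 1: 0.8, 2: 0.5, 3: 0.3}
_PHASES = {"asthma": 0.0, "atopic_dermatitis": np.pi / 2, "allergic_rhinitis": np.pi}
_BASELINES = {"asthma": 200.0, "atopic_dermatitis": 150.0, "allergic_rhinitis": 250.0}


def _profiles(lag_kernel: dict, diffusion: float, obs_noise: float = 15.0,
              seasonal_amp: float = 10.0) -> list:
    return [
        DiseaseProfile(
            name=name,
            baseline=_BASELINES[name],
            seasonal_amp=seasonal_amp,
            lag_kernel=_kernel(lag_kernel),
            spatial_diffusion=diffusion,
            obs_noise=obs_noise,
            phase=_PHASES[name],
        )
        for name in _BASELINES
    ]


def recovery_panel(seed: int, n_regions: int = 30, n_days: int = 500):
    """Strong spatial + PM10 signal: the model-comparison study conditions."""
    config = SyntheticConfig(
        n_regions=n_regions, n_days=n_days, seed=seed,
        pm10_spatial_length=10.0, knn_k=2,
    )
    profiles = _profiles(RECOVERY_LAG_KERNEL, diffusion=0.4)
    return generate_dataset(config, profiles, noise="gaussian")


def decoupled_panel(seed: int, n_regions: int = 30, n_days: int = 500):
    """PM10-decoupled null: counts never react to pollution.

    The seasonal amplitude is raised and the count noise lowered relative
    to the recovery panel so the counts keep substantial predictable
    structure: R^2 is then a stable statistic and the with/without-PM10
    difference measures the (absent) PM10 contribution rather than fit
    noise.
    """
    config = SyntheticConfig(
        n_regions=n_regions, n_days=n_days, seed=seed,
        pm10_spatial_length=10.0, knn_k=2,
    )
    profiles = _profiles({}, diffusion=0.4, obs_noise=5.0, seasonal_amp=30.0)
    return generate_dataset(config, profiles, noise="gaussian")


def no_spatial_panel(seed: int, n_regions: int = 30, n_days: int = 500):
    """Zero spatial coupling: regions evolve independently given season."""
    config = SyntheticConfig(
        n_regions=n_regions, n_days=n_days, seed=seed,
        pm10_spatial_length=0.1, knn_k=2,
    )
    profiles = _profiles(RECOVERY_LAG_KERNEL, diffusion=0.0)
    return generate_dataset(config, profiles, noise="gaussian")


def persistent_panel(seed: int, n_regions: int = 30, n_days: int = 560):
    """Slowly varying process for the multi-horizon stability study.

    The PM10 anomaly decays with coefficient 0.98/day (autocorrelation 0.75
    across the 14-day horizon) and its innovations are small next to the
    annual cycle, so the information available for 14-day-ahead prediction
    is nearly that of 1-day-ahead.
    """
    config = SyntheticConfig(
        n_regions=n_regions, n_days=n_days, seed=seed,
        pm10_ar_coef=0.98, pm10_spatial_length=50.0, pm10_noise_sd=3.0, knn_k=3,
    )
    profiles = _profiles({l: 0.2 for l in range(8)}, diffusion=0.2, obs_noise=4.0)
    return generate_dataset(config, profiles, noise="gaussian")


def study_model_config(kind: str, seed: int = 0) -> ModelConfig:
    """Compact forecaster configuration used across the recovery studies."""
    return ModelConfig(
        model_kind=kind, gcn_hidden=16, gru_hidden=32, seed=seed, dtype="float32"
    )


def study_train_config(seed: int = 0, epochs: int = 150) -> TrainConfig:
    return TrainConfig(
        epochs=epochs, learning_rate=5e-3, batch_size=96, patience=25, seed=seed
    )


# ---------------------------------------------------------------------------
# study runners (shared by the test suite and the acceptance script)
# ---------------------------------------------------------------------------

def _persistence_val_mse(windows) -> float:
    """Validation MSE of the trivial forecast: every future day = last observed."""
    idx = [windows.feature_names.index(f) for f in windows.target_features]
    last = windows.val.histories[:, -1, :, :][:, :, idx]  # (S, N, D)
    return float(np.mean((windows.val.targets - last[:, None, :, :]) ** 2))


def _fit(kind: str, windows, network, seed: int, epochs: int = 100,
         max_attempts: int = 2):
    """Train one forecaster with validation-guarded restarts.

    Gradient training of these compact recurrent networks occasionally
    lands in a degenerate trajectory; a fit whose best validation MSE is
    worse than the persistence forecast has clearly failed to converge and
    is retried with a fresh initialisation (selection uses validation only,
    never test data).  The attempt with the best validation MSE is kept.
    """
    from .experiments import train_and_evaluate

    floor = _persistence_val_mse(windows)
    best = None
    for attempt in range(max_attempts):
        attempt_seed = seed + 1000 * attempt
        rep = train_and_evaluate(
            study_model_config(kind, attempt_seed), windows,
            network, study_train_config(attempt_seed, epochs=epochs),
        )
        if best is None or rep.metadata["val_mse"] < best.metadata["val_mse"]:
            best = rep
        if best.metadata["val_mse"] < floor:
            break
    return best


def spatial_recovery_study(seeds=(0, 1, 2), target: str = "asthma") -> dict:
    """Train the spatiotemporal model and the GRU baseline per seed.

    Returns per-seed test R^2 for both models on the strong-signal panel;
    the planted spatial structure should make the graph model win.
    """
    from .experiments import prepare_windows

    out = {"mstgcn": [], "gru": []}
    for seed in seeds:
        panel, _, network, _ = recovery_panel(100 + seed)
        windows = prepare_windows(panel, 14, 1, [target])
        for kind in ("mstgcn", "gru"):
            out[kind].append(_fit(kind, windows, network, seed).r2)
    return out


def pm10_ablation_study(seeds=(0, 1, 2), decoupled: bool = False,
                        target: str = "asthma",
                        precomputed_with: list | None = None) -> dict:
    """Paired with/without-PM10 fits per seed; returns per-seed R^2 deltas.

    Both arms share seed, schedule and panel, differing only by the PM10
    input column.  ``precomputed_with`` lets a caller that already trained
    the full model on these exact panels (the spatial-recovery study) pass
    its R^2 values instead of refitting the with-PM10 arm; it applies only
    to the PM10-driven panels, never the decoupled null.
    """
    from .experiments import prepare_windows

    epochs = 100
    deltas, with_r2, without_r2 = [], [], []
    for i, seed in enumerate(seeds):
        make_panel = decoupled_panel if decoupled else recovery_panel
        panel, _, network, _ = make_panel(100 + seed)
        pair = {}
        for variant, drop in (("with", ()), ("without", ("pm10",))):
            if variant == "with" and not decoupled and precomputed_with is not None:
                pair[variant] = precomputed_with[i]
                continue
            windows = prepare_windows(panel, 14, 1, [target], drop_features=drop)
            pair[variant] = _fit("mstgcn", windows, network, seed, epochs=epochs).r2
        deltas.append(pair["with"] - pair["without"])
        with_r2.append(pair["with"])
        without_r2.append(pair["without"])
    return {"delta": deltas, "with_pm10": with_r2, "without_pm10": without_r2}


def horizon_stability_study(seed: int = 0, horizons=(1, 14),
                            target: str = "asthma") -> dict:
    """R^2 per forecast horizon on the persistent process."""
    from .experiments import prepare_windows

    panel, _, network, _ = persistent_panel(100 + seed)
    out = {}
    for l_p in horizons:
        windows = prepare_windows(panel, 14, l_p, [target])
        out[l_p] = _fit("mstgcn", windows, network, seed, epochs=120).r2
    return out
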