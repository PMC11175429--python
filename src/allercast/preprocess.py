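"""From raw extracts to the aligned region x day x feature panel.

Two raw sources feed the analysis: long-form daily patient counts per
administrative district, stratified by visit type, age group and sex, and
hourly PM10 concentrations from monitoring stations.  This module collapses
the strata, averages stations to days and days to regions, appends calendar
covariates, min-max normalises on the training span only, and slices the
panel into supervised (history, target) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .network import haversine_distance

DISEASES = ("asthma", "atopic_dermatitis", "allergic_rhinitis")
CALENDAR_FEATURES = ("year", "month", "day")


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------

@dataclass
class MinMaxState:
    """Per-feature (min, max) fitted on the training span."""

    feature_min: np.ndarray
    feature_max: np.ndarray

    def as_dict(self) -> dict:
        return {
            "feature_min": [float(v) for v in self.feature_min],
            "feature_max": [float(v) for v in self.feature_max],
        }


@dataclass
class PanelDataset:
    """Dense panel of node attributes: values[t, i, f] on day t, region i.

    Dates are strictly increasing with daily spacing and no gaps; after
    preprocessing there are no missing values.
    """

    values: np.ndarray  # (T, N, F)
    dates: pd.DatetimeIndex
    region_ids: list
    feature_names: list
    norm_state: MinMaxState | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        t, n, f = self.values.shape
        if len(self.dates) != t or len(self.region_ids) != n or len(self.feature_names) != f:
            raise ValueError("panel axis labels do not match value shape")
        diffs = np.diff(self.dates.values).astype("timedelta64[D]")
        if t > 1 and not np.all(diffs == np.timedelta64(1, "D")):
            raise ValueError("dates must be consecutive days")
        if np.isnan(self.values).any():
            raise ValueError("panel contains missing values")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def select_features(self, names: list) -> "PanelDataset":
        idx = [self.feature_index(n) for n in names]
        state = None
        if self.norm_state is not None:
            state = MinMaxState(
                self.norm_state.feature_min[idx], self.norm_state.feature_max[idx]
            )
        return PanelDataset(
            self.values[:, :, idx], self.dates, self.region_ids, list(names), state
        )

    def slice_days(self, start: int, stop: int) -> "PanelDataset":
        return replace(
            self,
            values=self.values[start:stop],
            dates=self.dates[start:stop],
        )

    # -- tidy CSV round-trip ------------------------------------------------
    def to_csv(self, path) -> None:
        t, n, f = self.values.shape
        df = pd.DataFrame(
            {
                "date": np.repeat(self.dates, n * f),
                "region_id": np.tile(np.repeat(self.region_ids, f), t),
                "feature": np.tile(self.feature_names, t * n),
                "value": self.values.ravel(),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        df = pd.read_csv(path, parse_dates=["date"])
        dates = pd.DatetimeIndex(sorted(df["date"].unique()))
        region_ids = list(pd.unique(df["region_id"]))
        feature_names = list(pd.unique(df["feature"]))
        wide = df.pivot_table(
            index="date", columns=["region_id", "feature"], values="value", sort=False
        )
        cols = pd.MultiIndex.from_product([region_ids, feature_names])
        values = wide.loc[dates, cols].to_numpy().reshape(
            len(dates), len(region_ids), len(feature_names)
        )
        return cls(values, dates, region_ids, feature_names)

    def save_norm_state(self, path) -> None:
        if self.norm_state is None:
            raise ValueError("no normalisation state fitted")
        with open(path, "w") as fh:
            yaml.safe_dump(self.norm_state.as_dict(), fh)


# ---------------------------------------------------------------------------
# patient counts
# ---------------------------------------------------------------------------

def aggregate_patient_counts(
    long_table: pd.DataFrame,
    date_range: pd.DatetimeIndex | None = None,
    region_ids: list | None = None,
) -> pd.DataFrame:
    """Collapse visit-type x age x sex strata to daily totals.

    Returns one row per (date, region_id, disease) with the summed count.
    Duplicate raw rows are summed, not deduplicated.  Combinations absent
    from the input appear as 0 when a declared ``date_range`` (and
    optionally ``region_ids``) establishes the full grid.
    """
    required = {"date", "region_id", "disease", "count"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (long_table["count"] < 0).any():
        raise ValueError("negative patient counts")
    unknown = set(long_table["disease"]) - set(DISEASES)
    if unknown:
        raise ValueError(f"unknown disease labels: {sorted(unknown)}")
    tbl = long_table.copy()
    tbl["date"] = pd.to_datetime(tbl["date"])
    agg = (
        tbl.groupby(["date", "region_id", "disease"], as_index=False)["count"]
        .sum()
    )
    if date_range is not None:
        regions = region_ids if region_ids is not None else sorted(agg["region_id"].unique())
        full = pd.MultiIndex.from_product(
            [date_range, regions, list(DISEASES)], names=["date", "region_id", "disease"]
        )
        agg = (
            agg.set_index(["date", "region_id", "disease"])
            .reindex(full, fill_value=0)
            .reset_index()
        )
    return agg


# ---------------------------------------------------------------------------
# PM10 station pipeline
# ---------------------------------------------------------------------------

def daily_mean_pm10(hourly_table: pd.DataFrame) -> pd.DataFrame:
    """Average hourly station PM10 to daily means, tracking missingness.

    A day with no valid hour is emitted with a NaN mean and missing
    fraction 1.0 (24 expected hours per day).
    """
    tbl = hourly_table.copy()
    tbl["date"] = pd.to_datetime(tbl["timestamp"]).dt.normalize()
    grouped = tbl.groupby(["station_id", "date"])["pm10"]
    out = grouped.agg(pm10="mean", n_valid="count").reset_index()
    out["missing_fraction"] = 1.0 - out["n_valid"] / 24.0
    return out.drop(columns="n_valid")


def filter_stations_by_missing_rate(
    daily_station_table: pd.DataFrame,
    threshold: float = 0.5,
    date_range: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Drop stations missing more than ``threshold`` of study days; interpolate the rest.

    A station's missing rate counts both days absent from the table and days
    present with a NaN mean, over the study span (``date_range``, defaulting
    to the span observed in the table).  Interior gaps of retained stations
    are filled by linear interpolation in time; edge gaps take the nearest
    observed value.
    """
    tbl = daily_station_table.copy()
    tbl["date"] = pd.to_datetime(tbl["date"])
    if date_range is None:
        date_range = pd.date_range(tbl["date"].min(), tbl["date"].max(), freq="D")
    n_days = len(date_range)
    kept = []
    for station, grp in tbl.groupby("station_id"):
        series = grp.set_index("date")["pm10"].reindex(date_range)
        missing_rate = series.isna().sum() / n_days
        if missing_rate > threshold:
            continue
        filled = series.interpolate(method="linear", limit_direction="both")
        kept.append(
            pd.DataFrame(
                {"station_id": station, "date": date_range, "pm10": filled.to_numpy()}
            )
        )
    if not kept:
        raise ValueError("all stations exceeded the missing-rate threshold")
    return pd.concat(kept, ignore_index=True)


def assign_stations_to_regions(
    station_coords: pd.DataFrame, regions: pd.DataFrame
) -> pd.Series:
    """Map each station to the nearest region centroid (great-circle)."""
    s = station_coords[["lon", "lat"]].to_numpy(dtype=float)
    r = regions[["lon", "lat"]].to_numpy(dtype=float)
    d = haversine_distance(s[:, None, :], r[None, :, :])
    nearest = d.argmin(axis=1)
    return pd.Series(
        [regions["region_id"].iloc[i] for i in nearest],
        index=station_coords["station_id"],
        name="region_id",
    )


def aggregate_pm10_by_region(
    daily_station_table: pd.DataFrame,
    station_coords: pd.DataFrame | None = None,
    regions: pd.DataFrame | None = None,
    region_assignment: pd.Series | None = None,
) -> pd.DataFrame:
    """Unweighted mean of station daily means per region and day.

    Regions with no assigned station are simply absent from the output (the
    panel keeps only regions covered by both data sources).
    """
    if region_assignment is None:
        if station_coords is None or regions is None:
            raise ValueError("need either region_assignment or station_coords+regions")
        region_assignment = assign_stations_to_regions(station_coords, regions)
    tbl = daily_station_table.copy()
    tbl["region_id"] = tbl["station_id"].map(region_assignment)
    tbl = tbl.dropna(subset=["region_id"])
    return (
        tbl.groupby(["region_id", "date"], as_index=False)["pm10"].mean()
    )


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------

def build_panel(
    counts: pd.DataFrame, region_pm10: pd.DataFrame, dates: pd.DatetimeIndex
) -> PanelDataset:
    """Join daily counts and regional PM10 into a dense panel.

    Only regions present in both sources are kept.  Feature order is the
    three diseases, then pm10; calendar covariates are appended separately.
    """
    regions = sorted(set(counts["region_id"]) & set(region_pm10["region_id"]))
    if not regions:
        raise ValueError("no region covered by both data sources")
    n, t = len(regions), len(dates)
    features = list(DISEASES) + ["pm10"]
    values = np.zeros((t, n, len(features)))
    count_wide = counts.pivot_table(
        index="date", columns=["region_id", "disease"], values="count", fill_value=0.0
    )
    for fi, disease in enumerate(DISEASES):
        cols = pd.MultiIndex.from_product([regions, [disease]])
        values[:, :, fi] = count_wide.reindex(index=dates, columns=cols, fill_value=0.0).to_numpy()
    pm_wide = region_pm10.pivot_table(index="date", columns="region_id", values="pm10")
    values[:, :, len(DISEASES)] = pm_wide.reindex(index=dates, columns=regions).to_numpy()
    panel = PanelDataset(values, dates, regions, features)
    return add_calendar_features(panel)


def add_calendar_features(panel: PanelDataset) -> PanelDataset:
    """Append integer year, month, day features, constant across regions."""
    t, n, _ = panel.values.shape
    cal = np.stack(
        [panel.dates.year, panel.dates.month, panel.dates.day], axis=-1
    ).astype(float)
    cal = np.broadcast_to(cal[:, None, :], (t, n, 3))
    return PanelDataset(
        np.concatenate([panel.values, cal], axis=2),
        panel.dates,
        panel.region_ids,
        panel.feature_names + list(CALENDAR_FEATURES),
        panel.norm_state,
    )


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def fit_minmax(panel: PanelDataset, training_days: int | None = None) -> MinMaxState:
    """Per-feature (min, max) over the first ``training_days`` days only."""
    span = panel.values if training_days is None else panel.values[:training_days]
    return MinMaxState(span.min(axis=(0, 1)), span.max(axis=(0, 1)))


def apply_minmax(panel: PanelDataset, state: MinMaxState) -> PanelDataset:
    """Scale to x' = (x - min) / (max - min); degenerate features map to 0.

    Values outside the training span may fall outside [0, 1]; they are not
    clipped.
    """
    span = state.feature_max - state.feature_min
    safe = np.where(span > 0, span, 1.0)
    scaled = (panel.values - state.feature_min) / safe
    scaled[..., span == 0] = 0.0
    return replace(panel, values=scaled, norm_state=state)


def invert_minmax(values: np.ndarray, state: MinMaxState, feature_idx=None) -> np.ndarray:
    """Map normalised values back to the original scale."""
    lo, hi = state.feature_min, state.feature_max
    if feature_idx is not None:
        lo, hi = lo[feature_idx], hi[feature_idx]
    return values * (hi - lo) + lo


# ---------------------------------------------------------------------------
# windows and splits
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Paired supervised samples: ``l_h`` days of history, ``l_p`` days of target."""

    histories: np.ndarray  # (S, l_h, N, F)
    targets: np.ndarray  # (S, l_p, N, D_out)
    l_h: int
    l_p: int
    target_features: list
    feature_names: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.histories.shape[0]

    def drop_feature(self, name: str) -> "WindowSet":
        idx = [i for i, f in enumerate(self.feature_names) if f != name]
        if len(idx) == len(self.feature_names):
            raise ValueError(f"feature {name!r} not present")
        return replace(
            self,
            histories=self.histories[:, :, :, idx],
            feature_names=[self.feature_names[i] for i in idx],
        )


def make_windows(
    panel: PanelDataset, l_h: int, l_p: int, target_features: list
) -> WindowSet:
    """Slide an (l_h history, l_p target) window over the panel.

    Yields S = T - l_h - l_p + 1 samples; history[s] ends the day before
    target[s] begins.
    """
    t = panel.n_days
    if t < l_h + l_p:
        raise ValueError(f"panel too short: T={t} < l_h+l_p={l_h + l_p}")
    target_idx = [panel.feature_index(f) for f in target_features]
    s = t - l_h - l_p + 1
    sliding = np.lib.stride_tricks.sliding_window_view(
        panel.values, l_h + l_p, axis=0
    )  # (S, N, F, l_h+l_p)
    window = sliding[:s].transpose(0, 3, 1, 2)  # (S, l_h+l_p, N, F)
    histories = np.ascontiguousarray(window[:, :l_h])
    targets = np.ascontiguousarray(window[:, l_h:, :, :][:, :, :, target_idx])
    return WindowSet(
        histories, targets, l_h, l_p, list(target_features), list(panel.feature_names)
    )


def chronological_split(
    panel: PanelDataset, fractions: tuple = (0.7, 0.1, 0.2)
) -> tuple:
    """Split days chronologically into train / validation / test panels.

    Windows are made within each span, so no window straddles a boundary.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    t = panel.n_days
    n_train = int(round(t * fractions[0]))
    n_val = int(round(t * fractions[1]))
    return (
        panel.slice_days(0, n_train),
        panel.slice_days(n_train, n_train + n_val),
        panel.slice_days(n_train + n_val, t),
    )
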