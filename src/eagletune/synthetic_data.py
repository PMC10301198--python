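"""Seeded synthetic daily sensor datasets for a subtropical tea plantation.

The regression task is predicting volumetric soil moisture content
(SMC, %) from six co-located sensor channels: air temperature, relative
humidity, light intensity, rainfall, soil temperature and soil electrical
conductivity (SEC).  No public dataset exists for the task, so this
module generates one with the statistical structure such plantation
records exhibit:

* seasonal, autocorrelated weather — sinusoidal annual air temperature
  with AR(1) noise, intermittent exponential rainfall, humidity that
  rises on wet days, lognormal light halved under rain cloud;
* a *bucket water balance* driving the latent moisture: rainfall fills
  the soil store at ``k_in`` % per mm, evapotranspiration drains it at
  ``k_et * ET`` % per day where ``ET`` is a linear function of
  temperature, light and humidity, and the store is limited to
  ``[floor, capacity]``;
* soil temperature as a smoothed (3-day EMA) copy of air temperature,
  and SEC coupled to the latent moisture — bulk conductivity rises with
  water content — plus a slow mean-reverting sensor drift.  The coupling
  is what makes the day's moisture recoverable from the day's readings,
  i.e. what makes a regression on daily rows learnable at all: without a
  state-carrying channel the bucket's memory of past rainfall would be
  invisible to any per-row model.

Observed SMC adds Gaussian sensor noise to the latent state, so the
best achievable test MSE on generated data is ``noise_sd**2`` — a known
noise floor that tuning experiments can be checked against.

Also provided: the raw-data aggregation and cleaning stages (per-day
averaging with rainfall summed, then robust outlier removal), a small
printed-table fixture, and CSV I/O with a documented header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chaos import ConfigurationError

__all__ = [
    "BucketParams",
    "SyntheticConfig",
    "SensorDataset",
    "CleaningReport",
    "generate",
    "table1_fixture",
    "daily_aggregate",
    "clean_outliers",
    "subdaily_expand",
    "pipeline_fixture",
    "read_csv",
    "write_csv",
]

#: CSV column order; timestamps are ISO-8601, "." decimal separator, UTF-8.
COLUMNS = [
    "timestamp",
    "air_temp_c",
    "humidity_pct",
    "light_lux",
    "rainfall_mm",
    "soil_temp_c",
    "sec_us_cm",
    "smc_pct",
]
FEATURE_COLUMNS = [
    "air_temp_c",
    "humidity_pct",
    "light_lux",
    "rainfall_mm",
    "soil_temp_c",
    "sec_us_cm",
]
TARGET_COLUMN = "smc_pct"

SEC_RANGE = (0.0, 5000.0)  # sensor measuring range, μS/cm
SMC_RANGE = (0.0, 100.0)  # sensor measuring range, %


@dataclass(frozen=True)
class BucketParams:
    """Water-balance coefficients of the soil moisture bucket.

    ``smc' = clip(smc + k_in * rain - k_et * ET, floor, capacity)`` with
    ``ET = et0 + et_temp * (T_air - 20) + et_light * light / 1e4
    - et_humidity * humidity / 100`` (% of soil water per day).
    """

    k_in: float = 0.35  # % SMC gained per mm of rainfall
    k_et: float = 1.0  # scaling of the evapotranspiration drain
    capacity: float = 45.0  # saturation, % SMC; excess rain runs off
    floor: float = 5.0  # residual moisture, % SMC
    et0: float = 1.6  # baseline ET, %/day
    et_temp: float = 0.03  # ET response to air temperature, %/day/°C
    et_light: float = 0.04  # ET response to light, %/day per 1e4 lux
    et_humidity: float = 0.35  # ET reduction by relative humidity


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate a 216-day subtropical record.

    Climate constants follow the study region (annual mean temperature
    20.4 °C, mean relative humidity 77%); the remainder are plumbing with
    realistic magnitudes, all overridable.
    """

    n_days: int = 216
    seed: int = 0
    noise_sd: float = 0.5  # SMC observation noise, % units
    rain_prob: float = 0.35  # daily probability of rain
    rain_mean: float = 8.0  # mean wet-day rainfall, mm
    temp_base: float = 20.4  # annual mean air temperature, °C
    temp_amp: float = 6.0  # seasonal amplitude, °C
    temp_ar_rho: float = 0.7  # AR(1) coefficient of temperature noise
    temp_ar_sd: float = 1.2  # marginal sd of temperature noise, °C
    humidity_base: float = 77.0  # mean relative humidity, %
    humidity_noise_sd: float = 3.0
    light_log_mean: float = 9.9  # lognormal location (~2e4 lux median)
    light_log_sd: float = 0.45
    sec_base: float = 118.0  # μS/cm at the reference moisture
    sec_coupling: float = 5.0  # μS/cm per % SMC deviation
    sec_walk_rho: float = 0.97  # AR(1) coefficient of the SEC drift
    sec_walk_sd: float = 0.1  # innovation sd of the SEC drift, μS/cm
    smc_init: float = 25.0  # initial soil moisture, %
    start: str = "2020-08-20"  # first day of the record
    bucket: BucketParams = field(default_factory=BucketParams)

    def __post_init__(self) -> None:
        if self.n_days < 10:
            raise ConfigurationError(f"n_days must be >= 10, got {self.n_days}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.rain_prob <= 1.0:
            raise ConfigurationError("rain_prob must lie in [0, 1]")
        if self.rain_mean < 0:
            raise ConfigurationError("rain_mean must be >= 0")


@dataclass
class SensorDataset:
    """Timestamped sensor table with the SMC regression target.

    Thin wrapper around a :class:`pandas.DataFrame` with the fixed column
    schema in :data:`COLUMNS`; construction validates the physical-range
    and ordering invariants.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)
        self.frame["timestamp"] = pd.to_datetime(self.frame["timestamp"])

    def validate(self) -> None:
        """Raise if any dataset invariant is violated."""
        f = self.frame
        ts = f["timestamp"].to_numpy()
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise ValueError("timestamps must be strictly increasing")
        checks = [
            ("humidity_pct", 0.0, 100.0),
            ("smc_pct", *SMC_RANGE),
            ("sec_us_cm", *SEC_RANGE),
        ]
        for col, lo, hi in checks:
            v = f[col].to_numpy()
            if (v < lo).any() or (v > hi).any():
                raise ValueError(f"{col} outside [{lo}, {hi}]")
        for col in ("rainfall_mm", "light_lux"):
            if (f[col].to_numpy() < 0).any():
                raise ValueError(f"{col} must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    def features(self) -> np.ndarray:
        """(n, 6) feature matrix: air temp, humidity, light, rainfall, soil temp, SEC."""
        return self.frame[FEATURE_COLUMNS].to_numpy(dtype=float)

    def targets(self) -> np.ndarray:
        return self.frame[TARGET_COLUMN].to_numpy(dtype=float)

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]

    def iloc(self, idx) -> "SensorDataset":
        return SensorDataset(self.frame.iloc[idx].reset_index(drop=True))


def generate(config: SyntheticConfig) -> SensorDataset:
    """Generate a daily synthetic dataset; deterministic for a given seed.

    The random stream is consumed in a fixed order (temperature noise,
    rain indicators, rain amounts, light, humidity noise, SEC drift, SMC
    observation noise), so two calls with equal configs are identical.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_days
    b = config.bucket

    dates = pd.date_range(config.start, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    # seasonal temperature, peaking in midsummer, with AR(1) noise
    innov_sd = config.temp_ar_sd * np.sqrt(max(1.0 - config.temp_ar_rho**2, 0.0))
    e = np.empty(n)
    e[0] = rng.normal(0.0, config.temp_ar_sd if config.temp_ar_sd > 0 else 0.0)
    innov = rng.normal(0.0, innov_sd if innov_sd > 0 else 0.0, size=n)
    for t in range(1, n):
        e[t] = config.temp_ar_rho * e[t - 1] + innov[t]
    air_temp = config.temp_base + config.temp_amp * np.sin(2.0 * np.pi * (doy - 110.0) / 365.0) + e

    wet = rng.uniform(size=n) < config.rain_prob
    amounts = rng.exponential(config.rain_mean, size=n) if config.rain_mean > 0 else np.zeros(n)
    rainfall = np.where(wet, amounts, 0.0)

    light = rng.lognormal(config.light_log_mean, config.light_log_sd, size=n)
    light = np.where(wet, 0.5 * light, light)

    humidity = np.clip(
        config.humidity_base
        + 8.0 * wet.astype(float)
        - 0.6 * (air_temp - config.temp_base)
        + rng.normal(0.0, config.humidity_noise_sd, size=n),
        40.0,
        100.0,
    )

    soil_temp = pd.Series(air_temp).ewm(span=3, adjust=False).mean().to_numpy()

    et = (
        b.et0
        + b.et_temp * (air_temp - 20.0)
        + b.et_light * light / 1e4
        - b.et_humidity * humidity / 100.0
    )

    latent = np.empty(n)
    prev = config.smc_init
    for t in range(n):
        prev = float(np.clip(prev + b.k_in * rainfall[t] - b.k_et * et[t], b.floor, b.capacity))
        latent[t] = prev

    walk = np.empty(n)
    sec_innov = rng.normal(0.0, config.sec_walk_sd, size=n)
    walk[0] = sec_innov[0]
    for t in range(1, n):
        walk[t] = config.sec_walk_rho * walk[t - 1] + sec_innov[t]
    sec = np.clip(
        config.sec_base + config.sec_coupling * (latent - config.smc_init) + walk, *SEC_RANGE
    )

    smc = np.clip(latent + rng.normal(0.0, config.noise_sd, size=n), *SMC_RANGE)

    ds = SensorDataset(
        pd.DataFrame(
            {
                "timestamp": dates,
                "air_temp_c": air_temp,
                "humidity_pct": humidity,
                "light_lux": light,
                "rainfall_mm": rainfall,
                "soil_temp_c": soil_temp,
                "sec_us_cm": sec,
                "smc_pct": smc,
            }
        )
    )
    ds.validate()
    return ds


_TABLE1_ROWS = [
    # date, air_temp, humidity, light, rainfall, soil_temp, smc, sec
    ("2021-03-16", 23.87, 100.00, 6968.00, 420.93, 18.77, 27.24, 115.75),
    ("2021-03-17", 24.98, 100.00, 5482.75, 410.00, 19.75, 27.15, 116.15),
    ("2021-03-18", 26.60, 100.00, 6266.00, 409.60, 20.67, 27.10, 116.17),
    ("2021-03-19", 26.67, 100.00, 7702.67, 409.60, 21.14, 27.06, 116.31),
    ("2021-03-22", 16.60, 86.40, 6658.00, 537.60, 16.98, 27.18, 120.27),
    ("2021-03-23", 17.36, 99.40, 3888.29, 536.37, 17.53, 27.06, 119.16),
    ("2021-03-24", 17.36, 94.15, 3492.50, 503.45, 17.63, 26.89, 118.76),
    ("2021-03-25", 15.70, 100.00, 134.00, 537.60, 18.87, 26.88, 118.56),
    ("2021-03-27", 21.85, 100.00, 1860.00, 411.20, 19.05, 26.94, 120.32),
]


def table1_fixture() -> SensorDataset:
    """Nine published example rows of processed plantation data, time-ascending.

    Rainfall values are stored verbatim from the printed table (their unit
    is not mm/day and is left uninterpreted).
    """
    df = pd.DataFrame(
        [
            {
                "timestamp": d,
                "air_temp_c": at,
                "humidity_pct": h,
                "light_lux": li,
                "rainfall_mm": r,
                "soil_temp_c": st,
                "sec_us_cm": sec,
                "smc_pct": smc,
            }
            for (d, at, h, li, r, st, smc, sec) in _TABLE1_ROWS
        ]
    )
    return SensorDataset(df)


def daily_aggregate(raw: SensorDataset) -> SensorDataset:
    """Collapse sub-daily readings to one row per calendar day.

    Every channel is averaged within the day except rainfall, which is an
    accumulation and is summed.  The output timestamp is the day at
    midnight.
    """
    if len(raw) == 0:
        raise ValueError("cannot aggregate an empty dataset")
    f = raw.frame.copy()
    day = f["timestamp"].dt.normalize()
    agg = {c: "mean" for c in COLUMNS if c != "timestamp"}
    agg["rainfall_mm"] = "sum"
    out = f.groupby(day).agg(agg).reset_index()
    return SensorDataset(out)


@dataclass(frozen=True)
class CleaningReport:
    """Outcome of :func:`clean_outliers`."""

    n_removed: int
    removed_indices: tuple[int, ...]


# channels screened by robust z-score; light on a log scale (lognormal tail),
# rainfall excluded (zero-inflated, its median absolute deviation degenerates)
_Z_CHANNELS = ["air_temp_c", "humidity_pct", "soil_temp_c", "sec_us_cm", "smc_pct"]
_Z_THRESHOLD = 3.5


def _robust_flags(frame: pd.DataFrame, threshold: float = _Z_THRESHOLD) -> np.ndarray:
    """Rows whose modified z-score exceeds the threshold on any screened channel."""
    flags = np.zeros(len(frame), dtype=bool)
    channels = {c: frame[c].to_numpy(dtype=float) for c in _Z_CHANNELS}
    channels["log_light"] = np.log10(frame["light_lux"].to_numpy(dtype=float) + 1.0)
    for v in channels.values():
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0.0:
            continue
        z = 0.6745 * np.abs(v - med) / mad
        flags |= z > threshold
    return flags


def _range_flags(frame: pd.DataFrame) -> np.ndarray:
    # small negative tolerance: day-averaging values that sit exactly on a
    # zero bound leaves float residue of order 1e-15
    tol = 1e-9
    f = frame
    bad = (
        (f["humidity_pct"] < -tol)
        | (f["humidity_pct"] > 100)
        | (f["smc_pct"] < SMC_RANGE[0] - tol)
        | (f["smc_pct"] > SMC_RANGE[1])
        | (f["sec_us_cm"] < SEC_RANGE[0] - tol)
        | (f["sec_us_cm"] > SEC_RANGE[1])
        | (f["rainfall_mm"] < -tol)
        | (f["light_lux"] < -tol)
    )
    return bad.to_numpy()


def clean_outliers(daily: SensorDataset) -> tuple[SensorDataset, CleaningReport]:
    """Drop rows violating physical ranges or a 3.5 modified z-score.

    The z-score uses median/MAD statistics (consistency constant 0.6745),
    computed per channel over the whole table, so a handful of corrupt
    rows cannot drag the screen.  Returns the surviving rows and a report
    of what was removed.
    """
    if len(daily) < 10:
        raise ValueError(f"need at least 10 rows to screen outliers, got {len(daily)}")
    bad = _range_flags(daily.frame) | _robust_flags(daily.frame)
    removed = tuple(int(i) for i in np.nonzero(bad)[0])
    cleaned = SensorDataset(daily.frame.loc[~bad].reset_index(drop=True))
    return cleaned, CleaningReport(n_removed=len(removed), removed_indices=removed)


def subdaily_expand(
    daily: SensorDataset,
    n_total: int,
    rng: np.random.Generator,
    jitter_frac: float = 0.02,
) -> SensorDataset:
    """Expand a daily table into ``n_total`` sub-daily readings.

    Readings are spread across the days (extras go to the earliest days),
    evenly spaced within each day.  Mean-type channels get zero-sum
    within-day jitter (relative scale ``jitter_frac``), so each day's mean
    is preserved exactly; rainfall is split evenly so the daily sum is
    preserved.  The inverse of :func:`daily_aggregate` up to jitter.
    """
    n_days = len(daily)
    if n_total < n_days:
        raise ValueError("need at least one reading per day")
    counts = np.full(n_days, n_total // n_days)
    counts[: n_total % n_days] += 1
    rows = []
    for i, cnt in enumerate(counts):
        day = daily.frame.iloc[i]
        base = pd.Timestamp(day["timestamp"]).normalize()
        offsets = (np.arange(cnt) + 0.5) * (24.0 * 3600.0 / cnt)
        block = {
            "timestamp": base + pd.to_timedelta(offsets, unit="s"),
            "rainfall_mm": np.full(cnt, day["rainfall_mm"] / cnt),
        }
        for col in ["air_temp_c", "humidity_pct", "light_lux", "soil_temp_c", "sec_us_cm", "smc_pct"]:
            v = float(day[col])
            jit = rng.normal(0.0, jitter_frac * max(abs(v), 1.0), size=cnt)
            jit -= jit.mean()  # zero-sum: daily mean preserved exactly
            block[col] = v + jit
        rows.append(pd.DataFrame(block))
    return SensorDataset(pd.concat(rows, ignore_index=True))


def pipeline_fixture(
    seed: int = 0, n_total: int = 18_345, n_days: int = 229, n_corrupt: int = 13
) -> tuple[SensorDataset, tuple[int, ...]]:
    """Synthetic stand-in for a raw field collection with known defects.

    Builds a clean ``n_days``-day record (any naturally extreme base rows
    are winsorized to the channel median, so the only anomalies are the
    planted ones), expands it to ``n_total`` sub-daily readings, then
    corrupts every reading of ``n_corrupt`` randomly chosen days with
    out-of-range values (SMC 500%, SEC 9000 μS/cm, humidity 150%, cycled).
    Aggregating and cleaning the result recovers exactly
    ``n_days - n_corrupt`` daily rows.

    Returns the sub-daily dataset and the corrupted day indices.
    """
    cfg = SyntheticConfig(n_days=n_days, seed=seed)
    daily = generate(cfg)
    frame = daily.frame.copy()
    # winsorize the base record: clip every screened channel to a modified
    # z of 3.0 (margin under the 3.5 cut, since the planted corruption will
    # shift the median/MAD stats slightly).  One pass with the original
    # stats; clipping a handful of tail values barely moves median or MAD.
    margin = 3.0
    for col in _Z_CHANNELS:
        v = frame[col].to_numpy(dtype=float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad > 0.0:
            half = margin * mad / 0.6745
            frame[col] = np.clip(v, med - half, med + half)
    lv = np.log10(frame["light_lux"].to_numpy(dtype=float) + 1.0)
    med = np.median(lv)
    mad = np.median(np.abs(lv - med))
    if mad > 0.0:
        half = margin * mad / 0.6745
        frame["light_lux"] = 10.0 ** np.clip(lv, med - half, med + half) - 1.0
    daily = SensorDataset(frame)

    rng = np.random.default_rng(seed + 1)
    sub = subdaily_expand(daily, n_total, rng)
    corrupt_days = tuple(sorted(int(i) for i in rng.choice(n_days, size=n_corrupt, replace=False)))
    f = sub.frame
    day_index = f["timestamp"].dt.normalize()
    days = sorted(day_index.unique())
    modes = [("smc_pct", 500.0), ("sec_us_cm", 9000.0), ("humidity_pct", 150.0)]
    for k, di in enumerate(corrupt_days):
        col, val = modes[k % len(modes)]
        f.loc[day_index == days[di], col] = val
    return SensorDataset(f), corrupt_days


def write_csv(dataset: SensorDataset, path) -> None:
    """Write the documented CSV layout (ISO-8601 timestamps, '.' decimals, UTF-8)."""
    out = dataset.frame.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, encoding="utf-8")


def read_csv(path) -> SensorDataset:
    df = pd.read_csv(path, encoding="utf-8")
    return SensorDataset(df)
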