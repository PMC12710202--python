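"""Meteorological driver series: synthesis, reading and writing.

The forcing table dialect is UTF-8 delimited text with columns
``timestamp,air_temp_C,precip_mm,rh_pct,sw_Wm2,wind_ms,pressure_kPa,co2_ppm``
and ISO-8601 hourly timestamps.  All calendars are 365-day: leap days are
dropped everywhere so that hourly/daily/annual alignment is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import HOURS_PER_DAY, HOURS_PER_YEAR
from .errors import ForcingFormatError, ParameterError

FORCING_COLUMNS = [
    "timestamp",
    "air_temp_C",
    "precip_mm",
    "rh_pct",
    "sw_Wm2",
    "wind_ms",
    "pressure_kPa",
    "co2_ppm",
]


@dataclass
class MeteoForcing:
    """Validated hourly driver series for a whole simulation.

    Wraps a DataFrame with the dialect columns.  Invariants (strictly
    increasing gap-free hourly timestamps, non-negative precipitation,
    relative humidity in [0, 100], positive CO2) are enforced on
    construction.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in FORCING_COLUMNS if c not in df.columns]
        if missing:
            raise ForcingFormatError(f"missing forcing columns: {missing}")
        ts = pd.to_datetime(df["timestamp"])
        if ts.duplicated().any():
            first = ts[ts.duplicated()].iloc[0]
            raise ForcingFormatError(f"duplicated timestamp: {first}")
        deltas = ts.diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            bad = ts[deltas.index[deltas <= pd.Timedelta(0)][0]]
            raise ForcingFormatError(f"non-monotone timestamp at {bad}")
        if len(ts) > 1:
            # gap-free hourly on the 365-day calendar (Feb 29 dropped)
            ref = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="h")
            ref = ref[~((ref.month == 2) & (ref.day == 29))]
            if len(ref) != len(ts) or (ts.to_numpy() != ref.to_numpy()).any():
                raise ForcingFormatError(
                    "timestamps are not gap-free hourly on the 365-day calendar"
                )
        if (df["precip_mm"].to_numpy() < 0).any():
            raise ForcingFormatError("negative precipitation")
        rh = df["rh_pct"].to_numpy()
        if ((rh < 0) | (rh > 100)).any():
            raise ForcingFormatError("relative humidity outside [0, 100]")
        if (df["co2_ppm"].to_numpy() <= 0).any():
            raise ForcingFormatError("non-positive atmospheric CO2")
        if df[FORCING_COLUMNS[1:]].isna().any().any():
            raise ForcingFormatError("NaN in forcing values")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_days(self) -> int:
        return len(self.data) // HOURS_PER_DAY

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def _noleap_hourly_index(start: str, n_hours: int) -> pd.DatetimeIndex:
    """Hourly timestamps skipping Feb 29 (365-day calendar)."""
    # over-generate then drop leap days
    raw = pd.date_range(start, periods=int(n_hours * 1.01) + 48, freq="h")
    keep = ~((raw.month == 2) & (raw.day == 29))
    return raw[keep][:n_hours]


def generate_synthetic_forcing(
    mean_annual_temp: float = 11.0,
    seasonal_amplitude: float = 12.0,
    diurnal_amplitude: float = 5.0,
    annual_rainfall: float = 950.0,
    storm_frequency: float = 0.30,
    noise_sd: float = 1.5,
    mean_rh: float = 72.0,
    co2_ppm: float = 415.0,
    seed: int = 0,
    n_years: int = 1,
    start: str = "2017-01-01",
) -> MeteoForcing:
    """Statistically plausible hourly forcing with a marked-Poisson rain model.

    Temperature is an annual sinusoid (peak at day 200) plus a diurnal
    sinusoid (peak at 15:00) plus bounded AR(1) noise.  Rain arrives as a
    Poisson number of storms per day (``storm_frequency`` d-1), each storm
    carrying an exponentially distributed depth whose mean is chosen so the
    expected annual total equals ``annual_rainfall`` (mm).  Identical seeds
    give bit-identical series.
    """
    if n_years < 1:
        raise ParameterError("n_years must be >= 1")
    if annual_rainfall <= 0 or storm_frequency <= 0:
        raise ParameterError("annual rainfall and storm frequency must be positive")
    for name, val in (
        ("mean_annual_temp", mean_annual_temp),
        ("seasonal_amplitude", seasonal_amplitude),
        ("diurnal_amplitude", diurnal_amplitude),
    ):
        if not np.isfinite(val):
            raise ParameterError(f"{name} must be finite")

    rng = np.random.default_rng(seed)
    n_hours = n_years * HOURS_PER_YEAR
    n_days = n_years * 365
    idx = _noleap_hourly_index(start, n_hours)

    hour = np.arange(n_hours)
    doy = (hour // HOURS_PER_DAY) % 365
    hod = hour % HOURS_PER_DAY

    seasonal = seasonal_amplitude * np.sin(2 * np.pi * (doy - 110.0) / 365.0)
    diurnal = diurnal_amplitude * np.sin(2 * np.pi * (hod - 9.0) / 24.0)
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd * np.sqrt(1 - 0.9**2), size=n_hours)
        noise = np.empty(n_hours)
        prev = 0.0
        for i in range(n_hours):
            prev = 0.9 * prev + eps[i]
            noise[i] = prev
        noise = np.clip(noise, -3 * noise_sd, 3 * noise_sd)
    else:
        noise = np.zeros(n_hours)
    air_temp = mean_annual_temp + seasonal + diurnal + noise

    # marked-Poisson storms: mean depth fixed by the annual-total constraint
    mean_depth = annual_rainfall / (365.0 * storm_frequency)
    precip = np.zeros(n_hours)
    n_storms = rng.poisson(storm_frequency, size=n_days)
    for d in range(n_days):
        for _ in range(n_storms[d]):
            h = d * HOURS_PER_DAY + int(rng.integers(0, HOURS_PER_DAY))
            precip[h] += rng.exponential(mean_depth)

    rain_day = np.repeat(n_storms > 0, HOURS_PER_DAY)[:n_hours]
    daylen_factor = 1.0 + 0.35 * np.sin(2 * np.pi * (doy - 81.0) / 365.0)
    solar = np.maximum(0.0, np.sin(np.pi * (hod - 6.0) / 12.0))
    cloud = np.where(rain_day, 0.35, 1.0)
    sw = 850.0 * solar * daylen_factor * cloud

    rh = np.clip(
        mean_rh - 1.5 * (diurnal + noise) + np.where(rain_day, 12.0, 0.0), 5.0, 100.0
    )
    wind = np.clip(2.0 + rng.gamma(2.0, 0.8, size=n_hours) - 1.6, 0.1, None)
    pressure = np.full(n_hours, 101.3)

    df = pd.DataFrame(
        {
            "timestamp": idx,
            "air_temp_C": air_temp,
            "precip_mm": precip,
            "rh_pct": rh,
            "sw_Wm2": sw,
            "wind_ms": wind,
            "pressure_kPa": pressure,
            "co2_ppm": np.full(n_hours, float(co2_ppm)),
        }
    )
    return MeteoForcing(df)


def read_forcing_table(path) -> MeteoForcing:
    """Read and validate a forcing table; interpolate gaps of <= 3 hours.

    Longer gaps, missing columns, duplicated or non-monotone timestamps
    raise :class:`ForcingFormatError` naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ForcingFormatError(f"{path}: missing column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"])
    if ts.duplicated().any():
        raise ForcingFormatError(
            f"{path}: duplicated timestamp {ts[ts.duplicated()].iloc[0]}"
        )
    if not ts.is_monotonic_increasing:
        bad = ts[ts.diff() < pd.Timedelta(0)].iloc[0]
        raise ForcingFormatError(f"{path}: non-monotone timestamp at {bad}")
    df = df.set_index(ts).drop(columns=["timestamp"])
    full = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="h")
    full = full[~((full.month == 2) & (full.day == 29))]
    df = df.reindex(full)
    isna = df.isna().any(axis=1).to_numpy()
    if isna.any():
        run = 0
        for i, flag in enumerate(isna):
            run = run + 1 if flag else 0
            if run > 3:
                raise ForcingFormatError(
                    f"{path}: gap longer than 3 h ending at {full[i]}"
                )
        df = df.interpolate(method="linear", limit=3, limit_area="inside")
        if df.isna().any().any():
            raise ForcingFormatError(f"{path}: unfillable gap at series edge")
    df = df.reset_index(names="timestamp")
    return MeteoForcing(df)


def write_forcing_table(forcing: MeteoForcing, path) -> None:
    """Write a forcing table in the documented dialect (full precision)."""
    out = forcing.data.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False, float_format="%.17g")
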