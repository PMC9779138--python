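"""Synthetic hourly monitoring series with realistic statistical structure.

The generator emulates what multi-year station records look like: seasonal
and diurnal cycles, autocorrelated noise, right-skewed heavy-tailed
concentration distributions, cross-variable structure (ozone suppressed by
NO and driven by radiation/temperature, particulates coupled to SO2 in
winter) and configurable missingness including multi-hour instrument
outages.  No attempt is made to match any real station numerically — only
orderings and sign structure are calibrated.

Positivity of concentrations is structural, never clamped: skew-flagged
pollutants are exponentials of Gaussian latents (lognormal-like), the rest
pass through a softplus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import MonitoringSeries

__all__ = [
    "VariableParams",
    "SyntheticConfig",
    "generate_series",
    "default_paperlike_config",
    "write_series_csv",
]


@dataclass(frozen=True)
class VariableParams:
    """Shape of one simulated variable.

    ``baseline`` is on the latent scale (log scale when ``skew`` is set).
    ``seasonal_amp`` is signed: positive peaks in summer, negative in winter.
    ``diurnal_phase`` is the hour of the daily maximum.  Noise is AR(1) with
    coefficient ``ar_coef`` and innovation scale ``noise_scale``.
    """

    baseline: float
    seasonal_amp: float = 0.0
    diurnal_amp: float = 0.0
    diurnal_phase: float = 12.0
    ar_coef: float = 0.9
    noise_scale: float = 1.0
    skew: bool = False
    missing_rate: float = 0.0
    block_rate: float = 0.0
    block_len: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must be in [0, 1)")
        for r in (self.missing_rate, self.block_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("missingness rates must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic station record."""

    station_id: str = "SYN"
    start: str = "2011-01-01"
    years: int = 6
    seed: int = 0
    variables: dict = field(default_factory=dict)
    o3_no_coef: float = -0.8
    o3_t_coef: float = 0.9
    o3_i_coef: float = 0.035
    pm10_so2_coef: float = 0.45
    heteroscedastic: float = 0.0  # extra O3 noise growing with signal level


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _ar1(rng: np.random.Generator, n: int, coef: float, scale: float) -> np.ndarray:
    if scale == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, scale, size=n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(1.0 - coef * coef)
    for t in range(1, n):
        out[t] = coef * out[t - 1] + eps[t]
    return out


def _cycles(idx: pd.DatetimeIndex):
    doy = idx.dayofyear.to_numpy(dtype=float)
    hour = idx.hour.to_numpy(dtype=float)
    season = -np.cos(2.0 * np.pi * (doy - 1) / 365.25)  # +1 midsummer
    return season, hour


def _diurnal(hour: np.ndarray, phase: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (hour - phase) / 24.0)


def _latent(
    rng: np.random.Generator, p: VariableParams, season: np.ndarray, hour: np.ndarray
) -> np.ndarray:
    n = len(season)
    return (
        p.baseline
        + p.seasonal_amp * season
        + p.diurnal_amp * _diurnal(hour, p.diurnal_phase)
        + _ar1(rng, n, p.ar_coef, p.noise_scale)
    )


def _inject_missing(
    rng: np.random.Generator, values: np.ndarray, p: VariableParams
) -> np.ndarray:
    out = values.astype(float).copy()
    n = len(out)
    if p.missing_rate > 0:
        out[rng.random(n) < p.missing_rate] = np.nan
    if p.block_rate > 0:
        starts = np.flatnonzero(rng.random(n) < p.block_rate)
        for s in starts:
            length = max(1, int(rng.geometric(1.0 / p.block_len)))
            out[s : s + length] = np.nan
    return out


def default_paperlike_config(
    station: str = "zabrze", years: int = 6, seed: int = 0
) -> SyntheticConfig:
    """Config whose 6-year output has station-like orderings and skew.

    Two presets: ``zabrze`` (urban background, has CO, no RH) and
    ``zloty_potok`` (rural background, has RH, no CO, much lower NO).
    """
    station = station.lower().replace("-", "_").replace(" ", "_")
    if station not in ("zabrze", "zloty_potok"):
        raise ValueError(f"unknown preset {station!r}")
    urban = station == "zabrze"

    variables = {
        "T": VariableParams(9.0, seasonal_amp=10.0, diurnal_amp=4.0,
                            diurnal_phase=14.0, ar_coef=0.97, noise_scale=0.8,
                            missing_rate=0.01, block_rate=0.0003),
        "I": VariableParams(0.0, missing_rate=0.01, block_rate=0.0003),
        "WS": VariableParams(2.2, seasonal_amp=-0.4, diurnal_amp=0.6,
                             diurnal_phase=14.0, ar_coef=0.92, noise_scale=0.5,
                             missing_rate=0.01, block_rate=0.0003),
        "NO": VariableParams(np.log(3.0) if urban else np.log(0.8),
                             seasonal_amp=-0.7, diurnal_amp=0.8,
                             diurnal_phase=7.0, ar_coef=0.88,
                             noise_scale=0.55, skew=True,
                             missing_rate=0.08, block_rate=0.001),
        "NO2": VariableParams(22.0 if urban else 8.5, seasonal_amp=-7.0,
                              diurnal_amp=5.0, diurnal_phase=9.0,
                              ar_coef=0.93, noise_scale=2.5,
                              missing_rate=0.02, block_rate=0.0005),
        "SO2": VariableParams(np.log(9.0) if urban else np.log(4.0),
                              seasonal_amp=-0.8, diurnal_amp=0.25,
                              diurnal_phase=10.0, ar_coef=0.92,
                              noise_scale=0.35, skew=True,
                              missing_rate=0.04, block_rate=0.0005),
        "PM10": VariableParams(np.log(26.0) if urban else np.log(16.0),
                               seasonal_amp=-0.55, diurnal_amp=0.25,
                               diurnal_phase=20.0, ar_coef=0.93,
                               noise_scale=0.4, skew=True,
                               missing_rate=0.08, block_rate=0.001),
        "O3": VariableParams(34.0, seasonal_amp=16.0, diurnal_amp=11.0,
                             diurnal_phase=15.0, ar_coef=0.93,
                             noise_scale=3.0,
                             missing_rate=0.02, block_rate=0.0005),
    }
    if urban:
        variables["CO"] = VariableParams(np.log(0.42), seasonal_amp=-0.55,
                                         diurnal_amp=0.35, diurnal_phase=8.0,
                                         ar_coef=0.92, noise_scale=0.3,
                                         skew=True, missing_rate=0.02,
                                         block_rate=0.0005)
    else:
        variables["RH"] = VariableParams(76.0, seasonal_amp=-6.0,
                                         diurnal_amp=-9.0, diurnal_phase=14.0,
                                         ar_coef=0.93, noise_scale=3.0,
                                         missing_rate=0.02, block_rate=0.0005)
    return SyntheticConfig(
        station_id="ZAB-SYN" if urban else "ZP-SYN",
        years=years,
        seed=seed,
        variables=variables,
    )


def generate_series(cfg: SyntheticConfig) -> MonitoringSeries:
    """Generate a complete hourly grid, then inject missingness.

    Deterministic at a fixed seed.  Concentrations are non-negative by
    construction; RH is clipped to [0, 100] (meteorology only).
    """
    start = pd.Timestamp(cfg.start)
    end = start + pd.DateOffset(years=cfg.years) - pd.Timedelta(hours=1)
    idx = pd.date_range(start, end, freq="h")
    season, hour = _cycles(idx)
    n = len(idx)

    children = np.random.SeedSequence(cfg.seed).spawn(len(cfg.variables) + 1)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(sorted(cfg.variables) + ["_miss"], children)
    }
    miss_rng = streams.pop("_miss")

    clean: dict[str, np.ndarray] = {}

    def simple(name: str) -> np.ndarray:
        p = cfg.variables[name]
        lat = _latent(streams[name], p, season, hour)
        return np.exp(lat) if p.skew else lat

    if "T" in cfg.variables:
        clean["T"] = simple("T")
    if "I" in cfg.variables:
        p = cfg.variables["I"]
        elev = np.maximum(0.0, _diurnal(hour, 12.0))
        strength = 650.0 * (0.55 + 0.45 * season)
        noise = _ar1(streams["I"], n, 0.7, 25.0)
        clean["I"] = np.maximum(0.0, strength * elev**1.3 + noise * elev)
    if "WS" in cfg.variables:
        clean["WS"] = _softplus(_latent(streams["WS"], cfg.variables["WS"], season, hour))
    if "RH" in cfg.variables:
        clean["RH"] = np.clip(
            _latent(streams["RH"], cfg.variables["RH"], season, hour), 0.0, 100.0
        )

    for name in ("NO", "NO2", "SO2", "CO"):
        if name in cfg.variables:
            p = cfg.variables[name]
            lat = _latent(streams[name], p, season, hour)
            clean[name] = np.exp(lat) if p.skew else _softplus(lat)

    if "PM10" in cfg.variables:
        p = cfg.variables["PM10"]
        lat = _latent(streams["PM10"], p, season, hour)
        if "SO2" in clean:
            so2_lat = np.log(np.maximum(clean["SO2"], 1e-6))
            winter = np.maximum(0.0, -season)
            lat = lat + cfg.pm10_so2_coef * winter * (so2_lat - so2_lat.mean())
        clean["PM10"] = np.exp(lat) if p.skew else _softplus(lat)

    if "O3" in cfg.variables:
        p = cfg.variables["O3"]
        signal = (
            p.baseline
            + p.seasonal_amp * season
            + p.diurnal_amp * _diurnal(hour, p.diurnal_phase)
        )
        if "T" in clean:
            signal = signal + cfg.o3_t_coef * (clean["T"] - 9.0)
        if "I" in clean:
            signal = signal + cfg.o3_i_coef * clean["I"]
        if "NO" in clean:
            signal = signal + cfg.o3_no_coef * np.minimum(clean["NO"], 60.0)
        noise = _ar1(streams["O3"], n, p.ar_coef, p.noise_scale)
        if cfg.heteroscedastic > 0:
            level = np.maximum(0.0, signal) / max(1.0, np.max(signal))
            noise = noise * (1.0 + cfg.heteroscedastic * level)
        clean["O3"] = _softplus(signal + noise)

    data = pd.DataFrame(index=idx)
    data.index.name = "timestamp"
    order = [v for v in ("O3", "NO", "NO2", "SO2", "CO", "PM10", "WS", "T", "I", "RH")
             if v in clean]
    for name in order:
        data[name] = _inject_missing(miss_rng, clean[name], cfg.variables[name])
    return MonitoringSeries(station_id=cfg.station_id, data=data)


def write_series_csv(series: MonitoringSeries, path) -> None:
    """Write the CSV dialect that the ingestion reader consumes."""
    out = series.data.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False)
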