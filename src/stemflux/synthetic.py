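"""Synthetic driver and flux generator with known ground truth.

The generator emulates the conditions of a boreal Scots pine stem gas-exchange
campaign run from June to September: long photoperiods shrinking through the
season, a mid-afternoon xylem-temperature peak riding on seasonal and synoptic
trends, a daytime sap-flow hump tracking light, and paired dark/transparent
chamber fluxes assembled from the three process models

    R' = R0 * exp(b * temp)                       (respiration)
    P  = Pmax * f * PPFD / (f * PPFD + Pmax)      (bark photosynthesis)
    T  = e * J                                    (sap-transport term)

with the net-flux sign convention FCO2 < 0 for efflux to the atmosphere:
dark chamber = -R' + T, transparent chamber = -R' + P + T.  Parameters step at
calendar-month boundaries; additive i.i.d. Gaussian noise is applied per chamber;
the noise-free components are stored alongside as ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArtifactConfig, ChamberGeometry, R_GAS, SimConfig
from .errors import ConfigError, MonthMissingError

DRIVER_COLUMNS = ["temp", "ppfd", "rh", "sapflux", "co2_ambient"]

#: Day-of-year anchors for the deterministic seasonal cycles.
_SOLSTICE_DOY = 172
_TEMP_PEAK_DOY = 200


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth monthly parameters and noise level of a simulation.

    Each map is keyed by calendar month (1-12).  Units: R0 umol m^-2 s^-1 at
    0 degC; b 1/degC; Pmax umol m^-2 s^-1; f umol CO2 per umol quanta; e
    umol m^-2 s^-1 per unit sap flux density; noise_sd umol m^-2 s^-1.
    """

    r0: dict[int, float]
    b: dict[int, float]
    pmax: dict[int, float]
    f: dict[int, float]
    e: dict[int, float]
    noise_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        months = set(self.r0)
        for name in ("b", "pmax", "f", "e"):
            if set(getattr(self, name)) != months:
                raise ConfigError(f"parameter map {name!r} covers different months")
        for m in months:
            if self.r0[m] <= 0 or self.b[m] <= 0 or self.pmax[m] <= 0:
                raise ConfigError(f"R0, b, Pmax must be positive (month {m})")
            if not 0.0 < self.f[m] < 1.0:
                raise ConfigError(f"quantum yield f must be in (0, 1) (month {m})")
            if self.e[m] < 0:
                raise ConfigError(f"transport slope e must be >= 0 (month {m})")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def months(self) -> list[int]:
        return sorted(self.r0)

    def param(self, name: str, month: int) -> float:
        table = getattr(self, name)
        if month not in table:
            raise MonthMissingError(f"no ground-truth {name!r} for month {month}")
        return table[month]

    def replace(self, **kw) -> "SimTruth":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def default_truth(noise_sd: float = 0.1, rng_seed: int = 0) -> SimTruth:
    """Season of monthly parameters with the observed seasonal shapes.

    Respiration at 0 degC declines over the season within 0.3-0.8 umol m^-2 s^-1
    while its temperature sensitivity rises; the light-saturation point and
    quantum yield fall after midsummer; the transport slope declines as the
    axial CO2 gradient relaxes.
    """
    return SimTruth(
        r0={6: 0.80, 7: 0.62, 8: 0.45, 9: 0.30},
        b={6: 0.075, 7: 0.085, 8: 0.100, 9: 0.120},
        pmax={6: 1.50, 7: 1.20, 8: 0.80, 9: 0.50},
        f={6: 0.018, 7: 0.014, 8: 0.010, 9: 0.006},
        e={6: 0.020, 7: 0.015, 8: 0.010, 9: 0.005},
        noise_sd=noise_sd,
        rng_seed=rng_seed,
    )


def _daylength_h(doy: np.ndarray) -> np.ndarray:
    # Boreal photoperiod proxy: ~20 h at solstice, ~13 h at the autumn equinox.
    return 12.0 + 8.0 * np.cos(2 * np.pi * (doy - _SOLSTICE_DOY) / 365.25)


def generate_drivers(config: SimConfig) -> pd.DataFrame:
    """Simulate a gap-free driver table on a uniform time grid.

    Returns a DataFrame indexed by timestamp with columns ``temp`` (degC),
    ``ppfd`` (umol m^-2 s^-1, 0 at night), ``rh`` (%), ``sapflux``
    (field-convention g m^-2 h^-1, 0 below the detection threshold) and
    ``co2_ambient`` (ppm).  Deterministic apart from AR(1) temperature jitter
    drawn from ``config.seed``.
    """
    index = pd.date_range(config.start, config.end, freq=f"{config.step_min}min",
                          inclusive="left")
    if len(index) == 0:
        raise ConfigError("date range produced an empty grid")
    doy = index.dayofyear.to_numpy(dtype=float)
    hour = index.hour.to_numpy(dtype=float) + index.minute.to_numpy(dtype=float) / 60.0

    # Light: half-sine over a season-dependent photoperiod centred on solar noon.
    length = _daylength_h(doy)
    x = (hour - (12.0 - length / 2.0)) / length
    elev = np.sin(np.pi * np.clip(x, 0.0, 1.0))
    ppfd_peak = config.ppfd_max * (0.65 + 0.35 * np.cos(
        2 * np.pi * (doy - _SOLSTICE_DOY) / 365.25))
    ppfd = np.where((x > 0) & (x < 1), ppfd_peak * elev, 0.0)
    ppfd = np.clip(ppfd, 0.0, None)

    temp = (config.temp_mean
            + config.temp_seasonal_amp * np.cos(2 * np.pi * (doy - _TEMP_PEAK_DOY) / 365.25)
            + config.temp_diurnal_amp * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
            + config.temp_synoptic_amp * np.sin(2 * np.pi * doy / 6.5 + 1.0))
    if config.temp_jitter_sd > 0:
        rng = np.random.default_rng(config.seed)
        eps = rng.normal(0.0, config.temp_jitter_sd, size=len(index))
        jitter = np.empty_like(eps)
        acc = 0.0
        for i, value in enumerate(eps):  # AR(1), phi = 0.8
            acc = 0.8 * acc + value
            jitter[i] = acc
        temp = temp + jitter

    rh = (config.rh_base
          + config.rh_diurnal_amp * np.cos(2 * np.pi * (hour - 4.0) / 24.0)
          + config.rh_synoptic_amp * np.sin(2 * np.pi * doy / 9.0))
    rh = np.clip(rh, 5.0, 100.0)

    # Sap flow tracks light with mild saturation; the thermal-dissipation
    # baselining reports values below the detection threshold as zero.
    jmax = config.sapflux_max * (0.75 + 0.25 * np.cos(
        2 * np.pi * (doy - _SOLSTICE_DOY) / 365.25))
    sap = jmax * ppfd / (ppfd + 250.0)
    sap = np.where(sap < config.sapflux_detect, 0.0, sap)

    co2 = np.full(len(index), config.co2_ambient_ppm)

    frame = pd.DataFrame(
        {"temp": temp, "ppfd": ppfd, "rh": rh, "sapflux": sap, "co2_ambient": co2},
        index=index,
    )
    frame.index.name = "timestamp"
    return frame


def _month_param(truth: SimTruth, name: str, months: np.ndarray) -> np.ndarray:
    table = getattr(truth, name)
    missing = sorted(set(months) - set(table))
    if missing:
        raise MonthMissingError(
            f"driver months {missing} absent from ground-truth map {name!r}")
    return np.array([table[m] for m in months], dtype=float)


def process_fluxes(drivers: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Noise-free component series R', P, T on the driver grid."""
    months = drivers.index.month.to_numpy()
    r0 = _month_param(truth, "r0", months)
    b = _month_param(truth, "b", months)
    pmax = _month_param(truth, "pmax", months)
    f = _month_param(truth, "f", months)
    e = _month_param(truth, "e", months)

    temp = drivers["temp"].to_numpy(dtype=float)
    ppfd = drivers["ppfd"].to_numpy(dtype=float)
    sap = drivers["sapflux"].to_numpy(dtype=float)

    r_prime = r0 * np.exp(b * temp)
    p_true = pmax * f * ppfd / (f * ppfd + pmax)
    t_true = e * sap
    out = pd.DataFrame(
        {"r_prime": r_prime, "p_true": p_true, "t_true": t_true},
        index=drivers.index,
    )
    out.index.name = "timestamp"
    return out


def _flux_frame(index: pd.DatetimeIndex, fco2: np.ndarray, chamber: str,
                tree: str) -> pd.DataFrame:
    frame = pd.DataFrame({
        "fco2": fco2,
        "chamber": chamber,
        "tree": tree,
        "flags": "",
    }, index=index)
    frame.index.name = "timestamp"
    return frame


def generate_true_fluxes(
    drivers: pd.DataFrame,
    truth: SimTruth,
    tree: str = "A",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired chamber observations plus the noise-free truth components.

    Dark chamber: FCO2 = -R' + T (no light, so no photosynthesis); transparent
    chamber: FCO2 = -R' + P + T.  Gaussian noise of sd ``truth.noise_sd`` is
    added independently per chamber; ``truth_components`` stays noise-free.
    """
    comp = process_fluxes(drivers, truth)
    dark_clean = -comp["r_prime"].to_numpy() + comp["t_true"].to_numpy()
    transparent_clean = dark_clean + comp["p_true"].to_numpy()

    rng = np.random.default_rng(truth.rng_seed)
    if truth.noise_sd > 0:
        dark = dark_clean + rng.normal(0.0, truth.noise_sd, len(comp))
        transparent = transparent_clean + rng.normal(0.0, truth.noise_sd, len(comp))
    else:
        dark, transparent = dark_clean, transparent_clean

    return (
        _flux_frame(drivers.index, dark, "dark", tree),
        _flux_frame(drivers.index, transparent, "transparent", tree),
        comp,
    )


# --------------------------------------------------------------------------
# closure-trace forward model


def closure_rate_constant(geom: ChamberGeometry) -> float:
    """Dilution rate q/V of the closed chamber, 1/s."""
    return (geom.flow_closed_l_min / 60.0) / geom.volume_l


def molar_flow(geom: ChamberGeometry, temp_c: float, pressure_kpa: float) -> float:
    """Throughflow in mol air s^-1 at chamber temperature and pressure."""
    q_m3_s = geom.flow_closed_l_min / 1000.0 / 60.0
    return pressure_kpa * 1000.0 * q_m3_s / (R_GAS * (temp_c + 273.15))


def closure_trace_concentration(
    t_s: np.ndarray,
    fco2: float,
    geom: ChamberGeometry,
    c_in_ppm: float,
    c0_ppm: float | None = None,
    temp_c: float = 15.0,
    pressure_kpa: float = 101.325,
) -> np.ndarray:
    """Closed-form chamber CO2 trace C(t) for a constant stem flux.

    The chamber mass balance is V dC/dt = S*A + q*(C_in - C) where S = -FCO2 is
    the source into the chamber air (efflux raises concentration).  Its solution
    is C(t) = C_eq + (C0 - C_eq) exp(-q t / V) with
    C_eq = C_in + S*A / q_mol (ppm).
    """
    k = closure_rate_constant(geom)
    # steady state: source S*A (umol/s) diluted by the molar throughflow
    c_eq = c_in_ppm + (-fco2) * geom.stem_area_m2 / molar_flow(geom, temp_c, pressure_kpa)
    if c0_ppm is None:
        c0_ppm = c_in_ppm
    return c_eq + (c0_ppm - c_eq) * np.exp(-k * np.asarray(t_s, dtype=float))


def generate_closure_traces(
    flux: pd.DataFrame,
    geom: ChamberGeometry,
    drivers: pd.DataFrame,
    pressure_kpa: float = 101.325,
) -> list:
    """Forward-model a 21-sample closure trace for each flux record.

    Chamber air temperature is taken from the driver series at the closure start;
    the trace starts at ambient CO2 (the chamber is flushed between closures).
    Returns a list of :class:`stemflux.chamber.ClosureTrace`.
    """
    from .chamber import ClosureTrace  # local import to avoid a cycle

    if geom.volume_l <= 0 or geom.flow_closed_l_min <= 0:
        raise ConfigError("invalid chamber geometry")
    t_s = np.arange(geom.n_samples, dtype=float) * geom.sample_dt_s
    temp = drivers["temp"].reindex(flux.index, method="nearest")
    c_in = drivers["co2_ambient"].reindex(flux.index, method="nearest")
    traces = []
    for i, (stamp, row) in enumerate(flux.iterrows()):
        fco2 = float(row["fco2"])
        if not math.isfinite(fco2):
            raise ConfigError(f"non-finite flux at {stamp}")
        tc = float(temp.loc[stamp])
        ci = float(c_in.loc[stamp])
        conc = closure_trace_concentration(
            t_s, fco2, geom, ci, temp_c=tc, pressure_kpa=pressure_kpa)
        traces.append(ClosureTrace(
            closure_id=f"{row.get('chamber', 'chamber')}-{i:05d}",
            chamber_id=str(row.get("chamber", "chamber")),
            start_time=stamp,
            t_s=t_s.copy(),
            co2_ppm=conc,
            c_in_ppm=ci,
            geometry=geom,
            chamber_air_temp_c=tc,
            pressure_kpa=pressure_kpa,
        ))
    return traces


# --------------------------------------------------------------------------
# QC artifacts


def inject_artifacts(
    dark: pd.DataFrame,
    transparent: pd.DataFrame,
    drivers: pd.DataFrame,
    config: ArtifactConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant spikes, high-RH windows and gaps; log every planted artifact.

    Spikes are offsets of ``spike_sd_mult`` group standard deviations added to
    randomly chosen records (alternating sign), split between the two chambers.
    High-RH windows overwrite driver RH with ``high_rh_value``.  Gaps delete
    records from both chambers.  Returns (dark, transparent, drivers, log); the
    log has columns kind, timestamp, chamber.
    """
    rng = np.random.default_rng(config.seed)
    dark = dark.copy()
    transparent = transparent.copy()
    drivers = drivers.copy()
    log_rows: list[dict] = []

    if config.n_spikes:
        frames = {"dark": dark, "transparent": transparent}
        names = rng.choice(["dark", "transparent"], size=config.n_spikes)
        for chamber in ("dark", "transparent"):
            frame = frames[chamber]
            count = int((names == chamber).sum())
            if count == 0:
                continue
            sd = float(frame["fco2"].std(ddof=1))
            locs = rng.choice(len(frame), size=count, replace=False)
            signs = np.where(rng.random(count) < 0.5, -1.0, 1.0)
            for loc, sign in zip(locs, signs):
                frame.iloc[loc, frame.columns.get_loc("fco2")] += (
                    sign * config.spike_sd_mult * sd)
                log_rows.append({"kind": "spike", "timestamp": frame.index[loc],
                                 "chamber": chamber})

    if config.high_rh_fraction > 0:
        n = max(1, int(round(config.high_rh_fraction * len(drivers))))
        locs = rng.choice(len(drivers), size=n, replace=False)
        drivers.iloc[locs, drivers.columns.get_loc("rh")] = config.high_rh_value
        for loc in locs:
            log_rows.append({"kind": "high_rh", "timestamp": drivers.index[loc],
                             "chamber": ""})

    if config.gap_fraction > 0:
        n = int(round(config.gap_fraction * len(dark)))
        locs = rng.choice(len(dark), size=n, replace=False)
        stamps = dark.index[locs]
        dark = dark.drop(index=stamps)
        transparent = transparent.drop(index=stamps, errors="ignore")
        for stamp in stamps:
            log_rows.append({"kind": "gap", "timestamp": stamp, "chamber": "both"})

    log = pd.DataFrame(log_rows, columns=["kind", "timestamp", "chamber"])
    return dark, transparent, drivers, log
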