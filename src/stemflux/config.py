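"""Configuration objects: chamber geometry, simulation settings, pipeline thresholds.

Every printed constant of the measurement protocol lives here with its unit so a
single config file can reproduce a run: chamber volume and flows, the 5 s / 100 s /
30 min closure scheme, the 85 % relative-humidity cutoff, the 3-SD outlier
multiplier, the 5 g m^-2 h^-1 low-sap-flow threshold for the respiration subset,
the PPFD > 10 umol m^-2 s^-1 daytime mask and the 8:2 validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigError

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: Months of the boreal measurement season (June-September).
SEASON_MONTHS = (6, 7, 8, 9)


@dataclass(frozen=True)
class ChamberGeometry:
    """Dimensions and flow scheme of one dynamic flow-through stem chamber.

    Volumes are in liters, flows in liters per minute, the enclosed stem-section
    surface in m^2.  The closure scheme samples CO2 every ``sample_dt_s`` seconds
    for ``closure_len_s`` seconds, every ``closure_interval_min`` minutes.
    """

    volume_l: float = 1.28
    flow_closed_l_min: float = 1.1
    flow_open_l_min: float = 0.5
    stem_area_m2: float = 0.14
    closure_len_s: float = 100.0
    sample_dt_s: float = 5.0
    closure_interval_min: float = 30.0

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ConfigError(f"chamber volume must be positive, got {self.volume_l}")
        for name in ("flow_closed_l_min", "flow_open_l_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.stem_area_m2 <= 0:
            raise ConfigError("stem_area_m2 must be positive")
        n = self.closure_len_s / self.sample_dt_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                "closure_len_s must be an integer multiple of sample_dt_s "
                f"({self.closure_len_s}/{self.sample_dt_s})"
            )

    @property
    def n_samples(self) -> int:
        """Samples per closure including t = 0 (21 for the 5 s / 100 s scheme)."""
        return int(round(self.closure_len_s / self.sample_dt_s)) + 1

    @property
    def turnover_s(self) -> float:
        """Chamber air turnover time V/q under closed-lid flow, seconds."""
        return self.volume_l / (self.flow_closed_l_min / 60.0)


@dataclass(frozen=True)
class SimConfig:
    """Driver-simulation settings for a boreal June-September season.

    All diurnal/seasonal structure is deterministic given the amplitudes; setting
    every amplitude (and ``temp_jitter_sd``) to zero yields constant series at the
    stated means.  ``seed`` controls only the stochastic parts (weather jitter).
    """

    start: str = "2021-06-01"
    end: str = "2021-10-01"
    step_min: int = 30
    seed: int = 0
    # xylem temperature, degC
    temp_mean: float = 14.0
    temp_seasonal_amp: float = 5.0
    temp_diurnal_amp: float = 4.0
    temp_synoptic_amp: float = 2.5
    temp_jitter_sd: float = 0.3
    # photosynthetic photon flux density, umol m^-2 s^-1
    ppfd_max: float = 1500.0
    # relative humidity, %
    rh_base: float = 62.0
    rh_diurnal_amp: float = 16.0
    rh_synoptic_amp: float = 4.0
    # sap flux density, field-convention g m^-2 h^-1
    sapflux_max: float = 130.0
    sapflux_detect: float = 5.0
    # ambient CO2, ppm
    co2_ambient_ppm: float = 420.0

    def __post_init__(self) -> None:
        if self.step_min <= 0:
            raise ConfigError(f"timestep must be positive, got {self.step_min} min")
        import pandas as pd

        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ConfigError(f"invalid date range {self.start!r} .. {self.end!r}")


@dataclass(frozen=True)
class ArtifactConfig:
    """How many QC artifacts to plant in an otherwise clean simulated dataset."""

    n_spikes: int = 5
    spike_sd_mult: float = 10.0
    high_rh_fraction: float = 0.0
    high_rh_value: float = 92.0
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("high_rh_fraction", "gap_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {frac}")
        if self.n_spikes < 0:
            raise ConfigError("n_spikes must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and options binding the QC, partitioning and validation stages."""

    rh_threshold_pct: float = 85.0
    sd_mult: float = 3.0
    sapflow_threshold: float = 5.0           # g m^-2 h^-1, field-campaign convention
    sapflow_mode: str = "fixed"              # or "fraction_of_max"
    sapflow_fraction: float = 0.05
    ppfd_day_threshold: float = 10.0         # umol m^-2 s^-1
    split_ratio: float = 0.8
    split_seed: int = 0
    min_n: int = 30
    season_months: tuple[int, ...] = SEASON_MONTHS
    stratify_split_by_month: bool = True
    contribution_per_row: bool = False       # per-row ratio averaging (diagnostic)
    closure_estimator: str = "ode"           # or "slope"

    def __post_init__(self) -> None:
        for name in ("rh_threshold_pct", "sd_mult", "sapflow_threshold",
                     "ppfd_day_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.sapflow_mode not in ("fixed", "fraction_of_max"):
            raise ConfigError(f"unknown sapflow_mode {self.sapflow_mode!r}")
        if not self.season_months:
            raise ConfigError("season window is empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["season_months"] = list(self.season_months)
        return d
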