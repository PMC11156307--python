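"""Configuration objects shared across the projection pipeline.

The time axis follows the study design: a 20-year observational present
(2000-2019), a shorter historical window (2000-2014) used as the anchor of
the delta-method downscaling, and four 20-year future windows out to 2100.
Scenarios are labelled with the CMIP6 Shared Socioeconomic Pathway names and
carry the end-of-century forcing magnitudes the synthetic climate generator
imposes (basin-mean warming, fractional sea-ice and primary-production
decline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Environmental covariates used throughout: winter sea-surface temperature,
#: winter sea-ice concentration, winter/summer sea-bottom temperature, summer
#: net primary production, and static bathymetry.
ENV_VARIABLES = ("WSST", "WSIC", "WSBT", "SSBT", "SNPP", "depth")

ENV_UNITS = {
    "WSST": "degC",
    "WSIC": "%",
    "WSBT": "degC",
    "SSBT": "degC",
    "SNPP": "mg C m-2 d-1",
    "depth": "m",
}

PRESENT_PERIOD = "2000-2019"
HISTORICAL_PERIOD = "2000-2014"
FUTURE_PERIODS = ("2021-2040", "2041-2060", "2061-2080", "2081-2100")

#: Midpoint year of each window, used for shift-rate denominators and the
#: price/cost sensitivity ramp.
PERIOD_MIDPOINTS = {
    PRESENT_PERIOD: 2009.5,
    "2021-2040": 2030.5,
    "2041-2060": 2050.5,
    "2061-2080": 2070.5,
    "2081-2100": 2090.5,
}

EARTH_RADIUS_KM = 6371.0

#: kg per metric ton; densities are kg/km2, biomass is reported in mt.
KG_PER_MT = 1000.0


@dataclass(frozen=True)
class ScenarioSpec:
    """End-of-century forcing magnitudes for one emission scenario.

    warming_c applies additively to the three temperature layers;
    ice_decline_frac and npp_decline_frac are fractional losses applied to
    the historical WSIC and SNPP fields. All three ramp linearly in the
    window midpoint year, reaching the stated magnitude in 2081-2100.
    """

    name: str
    warming_c: float
    ice_decline_frac: float
    npp_decline_frac: float


DEFAULT_SCENARIOS = (
    ScenarioSpec("SSP126", 1.0, 0.30, 0.05),
    ScenarioSpec("SSP245", 2.0, 0.50, 0.10),
    ScenarioSpec("SSP370", 3.0, 0.75, 0.15),
    ScenarioSpec("SSP585", 4.0, 0.90, 0.20),
)


def trend_weight(period: str) -> float:
    """Fraction of the end-of-century forcing realised in a future window.

    Linear ramp in midpoint year from the present midpoint (weight 0) to the
    2081-2100 midpoint (weight 1).
    """
    mid = PERIOD_MIDPOINTS[period]
    lo = PERIOD_MIDPOINTS[PRESENT_PERIOD]
    hi = PERIOD_MIDPOINTS[FUTURE_PERIODS[-1]]
    return (mid - lo) / (hi - lo)


@dataclass
class SyntheticConfig:
    """Controls for the synthetic shelf-sea generator.

    The defaults emulate a Bering/Chukchi-like domain: a 20 x 15 degree
    box with a 0.25 degree observational grid, a 1 degree scenario grid,
    eight commercial species, and annual summer trawl surveys over
    2000-2019.
    """

    lon_min: float = -180.0
    lon_max: float = -160.0
    lat_min: float = 55.0
    lat_max: float = 70.0
    fine_res: float = 0.25
    coarse_res: float = 1.0
    n_species: int = 8
    n_surveys_per_year: int = 150
    year_start: int = 2000
    year_end: int = 2019
    scenarios: Sequence[ScenarioSpec] = DEFAULT_SCENARIOS
    n_members: int = 4
    #: lognormal sigma of multiplicative survey noise
    cpue_sigma: float = 0.3
    #: texture of member fields, as a fraction of the scenario trend magnitude
    texture_frac: float = 0.05
    #: cells of aggregated effort constructed to exceed the fishing-ground
    #: threshold (1000 hrs) around the southern port
    n_high_effort_cells: int = 40
    effort_threshold_hours: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fine_res <= 0 or self.coarse_res <= 0:
            raise ValueError("grid resolutions must be positive")
        ratio = self.coarse_res / self.fine_res
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"fine resolution {self.fine_res} must evenly divide "
                f"coarse resolution {self.coarse_res}"
            )
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("domain extent is empty")
        amps = [s.warming_c for s in self.scenarios]
        if any(b < a for a, b in zip(amps, amps[1:])):
            raise ValueError(
                "scenario warming amplitudes must be ordered by severity"
            )

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def block(self) -> int:
        """Number of fine cells per coarse cell along each axis."""
        return int(round(self.coarse_res / self.fine_res))

    def scenario(self, name: str) -> ScenarioSpec:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise KeyError(f"unknown scenario {name!r}")


@dataclass
class ModelSwitches:
    """Every place where the method leaves a choice open, with its default."""

    #: 'printed' uses MSY = g B (phi+1)^(1/phi); 'bmsy_consistent' uses the
    #: negative exponent so that B interpreted as carrying capacity yields
    #: MSY = g * B_MSY.
    msy_exponent_sign: str = "printed"
    #: cost grouping: 'zero_profit' is c = p fbar bbar MSY / (g fbar)^beta
    cost_grouping: str = "zero_profit"
    #: 'inverse_rmse' gives w_m proportional to 1/RMSE_m
    ensemble_weight_rule: str = "inverse_rmse"
    #: bilinear or nearest resampling of the coarse anomaly
    resampling: str = "bilinear"
    #: cold-pool comparator ('le' or 'lt') and threshold in degC
    cold_pool_comparator: str = "le"
    cold_pool_threshold_c: float = 2.0
    #: fishing-ground effort threshold, hours
    effort_threshold_hours: float = 1000.0
    #: optional log1p transform of CPUE before model fitting
    log1p_response: bool = False


@dataclass
class PipelineConfig:
    """End-to-end driver configuration; fully determines one run."""

    out_dir: str = "fishcast_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    switches: ModelSwitches = field(default_factory=ModelSwitches)
    #: scenario names to project; must exist in synthetic.scenarios
    scenario_names: Sequence[str] = tuple(s.name for s in DEFAULT_SCENARIOS)
    periods: Sequence[str] = FUTURE_PERIODS
    #: sensitivity scenarios to evaluate
    sensitivities: Sequence[str] = ("base",)

    def validate(self) -> None:
        known = {s.name for s in self.synthetic.scenarios}
        unknown = [n for n in self.scenario_names if n not in known]
        if unknown:
            raise ValueError(f"unknown scenario label(s): {unknown}")
        bad = [p for p in self.periods if p not in FUTURE_PERIODS]
        if bad:
            raise ValueError(f"unknown period label(s): {bad}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        syn = raw.get("synthetic", {})
        scen = [ScenarioSpec(**s) for s in syn.pop("scenarios", [])]
        synthetic = SyntheticConfig(
            **syn, **({"scenarios": scen} if scen else {})
        )
        switches = ModelSwitches(**raw.get("switches", {}))
        kwargs = {
            k: v
            for k, v in raw.items()
            if k not in ("synthetic", "switches")
        }
        return cls(synthetic=synthetic, switches=switches, **kwargs)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj
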