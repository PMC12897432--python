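"""Configuration schema, defaults, calendar helpers, and file I/O.

All tunable model constants live here so that a single YAML file plus a seed
fully determines a simulation.  Defaults encode the study conditions: a
100-female spring-calving drylot herd, a 2.25 Mcal ME/kg DM total mixed
ration, a June 15 breeding season of 90 days, and the 3 x 3 genotype grid
(mature shrunk body weight 450/550/650 kg, peak milk 8/10/12 kg/d) crossed
with dry-matter-intake levels of 58/76/93/111 g per kg^0.75 of MSBW.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "GenotypeSpec",
    "DietSpec",
    "IntakePolicy",
    "EnergyParams",
    "LactationParams",
    "ReproParams",
    "SimulationConfig",
    "load_config",
    "save_config",
    "doy_from_monthday",
]

# fixed 365-day calendar (no leap days); cumulative days before each month
_CUM_DAYS = [0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334]


def doy_from_monthday(monthday: str) -> int:
    """Convert 'MM-DD' to 1-based day of a 365-day year ('06-15' -> 166)."""
    month, day = monthday.split("-")
    m, d = int(month), int(day)
    if not (1 <= m <= 12 and 1 <= d <= 31):
        raise ValueError(f"invalid month-day {monthday!r}")
    return _CUM_DAYS[m - 1] + d


class GenotypeSpec(BaseModel):
    """One cell of the genotype grid: size and milk means with sampling SDs."""

    msbw_mean: float = Field(gt=0, description="mature shrunk body weight, kg")
    msbw_sd: float = Field(default=25.4, gt=0)
    peak_milk_mean: float = Field(gt=0, description="peak lactation yield, kg/d")
    peak_milk_sd: float = Field(default=1.45, gt=0)

    @property
    def label(self) -> str:
        return f"{self.msbw_mean:.0f}-{self.peak_milk_mean:.1f}"


class DietSpec(BaseModel):
    """Ration energy description; NE contents derived from ME (Garrett)."""

    me_content: float = Field(default=2.25, gt=0, lt=3.7,
                              description="Mcal ME per kg DM")
    silage_me_content: float = Field(default=2.25, gt=0, lt=3.7)
    milk_ge_content: float = Field(default=1.1, gt=0,
                                   description="Mcal GE per kg whole milk")

    @property
    def nem_content(self) -> float:
        return nem_from_me(self.me_content)

    @property
    def neg_content(self) -> float:
        return neg_from_me(self.me_content)


def nem_from_me(me: float) -> float:
    """NEm concentration (Mcal/kg DM) from ME via the Garrett polynomial."""
    return 1.37 * me - 0.138 * me**2 + 0.0105 * me**3 - 1.12


def neg_from_me(me: float) -> float:
    """NEg concentration (Mcal/kg DM) from ME via the Garrett polynomial."""
    return 1.42 * me - 0.174 * me**2 + 0.0122 * me**3 - 1.65


class IntakePolicy(BaseModel):
    """Fixed lifetime intake prescription for 3+-yr-old cows."""

    dmi_level: float = Field(gt=0, description="g DM per kg^0.75 MSBW per day")
    lactation_addon: float = Field(default=18.0, ge=0)
    age_scaling_3yr: float = Field(default=0.96, gt=0, le=1)
    age_scaling_4yr: float = Field(default=0.98, gt=0, le=1)


class EnergyParams(BaseModel):
    """Cow-side energy balance constants.

    ``gain_energy_*`` define the linear energy content of gain/loss versus
    empty-body-fat percentage; they are calibration constants (the condition
    trajectory they produce at the lowest and highest intake levels is the
    calibration target, see docs/methods.md).
    """

    nem_factor: float = Field(default=0.077, gt=0,
                              description="Mcal NEm per kg^0.75 current SBW")
    low_milk_cutoff: float = Field(default=7.0, gt=0)
    low_milk_adjust: float = Field(default=0.88, gt=0, le=1)
    gestation_efficiency: float = Field(default=0.13, gt=0, le=1)
    gestation_length: int = Field(default=283, gt=0)
    # energy content of gain/loss: e_g = a + b * EBF%, Mcal per kg SBW change
    gain_energy_intercept: float = Field(default=0.55)
    gain_energy_slope: float = Field(default=0.165, gt=0)
    gain_energy_min: float = Field(default=1.4, gt=0)
    # tissue composition used to convert gain energy to fat accretion
    fat_energy: float = Field(default=9.4, gt=0)
    lean_energy: float = Field(default=1.1, gt=0)
    shrunk_to_empty: float = Field(default=0.891, gt=0, le=1)
    # EBF <-> BCS linear map (EBF% = bcs_slope * BCS)
    bcs_slope: float = Field(default=3.7678, gt=0)
    ebf_max: float = Field(default=45.0, gt=0, lt=50)
    ebf_min: float = Field(default=1.0, ge=0)
    # milk net energy on a maintenance-equivalent basis, Mcal per kg milk
    milk_ne_content: float = Field(default=0.75, gt=0)
    initial_bcs: float = Field(default=5.0, ge=1, le=9)


class LactationParams(BaseModel):
    """Lactation curve and calf intake/growth constants.

    The calf gain model is a calibrated net-energy formulation: coefficients
    were fitted once so the simulated progeny grid (pre-weaning ADG, weaning
    weight, creep intake across the nine genotypes) matches the study's
    drylot conditions; see docs/methods.md.
    """

    peak_day: float = Field(default=60.0, gt=0)
    wood_shape: float = Field(default=0.35, gt=0)
    # calf birth weight: mean = intercept + slope * genotype MSBW mean
    birth_weight_intercept: float = Field(default=31.475)
    birth_weight_slope: float = Field(default=0.0045)
    birth_weight_sd: float = Field(default=2.0, ge=0)
    # creep feed: factor * max(0, c1 * BW^0.75 - c2 * milk), from start_age
    creep_start_age: int = Field(default=75, ge=0)
    creep_factor: float = Field(default=0.2, gt=0)
    creep_bw_coeff: float = Field(default=0.1857, ge=0)
    creep_milk_coeff: float = Field(default=0.3562, ge=0)
    # calf gain: ADG = (k_milk*milk + k_creep*creep - k_maint*BW^0.75) / e_gain
    # with e_gain scaled by (msbw_ref / MSBW)^size_exponent; k_milk and
    # k_maint are effective regression-style coefficients, not literal
    # milk energy contents (see docs/methods.md)
    calf_k_milk: float = Field(default=0.126, gt=0,
                               description="effective Mcal NE per kg milk")
    calf_k_creep: float = Field(default=0.803, gt=0,
                                description="Mcal NEg per kg creep DM")
    calf_k_maint: float = Field(default=0.01, gt=0)
    calf_gain_energy: float = Field(default=1.5, gt=0,
                                    description="Mcal NE per kg calf gain at msbw_ref")
    calf_size_exponent: float = Field(default=0.251, ge=0)
    # gain becomes costlier as the calf grows (fatter composition of gain)
    calf_bw_exponent: float = Field(default=0.0, ge=0)
    calf_bw_ref: float = Field(default=90.0, gt=0)
    msbw_ref: float = Field(default=550.0, gt=0)


class ReproParams(BaseModel):
    """Stochastic reproduction parameters.

    ``ppi_table`` maps a BCS-at-calving band to a triangular (min, mode,
    max) postpartum interval in days.  Only the top-band mode (50 d at BCS
    >= 6) is fixed by the model description; the remaining entries are
    calibration constants.
    """

    ppi_table: Dict[str, Tuple[float, float, float]] = Field(
        default={
            "bcs_ge_6": (40.0, 50.0, 68.0),
            "bcs_5": (42.0, 56.0, 88.0),
            "bcs_4": (55.0, 75.0, 120.0),
            "bcs_le_3": (170.0, 205.0, 260.0),
        }
    )
    cycle_length: int = Field(default=21, gt=0)
    conception_prob: float = Field(default=0.58, ge=0, le=1)
    pregnancy_loss_prob: float = Field(default=0.03, ge=0, le=1)
    calf_preweaning_mortality: float = Field(default=0.046, ge=0, le=1)
    calf_death_max_age: int = Field(default=60, gt=0,
                                    description="deaths drawn uniformly in [1, max]")
    gestation_length: int = Field(default=283, gt=0)
    pregnancy_diagnosis_delay: int = Field(default=60, ge=0,
                                           description="days after breeding-season end")
    cow_mortality_annual: float = Field(default=0.0, ge=0, le=1)
    min_cull_thresholds: Dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_table(self) -> "ReproParams":
        prev_mode = None
        for band in ("bcs_ge_6", "bcs_5", "bcs_4", "bcs_le_3"):
            lo, mode, hi = self.ppi_table[band]
            if not (lo <= mode <= hi):
                raise ValueError(f"ppi_table[{band}]: need min <= mode <= max")
            if prev_mode is not None and mode < prev_mode:
                raise ValueError("ppi_table modes must be non-increasing in BCS")
            prev_mode = mode
        if self.ppi_table["bcs_ge_6"][1] < 50.0:
            raise ValueError("top-band PPI mode has a 50-day minimum")
        return self


class SimulationConfig(BaseModel):
    """Top-level run configuration; a minimal file needs only ``rng_seed``."""

    herd_size: int = Field(default=100, ge=1)
    horizon_years: int = Field(default=24, ge=2, le=24)
    breeding_start: str = Field(default="06-15")
    breeding_season_length: int = Field(default=90, gt=0)
    weaning_trigger_age: int = Field(default=220, ge=0)
    max_cow_age_years: int = Field(default=13, ge=2)
    precalving_feed_lead: int = Field(default=14, ge=0)
    postcalving_feed_resume: int = Field(default=10, ge=0)
    silage_dmi: float = Field(default=7.0, gt=0)
    rng_seed: int = Field(...)
    n_replicates: int = Field(default=5, ge=1)
    burn_in_years: int = Field(default=3, ge=0)

    diet: DietSpec = Field(default_factory=DietSpec)
    energy: EnergyParams = Field(default_factory=EnergyParams)
    lactation: LactationParams = Field(default_factory=LactationParams)
    repro: ReproParams = Field(default_factory=ReproParams)

    msbw_means: List[float] = Field(default=[450.0, 550.0, 650.0])
    peak_milk_means: List[float] = Field(default=[8.0, 10.0, 12.0])
    msbw_sd: float = Field(default=25.4, gt=0)
    peak_milk_sd: float = Field(default=1.45, gt=0)
    dmi_levels: List[float] = Field(default=[58.0, 76.0, 93.0, 111.0])

    # heifer development targets as fractions of individual MSBW
    heifer_breeding_target: float = Field(default=0.60, gt=0, le=1)
    heifer_calving_target: float = Field(default=0.80, gt=0, le=1)

    @field_validator("breeding_start")
    @classmethod
    def _valid_monthday(cls, v: str) -> str:
        doy_from_monthday(v)
        return v

    @property
    def breeding_start_doy(self) -> int:
        return doy_from_monthday(self.breeding_start)

    @property
    def genotype_grid(self) -> List[GenotypeSpec]:
        return [
            GenotypeSpec(msbw_mean=m, msbw_sd=self.msbw_sd,
                         peak_milk_mean=p, peak_milk_sd=self.peak_milk_sd)
            for m in self.msbw_means
            for p in self.peak_milk_means
        ]


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML configuration file, applying defaults and validation."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return SimulationConfig.model_validate(raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
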