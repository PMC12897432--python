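"""Synthetic population: genotype sampling, herd initialization, and the
replacement-heifer draft.

Individual genotypes are drawn from normal distributions around the
scenario cell means (MSBW SD 25.4 kg, peak milk SD 1.45 kg/d), truncated
at +-3 SD to exclude non-physical draws.  The initial herd approximates
the stationary age structure implied by the culling rules (geometric
survival over ages 2-13); the first simulated years are treated as burn-in
by the experiment layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .config import GenotypeSpec, SimulationConfig
from .energetics import ebf_from_bcs
from .lactation import birth_weight_mean
from .rng import CounterRNG, Purpose

__all__ = ["GenotypeDraw", "Herd", "sample_genotype", "initialize_herd",
           "draft_replacements"]

_NEVER = np.int32(-100_000)

# survival odds used for the initial age pyramid (ages 2..13)
_AGE_SURVIVAL = 0.85
# fraction of MSBW attained by age class (2, 3, 4, mature)
_AGE_BW_FRACTION = {2: 0.85, 3: 0.96, 4: 0.98}


@dataclass
class GenotypeDraw:
    """Sampled individual genotypes for one or more females."""

    msbw: np.ndarray
    peak_milk: np.ndarray
    birth_weight_ebv: np.ndarray  # expected calf birth weight, kg


def _trunc_std_normal(u, lo: float = -3.0, hi: float = 3.0) -> np.ndarray:
    return truncnorm.ppf(np.asarray(u, dtype=float), lo, hi)


def sample_genotype(spec: GenotypeSpec, rng, n: int = 1,
                    keys: Optional[tuple] = None) -> GenotypeDraw:
    """Draw ``n`` independent individual genotypes from a grid cell.

    ``rng`` may be a numpy Generator (sequential draws) or a
    :class:`~cowcalf.rng.CounterRNG`, in which case ``keys`` supplies the
    (herd, animal-id) integer keys for reproducible keyed draws.
    """
    if isinstance(rng, CounterRNG):
        if keys is None:
            raise ValueError("CounterRNG sampling requires keys")
        z_m = _trunc_std_normal(rng.uniform(*keys, int(Purpose.GENOTYPE_MSBW)))
        z_p = _trunc_std_normal(rng.uniform(*keys, int(Purpose.GENOTYPE_MILK)))
    else:
        z_m = _trunc_std_normal(rng.uniform(size=n))
        z_p = _trunc_std_normal(rng.uniform(size=n))
    msbw = spec.msbw_mean + spec.msbw_sd * np.atleast_1d(z_m)
    peak = spec.peak_milk_mean + spec.peak_milk_sd * np.atleast_1d(z_p)
    ebv = np.full_like(msbw, float(birth_weight_mean(spec.msbw_mean)))
    return GenotypeDraw(msbw=msbw, peak_milk=peak, birth_weight_ebv=ebv)


@dataclass
class Herd:
    """Structure-of-arrays container for breeding females and their calves.

    One row per female; a nursing calf lives in the dam's row (a cow
    raises at most one calf per year).  Integer sentinel ``-100000`` marks
    'never'/'none' for day-valued fields.
    """

    herd: np.ndarray          # stacked-herd index (int32)
    uid: np.ndarray           # per-herd unique animal id (int64), RNG key
    msbw: np.ndarray
    peak_milk: np.ndarray
    bw_ebv: np.ndarray        # expected calf birth weight (genotype-cell based)
    birth_day: np.ndarray     # simulation day of birth (negative for founders)
    sbw: np.ndarray           # shrunk body weight, kg
    fat_kg: np.ndarray        # empty-body fat mass, kg
    alive: np.ndarray
    purchased: np.ndarray
    parity: np.ndarray
    pregnant: np.ndarray
    days_pregnant: np.ndarray
    conception_day: np.ndarray
    conception_year: np.ndarray   # breeding-season year of conception
    abort_day: np.ndarray
    expected_cbw: np.ndarray
    ppi: np.ndarray
    last_calving_day: np.ndarray
    lactating: np.ndarray
    cull_flag: np.ndarray
    exposed_year: np.ndarray
    eff_member: np.ndarray    # exposed this season with a calf at side (3+)
    cum_dmi: np.ndarray       # production-year DMI accumulator, kg
    annual_dmi: np.ndarray    # DMI accumulated since last exposure, kg
    calf_cohort: np.ndarray   # breeding-season year that produced the calf
    calf_alive: np.ndarray
    calf_bw: np.ndarray
    calf_birth_bw: np.ndarray
    calf_birth_day: np.ndarray
    calf_female: np.ndarray
    calf_death_age: np.ndarray
    calf_creep_cum: np.ndarray

    @property
    def n(self) -> int:
        return self.herd.size

    def age_days(self, day: int) -> np.ndarray:
        return day - self.birth_day

    def select(self, mask_or_idx) -> "Herd":
        return Herd(**{f.name: getattr(self, f.name)[mask_or_idx]
                       for f in dc_fields(self)})

    def concat(self, other: "Herd") -> "Herd":
        return Herd(**{f.name: np.concatenate([getattr(self, f.name),
                                               getattr(other, f.name)])
                       for f in dc_fields(self)})

    @staticmethod
    def empty(n: int) -> "Herd":
        i32 = lambda v: np.full(n, v, dtype=np.int32)
        return Herd(
            herd=i32(0), uid=np.zeros(n, dtype=np.int64),
            msbw=np.zeros(n), peak_milk=np.zeros(n), bw_ebv=np.zeros(n),
            birth_day=i32(_NEVER), sbw=np.zeros(n), fat_kg=np.zeros(n),
            alive=np.ones(n, dtype=bool), purchased=np.zeros(n, dtype=bool),
            parity=np.zeros(n, dtype=np.int16),
            pregnant=np.zeros(n, dtype=bool),
            days_pregnant=np.zeros(n, dtype=np.int16),
            conception_day=i32(_NEVER), conception_year=i32(-1),
            abort_day=i32(_NEVER), expected_cbw=np.zeros(n),
            ppi=np.zeros(n), last_calving_day=i32(_NEVER),
            lactating=np.zeros(n, dtype=bool),
            cull_flag=np.zeros(n, dtype=bool),
            exposed_year=i32(-1), eff_member=np.zeros(n, dtype=bool),
            cum_dmi=np.zeros(n), annual_dmi=np.zeros(n),
            calf_cohort=i32(-1),
            calf_alive=np.zeros(n, dtype=bool), calf_bw=np.zeros(n),
            calf_birth_bw=np.zeros(n), calf_birth_day=i32(_NEVER),
            calf_female=np.zeros(n, dtype=bool),
            calf_death_age=i32(_NEVER), calf_creep_cum=np.zeros(n),
        )


def _initial_ages_years(u: np.ndarray, max_age: int = 13) -> np.ndarray:
    """Sample integer ages 2..max_age from a geometric survival profile."""
    ages = np.arange(2, max_age + 1)
    w = _AGE_SURVIVAL ** (ages - 2)
    cdf = np.cumsum(w) / w.sum()
    return ages[np.searchsorted(cdf, np.asarray(u))]


def initialize_herd(spec: GenotypeSpec, config: SimulationConfig,
                    crng: CounterRNG, herd_index: int = 0) -> Herd:
    """Create the founding herd: ``herd_size`` pregnant females with a
    stable age pyramid and spring calving dates scattered over the window
    implied by the previous breeding season.

    Simulation day 0 is January 1; founders are mid-gestation so the first
    calving season unfolds immediately.
    """
    n = config.herd_size
    herd = Herd.empty(n)
    uid = np.arange(n, dtype=np.int64)
    herd.uid = uid
    herd.herd = np.full(n, herd_index, dtype=np.int32)

    geno = sample_genotype(spec, crng, keys=(herd_index, uid))
    herd.msbw, herd.peak_milk, herd.bw_ebv = geno.msbw, geno.peak_milk, geno.birth_weight_ebv

    ages = _initial_ages_years(crng.uniform(herd_index, uid, int(Purpose.INIT_AGE)))
    # founders were born in spring (~ day-of-year 95) of year -age
    herd.birth_day = (95 - 365 * ages).astype(np.int32)
    herd.parity = (ages - 2).astype(np.int16)

    frac = np.ones(n)
    for age, f in _AGE_BW_FRACTION.items():
        frac[ages == age] = f
    herd.sbw = frac * herd.msbw
    p = config.energy
    herd.fat_kg = ebf_from_bcs(p.initial_bcs, p) / 100.0 * p.shrunk_to_empty * herd.sbw

    # conception day within last year's season: geometric over 21-d cycles
    u1 = crng.uniform(herd_index, uid, int(Purpose.INIT_CONCEPTION), 0)
    u2 = crng.uniform(herd_index, uid, int(Purpose.INIT_CONCEPTION), 1)
    p_c = min(max(config.repro.conception_prob, 0.3), 0.99)
    cycles = np.minimum(np.floor(np.log(u1) / np.log1p(-p_c)), 3)
    c = np.minimum(cycles * 21 + u2 * 21, config.breeding_season_length - 1.0)
    season0 = config.breeding_start_doy - 1  # 0-based day of year
    herd.pregnant[:] = True
    herd.conception_day = (season0 + c - 365).astype(np.int32)
    herd.conception_year = np.full(n, -1, dtype=np.int32)
    herd.days_pregnant = (-herd.conception_day).astype(np.int16)
    u3 = crng.uniform(herd_index, uid, int(Purpose.BIRTH_WEIGHT), 0)
    herd.expected_cbw = (birth_weight_mean(spec.msbw_mean, config.lactation)
                         + config.lactation.birth_weight_sd * _trunc_std_normal(u3))
    return herd


def draft_replacements(open_slots: int, raised_heifers: Herd,
                       spec: GenotypeSpec, rng, entry_age_days: int | None = None
                       ) -> Herd:
    """Select replacement heifers for ``open_slots`` herd openings.

    Raised heifers are taken oldest-first; any shortfall is filled with
    purchased heifers whose genotypes are drawn from the same scenario
    cell ("purchased to match traits").  Purchased heifers enter at the
    median raised-heifer age (or ``entry_age_days``).
    """
    if open_slots < 0:
        raise ValueError("open_slots must be non-negative")
    order = np.argsort(raised_heifers.birth_day, kind="stable")
    take = order[: min(open_slots, raised_heifers.n)]
    selected = raised_heifers.select(take)
    shortfall = open_slots - selected.n
    if shortfall <= 0:
        return selected
    bought = Herd.empty(shortfall)
    geno = sample_genotype(spec, rng, n=shortfall)
    bought.msbw, bought.peak_milk, bought.bw_ebv = (geno.msbw, geno.peak_milk,
                                                   geno.birth_weight_ebv)
    if entry_age_days is None:
        entry_age_days = (int(np.median(-raised_heifers.birth_day))
                          if raised_heifers.n else 420)
    bought.birth_day = np.full(shortfall, -entry_age_days, dtype=np.int32)
    bought.purchased[:] = True
    bought.sbw = 0.60 * bought.msbw
    return selected.concat(bought)
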