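"""Reproductive event logic: postpartum interval, estrus and conception,
pregnancy loss, culling rules, and the herd-wide weaning schedule.

Functions here are pure and vectorized; the daily event engine
(:mod:`cowcalf.engine`) wires them to the calendar.  The stochastic
primitives take uniforms so they compose with the counter-based RNG.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .config import ReproParams

__all__ = [
    "ppi_band",
    "triangular_ppf",
    "assign_ppi",
    "estrus_today",
    "conception_trial",
    "cycling_in_first_21d",
    "cull_flags",
    "schedule_weaning",
    "production_year_bounds",
]

_BANDS = ("bcs_le_3", "bcs_4", "bcs_5", "bcs_ge_6")


def ppi_band(bcs) -> np.ndarray:
    """Band index for BCS at calving: 0 = BCS<=3 ... 3 = BCS>=6."""
    b = np.asarray(bcs, dtype=float)
    return np.clip(np.floor(b).astype(int) - 3, 0, 3)


def triangular_ppf(u, lo, mode, hi):
    """Inverse CDF of the triangular(min, mode, max) distribution."""
    u = np.asarray(u, dtype=float)
    lo = np.asarray(lo, dtype=float)
    mode = np.asarray(mode, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(span > 0, (mode - lo) / np.where(span > 0, span, 1.0), 1.0)
        left = lo + np.sqrt(np.maximum(u * span * (mode - lo), 0.0))
        right = hi - np.sqrt(np.maximum((1.0 - u) * span * (hi - mode), 0.0))
    out = np.where(u < fc, left, right)
    return np.where(span > 0, out, lo)


def assign_ppi(bcs_at_calving, params: ReproParams, u) -> np.ndarray:
    """Draw a postpartum anestrus interval (days) from the triangular
    distribution of the cow's BCS-at-calving band.  Higher condition bands
    have stochastically shorter intervals."""
    bcs = np.asarray(bcs_at_calving, dtype=float)
    if np.any(bcs < 1.0) or np.any(bcs > 9.0):
        raise ValueError("BCS must lie in [1, 9]")
    table = np.array([params.ppi_table[b] for b in _BANDS], dtype=float)
    band = ppi_band(bcs)
    lo, mode, hi = table[band, 0], table[band, 1], table[band, 2]
    return triangular_ppf(u, lo, mode, hi)


def estrus_today(days_postpartum, ppi, cycle_length: int = 21) -> np.ndarray:
    """True on the days a cow stands in estrus: at resumption of cycling
    (days postpartum equals the assigned interval) and every cycle after."""
    dpp = np.asarray(days_postpartum)
    ppi = np.asarray(ppi)
    since = dpp - np.ceil(ppi).astype(dpp.dtype)
    return (since >= 0) & (since % cycle_length == 0)


def conception_trial(in_season, in_estrus, open_, u, conception_prob: float
                     ) -> np.ndarray:
    """Bernoulli conception at each in-season estrus of an open female.

    Returns a boolean array of conceptions today; the per-cycle probability
    is constant, independent of condition — a stated model assumption.
    """
    trial = np.asarray(in_season) & np.asarray(in_estrus) & np.asarray(open_)
    return trial & (np.asarray(u) < conception_prob)


def cycling_in_first_21d(calving_day, ppi, season_start: int, window: int = 21
                         ) -> np.ndarray:
    """True for cows whose postpartum interval has elapsed at some point in
    the first ``window`` days of the breeding season."""
    resume = np.asarray(calving_day, dtype=float) + np.asarray(ppi, dtype=float)
    return resume < season_start + window


def cull_flags(pregnant, age_years_at_diagnosis, max_age_years: int = 13
               ) -> np.ndarray:
    """Open cows and cows older than the maximum age at pregnancy diagnosis
    are flagged for culling (sold at calf weaning); over-age cows are culled
    even when pregnant."""
    return (~np.asarray(pregnant, dtype=bool)) | (
        np.asarray(age_years_at_diagnosis, dtype=float) > max_age_years
    )


def schedule_weaning(calf_birth_days: Sequence[int], trigger_age: int = 220
                     ) -> Tuple[int, np.ndarray]:
    """Herd-wide weaning date: the day the oldest live calf is ``trigger_age``
    days old.  Returns (weaning_day, weaning_age_per_calf)."""
    births = np.asarray(calf_birth_days)
    if births.size == 0:
        raise ValueError("no live calves to schedule weaning for")
    weaning_day = int(births.min()) + int(trigger_age)
    return weaning_day, weaning_day - births


def production_year_bounds(calving_days: Sequence[int], cull_day: int | None = None
                           ) -> list[Tuple[int, int]]:
    """Per-female production-year intervals: calving-to-next-calving, with
    the final interval closed by the cull date if the cow left the herd."""
    days = sorted(int(d) for d in calving_days)
    if not days:
        return []
    bounds = [(days[i], days[i + 1]) for i in range(len(days) - 1)]
    if cull_day is not None:
        if cull_day < days[-1]:
            raise ValueError("cull day precedes final calving")
        bounds.append((days[-1], int(cull_day)))
    return bounds
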