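"""Daily-time-step herd engine.

Simulates one or many herds ("scenarios x replicates") in a single stacked
structure-of-arrays pass.  Because every stochastic draw is keyed by
(seed, herd, animal, day, purpose) through the counter-based RNG, each
herd's trajectory is a pure function of its own key — stacking is purely a
performance device and has no statistical side effects.

Calendar: fixed 365-day years, day 0 = January 1 of year 0.  The default
production calendar: breeding June 15 for 90 days; calving the following
spring (283-day gestation); herd-wide weaning when the oldest calf turns
220 days; pregnancy diagnosis 60 days after the season ends, when open
and over-age females are culled; pre-calving corn silage feeding from 14
days before the calving season until 10 days after each cow's calving.

Output accounting distinguishes two cohort views (both per breeding-season
year ``y``):

* forward percentages (pregnancy/calving/weaning per cow exposed): the
  denominator is every 3+-yr-old female present at the season-``y`` start;
  numerators are diagnosis-``y`` pregnancies, spring-``y+1`` calvings and
  fall-``y+1`` weanings from those conceptions.
* contemporaneous progeny metrics (birth weight, creep, ADG, weaning
  weight, weaning weight per cow exposed, annual DMI, efficiency): over
  exposed 3+ dams with a calf at side in season ``y`` and their calves
  weaned that fall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import GenotypeSpec, SimulationConfig, nem_from_me
from .energetics import (bcs_from_ebf, conceptus_energy_rate, ebf_from_bcs,
                         energy_balance_step, heifer_dmi_for_target,
                         nem_required)
from .lactation import birth_weight_mean, calf_creep_intake, calf_gain, milk_yield
from .population import Herd, initialize_herd, _trunc_std_normal
from .reproduction import assign_ppi
from .rng import CounterRNG, Purpose

__all__ = ["ScenarioDef", "StackResult", "run_stack", "simulate_scenario"]

_NEVER = np.int32(-100_000)
_BIG = np.int64(10_000_000)


@dataclass
class ScenarioDef:
    """One herd to simulate: a genotype cell at one intake level."""

    genotype: GenotypeSpec
    dmi_level: float
    scenario_id: int = 0
    replicate: int = 0

    @property
    def herd_key(self) -> int:
        return self.scenario_id * 1009 + self.replicate


@dataclass
class StackResult:
    """Per-herd-per-year outputs, the event log, and census bookkeeping."""

    per_year: pd.DataFrame
    events: pd.DataFrame
    final_herd: Herd
    entrants: np.ndarray
    exits: np.ndarray
    final_census: np.ndarray


class _Acc:
    """Per-(herd, cohort-year) accumulators; slot index is year + 1 so the
    founders' conception year (-1) has a slot."""

    NAMES = [
        "exposed3p", "exposed_wc", "pregnant3p", "calved3p", "weaned3p",
        "cycling21", "n_wean", "ww_sum", "weanage_sum", "adg_sum",
        "creep_sum", "birthbw_sum", "birthbw_n", "ppi_sum", "ppi_n",
        "bw_calv_sum", "bcs_calv_n", "bcs_wean_sum", "bcs_wean_n",
        "dmi_eff_sum", "pydmi_sum", "pydmi_n",
    ]

    def __init__(self, n_herds: int, n_years: int):
        self.n_herds = n_herds
        self.n_years = n_years
        for name in self.NAMES:
            setattr(self, name, np.zeros((n_herds, n_years + 2)))
        # raw BCS-at-calving samples for herd medians
        self.bcs_samples: list[tuple[np.ndarray, int, np.ndarray]] = []

    def add(self, name: str, herd_idx, cohort, values=None):
        arr = getattr(self, name)
        herd_idx = np.asarray(herd_idx)
        slot = np.asarray(cohort) + 1
        if values is None:
            np.add.at(arr, (herd_idx, np.broadcast_to(slot, herd_idx.shape)), 1.0)
        else:
            np.add.at(arr, (herd_idx, np.broadcast_to(slot, herd_idx.shape)),
                      values)


class _Events:
    def __init__(self, log_all: bool):
        self.log_all = log_all
        self.rows: list[tuple] = []

    def add(self, day: int, herd, uid, event: str, cause=""):
        herd = np.atleast_1d(np.asarray(herd))
        uid = np.atleast_1d(np.asarray(uid))
        cause = np.broadcast_to(np.atleast_1d(np.asarray(cause, dtype=object)),
                                herd.shape)
        for h, u, c in zip(herd.tolist(), uid.tolist(), cause.tolist()):
            self.rows.append((day, h, u, event, c))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["day", "herd", "uid", "event", "cause"])


def run_stack(scenarios: Sequence[ScenarioDef], config: SimulationConfig,
              base_seed: Optional[int] = None, log_all_events: bool = False
              ) -> StackResult:
    """Simulate a stack of independent herds and collect yearly outputs."""
    seed = config.rng_seed if base_seed is None else base_seed
    crng = CounterRNG(seed)
    n_herds = len(scenarios)
    n_years = config.horizon_years
    total_days = n_years * 365

    herd_key = np.array([s.herd_key for s in scenarios], dtype=np.int64)
    dmi_level = np.array([s.dmi_level for s in scenarios])
    msbw_mean = np.array([s.genotype.msbw_mean for s in scenarios])
    peak_mean = np.array([s.genotype.peak_milk_mean for s in scenarios])
    msbw_sd = np.array([s.genotype.msbw_sd for s in scenarios])
    peak_sd = np.array([s.genotype.peak_milk_sd for s in scenarios])

    p_e, p_l, p_r, diet = (config.energy, config.lactation, config.repro,
                           config.diet)
    nem = diet.nem_content
    nem_silage = nem_from_me(diet.silage_me_content)
    km = nem / diet.me_content
    season_start = config.breeding_start_doy - 1          # 0-based doy
    season_len = config.breeding_season_length
    diag_doy = season_start + season_len + p_r.pregnancy_diagnosis_delay
    gest = p_r.gestation_length
    first_calving_doy = (season_start + gest) % 365
    silage_start_doy = first_calving_doy - config.precalving_feed_lead
    silage_end_doy = min(season_start + season_len + gest - 365
                         + config.postcalving_feed_resume + 1, 364)
    ebf5_frac = float(ebf_from_bcs(p_e.initial_bcs, p_e)) / 100.0 * p_e.shrunk_to_empty

    # lookup tables: normalized lactation curve, conceptus NEm-basis shape
    milk_shape = milk_yield(np.arange(0, 500), 1.0, p_l)
    gest_axis = np.arange(0, gest + 2)
    gest_shape = (conceptus_energy_rate(np.minimum(gest_axis, gest), 1.0)
                  / p_e.gestation_efficiency * km)

    herds = [initialize_herd(s.genotype, config, crng,
                             herd_index=int(herd_key[i]))
             for i, s in enumerate(scenarios)]
    for i, h in enumerate(herds):
        h.herd[:] = i
    H = herds[0]
    for h in herds[1:]:
        H = H.concat(h)
    next_uid = np.full(n_herds, config.herd_size, dtype=np.int64)

    acc = _Acc(n_herds, n_years)
    ev = _Events(log_all_events)
    n_entrants = np.full(n_herds, config.herd_size, dtype=np.int64)
    n_exits = np.zeros(n_herds, dtype=np.int64)

    def _dmi_base(h: Herd) -> np.ndarray:
        scale = np.where(h.parity == 2, 0.96,
                         np.where(h.parity == 3, 0.98, 1.0))
        return (scale * h.msbw) ** 0.75

    dmi_base = _dmi_base(H)
    first_birth = np.full(n_herds, _BIG)
    weaning_day = np.full(n_herds, _BIG)
    pend: List[Herd] = []

    for day in range(total_days):
        doy = day % 365
        year = day // 365
        hk = herd_key[H.herd]
        alive = H.alive

        if doy == 0:
            first_birth[:] = _BIG

        # ---------------- season start: purchases + exposure -----------
        if doy == season_start:
            counts = np.bincount(H.herd[alive], minlength=n_herds)
            need = np.maximum(config.herd_size - counts, 0)
            if need.sum() > 0:
                buys = _make_purchases(need, day, next_uid, herd_key,
                                       msbw_mean, peak_mean, msbw_sd, peak_sd,
                                       crng, config, ebf5_frac)
                pend.append(buys)
                n_entrants += need
            H.exposed_year[alive] = year
            three_plus = alive & (H.parity >= 2)
            acc.add("exposed3p", H.herd[three_plus], year)
            with_calf = three_plus & H.calf_alive
            H.eff_member[:] = False
            H.eff_member[with_calf] = True
            acc.add("exposed_wc", H.herd[with_calf], year)
            heif = alive & (H.parity == 0) & ~H.pregnant
            if heif.any():
                u = crng.uniform(hk[heif], H.uid[heif],
                                 int(Purpose.ESTRUS_PHASE), year)
                H.last_calving_day[heif] = day - np.floor(u * 21).astype(np.int32)
                H.ppi[heif] = 0.0

        # ---------------- percent cycling in the first 21 days ----------
        if doy == season_start + 20:
            m = (alive & (H.parity >= 2) & (H.exposed_year == year)
                 & (H.last_calving_day >= year * 365)
                 & (H.last_calving_day + H.ppi
                    < year * 365 + season_start + 21))
            acc.add("cycling21", H.herd[m], year)

        # ---------------- estrus and conception -------------------------
        if season_start <= doy < season_start + season_len:
            dpp = (day - H.last_calving_day).astype(np.int64)
            since = dpp - np.ceil(H.ppi).astype(np.int64)
            estrus = (since >= 0) & (since % p_r.cycle_length == 0)
            open_ = alive & ~H.pregnant & (H.exposed_year == year) & estrus
            if open_.any():
                idx = np.flatnonzero(open_)
                u = crng.uniform(hk[idx], H.uid[idx],
                                 int(Purpose.CONCEPTION), day)
                idx = idx[u < p_r.conception_prob]
                if idx.size:
                    H.pregnant[idx] = True
                    H.days_pregnant[idx] = 0
                    H.conception_day[idx] = day
                    H.conception_year[idx] = year
                    kh, ku = hk[idx], H.uid[idx]
                    z = _trunc_std_normal(
                        crng.uniform(kh, ku, int(Purpose.BIRTH_WEIGHT), day))
                    H.expected_cbw[idx] = H.bw_ebv[idx] + p_l.birth_weight_sd * z
                    lose = crng.uniform(kh, ku, int(Purpose.PREGNANCY_LOSS),
                                        day) < p_r.pregnancy_loss_prob
                    diag_day = year * 365 + diag_doy
                    u_ab = crng.uniform(kh, ku, int(Purpose.ABORT_DAY), day)
                    ab = (diag_day + u_ab * (day + gest - diag_day)).astype(np.int32)
                    H.abort_day[idx] = np.where(lose, ab, _NEVER)
                    if ev.log_all:
                        ev.add(day, H.herd[idx], H.uid[idx], "conception")

        # ---------------- pregnancy diagnosis + culling ------------------
        if doy == diag_doy:
            m_exposed = alive & (H.exposed_year == year)
            preg3 = m_exposed & H.pregnant & (H.parity >= 2)
            acc.add("pregnant3p", H.herd[preg3], year)
            over_age = alive & ((day - H.birth_day)
                                > config.max_cow_age_years * 365)
            cull = (m_exposed & ~H.pregnant) | over_age
            if cull.any():
                idx = np.flatnonzero(cull)
                H.alive[idx] = False
                H.calf_alive[idx] = False
                np.add.at(n_exits, H.herd[idx], 1)
                ev.add(day, H.herd[idx], H.uid[idx], "cull",
                       np.where(H.pregnant[idx], "over_age", "open"))
                alive = H.alive

        # ---------------- pregnancy loss (post-diagnosis abortion) -------
        ab = alive & H.pregnant & (H.abort_day == day)
        if ab.any():
            idx = np.flatnonzero(ab)
            H.pregnant[idx] = False
            H.alive[idx] = False
            H.calf_alive[idx] = False
            np.add.at(n_exits, H.herd[idx], 1)
            ev.add(day, H.herd[idx], H.uid[idx], "cull", "abortion")
            alive = H.alive

        # ---------------- gestation advance + calving --------------------
        H.days_pregnant[alive & H.pregnant] += 1
        calv = alive & H.pregnant & (H.days_pregnant >= gest)
        if calv.any():
            idx = np.flatnonzero(calv)
            coh = H.conception_year[idx]
            had_prior = H.last_calving_day[idx] > _NEVER
            three_at_exposure = H.parity[idx] >= 2
            if had_prior.any():
                sel = idx[had_prior]
                acc.add("pydmi_sum", H.herd[sel], coh[had_prior],
                        np.where(three_at_exposure[had_prior],
                                 H.cum_dmi[sel], 0.0))
                acc.add("pydmi_n", H.herd[sel], coh[had_prior],
                        np.where(three_at_exposure[had_prior], 1.0, 0.0))
            H.cum_dmi[idx] = 0.0
            H.parity[idx] += 1
            H.pregnant[idx] = False
            H.days_pregnant[idx] = 0
            H.last_calving_day[idx] = day
            H.lactating[idx] = True
            dmi_base[idx] = (np.where(H.parity[idx] == 2, 0.96,
                                      np.where(H.parity[idx] == 3, 0.98, 1.0))
                             * H.msbw[idx]) ** 0.75
            ebw = p_e.shrunk_to_empty * H.sbw[idx]
            bcs = bcs_from_ebf(100.0 * H.fat_kg[idx] / ebw, p_e)
            u = crng.uniform(hk[idx], H.uid[idx], int(Purpose.PPI), day)
            H.ppi[idx] = assign_ppi(bcs, p_r, u)
            now3 = H.parity[idx] >= 2      # 3+-yr-old this production year
            fwd3 = H.parity[idx] >= 3      # 3+ at last season's exposure
            acc.add("calved3p", H.herd[idx], coh, fwd3.astype(float))
            acc.add("ppi_sum", H.herd[idx], year, np.where(now3, H.ppi[idx], 0.0))
            acc.add("ppi_n", H.herd[idx], year, now3.astype(float))
            acc.add("bw_calv_sum", H.herd[idx], year,
                    np.where(now3, H.sbw[idx], 0.0))
            acc.add("bcs_calv_n", H.herd[idx], year, now3.astype(float))
            if now3.any():
                acc.bcs_samples.append((H.herd[idx][now3].copy(), year,
                                        bcs[now3].copy()))
            # calf drop
            H.calf_alive[idx] = True
            H.calf_birth_bw[idx] = np.maximum(H.expected_cbw[idx], 15.0)
            H.calf_bw[idx] = H.calf_birth_bw[idx]
            H.calf_birth_day[idx] = day
            H.calf_cohort[idx] = coh
            H.calf_creep_cum[idx] = 0.0
            kh, ku = hk[idx], H.uid[idx]
            H.calf_female[idx] = crng.uniform(kh, ku, int(Purpose.CALF_SEX),
                                              day) < 0.5
            u_d = crng.uniform(kh, ku, int(Purpose.CALF_DEATH), day)
            u_a = crng.uniform(kh, ku, int(Purpose.CALF_DEATH), day + 500_000)
            dies = u_d < p_r.calf_preweaning_mortality
            age_d = 1 + np.floor(u_a * p_r.calf_death_max_age).astype(np.int32)
            H.calf_death_age[idx] = np.where(dies, age_d,
                                             _NEVER).astype(np.int32)
            acc.add("birthbw_sum", H.herd[idx], coh,
                    np.where(now3, H.calf_birth_bw[idx], 0.0))
            acc.add("birthbw_n", H.herd[idx], coh, now3.astype(float))
            np.minimum.at(first_birth, H.herd[idx], day)
            weaning_day = np.where(first_birth < _BIG,
                                   first_birth + config.weaning_trigger_age,
                                   weaning_day)
            if ev.log_all:
                ev.add(day, H.herd[idx], H.uid[idx], "calving")

        # ---------------- calf growth, creep, death ----------------------
        cm = alive & H.calf_alive
        milk_row = np.zeros(H.n)
        if cm.any():
            ci = np.flatnonzero(cm)
            age = (day - H.calf_birth_day[ci]).astype(np.int64)
            dim = (day - H.last_calving_day[ci]).astype(np.int64)
            milk = H.peak_milk[ci] * milk_shape[np.clip(dim, 0, 499)]
            milk_row[ci] = milk
            creep = calf_creep_intake(H.calf_bw[ci], milk, age, p_l)
            gain = calf_gain(H.calf_bw[ci], milk, creep, H.msbw[ci], diet, p_l)
            H.calf_bw[ci] += gain
            H.calf_creep_cum[ci] += creep
            dead = age == H.calf_death_age[ci]
            if dead.any():
                di = ci[dead]
                H.calf_alive[di] = False
                H.lactating[di] = False  # dam dries off
                ev.add(day, H.herd[di], H.uid[di], "calf_death")
                if doy < season_start:
                    H.alive[di] = False
                    np.add.at(n_exits, H.herd[di], 1)
                    ev.add(day, H.herd[di], H.uid[di], "cull", "calf_death")
                    alive = H.alive

        # ---------------- herd-wide weaning ------------------------------
        wean_h = np.flatnonzero(weaning_day == day)
        if wean_h.size:
            in_wean = alive & H.calf_alive & np.isin(H.herd, wean_h)
            if in_wean.any():
                wi = np.flatnonzero(in_wean)
                age = (day - H.calf_birth_day[wi]).astype(float)
                adg = (H.calf_bw[wi] - H.calf_birth_bw[wi]) / age
                eff = H.eff_member[wi]
                hsel = H.herd[wi]
                acc.add("n_wean", hsel[eff], year)
                acc.add("ww_sum", hsel[eff], year, H.calf_bw[wi][eff])
                acc.add("weanage_sum", hsel[eff], year, age[eff])
                acc.add("adg_sum", hsel[eff], year, adg[eff])
                acc.add("creep_sum", hsel[eff], year,
                        (H.calf_creep_cum[wi] / age)[eff])
                fwd = H.parity[wi] >= 3
                if fwd.any():
                    acc.add("weaned3p", hsel[fwd], H.calf_cohort[wi][fwd])
                ebw = p_e.shrunk_to_empty * H.sbw[wi]
                bcs = bcs_from_ebf(100.0 * H.fat_kg[wi] / ebw, p_e)
                now3 = H.parity[wi] >= 2
                acc.add("bcs_wean_sum", hsel[now3], year, bcs[now3])
                acc.add("bcs_wean_n", hsel[now3], year)
                if ev.log_all:
                    ev.add(day, hsel, H.uid[wi], "wean")
                retained = _retain_heifers(H, wi, wean_h, day, config, crng,
                                           herd_key, next_uid, ebf5_frac,
                                           msbw_mean, peak_mean, msbw_sd,
                                           peak_sd)
                if retained is not None:
                    pend.append(retained)
                    np.add.at(n_entrants, retained.herd, 1)
                H.calf_alive[wi] = False
                H.lactating[wi] = False

        # ---------------- feeding and energy balance ---------------------
        lact = alive & H.lactating
        on_silage = (alive & (H.parity >= 1)
                     & (silage_start_doy <= doy) & (doy <= silage_end_doy)
                     & ((H.pregnant & (H.days_pregnant >= 200))
                        | (lact & ((day - H.last_calving_day)
                                   <= config.postcalving_feed_resume))))
        cows3 = alive & (H.parity >= 2)
        cows2 = alive & (H.parity == 1)
        heifer = alive & (H.parity == 0)

        dmi = np.zeros(H.n)
        lvl = dmi_level[H.herd]
        dmi[cows3] = ((lvl[cows3] + np.where(lact[cows3], 18.0, 0.0))
                      / 1000.0 * dmi_base[cows3])
        if cows2.any():
            c2 = np.flatnonzero(cows2)
            dmi[c2] = (H.sbw[c2]**0.75 * (0.04997 * nem**2 + 0.04631) / nem
                       + 0.2 * milk_row[c2])
        dmi[on_silage] = config.silage_dmi

        cowm = cows3 | cows2
        if cowm.any():
            ci = np.flatnonzero(cowm)
            supply = dmi[ci] * np.where(on_silage[ci], nem_silage, nem)
            req = nem_required(H.sbw[ci], H.peak_milk[ci], p_e)
            dim = (day - H.last_calving_day[ci]).astype(np.int64)
            req = req + np.where(lact[ci],
                                 H.peak_milk[ci]
                                 * milk_shape[np.clip(dim, 0, 499)]
                                 * p_e.milk_ne_content, 0.0)
            dp = np.clip(H.days_pregnant[ci].astype(np.int64), 0, gest + 1)
            req = req + np.where(H.pregnant[ci],
                                 H.expected_cbw[ci] * gest_shape[dp], 0.0)
            sbw, fat, _ = energy_balance_step(H.sbw[ci], H.fat_kg[ci],
                                              supply - req, p_e)
            H.sbw[ci] = sbw
            H.fat_kg[ci] = fat

        if heifer.any():
            hi = np.flatnonzero(heifer)
            preg_h = H.pregnant[hi]
            target = np.where(preg_h,
                              config.heifer_calving_target * H.msbw[hi],
                              config.heifer_breeding_target * H.msbw[hi])
            next_season = ((year + (1 if doy >= season_start else 0)) * 365
                           + season_start)
            t_day = np.where(preg_h, H.conception_day[hi] + gest,
                             next_season).astype(float)
            days_left = np.maximum(t_day - day, 1.0)
            dmi[hi] = heifer_dmi_for_target(H.sbw[hi], target, days_left,
                                            diet, H.msbw[hi], p_e)
            adg = np.clip((target - H.sbw[hi]) / days_left, 0.0, 1.6)
            H.sbw[hi] += adg
            H.fat_kg[hi] = ebf5_frac * H.sbw[hi]

        H.cum_dmi[alive] += dmi[alive]
        em = alive & H.eff_member
        if em.any():
            np.add.at(acc.dmi_eff_sum,
                      (H.herd[em], H.exposed_year[em] + 1), dmi[em])

        if pend:
            for ph in pend:
                H = H.concat(ph)
            pend = []
            dmi_base = _dmi_base(H)
        if doy == 364:
            keep = H.alive
            H = H.select(keep)
            dmi_base = dmi_base[keep]

    final_census = np.bincount(H.herd[H.alive], minlength=n_herds)
    per_year = _assemble(acc, scenarios, config)
    return StackResult(per_year=per_year, events=ev.frame(), final_herd=H,
                       entrants=n_entrants, exits=n_exits,
                       final_census=final_census)


def _make_purchases(need, day, next_uid, herd_key, msbw_mean, peak_mean,
                    msbw_sd, peak_sd, crng: CounterRNG,
                    config: SimulationConfig, ebf5_frac: float) -> Herd:
    """Purchased yearling heifers matching each herd's genotype cell."""
    herds = np.repeat(np.arange(need.size), need)
    n = herds.size
    uid = np.empty(n, dtype=np.int64)
    pos = 0
    for h in range(need.size):
        k = int(need[h])
        uid[pos:pos + k] = next_uid[h] + np.arange(k)
        next_uid[h] += k
        pos += k
    buys = Herd.empty(n)
    buys.herd = herds.astype(np.int32)
    buys.uid = uid
    hk = herd_key[herds]
    z_m = _trunc_std_normal(crng.uniform(hk, uid, int(Purpose.GENOTYPE_MSBW)))
    z_p = _trunc_std_normal(crng.uniform(hk, uid, int(Purpose.GENOTYPE_MILK)))
    buys.msbw = msbw_mean[herds] + msbw_sd[herds] * z_m
    buys.peak_milk = peak_mean[herds] + peak_sd[herds] * z_p
    buys.bw_ebv = np.asarray(birth_weight_mean(msbw_mean[herds],
                                               config.lactation))
    buys.birth_day = np.full(n, day - 440, dtype=np.int32)
    buys.purchased[:] = True
    buys.sbw = config.heifer_breeding_target * buys.msbw
    buys.fat_kg = ebf5_frac * buys.sbw
    buys.exposed_year[:] = day // 365
    u = crng.uniform(hk, uid, int(Purpose.ESTRUS_PHASE), day)
    buys.last_calving_day = (day - np.floor(u * 21)).astype(np.int32)
    buys.ppi[:] = 0.0
    return buys


def _retain_heifers(H: Herd, weaned_idx, wean_herds, day,
                    config: SimulationConfig, crng: CounterRNG, herd_key,
                    next_uid, ebf5_frac, msbw_mean, peak_mean, msbw_sd,
                    peak_sd) -> Herd | None:
    """Keep enough heifer calves (oldest first) to refill each weaning herd.

    Retained heifers receive independent genotype draws from the scenario
    cell, keeping the population's moments anchored at the cell means.
    """
    rows = []
    alive = H.alive
    for h in wean_herds.tolist():
        projected = int(np.sum(alive & (H.herd == h) & H.pregnant
                               & ((day - H.birth_day)
                                  <= config.max_cow_age_years * 365)))
        need = max(config.herd_size - projected, 0)
        cand = weaned_idx[(H.herd[weaned_idx] == h)
                          & H.calf_female[weaned_idx]]
        if need == 0 or cand.size == 0:
            continue
        order = np.argsort(H.calf_birth_day[cand], kind="stable")
        rows.append((h, cand[order[:need]]))
    if not rows:
        return None
    total = sum(r[1].size for r in rows)
    out = Herd.empty(total)
    pos = 0
    for h, sel in rows:
        k = sel.size
        sl = slice(pos, pos + k)
        out.herd[sl] = h
        uid = next_uid[h] + np.arange(k)
        next_uid[h] += k
        out.uid[sl] = uid
        hk = np.full(k, herd_key[h])
        z_m = _trunc_std_normal(crng.uniform(hk, uid,
                                             int(Purpose.GENOTYPE_MSBW)))
        z_p = _trunc_std_normal(crng.uniform(hk, uid,
                                             int(Purpose.GENOTYPE_MILK)))
        out.msbw[sl] = msbw_mean[h] + msbw_sd[h] * z_m
        out.peak_milk[sl] = peak_mean[h] + peak_sd[h] * z_p
        out.bw_ebv[sl] = float(birth_weight_mean(msbw_mean[h], config.lactation))
        out.birth_day[sl] = H.calf_birth_day[sel]
        out.sbw[sl] = H.calf_bw[sel]
        out.fat_kg[sl] = ebf5_frac * out.sbw[sl]
        pos += k
    return out


def simulate_scenario(genotype: GenotypeSpec, dmi_level: float,
                      config: SimulationConfig, seed: Optional[int] = None,
                      replicate: int = 0, log_all_events: bool = False
                      ) -> StackResult:
    """Convenience wrapper: one genotype cell at one intake level."""
    sc = ScenarioDef(genotype=genotype, dmi_level=dmi_level,
                     scenario_id=0, replicate=replicate)
    return run_stack([sc], config, base_seed=seed,
                     log_all_events=log_all_events)


def _assemble(acc: _Acc, scenarios, config: SimulationConfig) -> pd.DataFrame:
    """Tidy per-(scenario, replicate, year) output table.

    Cohort year ``y`` rows combine forward reproduction percentages of the
    season-``y`` exposure cohort with the progeny metrics weaned in fall
    ``y`` (conceptions of season ``y-1``).  Usable rows run from year 0 to
    horizon - 2; the experiment layer applies burn-in on top.
    """
    years = np.arange(0, acc.n_years - 1)
    frames = []
    # herd medians of BCS at calving
    if acc.bcs_samples:
        bh = np.concatenate([s[0] for s in acc.bcs_samples])
        by = np.concatenate([np.full(s[0].size, s[1]) for s in acc.bcs_samples])
        bb = np.concatenate([s[2] for s in acc.bcs_samples])
        med = (pd.DataFrame({"h": bh, "year": by, "bcs": bb})
               .groupby(["h", "year"])["bcs"].median())
    else:
        med = pd.Series(dtype=float)

    def _safe(num, den):
        return np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)

    for i, s in enumerate(scenarios):
        slot = years + 1
        exp3 = acc.exposed3p[i, slot]
        expwc = acc.exposed_wc[i, slot]
        nwean = acc.n_wean[i, slot]
        dmi_eff = acc.dmi_eff_sum[i, slot]
        df = pd.DataFrame({
            "scenario_id": s.scenario_id,
            "replicate": s.replicate,
            "msbw": s.genotype.msbw_mean,
            "peak_milk": s.genotype.peak_milk_mean,
            "dmi_level": s.dmi_level,
            "year": years,
            "exposed": exp3,
            "pregnancy_pct": 100.0 * _safe(acc.pregnant3p[i, slot], exp3),
            "calving_pct": 100.0 * _safe(acc.calved3p[i, slot], exp3),
            "weaning_pct": 100.0 * _safe(acc.weaned3p[i, slot], exp3),
            "cycling21_pct": 100.0 * _safe(acc.cycling21[i, slot], exp3),
            "mean_ppi": _safe(acc.ppi_sum[i, slot], acc.ppi_n[i, slot]),
            "bw_calving": _safe(acc.bw_calv_sum[i, slot],
                                acc.bcs_calv_n[i, slot]),
            "bcs_wean": _safe(acc.bcs_wean_sum[i, slot],
                              acc.bcs_wean_n[i, slot]),
            "birth_weight": _safe(acc.birthbw_sum[i, slot],
                                  acc.birthbw_n[i, slot]),
            "weaning_weight": _safe(acc.ww_sum[i, slot], nwean),
            "weaning_age": _safe(acc.weanage_sum[i, slot], nwean),
            "preweaning_adg": _safe(acc.adg_sum[i, slot], nwean),
            "creep_dmi": _safe(acc.creep_sum[i, slot], nwean),
            "ww_per_cow_exposed": _safe(acc.ww_sum[i, slot], expwc),
            "annual_dmi_per_cow": _safe(dmi_eff, expwc),
            "pydmi_per_cow": _safe(acc.pydmi_sum[i, slot],
                                   acc.pydmi_n[i, slot]),
            "efficiency_g_per_kg": 1000.0 * _safe(acc.ww_sum[i, slot],
                                                  dmi_eff),
        })
        bcs_med = np.full(years.size, np.nan)
        for j, y in enumerate(years):
            key = (i, y)
            if key in med.index:
                bcs_med[j] = med.loc[key]
        df["bcs_calving_median"] = bcs_med
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
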