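"""Net-energy bioenergetics: intake schedule, requirements, and the daily
energy-balance -> body-weight -> empty-body-fat -> condition-score chain.

All functions are numpy-vectorized: scalars in, scalar out; arrays in,
element-wise arrays out.  Energy flows are expressed on a net-energy-for-
maintenance (NEm) equivalent basis, the convention of the underlying
cow-calf model: dietary NEm concentration is derived from metabolizable
energy, lactation and gestation demands are converted onto the same scale,
and the daily balance (supply minus requirement) drives tissue change.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .config import DietSpec, EnergyParams, IntakePolicy

__all__ = [
    "daily_dmi",
    "nem_required",
    "conceptus_energy_rate",
    "ne_gestation",
    "energy_of_gain",
    "energy_balance_step",
    "bcs_from_ebf",
    "ebf_from_bcs",
    "heifer_dmi_for_target",
    "cow_intake_nasem",
]


def daily_dmi(msbw, age_scaling, policy: IntakePolicy, lactating, on_silage,
              silage_dmi: float = 7.0):
    """Prescribed dry-matter intake (kg DM/d) of a 3+-yr-old cow.

    The intake level is applied to metabolic mature size — ``(age_scaling *
    MSBW)^0.75`` with the 96 %/98 % adjustments for three- and four-year-
    olds — plus the lactation add-on, and is overridden by the fixed corn
    silage allowance inside the pre-calving feeding window.
    """
    msbw = np.asarray(msbw, dtype=float)
    base = np.asarray(age_scaling, dtype=float) * msbw
    level = policy.dmi_level + np.where(lactating, policy.lactation_addon, 0.0)
    dmi = level / 1000.0 * base**0.75
    return np.where(on_silage, silage_dmi, dmi)


def nem_required(shrunk_bw, peak_milk_genotype, params: EnergyParams | None = None):
    """Maintenance NEm requirement (Mcal/d) on current shrunk body weight.

    Genotypes with peak milk potential below the cutoff (7 kg/d) get a 12 %
    reduction, reflecting lower maintenance of low-milk biological types.
    """
    p = params or EnergyParams()
    sbw = np.asarray(shrunk_bw, dtype=float)
    req = p.nem_factor * sbw**0.75
    adj = np.where(np.asarray(peak_milk_genotype, dtype=float) < p.low_milk_cutoff,
                   p.low_milk_adjust, 1.0)
    return req * adj


def conceptus_energy_rate(days_pregnant, expected_birth_weight):
    """Daily conceptus energy deposition (Mcal/d).

    Exponential-family conceptus growth: energy retained per day scales
    with expected calf birth weight and rises steeply through gestation.
    """
    t = np.asarray(days_pregnant, dtype=float)
    cbw = np.asarray(expected_birth_weight, dtype=float)
    rate = cbw * (0.05855 - 0.0000996 * t) * np.exp(0.03233 * t - 0.0000275 * t**2) / 1000.0
    return np.where(t > 0, np.maximum(rate, 0.0), 0.0)


def ne_gestation(days_pregnant, expected_birth_weight, diet: DietSpec,
                 params: EnergyParams | None = None):
    """Gestation requirement (Mcal/d) on the NEm-equivalent basis.

    Conceptus energy is expanded to metabolizable energy at the low (13 %)
    efficiency of ME use for conceptus growth, then converted to the NEm
    scale with the diet's partial efficiency km = NEm content / ME content.
    """
    p = params or EnergyParams()
    t = np.asarray(days_pregnant, dtype=float)
    if np.any(t < 0) or np.any(t > p.gestation_length):
        raise ValueError("days_pregnant outside [0, gestation length]")
    km = diet.nem_content / diet.me_content
    me_preg = conceptus_energy_rate(t, expected_birth_weight) / p.gestation_efficiency
    return me_preg * km


def energy_of_gain(ebf_pct, params: EnergyParams | None = None):
    """Energy content of body-weight change (Mcal per kg shrunk BW).

    Strictly increasing in empty body fat percentage: fatter animals deposit
    (and yield, on mobilization) more energy per kilogram of weight change.
    """
    p = params or EnergyParams()
    e = p.gain_energy_intercept + p.gain_energy_slope * np.asarray(ebf_pct, dtype=float)
    return np.maximum(e, p.gain_energy_min)


def bcs_from_ebf(ebf_pct, params: EnergyParams | None = None):
    """Body condition score (1-9) from empty body fat % via the linear map."""
    p = params or EnergyParams()
    return np.clip(np.asarray(ebf_pct, dtype=float) / p.bcs_slope, 1.0, 9.0)


def ebf_from_bcs(bcs, params: EnergyParams | None = None):
    """Inverse of the EBF -> BCS map (used to initialize body composition)."""
    p = params or EnergyParams()
    return np.asarray(bcs, dtype=float) * p.bcs_slope


def energy_balance_step(shrunk_bw, fat_kg, ne_balance,
                        params: EnergyParams | None = None
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance one day of tissue dynamics.

    ``ne_balance`` is NE supply minus requirement (Mcal/d, maintenance-
    equivalent).  Weight changes by balance divided by the energy content of
    gain at current EBF; the fat fraction of the tissue exchanged follows
    from its energy density, which updates empty body fat and hence BCS.
    Returns (new_sbw, new_fat_kg, new_ebf_pct).
    """
    p = params or EnergyParams()
    sbw = np.asarray(shrunk_bw, dtype=float)
    fat = np.asarray(fat_kg, dtype=float)
    ebw = p.shrunk_to_empty * sbw
    ebf = np.where(ebw > 0, 100.0 * fat / np.maximum(ebw, 1e-9), 0.0)

    e_g = energy_of_gain(ebf, p)
    d_sbw = np.asarray(ne_balance, dtype=float) / e_g
    f_frac = np.clip((e_g - p.lean_energy) / (p.fat_energy - p.lean_energy), 0.02, 0.98)
    d_fat = f_frac * p.shrunk_to_empty * d_sbw

    new_sbw = np.maximum(sbw + d_sbw, 1.0)
    new_ebw = p.shrunk_to_empty * new_sbw
    new_fat = np.clip(fat + d_fat, p.ebf_min / 100.0 * new_ebw,
                      p.ebf_max / 100.0 * new_ebw)
    new_ebf = 100.0 * new_fat / new_ebw
    return new_sbw, new_fat, new_ebf


def _growth_re(sbw, adg, msbw, params: EnergyParams | None = None):
    """Retained energy (Mcal/d) for a growing female at a target ADG.

    Size-scaled retained-energy relation for growing cattle: empty-body
    gain energy rises with metabolic size of the mature-size-equivalent
    weight and a bit faster than linearly with gain.
    """
    p = params or EnergyParams()
    sbw = np.asarray(sbw, dtype=float)
    adg = np.asarray(adg, dtype=float)
    eq_sbw = sbw * 478.0 / np.asarray(msbw, dtype=float)
    eq_ebw = p.shrunk_to_empty * eq_sbw
    ebg = 0.956 * adg
    return 0.0635 * eq_ebw**0.75 * np.maximum(ebg, 0.0) ** 1.097


def heifer_dmi_for_target(current_bw, target_bw, days_to_target, diet: DietSpec,
                          msbw, params: EnergyParams | None = None):
    """DMI (kg/d) for a growing heifer to reach ``target_bw`` on schedule.

    Required ADG is the straight-line gain; intake is back-solved from
    maintenance (NEm) plus growth (NEg) requirements at the diet's NE
    concentrations.  If the target is already met, maintenance-only intake
    is returned.
    """
    p = params or EnergyParams()
    days = np.maximum(np.asarray(days_to_target, dtype=float), 1.0)
    adg = np.maximum((np.asarray(target_bw, dtype=float)
                      - np.asarray(current_bw, dtype=float)) / days, 0.0)
    nem_req = p.nem_factor * np.asarray(current_bw, dtype=float) ** 0.75
    re = _growth_re(current_bw, adg, msbw, p)
    return nem_req / diet.nem_content + re / diet.neg_content


def cow_intake_nasem(shrunk_bw, nem_content, milk_yield=0.0):
    """Predicted voluntary DMI (kg/d) of a beef cow from the standard
    intake equation driven by body weight and diet NEm concentration, with
    a 0.2 kg DM per kg milk lactation adjustment.  Used for 2-yr-old cows,
    whose intake is not prescribed by the experimental design."""
    sbw = np.asarray(shrunk_bw, dtype=float)
    nem = float(nem_content)
    base = sbw**0.75 * (0.04997 * nem**2 + 0.04631) / nem
    return base + 0.2 * np.asarray(milk_yield, dtype=float)
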