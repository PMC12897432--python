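"""Lactation curve, milk energy, calf creep intake and calf growth.

The lactation curve is a normalized Wood curve whose maximum equals the
individual's genetic peak yield — deliberately independent of the cow's
energy intake, which is a documented behaviour of the underlying herd
model (cows achieve genetic milk potential regardless of nutrition and pay
for it in body reserves).

Calf growth is a calibrated net-energy gain model: daily gain is linear in
the net energy supplied by milk and creep feed above metabolic-weight
maintenance, divided by an energy content of gain scaled by mature size.
The coefficients were calibrated once against the drylot progeny grid
(birth weight, creep intake, pre-weaning ADG and weaning weight rising
with dam size and milk genotype); see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .config import DietSpec, LactationParams

__all__ = [
    "milk_yield",
    "birth_weight_mean",
    "calf_creep_intake",
    "calf_gain",
]


def milk_yield(days_in_milk, peak_yield, params: LactationParams | None = None):
    """Milk yield (kg/d) at a given days-in-milk from the Wood-type curve.

    The curve is normalized so its maximum is exactly ``peak_yield`` at
    ``params.peak_day``.  Day-0 yield is evaluated at day 1 (colostrum
    phase is not modelled separately), keeping yield strictly positive.
    """
    p = params or LactationParams()
    t = np.maximum(np.asarray(days_in_milk, dtype=float), 1.0)
    rel = t / p.peak_day
    y = np.asarray(peak_yield, dtype=float) * rel**p.wood_shape \
        * np.exp(p.wood_shape * (1.0 - rel))
    return y


def birth_weight_mean(msbw_mean, params: LactationParams | None = None):
    """Expected calf birth weight (kg), linear in the genotype's mean MSBW
    (sire mature weight assumed equal to the dam genotype mean)."""
    p = params or LactationParams()
    return p.birth_weight_intercept + p.birth_weight_slope * np.asarray(msbw_mean, dtype=float)


def calf_creep_intake(calf_bw, current_milk, age_days,
                      params: LactationParams | None = None):
    """Creep feed DMI (kg/d) of a nursing calf.

    Zero before the creep start age; afterwards a fraction of a predicted
    forage-equivalent intake that rises with calf metabolic weight and
    falls with current milk supply, so calves of low-milk dams compensate.
    """
    p = params or LactationParams()
    bw = np.asarray(calf_bw, dtype=float)
    pred = p.creep_bw_coeff * bw**0.75 - p.creep_milk_coeff * np.asarray(current_milk, dtype=float)
    intake = p.creep_factor * np.maximum(pred, 0.0)
    return np.where(np.asarray(age_days) >= p.creep_start_age, intake, 0.0)


def calf_gain(calf_bw, milk, creep, msbw, diet: DietSpec | None = None,
              params: LactationParams | None = None):
    """Daily body-weight gain (kg/d) of a nursing calf.

    Net energy from milk and creep feed above maintenance is converted to
    gain at an energy content of gain scaled by the calf's mature size
    (larger-framed calves deposit leaner, cheaper gain).  Sub-maintenance
    supply produces weight loss.
    """
    p = params or LactationParams()
    bw = np.asarray(calf_bw, dtype=float)
    ne = (p.calf_k_milk * np.asarray(milk, dtype=float)
          + p.calf_k_creep * np.asarray(creep, dtype=float)
          - p.calf_k_maint * bw**0.75)
    e_gain = (p.calf_gain_energy
              * (np.asarray(msbw, dtype=float) / p.msbw_ref) ** (-p.calf_size_exponent)
              * (np.maximum(bw, 20.0) / p.calf_bw_ref) ** p.calf_bw_exponent)
    return ne / e_gain
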