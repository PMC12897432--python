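import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cowcalf.config import DietSpec, EnergyParams, IntakePolicy
from cowcalf.energetics import (bcs_from_ebf, cow_intake_nasem, daily_dmi,
                                ebf_from_bcs, energy_balance_step,
                                energy_of_gain, heifer_dmi_for_target,
                                ne_gestation, nem_required)


class TestDailyDmi:
    @pytest.mark.parametrize("lactating,expected", [(False, 10.551),
                                                    (True, 12.593)])
    def test_mature_cow_level_93(self, lactating, expected):
        policy = IntakePolicy(dmi_level=93.0)
        dmi = daily_dmi(550.0, 1.0, policy, lactating=lactating,
                        on_silage=False)
        assert dmi == pytest.approx(expected, abs=0.02)

    def test_silage_window_overrides_level(self):
        policy = IntakePolicy(dmi_level=111.0)
        assert daily_dmi(550.0, 1.0, policy, True, on_silage=True) == 7.0

    def test_age_scaling_reduces_intake(self):
        policy = IntakePolicy(dmi_level=93.0)
        three = daily_dmi(550.0, 0.96, policy, False, False)
        mature = daily_dmi(550.0, 1.0, policy, False, False)
        assert three == pytest.approx(mature * 0.96**0.75)


class TestMaintenance:
    def test_factor_on_metabolic_weight(self):
        assert nem_required(550.0, 10.0) == pytest.approx(0.077 * 550**0.75,
                                                          rel=1e-9)

    def test_low_milk_genotype_discount(self):
        full = nem_required(550.0, 10.0)
        low = nem_required(550.0, 6.0)
        assert low == pytest.approx(full * 0.88, rel=1e-9)

    def test_computed_on_current_not_mature_weight(self):
        assert nem_required(500.0, 10.0) < nem_required(550.0, 10.0)


class TestGestation:
    def setup_method(self):
        self.diet = DietSpec()

    def test_zero_at_conception(self):
        assert ne_gestation(0, 35.0, self.diet) == 0.0

    def test_monotone_through_gestation(self):
        early = ne_gestation(150, 35.0, self.diet)
        late = ne_gestation(250, 35.0, self.diet)
        assert late > early > 0

    def test_scales_with_birth_weight(self):
        single = ne_gestation(250, 35.0, self.diet)
        double = ne_gestation(250, 70.0, self.diet)
        assert double == pytest.approx(2 * single, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ne_gestation(300, 35.0, self.diet)


class TestEnergyBalance:
    def test_zero_balance_is_stationary_to_machine_precision(self):
        p = EnergyParams()
        sbw, fat = 550.0, 0.15 * 0.891 * 550.0
        for _ in range(2000):
            sbw, fat, _ = energy_balance_step(sbw, fat, 0.0, p)
        assert float(sbw) == 550.0
        assert float(fat) == pytest.approx(0.15 * 0.891 * 550.0, rel=1e-12)

    def test_lean_animal_gains_more_per_mcal(self):
        p = EnergyParams()
        lean_gain = energy_balance_step(500.0, 0.10 * 0.891 * 500, 5.0, p)[0] - 500.0
        fat_gain = energy_balance_step(500.0, 0.25 * 0.891 * 500, 5.0, p)[0] - 500.0
        assert lean_gain > fat_gain > 0

    def test_energy_of_gain_strictly_increasing(self):
        e = energy_of_gain(np.linspace(10, 40, 50))
        assert np.all(np.diff(e) > 0)

    def test_self_stabilization_to_analytic_fixed_point(self):
        """At constant supply, weight converges to the point where the
        maintenance requirement equals the supply."""
        p = EnergyParams()
        supply = 10.0  # Mcal NEm/d
        target = (supply / p.nem_factor) ** (4.0 / 3.0)
        sbw, fat = 550.0, 0.2 * 0.891 * 550
        for _ in range(20_000):
            req = p.nem_factor * float(sbw) ** 0.75
            sbw, fat, _ = energy_balance_step(sbw, fat, supply - req, p)
        assert float(sbw) == pytest.approx(target, abs=1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(ebf=st.floats(5.0, 40.0),
           bal=st.floats(0.01, 8.0), negate=st.booleans())
    def test_weight_moves_with_the_sign_of_the_balance(self, ebf, bal, negate):
        p = EnergyParams()
        if negate:
            bal = -bal
        fat = ebf / 100 * 0.891 * 500.0
        new_sbw, _, _ = energy_balance_step(500.0, fat, bal, p)
        assert np.sign(float(new_sbw) - 500.0) == np.sign(bal)


class TestBcsMap:
    def test_anchor_point(self):
        p = EnergyParams()
        assert bcs_from_ebf(5 * p.bcs_slope, p) == pytest.approx(5.0)

    def test_clamped_at_extremes(self):
        assert bcs_from_ebf(0.0) == 1.0
        assert bcs_from_ebf(80.0) == 9.0

    def test_strictly_increasing_before_clamp(self):
        b = bcs_from_ebf(np.linspace(5, 33, 40))
        assert np.all(np.diff(b) > 0)

    def test_inverse_roundtrip(self):
        assert bcs_from_ebf(ebf_from_bcs(6.5)) == pytest.approx(6.5)


class TestHeiferFeeding:
    def setup_method(self):
        self.diet = DietSpec()

    def test_at_target_gives_maintenance_only(self):
        dmi = heifer_dmi_for_target(330.0, 330.0, 100, self.diet, 550.0)
        expected = 0.077 * 330**0.75 / self.diet.nem_content
        assert dmi == pytest.approx(expected, rel=1e-9)

    def test_stage_targets_are_fractions_of_msbw(self):
        # 60% of MSBW at breeding, 80% at first calving for a 550-kg genotype
        assert 0.60 * 550 == 330.0
        assert 0.80 * 550 == 440.0

    def test_higher_required_gain_needs_more_feed(self):
        slow = heifer_dmi_for_target(300.0, 330.0, 200, self.diet, 550.0)
        fast = heifer_dmi_for_target(300.0, 330.0, 50, self.diet, 550.0)
        assert fast > slow


def test_cow_intake_prediction_plausible():
    diet = DietSpec()
    dmi = cow_intake_nasem(500.0, diet.nem_content)
    assert 8.0 < float(dmi) < 14.0
    assert cow_intake_nasem(500.0, diet.nem_content, milk_yield=8.0) > dmi
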