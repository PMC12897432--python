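import numpy as np
import pandas as pd
import pytest

from cowcalf import SimulationConfig, efficiency, fit_response, make_tables
from cowcalf.experiment import (interaction_assessment, scenario_grid,
                                summarize_scenarios)


class TestGrid:
    def test_full_design_size(self):
        cfg = SimulationConfig(rng_seed=1)
        scens = scenario_grid(cfg)
        assert len(scens) == 9 * 4 * cfg.n_replicates
        ids = {s.scenario_id for s in scens}
        assert len(ids) == 36

    def test_balance(self):
        cfg = SimulationConfig(rng_seed=1, n_replicates=2)
        scens = scenario_grid(cfg)
        df = pd.DataFrame([(s.genotype.label, s.dmi_level, s.replicate)
                           for s in scens],
                          columns=["geno", "level", "rep"])
        counts = df.groupby(["geno", "level"]).size()
        assert (counts == 2).all()


class TestEfficiency:
    def test_definition(self):
        assert efficiency(149.0, 3725.0) == pytest.approx(40.0, abs=0.01)

    def test_zero_weaned(self):
        assert efficiency(0.0, 3000.0) == 0.0

    def test_ratio_invariance(self):
        assert efficiency(149.0, 3725.0) == efficiency(298.0, 7450.0)

    def test_zero_dmi_rejected(self):
        with pytest.raises(ValueError):
            efficiency(100.0, 0.0)


class TestFitResponse:
    def test_exact_parabola_recovered(self):
        x = np.array([2300.0, 3000.0, 3700.0, 4400.0])
        y = 5.0 - 0.01 * x + 2e-6 * x**2
        fit = fit_response(x, y, degree=2)
        np.testing.assert_allclose(fit.coefficients, [5.0, -0.01, 2e-6],
                                   rtol=1e-8)

    def test_two_points_exact_line(self):
        fit = fit_response([1.0, 3.0], [2.0, 6.0], degree=1)
        np.testing.assert_allclose(fit.coefficients, [0.0, 2.0], atol=1e-10)

    def test_residuals_orthogonal_to_basis(self):
        rng = np.random.default_rng(0)
        x = np.linspace(2000, 5000, 12)
        y = 40 - 0.005 * x + rng.normal(0, 1.0, x.size)
        fit = fit_response(x, y, degree=2)
        resid = y - fit.fitted
        V = np.vander(x, 3, increasing=True)
        norms = np.linalg.norm(V, axis=0)
        np.testing.assert_allclose(V.T @ resid / norms, 0.0, atol=1e-8)

    def test_duplicate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_response([1.0, 1.0, 2.0], [1.0, 2.0, 3.0], degree=2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_response([1.0, 2.0], [1.0, 2.0], degree=2)


def _quad_fit(genotype, c0, c1, c2, x):
    y = c0 + c1 * x + c2 * x**2
    return fit_response(x, y, degree=2, genotype=genotype)


class TestInteraction:
    def test_identical_curves_no_interaction(self):
        x = np.linspace(2500, 5000, 4)
        fits = {f"g{i}": _quad_fit(f"g{i}", 60, -0.01, 1e-6, x)
                for i in range(9)}
        a = interaction_assessment(fits)
        assert a["linear_range"] == pytest.approx(0.0, abs=1e-10)
        assert not a["curves_cross"]
        assert not a["interaction_flag"]

    def test_crossing_curves_flagged(self):
        """Curves built to cross inside the observed range (the empirical
        genotype-reranking pattern) must raise the interaction flag."""
        x = np.linspace(2500, 5000, 4)
        fits = {f"g{i}": _quad_fit(f"g{i}", 60, -0.01, 1e-6, x)
                for i in range(8)}
        # steeper curve crossing the family mid-range
        fits["g8"] = _quad_fit("g8", 120, -0.028, 2e-6, x)
        a = interaction_assessment(fits)
        assert a["curves_cross"]
        assert a["interaction_flag"]

    def test_missing_genotype_rejected(self):
        x = np.linspace(2500, 5000, 4)
        fits = {f"g{i}": _quad_fit(f"g{i}", 60, -0.01, 1e-6, x)
                for i in range(5)}
        with pytest.raises(ValueError):
            interaction_assessment(fits)


class TestTables:
    def _fake_summary(self):
        rows = []
        for m in (450.0, 550.0, 650.0):
            for p in (8.0, 10.0, 12.0):
                for lvl in (58.0, 76.0, 93.0, 111.0):
                    rows.append(dict(msbw=m, peak_milk=p, dmi_level=lvl,
                                     pregnancy_pct=96 - (lvl == 58) * 10,
                                     calving_pct=88.0, weaning_pct=84.0,
                                     birth_weight=31.475 + 0.0045 * m,
                                     creep_dmi=0.45, weaning_age=187.0,
                                     preweaning_adg=0.5 + p / 40 + m / 4000,
                                     weaning_weight=100 + 10 * p + m / 20,
                                     ww_per_cow_exposed=95 + 10 * p + m / 20))
        df = pd.DataFrame(rows)
        df["genotype"] = df.msbw.astype(int).astype(str) + "-" + df.peak_milk.astype(str)
        return df

    def test_shapes(self):
        t = make_tables(self._fake_summary())
        assert len(t["by_genotype"]) == 9
        assert len(t["by_level"]) == 4
        assert len(t["progeny"]) == 9

    def test_marginal_means_commute(self):
        """Both marginal tables average the same 36 balanced cells, so the
        grand means agree for every shared metric."""
        t = make_tables(self._fake_summary())
        for col in ("pregnancy_pct", "calving_pct", "weaning_pct"):
            assert t["by_genotype"][col].mean() == pytest.approx(
                t["by_level"][col].mean())

    def test_progeny_gradient(self):
        t = make_tables(self._fake_summary())
        prog = t["progeny"].sort_values(["msbw", "peak_milk"])
        within = prog.groupby("msbw")["weaning_weight"].apply(
            lambda s: s.is_monotonic_increasing)
        assert within.all()


def test_summary_excludes_burn_in():
    per_year = pd.DataFrame({
        "msbw": 550.0, "peak_milk": 10.0, "dmi_level": 93.0,
        "year": np.arange(6),
        "pregnancy_pct": [0.0, 0.0, 0.0, 96.0, 96.0, 96.0],
    }).assign(**{c: 1.0 for c in
                 ["calving_pct", "weaning_pct", "cycling21_pct", "mean_ppi",
                  "bw_calving", "bcs_calving_median", "bcs_wean",
                  "birth_weight", "weaning_weight", "weaning_age",
                  "preweaning_adg", "creep_dmi", "ww_per_cow_exposed",
                  "annual_dmi_per_cow", "pydmi_per_cow",
                  "efficiency_g_per_kg"]})
    cfg = SimulationConfig(rng_seed=1, burn_in_years=3)
    out = summarize_scenarios(per_year, cfg)
    assert out.loc[0, "pregnancy_pct"] == pytest.approx(96.0)
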