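"""Population scaling, PI curves, diagnostics and density-dependence fits."""

import math

import numpy as np
import pytest

from phytoflux.ecology import (
    DensityDependenceFit, PICurve, acclimate_strain, compare_strains,
    fit_density_dependence, fit_pi_curve, gross_oxygen_production,
    nitrogen_diagnostics, population_weight, quantum_yield,
)
from phytoflux.physiology import AcclimationResult, composition_metrics, default_composition
from phytoflux.thermal import ThermalParams
from phytoflux.synthgen import default_transporter_specs

from conftest import make_env


def fake_result(mu, fluxes=None, strain="S", env=None, light="HL"):
    comp = default_composition(light)
    return AcclimationResult(
        strain_id=strain, environment=env or make_env(), mu=mu,
        fluxes=fluxes or {}, composition=comp,
        metrics=composition_metrics(comp), absorbed_photons={},
    )


class TestPopulationWeight:
    def _setup(self, mus, abundances):
        env = make_env()
        results = {}
        eco = {}
        for i, mu in enumerate(mus):
            sid = f"S{i}"
            eco[sid] = "HLII" if i == 0 else "LLI"
            results[(sid, env.key)] = fake_result(mu, env=env, strain=sid)
        ab = {(e, env.key): a for e, a in abundances.items()}
        return results, ab, eco, env.key

    def test_weighted_growth_rate_arithmetic(self):
        # abundances (1e5, 5e4) on growth rates (0.5, 0.3) d⁻¹ → 0.4333 d⁻¹
        results, ab, eco, key = self._setup(
            [0.5 / 24.0, 0.3 / 24.0], {"HLII": 1e5, "LLI": 5e4})
        field = population_weight(results, ab, eco)
        assert field.weighted["growth_rate_d"][key] == pytest.approx(
            (1e5 * 0.5 + 5e4 * 0.3) / 1.5e5, rel=1e-12)

    def test_single_ecotype_passthrough(self):
        results, ab, eco, key = self._setup([0.02, 0.01], {"HLII": 2e4, "LLI": 0.0})
        field = population_weight(results, ab, eco)
        assert field.weighted["growth_rate_d"][key] == pytest.approx(0.02 * 24)

    def test_zero_total_abundance_is_missing(self):
        results, ab, eco, key = self._setup([0.02, 0.01], {"HLII": 0.0, "LLI": 0.0})
        field = population_weight(results, ab, eco)
        assert field.weighted["growth_rate_d"][key] is None
        assert field.weighted["c_to_n"][key] is None

    def test_tie_breaks_to_lexicographic_strain(self):
        env = make_env()
        results = {(s, env.key): fake_result(0.02, env=env, strain=s)
                   for s in ("SB", "SA")}
        eco = {"SA": "HLII", "SB": "HLII"}
        field = population_weight(results, {("HLII", env.key): 1e4}, eco)
        assert field.representative_strain[("HLII", env.key)] == "SA"

    def test_weighted_values_are_convex_combinations(self, transect_run, toy_pangenome):
        from phytoflux.synthgen import make_abundance_field

        results, _ = transect_run
        mu_field = {k: r.mu for k, r in results.items()}
        eco = {s.strain_id: s.ecotype for s in toy_pangenome.strains}
        sample_keys = {k[1] for k in results}
        ab = {}
        for e in set(eco.values()):
            for sk in sample_keys:
                ab[(e, sk)] = 1e4
        field = population_weight(results, ab, eco)
        for sk in sample_keys:
            mus = [r.mu * 24 for (s, k), r in results.items() if k == sk]
            w = field.weighted["growth_rate_d"][sk]
            if w is not None:
                assert min(mus) - 1e-9 <= w <= max(mus) + 1e-9


class TestPICurve:
    def test_exact_webb_curve_recovered(self):
        E = np.linspace(5, 400, 12)
        P = 5.0 * (1 - np.exp(-0.1 * E / 5.0))
        fit = fit_pi_curve(P, E)
        assert fit.p_max_b == pytest.approx(5.0, rel=1e-6)
        assert fit.alpha == pytest.approx(0.1, rel=1e-6)
        assert fit.e_k == pytest.approx(50.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.saturating

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(11)
        E = np.linspace(5, 400, 12)
        P = 5.0 * (1 - np.exp(-0.1 * E / 5.0)) * (1 + rng.normal(0, 0.05, 12))
        fit = fit_pi_curve(P, E)
        assert fit.p_max_b == pytest.approx(5.0, rel=0.10)
        assert fit.alpha == pytest.approx(0.1, rel=0.10)

    def test_ek_identity(self):
        fit = PICurve(alpha=0.08, p_max_b=4.0, r_squared=1.0)
        assert fit.e_k * fit.alpha == pytest.approx(fit.p_max_b, rel=1e-9)

    def test_non_saturating_data_warn(self):
        E = np.linspace(1, 10, 8)  # far below E_k = 50
        P = 0.1 * E
        with pytest.warns(UserWarning, match="saturation"):
            fit = fit_pi_curve(P, E)
        assert not fit.saturating
        assert fit.alpha == pytest.approx(0.1, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_pi_curve([1, 2, 3], [1, 2, 3])


class TestDiagnostics:
    def test_quantum_yield_simple_ratio(self):
        res = fake_result(0.02, fluxes={"CBB": 1.0})
        res.absorbed_photons = {"dv_chl_a": 6.0, "dv_chl_b": 2.0,
                                "alpha_carotene": 0.0, "zeaxanthin": 5.0}
        assert quantum_yield(res) == pytest.approx(0.125)  # zeax not counted

    def test_quantum_yield_undefined_without_absorption(self):
        res = fake_result(0.0, fluxes={"CBB": 0.0})
        res.absorbed_photons = {p.name: 0.0 for p in res.composition.pigments}
        assert quantum_yield(res) is None

    @pytest.mark.parametrize("v, expected", [
        ({"TR_NO3": 0.3, "TR_NO2": 0.0, "TR_NH4": 0.7}, 0.3),
        ({"TR_NO3": 0.0, "TR_NO2": 0.0, "TR_NH4": 1.2}, 0.0),
    ])
    def test_f_ratio(self, v, expected):
        f, per_source = nitrogen_diagnostics(fake_result(0.02, fluxes=v))
        assert f == pytest.approx(expected)
        assert per_source == v

    def test_f_ratio_undefined_without_uptake(self):
        f, _ = nitrogen_diagnostics(fake_result(0.0, fluxes={}))
        assert f is None

    def test_gop_zero_in_dark_and_exceeds_net_o2(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        dark = acclimate_strain(toy_hl, specs, make_env(par=0.0),
                                composition=default_composition("HL"))
        assert dark.mu == 0.0
        assert gross_oxygen_production(dark) == 0.0
        lit = acclimate_strain(toy_hl, specs, make_env(par=400.0),
                               composition=default_composition("HL"))
        gop = gross_oxygen_production(lit)
        net_o2 = -lit.fluxes.get("EX_o2", 0.0)  # positive = net export
        assert gop >= net_o2 - 1e-9

    def test_gop_within_photosynthetic_quotient_band(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        res = acclimate_strain(toy_hl, specs, make_env(par=400.0),
                               composition=default_composition("HL"))
        ratio = gross_oxygen_production(res) / res.fluxes["CBB"]
        assert 1.0 - 1e-9 <= ratio <= 1.5


class TestDensityDependence:
    def test_exact_power_law_recovered(self):
        m, x = 1e-6, 1.6
        mu = np.linspace(0.1, 0.9, 30)
        B = (mu / m) ** (1.0 / (x - 1.0))
        fit = fit_density_dependence(B, mu)
        assert fit.x == pytest.approx(x, abs=1e-9)
        assert fit.m == pytest.approx(m, rel=1e-6)
        assert fit.r_squared_power == pytest.approx(1.0, abs=1e-12)
        assert fit.preferred == "power"

    def test_noisy_exponent_within_tolerance(self):
        rng = np.random.default_rng(5)
        m, x = 6e-4, 1.6
        mu = rng.uniform(0.05, 1.0, 600)
        B = (mu / m) ** (1.0 / (x - 1.0)) * np.exp(rng.normal(0, 0.2, 600))
        fit = fit_density_dependence(B, mu)
        assert fit.x == pytest.approx(x, abs=0.1)

    def test_constant_growth_prefers_linear_mortality(self):
        rng = np.random.default_rng(0)
        B = rng.uniform(1e4, 1e6, 50)
        mu = np.full(50, 0.4)
        fit = fit_density_dependence(B, mu)
        assert fit.r_squared_power == pytest.approx(0.0, abs=1e-9)
        assert fit.preferred == "linear"

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_density_dependence([1e5, 2e5], [0.3, 0.4])


class TestCompareStrains:
    def test_identical_strains_give_zero_field(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        envs = [make_env(par=p, depth=d)
                for p, d in ((600, 10.0), (60, 80.0))]
        res = {e.key: acclimate_strain(toy_hl, specs, e,
                                       composition=default_composition("HL"))
               for e in envs}
        df = compare_strains(res, dict(res))
        assert np.allclose(df["relative_growth_pct"].to_numpy(), 0.0)

    def test_extra_n_source_never_hurts(self, toy_hl, toy_ll):
        """A strain with nitrate/nitrite access grows at least as fast, and
        strictly faster where ammonium is scarce but nitrate plentiful.

        Light-saturated fixtures: under light saturation the reductant cost
        of nitrate assimilation is covered by excess photons, so the extra
        N source is unambiguously beneficial."""
        specs_hl = default_transporter_specs(toy_hl)
        specs_ll = default_transporter_specs(toy_ll)
        comp = default_composition("HL")
        scarce_nh4 = make_env(par=1500.0, nutrients={
            "nh4_e": 1e-7, "no3_e": 2e-3, "no2_e": 1e-4})
        rich_nh4 = make_env(par=1500.0, nutrients={"nh4_e": 1e-3})
        for env in (scarce_nh4, rich_nh4):
            a = acclimate_strain(toy_hl, specs_hl, env, composition=comp)
            b = acclimate_strain(toy_ll, specs_ll, env, composition=comp)
            # equality up to the transporter-allocation grid resolution
            assert b.mu >= a.mu * (1.0 - 1e-3)
        a = acclimate_strain(toy_hl, specs_hl, scarce_nh4, composition=comp)
        b = acclimate_strain(toy_ll, specs_ll, scarce_nh4, composition=comp)
        assert b.mu > a.mu * 1.05

    def test_mismatched_grids_rejected(self, toy_hl):
        with pytest.raises(ValueError):
            compare_strains({("A", 1): None}, {("B", 2): None})


class TestAcclimatePipeline:
    def test_dark_sample_is_energy_limited(self, toy_ll):
        specs = default_transporter_specs(toy_ll)
        res = acclimate_strain(toy_ll, specs, make_env(par=0.0),
                               composition=default_composition("LL"))
        assert res.mu == 0.0
        assert res.limiting_resource == "energy"

    def test_replete_warm_surface_growth_limited_everywhere(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        env = make_env(par=600.0, temperature=298.0,
                       nutrients={"nh4_e": 1e-3, "po4_e": 1e-3})
        res = acclimate_strain(toy_hl, specs, env,
                               ThermalParams(65.0, 298.0, 220.0),
                               composition=default_composition("HL"))
        assert res.mu > 0
        assert all(d.regime == "growth_limited" for d in res.diagnoses.values())

    def test_acclimation_never_loses_to_frozen_phenotype(self, toy_hl):
        """The acclimated phenotype grows at least as fast as the replete
        batch phenotype in every fixture environment, and strictly faster
        in at least one (the paper-style acclimation gain, sign only)."""
        specs = default_transporter_specs(toy_hl)
        tp = ThermalParams(65.0, 298.0, 220.0)
        comp = default_composition("HL")
        gains = []
        for env in (make_env(par=1500.0), make_env(par=60.0),
                    make_env(par=200.0, nutrients={"nh4_e": 2e-7}),
                    make_env(par=30.0, temperature=290.0)):
            full = acclimate_strain(toy_hl, specs, env, tp, composition=comp)
            frozen = acclimate_strain(toy_hl, specs, env, tp, composition=comp,
                                      mode="frozen")
            assert full.mu >= frozen.mu - 1e-9
            gains.append(full.mu - frozen.mu)
        assert max(gains) > 1e-6
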