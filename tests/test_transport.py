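"""Uptake kinetics: limits, critical concentration, regimes, OptTrans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytoflux.transport import (
    AVOGADRO, CellGeometry, TransporterSpec, TransporterState,
    classify_limitation, critical_concentration, k_eff, optimize_transporters,
    per_cell_to_specific, specific_to_per_cell, uptake_rate,
    default_radius_grid,
)
from phytoflux.synthgen import toy_strain_model, default_transporter_specs

from conftest import make_env


def spec(**kw):
    base = dict(substrate_id="nh4_e", k_cat=50.0, footprint=25.0,
                diffusivity=1e-9, synthesis_cost=1500.0)
    base.update(kw)
    return TransporterSpec(**base)


def random_state(rng):
    s = spec(k_cat=float(rng.uniform(1, 200)),
             diffusivity=float(rng.uniform(0.3e-9, 3e-9)))
    geom = CellGeometry(float(rng.uniform(0.25, 1.0)))
    n = float(rng.uniform(10, 5e4))
    return TransporterState(s, n), geom


class TestUptakeRate:
    def test_zero_concentration_or_no_transporters(self):
        st = TransporterState(spec(), 100.0)
        geom = CellGeometry(0.3)
        assert uptake_rate(st, geom, 0.0) == 0.0
        assert uptake_rate(TransporterState(spec(), 0.0), geom, 1e-3) == 0.0

    def test_half_saturation_identity(self):
        st = TransporterState(spec(), 500.0)
        geom = CellGeometry(0.3)
        keff = k_eff(st, geom)
        vmax = st.n * st.spec.k_cat / AVOGADRO
        assert uptake_rate(st, geom, keff) == pytest.approx(vmax / 2, rel=1e-12)

    def test_closed_form_at_ten_keff(self):
        # V_max fixed at 1e-18 mol/cell/s via n = V_max·N_A/k_cat
        s = spec(diffusivity=1e-9)
        n = 1e-18 * AVOGADRO / s.k_cat
        st = TransporterState(s, n)
        geom = CellGeometry(0.3)
        keff = 1e-18 / (4 * math.pi * 1e-9 * 0.3e-6)
        assert k_eff(st, geom) == pytest.approx(keff, rel=1e-12)
        assert uptake_rate(st, geom, 10 * keff) == pytest.approx(
            (10 / 11) * 1e-18, rel=1e-12)

    def test_asymptotic_limits_over_random_draws(self):
        """Diffusive encounter limit at S≪K_eff, porter limit at S≫K_eff."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            st, geom = random_state(rng)
            keff = k_eff(st, geom)
            vmax = st.n * st.spec.k_cat / AVOGADRO
            r_m = geom.radius * 1e-6
            s_lo = 0.01 * keff
            diff_limit = 4 * math.pi * st.spec.diffusivity * r_m * s_lo
            assert uptake_rate(st, geom, s_lo) == pytest.approx(diff_limit, rel=0.01)
            assert uptake_rate(st, geom, 100 * keff) == pytest.approx(vmax, rel=0.01)

    def test_monotone_concave_and_below_both_limits(self):
        rng = np.random.default_rng(5)
        st, geom = random_state(rng)
        keff = k_eff(st, geom)
        S = np.linspace(1e-3 * keff, 1e2 * keff, 400)  # uniform grid: second
        v = np.array([uptake_rate(st, geom, s) for s in S])  # differences test
        assert np.all(np.diff(v) > 0)                        # concavity directly
        vmax = st.n * st.spec.k_cat / AVOGADRO
        assert np.all(np.diff(np.diff(v)) < 1e-12 * vmax)
        vmax = st.n * st.spec.k_cat / AVOGADRO
        r_m = geom.radius * 1e-6
        assert np.all(v <= 4 * math.pi * st.spec.diffusivity * r_m * S + 1e-30)
        assert np.all(v <= vmax + 1e-30)


class TestUptakeProperties:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        k_cat=st.floats(0.5, 500.0),
        diffusivity=st.floats(1e-10, 5e-9),
        radius=st.floats(0.25, 1.0),
        n=st.floats(1.0, 1e6),
        s1=st.floats(1e-9, 1e-1),
        factor=st.floats(1.0, 1e3),
    )
    def test_uptake_bounded_and_monotone(self, k_cat, diffusivity, radius, n,
                                         s1, factor):
        """v is nonnegative, below both physical limits, and nondecreasing
        in the ambient concentration — for any physical parameter choice."""
        st_ = TransporterState(
            spec(k_cat=k_cat, diffusivity=diffusivity), n)
        geom = CellGeometry(radius)
        s2 = s1 * factor
        v1 = uptake_rate(st_, geom, s1)
        v2 = uptake_rate(st_, geom, s2)
        vmax = n * k_cat / AVOGADRO
        diff1 = 4 * math.pi * diffusivity * radius * 1e-6 * s1
        assert 0.0 <= v1 <= min(vmax, diff1) * (1 + 1e-12)
        assert v2 >= v1 * (1 - 1e-12)


class TestCriticalConcentration:
    def test_half_vmax_demand_gives_keff(self):
        st = TransporterState(spec(), 800.0)
        geom = CellGeometry(0.4)
        vmax = st.n * st.spec.k_cat / AVOGADRO
        assert critical_concentration(st, geom, vmax / 2) == pytest.approx(
            k_eff(st, geom), rel=1e-12)

    def test_unreachable_demand_is_infinite(self):
        st = TransporterState(spec(), 800.0)
        geom = CellGeometry(0.4)
        vmax = st.n * st.spec.k_cat / AVOGADRO
        assert critical_concentration(st, geom, vmax) == math.inf
        assert critical_concentration(st, geom, 2 * vmax) == math.inf

    def test_nonpositive_demand_rejected(self):
        st = TransporterState(spec(), 800.0)
        with pytest.raises(ValueError):
            critical_concentration(st, CellGeometry(0.4), 0.0)

    def test_self_consistency_uptake_at_s_star_equals_demand(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            st, geom = random_state(rng)
            vmax = st.n * st.spec.k_cat / AVOGADRO
            demand = vmax * float(rng.uniform(0.05, 0.95))
            s_star = critical_concentration(st, geom, demand)
            assert uptake_rate(st, geom, s_star) == pytest.approx(demand, rel=1e-12)


class TestClassifyLimitation:
    def setup_method(self):
        self.st = TransporterState(spec(), 1000.0)
        self.geom = CellGeometry(0.4)
        self.vmax = self.st.n * self.st.spec.k_cat / AVOGADRO
        self.keff = k_eff(self.st, self.geom)

    def test_above_s_star_is_growth_limited(self):
        demand = self.vmax / 2
        s_star = critical_concentration(self.st, self.geom, demand)
        d = classify_limitation(self.st, self.geom, 2 * s_star, demand, 0.5)
        assert d.regime == "growth_limited"
        assert d.uptake == pytest.approx(demand, rel=1e-9)

    def test_dilute_with_area_slack_is_diffusion_limited(self):
        demand = self.vmax * 0.9
        d = classify_limitation(self.st, self.geom, self.keff / 100, demand, 0.5)
        assert d.regime == "diffusion_limited"

    def test_full_membrane_is_surface_area_limited(self):
        demand = self.vmax * 2  # unmet demand, S∞ above K_eff
        d = classify_limitation(self.st, self.geom, 10 * self.keff, demand, 1.0)
        assert d.regime == "surface_area_limited"

    def test_rich_but_unmet_demand_with_slack_is_porter_limited(self):
        demand = self.vmax * 2
        d = classify_limitation(self.st, self.geom, 10 * self.keff, demand, 0.2)
        assert d.regime == "porter_limited"

    def test_regime_flips_exactly_at_s_star(self):
        demand = self.vmax / 3
        s_star = critical_concentration(self.st, self.geom, demand)
        up = classify_limitation(self.st, self.geom, np.nextafter(s_star, np.inf),
                                 demand, 0.0)
        down = classify_limitation(self.st, self.geom, s_star, demand, 0.0)
        assert up.regime == "growth_limited"
        assert down.regime != "growth_limited"


class TestUnitConversions:
    def test_round_trip(self):
        dm = 3.3e-14
        v = 2.7e-20
        assert specific_to_per_cell(per_cell_to_specific(v, dm), dm) == pytest.approx(
            v, rel=1e-15)

    def test_known_value(self):
        # 1e-3 mol/cell/s in a 1e-13 g cell = 3.6e7 mmol/gDW/h... scaled case
        assert per_cell_to_specific(1e-21, 1e-13) == pytest.approx(3.6e-2, rel=1e-12)


class TestOptTrans:
    def test_single_substrate_saturating_uses_smallest_sufficient_n(self, toy_hl):
        specs = [s for s in default_transporter_specs(toy_hl)
                 if s.substrate_id == "nh4_e"]
        env = make_env(par=600.0, nutrients={"nh4_e": 1e-2, "po4_e": 1e-2})
        res = optimize_transporters(toy_hl, specs, env)
        st = res.states["nh4_e"]
        # dense scan at the chosen radius: smallest n meeting realized demand
        geom = res.geometry
        demand_cell = specific_to_per_cell(
            res.fluxes.get("TR_NH4", 0.0), geom.dry_mass)
        assert demand_cell > 0
        n_needed = demand_cell * AVOGADRO / specs[0].k_cat  # porter regime
        assert st.n_star == pytest.approx(n_needed, rel=0.10)

    def test_halving_concentration_in_diffusion_regime_halves_uptake(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        geom = CellGeometry(0.5)
        st = TransporterState(specs[0], 5e4)  # huge n: diffusion regime
        s0 = k_eff(st, geom) / 50
        v1 = uptake_rate(st, geom, s0)
        v2 = uptake_rate(st, geom, s0 / 2)
        assert v2 == pytest.approx(v1 / 2, rel=0.02)

    def test_two_substrates_tight_budget_saturate_the_membrane(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        # starve both nutrients: huge transporter demand, small area budget
        env = make_env(par=600.0, nutrients={"nh4_e": 2e-7, "po4_e": 5e-8})
        res = optimize_transporters(toy_hl, specs, env, f_area=0.002)
        assert res.area_budget_used == pytest.approx(1.0, abs=1e-6)

    def test_optimal_radius_grows_with_resource_richness(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        radii = []
        for scale in (0.2, 0.5, 1.0, 4.0, 20.0):
            env = make_env(par=600.0, nutrients={
                "nh4_e": 5e-6 * scale, "po4_e": 2e-5 * scale})
            res = optimize_transporters(toy_hl, specs, env)
            radii.append(res.geometry.radius)
        assert all(b >= a - 1e-12 for a, b in zip(radii, radii[1:]))
        assert radii[-1] > radii[0]

    def test_mu_monotone_in_area_fraction(self, toy_hl):
        specs = default_transporter_specs(toy_hl)
        env = make_env(par=600.0, nutrients={"nh4_e": 2e-7, "po4_e": 5e-8})
        mus = [optimize_transporters(toy_hl, specs, env, f_area=f).mu
               for f in (0.001, 0.004, 0.04)]
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))
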