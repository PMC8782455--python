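"""Shared fixtures: tiny hand-built networks, the synthetic pangenome and
environmental section, and the (expensive, session-scoped) transect run."""

from __future__ import annotations

import time

import numpy as np
import pytest

from phytoflux.core import Metabolite, Reaction, MetabolicNetwork
from phytoflux.environment import WAVELENGTHS, EnvironmentSample
from phytoflux.synthgen import (
    EnvironmentSpec, PangenomeSpec, make_environment_grid, make_toy_pangenome,
    toy_strain_model, default_transporter_specs,
)


def make_chain(uptake_ub: float = 10.0, biomass_coeff: float = 1.0) -> MetabolicNetwork:
    """Minimal chain: EX_A (uptake ≤ uptake_ub) → transport → biomass."""
    mets = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A_c", compartment="c"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1}, -uptake_ub, 0, is_exchange=True),
        Reaction("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
        Reaction("BIO", {"A_c": -biomass_coeff}, 0, 1000, is_biomass=True),
    ]
    return MetabolicNetwork(mets, rxns, "BIO")


def make_parallel_paths() -> MetabolicNetwork:
    """Two equivalent routes A_c → B_c (one direct, one via C_c) feeding biomass."""
    mets = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A_c"), Metabolite("B_c"), Metabolite("C_c"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1}, -10, 0, is_exchange=True),
        Reaction("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
        Reaction("P_direct", {"A_c": -1, "B_c": 1}, 0, 1000),
        Reaction("P_via1", {"A_c": -1, "C_c": 1}, 0, 1000),
        Reaction("P_via2", {"C_c": -1, "B_c": 1}, 0, 1000),
        Reaction("BIO", {"B_c": -1}, 0, 1000, is_biomass=True),
    ]
    return MetabolicNetwork(mets, rxns, "BIO")


def random_feasible_network(rng: np.random.Generator) -> MetabolicNetwork:
    """A random bounded toy: a guaranteed productive backbone plus random
    side reactions with finite bounds (so the LP is always bounded)."""
    n_internal = int(rng.integers(5, 9))
    mets = [Metabolite("A_e", compartment="e")] + [
        Metabolite(f"M{i}_c") for i in range(n_internal)
    ]
    uptake = float(rng.uniform(2.0, 20.0))
    rxns = [
        Reaction("EX_A", {"A_e": -1}, -uptake, 0, is_exchange=True),
        Reaction("T_A", {"A_e": -1, "M0_c": 1}, 0, float(rng.uniform(5, 50))),
    ]
    for i in range(n_internal - 1):
        coeff = float(rng.choice([1.0, 1.0, 2.0]))
        rxns.append(Reaction(
            f"C{i}", {f"M{i}_c": -coeff, f"M{i+1}_c": 1.0},
            0, float(rng.uniform(5, 60)),
        ))
    # random side reactions (may be useless or create shortcuts)
    for k in range(int(rng.integers(2, 5))):
        i, j = rng.choice(n_internal, size=2, replace=False)
        lb = 0.0 if rng.random() < 0.7 else -float(rng.uniform(0, 10))
        rxns.append(Reaction(
            f"S{k}", {f"M{i}_c": -float(rng.choice([1.0, 2.0])),
                      f"M{j}_c": float(rng.choice([1.0, 2.0]))},
            lb, float(rng.uniform(0, 30)),
        ))
    rxns.append(Reaction("BIO", {f"M{n_internal-1}_c": -1.0}, 0, 1000.0,
                         is_biomass=True))
    return MetabolicNetwork(mets, rxns, "BIO")


def flat_spectrum(par: float) -> np.ndarray:
    """Spectrally flat irradiance with the given PAR integral."""
    return np.full(WAVELENGTHS.shape, par / (len(WAVELENGTHS) * 5.0))


def make_env(par: float = 500.0, temperature: float = 295.0,
             nutrients: dict = None, depth: float = 10.0,
             station: str = "TEST") -> EnvironmentSample:
    nuts = {"nh4_e": 5e-5, "no2_e": 5e-6, "no3_e": 5e-5, "po4_e": 1e-4}
    if nutrients:
        nuts.update(nutrients)
    return EnvironmentSample(station, 0.0, depth, temperature, nuts,
                             flat_spectrum(par))


@pytest.fixture(scope="session")
def toy_hl():
    return toy_strain_model("HL")


@pytest.fixture(scope="session")
def toy_ll():
    return toy_strain_model("LL")


@pytest.fixture(scope="session")
def toy_pangenome():
    return make_toy_pangenome(PangenomeSpec())


@pytest.fixture(scope="session")
def samples_small():
    samples, env_df, spectra_df = make_environment_grid(EnvironmentSpec.small())
    return samples


@pytest.fixture(scope="session")
def transect_run(toy_pangenome, samples_small):
    """Full small-preset transect (the smoke run): returns (results, seconds)."""
    from phytoflux.ecology import simulate_transect

    t0 = time.monotonic()
    results = simulate_transect(toy_pangenome.strains, samples_small)
    return results, time.monotonic() - t0
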