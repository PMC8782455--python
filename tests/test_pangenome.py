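"""Pangenome assembly, rarefaction/Heaps, CS extraction and gap filling."""

import itertools

import numpy as np
import pytest

from phytoflux.core import Metabolite, Reaction, MetabolicNetwork, build_flux_problem
from phytoflux.pangenome import (
    OrthologMatrix, PanGEM, assemble_pangem, essential_core, extract_strain_gem,
    fit_heaps, gap_fill, rarefaction_curve,
)
from phytoflux import fba


MU_MIN = 1e-3


# ---------------------------------------------------------------------------
# abstract linear pangenome toys (also used by the acceptance oracle)
# ---------------------------------------------------------------------------

def linear_toy(n_parallel=(1, 2), chain_len=2, extra_blocked=0):
    """A_e → X1 → … → Xn → biomass with parallel alternatives per hop.

    ``n_parallel[i]`` is the number of interchangeable routes for hop i
    (each route of length 1); longer chains and planted dead reactions grow
    the search space without changing the true minimum support.
    """
    mets = [Metabolite("A_e", compartment="e")]
    mets += [Metabolite(f"X{i}_c") for i in range(chain_len + 1)]
    rxns = [
        Reaction("EX_A", {"A_e": -1}, -10, 0, is_exchange=True),
        Reaction("T_A", {"A_e": -1, "X0_c": 1}, 0, 1000),
    ]
    for i, k in enumerate(n_parallel[:chain_len]):
        for j in range(k):
            rxns.append(Reaction(
                f"H{i}_{j}", {f"X{i}_c": -1, f"X{i+1}_c": 1}, 0, 1000))
    for b in range(extra_blocked):
        mets.append(Metabolite(f"D{b}_c"))
        rxns.append(Reaction(f"DEAD{b}", {f"X0_c": -1, f"D{b}_c": 1}, 0, 1000))
    rxns.append(Reaction("BIO", {f"X{chain_len}_c": -1}, 0, 1000, is_biomass=True))
    return MetabolicNetwork(mets, rxns, "BIO")


def scaffold_of(network):
    """Exchanges + biomass with the full metabolite universe retained."""
    return MetabolicNetwork(
        network.metabolites,
        [r for r in network.reactions if r.is_exchange or r.is_biomass],
        network.biomass_reaction_id,
    )


def as_pangem(network, strains=("SA", "SB", "SC")):
    """Wrap a network as a trivial pangenome: one cluster per internal
    reaction, all strains carrying all clusters."""
    internal = [r for r in network.reactions if not r.is_exchange and not r.is_biomass]
    clusters = [f"cl_{r.id}" for r in internal]
    catalog = {f"cl_{r.id}": [Reaction(
        r.id, r.stoichiometry, r.lower_bound, r.upper_bound,
        ortholog_ids=frozenset({f"cl_{r.id}"}))] for r in internal}
    scaffold = scaffold_of(network)
    presence = np.ones((len(strains), len(clusters)), dtype=int)
    matrix = OrthologMatrix(list(strains), clusters, presence,
                            {s: "HLII" for s in strains})
    return assemble_pangem(matrix, catalog, scaffold)


def exhaustive_minimum_support(network, mu_min=MU_MIN):
    """Smallest number of internal reactions that still grow at mu_min,
    by brute-force enumeration in order of cardinality."""
    internal = sorted(r.id for r in network.reactions
                      if not r.is_exchange and not r.is_biomass)
    keep_always = [r for r in network.reactions if r.is_exchange or r.is_biomass]
    for k in range(len(internal) + 1):
        for subset in itertools.combinations(internal, k):
            sub = network.with_reactions(
                keep_always + [network.reaction(rid) for rid in subset])
            sol = fba.solve_fba(build_flux_problem(sub), "BIO")
            if sol.status == "optimal" and sol.objective_value >= mu_min:
                return k, set(subset)
    raise AssertionError("no feasible subset")


# ---------------------------------------------------------------------------


class TestOrthologMatrix:
    def test_rejects_non_binary_and_empty_strains(self):
        with pytest.raises(ValueError):
            OrthologMatrix(["a"], ["c1"], np.array([[2]]))
        with pytest.raises(ValueError):
            OrthologMatrix(["a", "b"], ["c1"], np.array([[1], [0]]))

    def test_tsv_round_trip(self, toy_pangenome, tmp_path):
        p = tmp_path / "matrix.tsv"
        m = toy_pangenome.matrix
        m.to_tsv(p)
        again = OrthologMatrix.from_tsv(p)
        assert again.strains == m.strains
        assert again.clusters == m.clusters
        assert (again.presence == m.presence).all()
        assert again.ecotype == m.ecotype


class TestAssembly:
    def test_core_accessory_partition(self, toy_pangenome):
        pg = toy_pangenome.pangem
        non_exchange = {r.id for r in pg.network.reactions if not r.is_exchange}
        union = (pg.core_reaction_ids | pg.accessory_reaction_ids
                 | pg.gapfilled_reaction_ids)
        assert union == non_exchange
        assert not pg.core_reaction_ids & pg.accessory_reaction_ids
        # planted niche traits are accessory
        assert {"TR_NO3", "NR", "TR_NO2", "NIR", "GDH"} <= pg.accessory_reaction_ids

    def test_shared_vs_private_clusters(self):
        net = linear_toy(n_parallel=(1, 1), chain_len=2)
        internal = [r for r in net.reactions if not r.is_exchange and not r.is_biomass]
        catalog = {}
        for r in internal:
            cl = f"cl_{r.id}"
            catalog[cl] = [Reaction(r.id, r.stoichiometry, r.lower_bound,
                                    r.upper_bound, ortholog_ids=frozenset({cl}))]
        clusters = sorted(catalog)
        presence = np.ones((3, len(clusters)), dtype=int)
        # cluster of H1_0 is private to strain 3
        j = clusters.index("cl_H1_0")
        presence[:2, j] = 0
        # keep growth possible for all strains: add an alternative route
        alt = Reaction("H1_alt", {"X1_c": -1, "X2_c": 1}, 0, 1000,
                       ortholog_ids=frozenset({"cl_alt"}))
        catalog["cl_alt"] = [alt]
        clusters = sorted(catalog)
        presence = np.ones((3, len(clusters)), dtype=int)
        presence[:2, clusters.index("cl_H1_0")] = 0
        matrix = OrthologMatrix(["s1", "s2", "s3"], clusters, presence)
        scaffold = scaffold_of(net)
        pg = assemble_pangem(matrix, catalog, scaffold)
        assert "H1_0" in pg.accessory_reaction_ids
        assert {"T_A", "H0_0", "H1_alt"} <= pg.core_reaction_ids

    def test_planted_gap_is_filled_and_flagged(self):
        net = linear_toy(n_parallel=(1, 1), chain_len=2)
        internal = [r for r in net.reactions if not r.is_exchange and not r.is_biomass]
        catalog = {}
        gap_candidates = []
        for r in internal:
            tagged = Reaction(r.id, r.stoichiometry, r.lower_bound, r.upper_bound,
                              ortholog_ids=frozenset({f"cl_{r.id}"}))
            if r.id == "H1_0":  # biomass needs it, but no cluster encodes it
                gap_candidates.append(r)
            else:
                catalog[f"cl_{r.id}"] = [tagged]
        clusters = sorted(catalog)
        matrix = OrthologMatrix(
            ["s1", "s2"], clusters, np.ones((2, len(clusters)), dtype=int))
        scaffold = scaffold_of(net)
        pg = assemble_pangem(matrix, catalog, scaffold,
                             gapfill_candidates=gap_candidates)
        assert pg.gapfilled_reaction_ids == {"H1_0"}
        sol = fba.solve_fba(build_flux_problem(pg.network), "BIO")
        assert sol.objective_value >= MU_MIN

    def test_orphan_component_error_names_it(self):
        net = linear_toy(n_parallel=(1, 1), chain_len=2)
        internal = [r for r in net.reactions if not r.is_exchange and not r.is_biomass]
        catalog = {f"cl_{r.id}": [Reaction(
            r.id, r.stoichiometry, r.lower_bound, r.upper_bound,
            ortholog_ids=frozenset({f"cl_{r.id}"}))]
            for r in internal if r.id != "H1_0"}
        clusters = sorted(catalog)
        matrix = OrthologMatrix(["s1", "s2"], clusters,
                                np.ones((2, len(clusters)), dtype=int))
        scaffold = scaffold_of(net)
        with pytest.raises(ValueError, match="X2_c"):
            assemble_pangem(matrix, catalog, scaffold)


class TestRarefaction:
    def test_identical_strains_contribute_nothing_new(self):
        m = OrthologMatrix(["a", "b", "c", "d"], ["c1", "c2"],
                           np.ones((4, 2), dtype=int))
        curve = rarefaction_curve(m, 20, seed=0)
        assert curve[0] == 2.0
        assert np.all(curve[1:] == 0.0)

    def test_disjoint_strains_contribute_constantly(self):
        g = 3
        presence = np.kron(np.eye(4, dtype=int), np.ones((1, g), dtype=int))
        m = OrthologMatrix([f"s{i}" for i in range(4)],
                           [f"c{j}" for j in range(4 * g)], presence)
        curve = rarefaction_curve(m, 10, seed=0)
        assert np.all(curve == g)

    def test_permutation_count_validated(self, toy_pangenome):
        with pytest.raises(ValueError):
            rarefaction_curve(toy_pangenome.matrix, 0)

    def test_generator_matrix_recovers_alpha(self, toy_pangenome):
        curve = rarefaction_curve(toy_pangenome.matrix, 200, seed=3)
        fit = fit_heaps(curve)
        assert fit.alpha == pytest.approx(toy_pangenome.spec.heaps_alpha, abs=0.15)
        assert fit.openness == "open"


class TestHeapsFit:
    def test_noiseless_open_curve_exact(self):
        k = np.arange(1, 31)
        fit = fit_heaps(100.0 * k ** -0.8)
        assert fit.alpha == pytest.approx(0.8, abs=1e-12)
        assert fit.kappa == pytest.approx(100.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.openness == "open"

    def test_noiseless_closed_curve(self):
        k = np.arange(1, 31)
        fit = fit_heaps(50.0 * k ** -1.9)
        assert fit.alpha == pytest.approx(1.9, abs=1e-12)
        assert fit.openness == "closed"

    def test_noisy_curve_within_tolerance(self):
        rng = np.random.default_rng(7)
        k = np.arange(1, 201)
        curve = 80.0 * k ** -0.8 * np.exp(rng.normal(0, 0.1, len(k)))
        fit = fit_heaps(curve)
        assert fit.alpha == pytest.approx(0.8, abs=0.1)

    def test_saturated_curve_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            fit_heaps(np.array([5.0, 0, 0, 0, 0]))


class TestEssentialCore:
    def test_redundant_parallel_path_excluded(self):
        pg = as_pangem(linear_toy(n_parallel=(1, 2), chain_len=2))
        support = essential_core(pg, MU_MIN)
        # exactly one of the two parallel hops, not both
        assert len({"H1_0", "H1_1"} & support) == 1
        assert {"T_A", "H0_0"} <= support

    @pytest.mark.parametrize("layout", [
        dict(n_parallel=(2, 2, 2), chain_len=3, extra_blocked=2),
        dict(n_parallel=(3, 2, 1), chain_len=3, extra_blocked=3),
        dict(n_parallel=(1, 2, 3), chain_len=3, extra_blocked=2),
    ])
    def test_cardinality_matches_exhaustive_oracle(self, layout):
        net = linear_toy(**layout)
        pg = as_pangem(net)
        support = essential_core(pg, MU_MIN)
        k_min, _ = exhaustive_minimum_support(net, MU_MIN)
        assert len(support) == k_min

    def test_support_within_core_when_accessory_redundant(self, toy_pangenome):
        pg = toy_pangenome.pangem
        support = essential_core(pg)
        gene_encoded = {r.id for r in pg.network.reactions if r.ortholog_ids}
        assert (support & gene_encoded) <= (
            pg.core_reaction_ids | pg.gapfilled_reaction_ids)


class TestExtraction:
    def test_full_cluster_strain_recovers_everything(self):
        net = linear_toy(n_parallel=(2, 1), chain_len=2)
        pg = as_pangem(net)
        model = extract_strain_gem(pg, "SA", MU_MIN)
        assert set(model.reaction_ids) == set(net.reaction_ids)

    def test_every_strain_grows(self, toy_pangenome):
        for cfg in toy_pangenome.strains:
            sol = fba.solve_fba(build_flux_problem(cfg.model), "BIOMASS")
            assert sol.status == "optimal"
            assert sol.objective_value >= MU_MIN

    def test_essential_core_subset_of_every_extraction(self, toy_pangenome):
        support = essential_core(toy_pangenome.pangem)
        for cfg in toy_pangenome.strains:
            assert support <= set(cfg.model.reaction_ids)

    def test_jaccard_between_ecotypes_exceeds_core_fraction(self, toy_pangenome):
        hl = next(s for s in toy_pangenome.strains if s.ecotype.startswith("HL"))
        ll = next(s for s in toy_pangenome.strains if not s.ecotype.startswith("HL"))
        a, b = set(hl.model.reaction_ids), set(ll.model.reaction_ids)
        jaccard = len(a & b) / len(a | b)
        pg = toy_pangenome.pangem
        core_fraction = len(pg.core_reaction_ids) / (
            len(pg.core_reaction_ids) + len(pg.accessory_reaction_ids))
        assert jaccard > core_fraction

    def test_unknown_strain_rejected(self, toy_pangenome):
        with pytest.raises(KeyError):
            extract_strain_gem(toy_pangenome.pangem, "nope")


class TestGapFill:
    def _split(self, net, missing):
        model = net.with_reactions(
            [r for r in net.reactions if r.id not in missing])
        return model

    def test_single_missing_essential_recovered(self):
        net = linear_toy(n_parallel=(1, 1), chain_len=2)
        added = gap_fill(self._split(net, {"H1_0"}), net, MU_MIN)
        assert added == {"H1_0"}
        assert added.exact

    def test_two_independent_essentials_minimum_two(self):
        net = linear_toy(n_parallel=(1, 1, 1), chain_len=3)
        added = gap_fill(self._split(net, {"H0_0", "H2_0"}), net, MU_MIN)
        assert added == {"H0_0", "H2_0"}

    def test_redundant_universe_adds_only_one(self):
        net = linear_toy(n_parallel=(1, 2), chain_len=2)
        added = gap_fill(self._split(net, {"H1_0", "H1_1"}), net, MU_MIN)
        assert len(added) == 1

    def test_feasible_model_needs_nothing(self):
        net = linear_toy()
        assert gap_fill(net, net, MU_MIN) == set()

    def test_infeasible_universe_rejected(self):
        net = linear_toy(n_parallel=(1, 1), chain_len=2)
        broken = net.with_reactions(
            [r for r in net.reactions if r.id != "T_A"])
        with pytest.raises(ValueError, match="universe"):
            gap_fill(broken, broken, MU_MIN)
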