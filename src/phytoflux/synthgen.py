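"""Seeded synthetic fixtures: toy pangenome, environmental section, abundances.

Everything here is deliberately synthetic but self-consistent: the toy
photoautotroph network uses a reduced chemistry (a CH2O carbon currency,
a single amino-acid species, lumped nucleotide/lipid/pigment precursors)
whose elemental formulas balance exactly, so the generated models pass the
full quality-control battery.  The generator's defaults define the study
conditions for every downstream test.

Core template (all strains): photosystem linear electron flow (8 photons →
2 NADPH + 3 ATP + O2), cyclic electron flow (2 photons → ATP), a lumped
Calvin cycle (RuBisCO carboxylation), respiration, GS-GOGAT nitrogen
assimilation, ammonium and phosphate transport, precursor and pigment
syntheses, maintenance ATP, non-photochemical quenching, and a singlet-
oxygen detoxification sink.  Accessory catalog: nitrate and nitrite
transport/reduction (planted in low-light ecotypes only), NADPH-dependent
glutamate dehydrogenase, and the plastoquinol terminal oxidase (PTOX).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Metabolite, Reaction, MetabolicNetwork, parse_formula
from .environment import WAVELENGTHS, EnvironmentSample
from .pangenome import OrthologMatrix, PanGEM, assemble_pangem, extract_strain_gem
from .physiology import BiomassComposition, build_biomass_reaction, default_composition
from .thermal import ThermalParams
from .transport import TransporterSpec

__all__ = [
    "PangenomeSpec",
    "EnvironmentSpec",
    "ToyPangenome",
    "toy_scaffold",
    "toy_core_reactions",
    "toy_accessory_catalog",
    "toy_strain_model",
    "default_transporter_specs",
    "make_toy_pangenome",
    "make_environment_grid",
    "make_abundance_field",
]

# photosystem capacity (flux unit = 8 photons) and cyclic-flow capacity
PSET_CAP = 1.875   # ×8 = 15 mmol photons gDW⁻¹ h⁻¹
CEF_CAP = 3.0      # ×2 = 6 mmol photons gDW⁻¹ h⁻¹
NGAM = 0.5         # maintenance ATP, mmol gDW⁻¹ h⁻¹

_M = {  # metabolite id -> (formula, compartment, name)
    "photon_e": ("", "e", "photon"),
    "co2_e": ("CO2", "e", "carbon dioxide"),
    "o2_e": ("O2", "e", "oxygen"),
    "h2o_e": ("H2O", "e", "water"),
    "nh4_e": ("H3N", "e", "ammonium"),
    "no2_e": ("HNO2", "e", "nitrite"),
    "no3_e": ("HNO3", "e", "nitrate"),
    "po4_e": ("H3O4P", "e", "phosphate"),
    "photon_c": ("", "c", "photon"),
    "co2_c": ("CO2", "c", "carbon dioxide"),
    "o2_c": ("O2", "c", "oxygen"),
    "h2o_c": ("H2O", "c", "water"),
    "nh4_c": ("H3N", "c", "ammonium"),
    "no2_c": ("HNO2", "c", "nitrite"),
    "no3_c": ("HNO3", "c", "nitrate"),
    "pi_c": ("H3O4P", "c", "orthophosphate"),
    "atp_c": ("C10H16N5O13P3", "c", "ATP"),
    "adp_c": ("C10H15N5O10P2", "c", "ADP"),
    "nadph_c": ("C21H29N7O17P3", "c", "NADPH"),
    "nadp_c": ("C21H27N7O17P3", "c", "NADP"),
    "ch2o_c": ("CH2O", "c", "carbohydrate unit"),
    "aa_c": ("C4H7NO2", "c", "amino acid unit"),
    "lipid_c": ("C4H8O2", "c", "lipid unit"),
    "nuc_c": ("C5H15N2O7P", "c", "nucleotide unit"),
    "dv_chl_a_c": ("C10H13NO", "c", "divinyl-chlorophyll a"),
    "dv_chl_b_c": ("C10H13NO", "c", "divinyl-chlorophyll b"),
    "alpha_carotene_c": ("C10H13NO", "c", "alpha-carotene"),
    "zeaxanthin_c": ("C10H13NO", "c", "zeaxanthin"),
    # massless accounting species: proteome working capacity, supplied in
    # proportion to the protein pool and consumed by growth and photodamage
    "psu_c": ("", "c", "photon-damage-sensitive proteome capacity"),
}


def toy_metabolites() -> list[Metabolite]:
    return [
        Metabolite(mid, name=name, formula=parse_formula(f), compartment=comp)
        for mid, (f, comp, name) in _M.items()
    ]


def _rxn(rid, stoich, lb=0.0, ub=1000.0, subsystem="", name="", **kw):
    return Reaction(rid, stoich, lb, ub, subsystem=subsystem, name=name or rid, **kw)


def toy_scaffold(composition: BiomassComposition = None) -> MetabolicNetwork:
    """Gene-free scaffold: exchanges, passive transport, maintenance,
    photoprotection sinks, and the biomass drain for the given composition."""
    comp = composition or default_composition("HL")
    rxns = [
        _rxn("EX_photon", {"photon_e": -1}, -10000, 0, "exchange", is_exchange=True),
        _rxn("EX_co2", {"co2_e": -1}, -1000, 1000, "exchange", is_exchange=True),
        _rxn("EX_o2", {"o2_e": -1}, -1000, 1000, "exchange", is_exchange=True),
        _rxn("EX_h2o", {"h2o_e": -1}, -1000, 1000, "exchange", is_exchange=True),
        _rxn("EX_nh4", {"nh4_e": -1}, -1000, 1000, "exchange", is_exchange=True),
        _rxn("EX_no2", {"no2_e": -1}, -1000, 1000, "exchange", is_exchange=True),
        _rxn("EX_no3", {"no3_e": -1}, -1000, 1000, "exchange", is_exchange=True),
        _rxn("EX_po4", {"po4_e": -1}, -1000, 1000, "exchange", is_exchange=True),
        _rxn("TR_PHOT", {"photon_e": -1, "photon_c": 1}, 0, 1000, "light"),
        _rxn("TR_CO2", {"co2_e": -1, "co2_c": 1}, -1000, 1000, "transport"),
        _rxn("TR_O2", {"o2_e": -1, "o2_c": 1}, -1000, 1000, "transport"),
        _rxn("TR_H2O", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000, "transport"),
        _rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
             NGAM, 1000, "maintenance", "non-growth maintenance ATPase"),
        # heat dissipation of absorbed photons (zeaxanthin NPQ capacity is
        # imposed as this reaction's upper bound during acclimation)
        _rxn("NPQ", {"photon_c": -1}, 0, 1000, "photoprotection",
             "non-photochemical quenching"),
        # singlet-oxygen detoxification: residual excess photons cost
        # reductant and damage the working proteome (psu_c), so
        # photoinhibition competes directly with growth for capacity
        _rxn("DETOX", {"photon_c": -1, "nadph_c": -1e-3, "o2_c": -5e-4,
                       "nadp_c": 1e-3, "h2o_c": 1e-3, "psu_c": -5e-4},
             0, 1000, "photoprotection", "ROS detoxification (peroxidase)"),
        # proteome capacity supply; its upper bound is set during acclimation
        # to (growth capacity per unit protein) × (protein mass fraction)
        _rxn("PSUPOOL", {"psu_c": 1}, 0, 1000, "capacity",
             "proteome capacity supply"),
        build_biomass_reaction(comp, "BIOMASS"),
    ]
    return MetabolicNetwork(toy_metabolites(), rxns, "BIOMASS")


#: core gene-encoded reactions (cluster assignment added at assembly)
def toy_core_reactions() -> list[Reaction]:
    return [
        _rxn("PSET", {"photon_c": -8, "nadp_c": -2, "adp_c": -3, "pi_c": -3,
                      "o2_c": 1, "nadph_c": 2, "atp_c": 3, "h2o_c": 1},
             0, PSET_CAP, "light", "photosystems (linear electron flow)"),
        _rxn("CEF", {"photon_c": -2, "adp_c": -1, "pi_c": -1,
                     "atp_c": 1, "h2o_c": 1},
             0, CEF_CAP, "light", "cyclic electron flow"),
        _rxn("CBB", {"co2_c": -1, "nadph_c": -2, "atp_c": -3, "h2o_c": -2,
                     "ch2o_c": 1, "nadp_c": 2, "adp_c": 3, "pi_c": 3},
             0, 1000, "carbon fixation", "RuBisCO carboxylation (Calvin cycle)"),
        _rxn("RESP", {"ch2o_c": -1, "o2_c": -1, "adp_c": -2, "pi_c": -2,
                      "co2_c": 1, "atp_c": 2, "h2o_c": 3},
             0, 1000, "respiration", "respiration"),
        _rxn("GS_GOGAT", {"ch2o_c": -4, "nh4_c": -1, "atp_c": -1,
                          "aa_c": 1, "adp_c": 1, "pi_c": 1, "h2o_c": 1},
             0, 1000, "nitrogen assimilation", "GS-GOGAT amino acid synthesis"),
        _rxn("TR_NH4", {"nh4_e": -1, "nh4_c": 1}, 0, 1000, "transport",
             "ammonium transporter"),
        _rxn("TR_PO4", {"po4_e": -1, "pi_c": 1}, 0, 1000, "transport",
             "phosphate transporter"),
        _rxn("LIPSYN", {"ch2o_c": -4, "nadph_c": -2, "atp_c": -1, "lipid_c": 1,
                        "nadp_c": 2, "adp_c": 1, "pi_c": 1, "h2o_c": 1},
             0, 1000, "lipid synthesis", "lipid synthesis"),
        _rxn("NUCSYN", {"ch2o_c": -5, "nh4_c": -2, "atp_c": -2,
                        "nuc_c": 1, "adp_c": 2, "pi_c": 1},
             0, 1000, "nucleotide synthesis", "nucleotide synthesis"),
    ] + [
        _rxn(f"PSYN_{pig}", {"ch2o_c": -10, "nh4_c": -1, "nadph_c": -4,
                             "atp_c": -2, f"{pig}_c": 1, "nadp_c": 4,
                             "adp_c": 2, "pi_c": 2, "h2o_c": 7},
             0, 1000, "pigment synthesis", f"{pig} synthesis")
        for pig in ("dv_chl_a", "dv_chl_b", "alpha_carotene", "zeaxanthin")
    ]


def toy_accessory_catalog() -> dict[str, list[Reaction]]:
    """Functional accessory clusters (niche traits planted by ecotype)."""
    return {
        "acc_no3": [
            _rxn("TR_NO3", {"no3_e": -1, "no3_c": 1}, 0, 1000, "transport",
                 "nitrate transporter"),
            _rxn("NR", {"no3_c": -1, "nadph_c": -1, "no2_c": 1, "nadp_c": 1,
                        "h2o_c": 1}, 0, 1000, "nitrogen assimilation",
                 "nitrate reductase"),
        ],
        "acc_no2": [
            _rxn("TR_NO2", {"no2_e": -1, "no2_c": 1}, 0, 1000, "transport",
                 "nitrite transporter"),
            _rxn("NIR", {"no2_c": -1, "nadph_c": -3, "nh4_c": 1, "nadp_c": 3,
                         "h2o_c": 2}, 0, 1000, "nitrogen assimilation",
                 "nitrite reductase"),
        ],
        "acc_gdh": [
            _rxn("GDH", {"ch2o_c": -4, "nh4_c": -1, "nadph_c": -1, "o2_c": -0.5,
                         "aa_c": 1, "nadp_c": 1, "h2o_c": 3},
                 0, 1000, "nitrogen assimilation",
                 "glutamate dehydrogenase (NADPH)"),
        ],
        "acc_ptox": [
            _rxn("PTOX", {"nadph_c": -2, "o2_c": -1, "nadp_c": 2, "h2o_c": 2},
                 0, 1000, "alternative electron flow",
                 "plastoquinol terminal oxidase"),
        ],
    }


_DIFFUSIVITY = {"nh4_e": 1.96e-9, "no2_e": 1.91e-9, "no3_e": 1.70e-9,
                "po4_e": 0.90e-9}
_KCAT = {"nh4_e": 50.0, "no2_e": 30.0, "no3_e": 20.0, "po4_e": 40.0}


def default_transporter_specs(model: MetabolicNetwork) -> list[TransporterSpec]:
    """Specs for every nutrient substrate the model can transport."""
    out = []
    for sid in sorted(_DIFFUSIVITY):
        has = any(
            not r.is_exchange and r.stoichiometry.get(sid, 0) < 0
            for r in model.reactions
        )
        if has:
            out.append(TransporterSpec(
                substrate_id=sid, k_cat=_KCAT[sid], footprint=25.0,
                diffusivity=_DIFFUSIVITY[sid], synthesis_cost=1500.0,
            ))
    return out


# ---------------------------------------------------------------------------
# pangenome generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PangenomeSpec:
    n_strains: int = 6
    n_ecotypes: int = 2
    core_cluster_count: int = 40
    accessory_cluster_count: int = 20
    heaps_alpha: float = 0.8
    seed: int = 1

    def __post_init__(self):
        if min(self.n_strains, self.n_ecotypes, self.core_cluster_count) <= 0:
            raise ValueError("counts must be positive")
        if self.accessory_cluster_count < 0:
            raise ValueError("accessory_cluster_count must be >= 0")
        if self.heaps_alpha <= 0:
            raise ValueError("heaps_alpha must be positive")
        if self.n_ecotypes > 5:
            raise ValueError("at most 5 ecotypes")


@dataclass
class StrainConfig:
    """Everything needed to acclimate one strain."""

    strain_id: str
    ecotype: str
    model: MetabolicNetwork
    transporter_specs: list[TransporterSpec]
    thermal: ThermalParams
    composition: BiomassComposition

    @property
    def light_adapted(self) -> str:
        return "HL" if self.ecotype.startswith("HL") else "LL"


@dataclass
class ToyPangenome:
    spec: PangenomeSpec
    matrix: OrthologMatrix
    catalog: dict[str, list[Reaction]]
    scaffold: MetabolicNetwork
    pangem: PanGEM
    strains: list[StrainConfig]
    table: pd.DataFrame  # strain physiology table

    def strain(self, strain_id: str) -> StrainConfig:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s
        raise KeyError(strain_id)


_ECOTYPE_ORDER = ("HLII", "HLI", "LLI", "LLII_III", "LLIV")

#: ecotype name subsets spanning the high-light → low-light range
_ECOTYPE_CHOICES = {
    1: ("HLII",),
    2: ("HLII", "LLI"),
    3: ("HLII", "LLI", "LLIV"),
    4: ("HLII", "HLI", "LLI", "LLIV"),
    5: _ECOTYPE_ORDER,
}


def _first_seen_prob(f: int, k: int, n: int) -> float:
    """P(a cluster carried by f of n strains is first seen at rank k of a
    uniformly random strain ordering)."""
    if k - 1 > n - f:
        return 0.0
    return (math.comb(n - f, k - 1) / math.comb(n, k - 1)) * f / (n - k + 1)


def _neutral_frequencies(m: int, n_strains: int, alpha: float,
                         fixed_freqs=()) -> np.ndarray:
    """Per-cluster strain counts whose *exact* expected rarefaction curve
    (including the fixed-frequency functional clusters) follows κ·k^(−α).

    The expected new-cluster curve is linear in the frequency histogram, so
    the histogram is planned by nonnegative least squares against the target
    power law over a deterministic grid of amplitudes; singleton clusters
    (whose contribution is rank-flat) absorb any count mismatch.
    """
    from scipy.optimize import nnls

    n = n_strains
    ks = np.arange(2, n + 1)
    H = np.array([[_first_seen_prob(f, k, n) for f in range(1, n + 1)]
                  for k in ks])
    fixed = np.zeros(len(ks))
    for f in fixed_freqs:
        fixed += np.array([_first_seen_prob(int(f), int(k), n) for k in ks])
    base = ks.astype(float) ** (-alpha)
    best = None
    for c in np.linspace(0.5, 20.0 * max(1, m // 4), 200):
        target = np.maximum(c * base - fixed, 0.0)
        counts, _ = nnls(H, target)
        counts = np.round(counts).astype(int)
        total = int(counts.sum())
        if total == 0:
            continue
        cand = counts.copy()
        if total > m:  # trim, removing flat singletons first
            excess = total - m
            take = min(excess, cand[0])
            cand[0] -= take
            excess -= take
            for f in range(n - 1, 0, -1):
                while excess > 0 and cand[f] > 0:
                    cand[f] -= 1
                    excess -= 1
        elif total < m:
            cand[0] += m - total
        curve = H @ cand + fixed
        if np.any(curve <= 0):
            continue
        slope = np.polyfit(np.log(ks), np.log(curve), 1)[0]
        err = abs(-slope - alpha)
        if best is None or err < best[0]:
            best = (err, cand)
    if best is None:
        raise ValueError("could not plan a Heaps-consistent frequency spectrum")
    freqs = []
    for f in range(1, n + 1):
        freqs += [f] * int(best[1][f - 1])
    return np.array(freqs[:m], dtype=int)


def make_toy_pangenome(spec: PangenomeSpec = PangenomeSpec()) -> ToyPangenome:
    """Generate a feasible toy pangenome with planted niche structure.

    Core clusters are present in all strains; the first core clusters carry
    the core metabolic reactions (the rest are non-metabolic, mirroring the
    open genetic / closed metabolic dichotomy).  Functional accessory
    clusters are assigned by ecotype (nitrate/nitrite assimilation and GDH
    to low-light ecotypes, PTOX to alternating high-light strains); neutral
    accessory clusters follow a Heaps frequency spectrum.  Every strain
    model is extracted and verified to grow.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strains
    strains = [f"S{i+1:02d}" for i in range(n)]
    names = _ECOTYPE_CHOICES[spec.n_ecotypes]
    ecos = [names[min(i * spec.n_ecotypes // n, spec.n_ecotypes - 1)]
            for i in range(n)]
    is_ll = [not e.startswith("HL") for e in ecos]

    core_clusters = [f"core_{i+1:04d}" for i in range(spec.core_cluster_count)]
    acc_fun = toy_accessory_catalog()
    # functional (niche-trait) clusters only fit when the accessory budget
    # allows them; a zero-accessory spec yields identical strains
    fun_names = list(acc_fun)[: spec.accessory_cluster_count]
    acc_fun = {c: acc_fun[c] for c in fun_names}
    n_neutral = spec.accessory_cluster_count - len(fun_names)
    neutral = [f"acc_n{i+1:04d}" for i in range(n_neutral)]
    clusters = core_clusters + fun_names + neutral

    core_rxns = toy_core_reactions()
    catalog: dict[str, list[Reaction]] = {c: [] for c in clusters}
    for i, r in enumerate(core_rxns):
        c = core_clusters[i % spec.core_cluster_count]
        catalog[c].append(replace(r, ortholog_ids=frozenset({c})))
    for c, rxns in acc_fun.items():
        catalog[c] = [replace(r, ortholog_ids=frozenset({c})) for r in rxns]

    presence = np.zeros((n, len(clusters)), dtype=int)
    presence[:, :len(core_clusters)] = 1
    col = {c: j for j, c in enumerate(clusters)}
    for i in range(n):
        if is_ll[i]:
            for c in ("acc_no3", "acc_no2", "acc_gdh"):
                if c in col:
                    presence[i, col[c]] = 1
        elif i % 2 == 0 and "acc_ptox" in col:
            presence[i, col["acc_ptox"]] = 1
    if n_neutral:
        fixed = [int(presence[:, col[c]].sum()) for c in fun_names
                 if presence[:, col[c]].sum() > 0]
        freqs = _neutral_frequencies(n_neutral, n, spec.heaps_alpha, fixed)
        for j, f in zip(range(len(core_clusters) + len(fun_names), len(clusters)), freqs):
            carriers = rng.choice(n, size=int(f), replace=False)
            presence[carriers, j] = 1

    matrix = OrthologMatrix(strains, clusters, presence,
                            {s: e for s, e in zip(strains, ecos)})
    scaffold = toy_scaffold(default_composition("HL"))
    pangem = assemble_pangem(matrix, catalog, scaffold)

    rows, configs = [], []
    for i, (s, e) in enumerate(zip(strains, ecos)):
        model = extract_strain_gem(pangem, s)
        light = "LL" if is_ll[i] else "HL"
        # modest within-ecotype spread, deterministic in the strain index
        ogt = (297.0 + 1.5 * (i % 3) if light == "HL" else 291.5 + 1.0 * (i % 3))
        therm = ThermalParams(E_a=65.0 if light == "HL" else 55.0,
                              OGT=ogt, E_h=220.0)
        comp = default_composition(light)
        specs = default_transporter_specs(model)
        configs.append(StrainConfig(s, e, model, specs, therm, comp))
        rows.append({
            "strain_id": s, "ecotype": e, "light_adapted": light,
            "E_a_kJ_mol": therm.E_a, "OGT_K": therm.OGT, "E_h_kJ_mol": therm.E_h,
            "n_reactions": len(model.reactions),
            "n_substrates": len(specs),
        })
    return ToyPangenome(
        spec=spec, matrix=matrix, catalog=catalog, scaffold=scaffold,
        pangem=pangem, strains=configs, table=pd.DataFrame(rows),
    )


def toy_strain_model(light_adapted: str = "HL") -> MetabolicNetwork:
    """A single stand-alone strain model (core + all accessory reactions for
    LL, core + PTOX for HL) without running the pangenome machinery."""
    scaffold = toy_scaffold(default_composition(light_adapted))
    rxns = list(scaffold.reactions) + toy_core_reactions()
    acc = toy_accessory_catalog()
    if light_adapted == "LL":
        for c in ("acc_no3", "acc_no2", "acc_gdh"):
            rxns += acc[c]
    else:
        rxns += acc["acc_ptox"]
    return MetabolicNetwork(scaffold.metabolites, rxns, "BIOMASS")


# ---------------------------------------------------------------------------
# environmental section generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentSpec:
    latitudes: tuple = (-30.0, 0.0, 30.0)
    depths: tuple = tuple(range(10, 201, 10))
    surface_par: float = 2200.0          # µmol photons m-2 s-1
    deep_temperature: float = 285.15     # K
    seed: int = 1

    @classmethod
    def small(cls) -> "EnvironmentSpec":
        """3 stations × 10 depth levels: the default desk-scale section."""
        return cls(latitudes=(-30.0, 0.0, 30.0), depths=tuple(range(10, 201, 20)))

    @classmethod
    def amt(cls) -> "EnvironmentSpec":
        """Transect-shaped section: 32 stations 48°N→45°S, 10-m depth steps."""
        lats = tuple(np.linspace(48.0, -45.0, 32).round(2))
        return cls(latitudes=lats, depths=tuple(range(10, 201, 10)))

    def surface_temperature(self, lat: float) -> float:
        """K; warm tropics, cooler poleward."""
        return 273.15 + 28.0 - 0.22 * abs(lat)

    def nutricline_depth(self, lat: float) -> float:
        """m; shallow near the equator, deep in the gyres."""
        return 150.0 - 70.0 * math.exp(-((lat / 15.0) ** 2))

    def attenuation(self) -> np.ndarray:
        """K_d(λ), m⁻¹, minimum in the blue near 480 nm."""
        return 0.022 + 1.3e-6 * (WAVELENGTHS - 480.0) ** 2

    def surface_spectrum(self) -> np.ndarray:
        """E0(λ), µmol m⁻² s⁻¹ nm⁻¹, broad daylight-like shape."""
        shape = 1.0 + 0.25 * np.exp(-0.5 * ((WAVELENGTHS - 520.0) / 90.0) ** 2)
        shape /= shape.sum() * 5.0
        return self.surface_par * shape


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_environment_grid(spec: EnvironmentSpec = EnvironmentSpec()):
    """Synthetic meridional section: exponentially attenuated, blue-shifting
    light; a thermocline; nutrients increasing through a nutricline.

    Returns (samples, env_df, spectra_df): the sample objects plus tidy
    frames matching the CSV interchange layout.
    """
    e0 = spec.surface_spectrum()
    kd = spec.attenuation()
    samples, rows, spec_rows = [], [], []
    for si, lat in enumerate(spec.latitudes):
        station = f"ST{si+1:02d}"
        sst = spec.surface_temperature(lat)
        zn = spec.nutricline_depth(lat)
        for z in spec.depths:
            E = e0 * np.exp(-kd * z)
            temp = spec.deep_temperature + (sst - spec.deep_temperature) * (
                1.0 - _sigmoid((z - 0.55 * zn) / 15.0)
            )
            # reduced N is confined to the upper layers: an ammonium
            # regeneration peak above the nutricline and a thin primary
            # nitrite maximum at it; below, nitrate is the only abundant N
            # source (drives the subsurface nitrate-fueled f-ratio maximum)
            nuts = {
                "nh4_e": 2e-8 + 2e-5 * math.exp(-(((z - (zn - 30.0)) / 30.0) ** 2)),
                "no2_e": 5e-8 + 2e-4 * math.exp(-(((z - zn) / 15.0) ** 2)),
                "no3_e": 1e-6 + 5e-3 * float(_sigmoid((z - zn) / 20.0)),
                "po4_e": 2e-5 + 1e-3 * float(_sigmoid((z - zn) / 20.0)),
            }
            s = EnvironmentSample(station, lat, float(z), float(temp), nuts, E)
            samples.append(s)
            rows.append({
                "station": station, "latitude": lat, "depth_m": z,
                "temp_K": temp, **{k: v for k, v in nuts.items()},
                "PAR": s.par,
            })
            for lam, e in zip(WAVELENGTHS, E):
                spec_rows.append({"station": station, "depth_m": z,
                                  "wavelength_nm": lam, "E": e})
    return samples, pd.DataFrame(rows), pd.DataFrame(spec_rows)


# ---------------------------------------------------------------------------
# abundance generator
# ---------------------------------------------------------------------------

def make_abundance_field(mu_field, m: float = 6e-4, x: float = 1.6,
                         noise_sigma: float = 0.0, seed: int = 0):
    """Steady-state abundances from a density-dependent mortality law.

    dB/dt = μB − mB^x = 0 gives B = (μ/m)^(1/(x−1)); multiplicative
    lognormal noise emulates observation scatter.  μ = 0 cells get B = 0.
    ``mu_field`` is a mapping key → growth rate; returns the same mapping
    shape with abundances.
    """
    if x <= 1:
        raise ValueError("density exponent x must exceed 1 (no steady state)")
    rng = np.random.default_rng(seed)
    out = {}
    for k, mu in mu_field.items():
        if mu < 0:
            raise ValueError("growth rates must be >= 0")
        if mu == 0:
            out[k] = 0.0
            continue
        b = (mu / m) ** (1.0 / (x - 1.0))
        if noise_sigma > 0:
            b *= math.exp(rng.normal(0.0, noise_sigma))
        out[k] = b
    return out
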