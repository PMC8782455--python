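# Methods

This note documents the models implemented in `phytoflux`, the assumptions
behind them, the defaults that matter, and what the synthetic fixtures do
and do not establish.

## Flux balance core

A metabolic network is posed as the linear program

```
maximize  cᵀv   subject to   S·v = 0,   v_lb ≤ v ≤ v_ub
```

with S the stoichiometric matrix over internal species, v the flux vector
in mmol·gDW⁻¹·h⁻¹, and the objective the biomass flux, interpreted as the
specific growth rate μ (h⁻¹): synthesis of one gram of ash-free dry biomass
per gram per hour. All solves use HiGHS through SciPy with feasibility and
optimality tolerances of 1e−9. Columns are ordered lexicographically by
reaction id, so identical networks give bit-identical problems and
solutions. Reported flux vectors come from parsimonious FBA (L1-minimal via
the standard split into nonnegative forward/reverse parts) at objective
fraction 1.0, which removes futile cycles and makes downstream diagnostics
(quantum yield, f-ratio, gross O₂) reproducible under degenerate optima.
Shadow prices and bound sensitivities are HiGHS duals, sign-corrected to the
maximization convention; at a degenerate optimum they are one valid
subgradient.

Model quality control runs five checks: stoichiometric consistency
(existence of a strictly positive molecular-mass vector annihilated by the
internal stoichiometry; massless bookkeeping species — photons and the
capacity unit below — are excluded), per-reaction elemental balance from
formulas (exchanges and the biomass drain are exempt; species with unknown
composition mark a reaction untestable rather than failed), biomass
producibility (FBA μ > 1e−6 with exchanges open), blocked reactions (FVA
with open exchanges; |v|max < 1e−9 counts as blocked), and freedom from
energy-generating cycles (zero maximal ATP-hydrolysis flux with all
exchanges closed and forced lower bounds released).

## Pangenome layer

The pangenome model is the union of all reactions encoded by any ortholog
cluster present in at least one strain, on a scaffold of gene-free
reactions (exchanges, biomass, maintenance, photoprotection sinks,
spontaneous transport). Reactions are partitioned into core (cluster in
every strain, plus the scaffold), accessory, and gap-filled (added without
gene evidence to make biomass producible; gap filling is a minimum-
cardinality mixed-integer program up to 64 candidates, then a greedy
L1-support heuristic flagged on the result).

Rarefaction draws random strain orderings (default 100, seeded) and counts
clusters first contributed by the k-th strain; the Heaps fit is least
squares of log(new) on log(k), excluding k = 1 (every cluster of the first
strain is trivially new) and zero entries. Openness is α ≤ 1.

Strain extraction is a compressed-sensing-style sparsification: an
iteratively reweighted L1 flux minimization (5 iterations,
w = 1/(|v| + 1e−6), support threshold 1e−9) finds a small reaction set
sustaining μ ≥ μ_min (default 1e−3 h⁻¹), followed by per-biomass-component
demand checks (each precursor must be producible de novo using only the
support; failures re-admit reactions via gap filling) and a deterministic
greedy deletion pass in lexicographic order that enforces superset-
minimality. The search is restricted to universally available reactions
(core, spontaneous, gap-filled): the essential subset is shared by every
strain, so accessory reactions are closed during the search. A strain model
is the essential core plus all reactions encoded by the strain's clusters,
plus exchanges, biomass and gene-free reactions (gap-filled reactions are
treated as universal).

On toys small enough for exhaustive enumeration (≤ 12 reactions) the
procedure recovers the true minimum support; on larger networks
superset-minimality, not global minimality, is guaranteed.

## Transport (OptTrans)

Uptake of a dissolved substrate by a spherical cell of radius r (µm)
carrying n transporter copies follows

```
v = V_max·S∞ / (S∞ + K_eff),   V_max = n·k_cat/N_A,   K_eff = V_max/(4πDr)
```

which interpolates exactly between the diffusive encounter limit 4πDrS∞
and the porter limit n·k_cat. The critical concentration
S* = demand·K_eff/(V_max − demand) is where supply meets demand; above it
the cell is growth-limited and uptake is clamped by the flux balance
itself. Limitation regimes: growth-limited (S∞ > S*), else surface-area-
limited (membrane budget exhausted), else diffusion-limited (S∞ < K_eff),
else porter-limited.

OptTrans searches a deterministic 16-point logarithmic radius grid
(0.25–1.0 µm). At each radius a demand probe solves FBA with every
substrate capped at its full-membrane ambient capacity — the capacity cap,
rather than saturation, is what lets scarce ammonium surface a nitrate
demand. Candidate transporter allocations are scalings of the demand
solution (with a 5% margin so supply strictly exceeds demand at the
optimum), or simplex splits of the full area budget
(Σ nᵢ·footprintᵢ ≤ f_A·4πr², f_A = 0.04, footprint 25 nm²) when demand
exceeds it. Each candidate is scored by FBA with growth-associated ATP
debits for transporter synthesis (cost × n per gDW) and for the cell
envelope. The envelope debit (0.6 mmol ATP and 0.6 mmol carbohydrate-
equivalents per gDW per µm⁻¹ of radius) encodes that membrane/wall mass per
unit biomass scales with the surface:volume ratio; it is the size benefit
that makes large cells optimal when uptake is not limiting, and together
with the small-cell diffusive advantage it produces the optimal radius
increasing with resource richness. Ties break toward smaller radius.
Dry mass is 250 fg·µm⁻³ × volume. Unit conversions (mol·cell⁻¹·s⁻¹ ↔
mmol·gDW⁻¹·h⁻¹) are centralized and tested.

The acclimation debits are internal to the OptTrans scoring; the final
reported fluxes come from the composition layer, which does not re-apply
them. The two-step OptTrans → PhysOpt sequence is itself an approximation:
allocations are chosen against the pre-acclimation composition, which can
be mildly suboptimal after the composition adjusts (visible as
grid-resolution-scale growth differences between otherwise comparable
strains).

## Composition and light (PhysOpt)

Biomass is a set of macromolecular pools (protein, DNA, RNA, lipid,
carbohydrate, cell wall, pigment, osmolyte, mineral, free metabolites) with
mass fractions summing to one, plus pigment quotas (mg·gDW⁻¹) for
divinyl-chlorophylls a and b, α-carotene (light harvesting) and zeaxanthin
(photoprotection). The biomass reaction consumes mmol of each precursor per
gram (fraction × 1000/M) plus an ATP polymerization cost per pool
(protein 40, nucleic acids 25, lipid 10, carbohydrate 5, pigment
50 mmol ATP·g⁻¹). Combustion enthalpies: protein 23.9, lipid 39.5,
carbohydrate 17.5, nucleic acids 14.5, others 20.0, minerals 0 kJ·g⁻¹.
Elemental metrics (C:N, C:P, enthalpy) follow from the precursor formulas;
the replete defaults sit near C:N ≈ 6, inside the observed 5.4–6.8 band.

Pigments carry Gaussian-band specific absorption spectra on the shared
400–700 nm / 5 nm grid (dv-chl a: 442/672 nm; dv-chl b: 460/650 nm;
α-carotene 450 nm; zeaxanthin 454 nm; widths 15–30 nm; peak amplitudes
0.010–0.022 m²·mg⁻¹). Absorbed photon flux per pigment is
quota × Σ a*(λ)E(λ)Δλ, converted to mmol photons·gDW⁻¹·h⁻¹. Photons
absorbed by harvest pigments are forced into the cell (the photon transport
flux is pinned to the absorbed flux); sinks are the photosystems (linear
electron flow: 8 photons → 2 NADPH + 3 ATP + O₂, capacity 15 mmol
photons·gDW⁻¹·h⁻¹), cyclic electron flow (2 photons → ATP, capacity
6 mmol photons·gDW⁻¹·h⁻¹), heat via non-photochemical quenching (capacity
50 mmol photons per mg zeaxanthin per h), and a singlet-oxygen
detoxification flux costing 1e−3 mol NADPH per mol excess photon.

Two capacity couplings matter. First, the 8-photon linear-electron-flow
stoichiometry fixes the quantum-yield ceiling: carbon fixation needs
2 NADPH per CO₂ and NADPH comes only from the photosystems, so
QY = v_carboxylation/Φ_harvest ≤ 1/8, with strict inequality whenever
maintenance or biosynthetic ATP diverts photons to cyclic flow. Second, a
massless proteome-capacity species couples growth to the protein pool: a
supply reaction bounded by (0.09 h⁻¹ per unit protein fraction) × protein
fraction is consumed 1:1 by biomass and 5e−4 per excess photon by the
detoxification reaction. This single row produces both the
protein-as-machinery trade-off (protein stays high under replete growth,
is shed under N scarcity to raise yield) and photoinhibition that bites
even when reductant is not limiting (photodamage competes with growth for
working proteome). Growth versus irradiance is therefore unimodal: linear
in the light-limited regime, saturating at the photosystem/proteome
capacity, declining once absorption at minimal pigmentation exceeds
photochemical plus quenching capacity.

The optimizer is a fixed-schedule coordinate descent: pigments then pools
in declared order, step 0.25 × (bound range) halved over 3 sweeps, each
move renormalized against the carbohydrate buffer pool, accepted only on
strict improvement. It is derivative-free, deterministic, and adequate for
the smooth unimodal responses here; it guarantees μ at least that of the
starting composition, not a global optimum.

## Thermal scaling

The dimensionless factor γ(T) is a Sharpe–Schoolfield-type curve with
high-temperature inactivation, normalized to γ(OGT) = 1; the inactivation
half-point solves the argmax condition in closed form,
1/T_h = 1/OGT + (R/E_h)·ln[E_a/(E_h − E_a)]. On the sub-optimal limb ln γ
is Arrhenius (slope −E_a/R); E_a is fit by least squares of ln μ on 1/T
restricted to observations at or below the empirical optimum. γ multiplies
μ and all fluxes uniformly (scaling a feasible flux vector preserves
S·v = 0); optical absorption is left unscaled, so the quantum yield
declines with γ at cold temperatures. Whether only biosynthetic rates
should scale is an open question; uniform scaling is the simplest choice
consistent with a single rate factor.

## Ecology layer

Acclimation of one strain at one grid point is OptTrans → PhysOpt →
thermal scaling; infeasible environments yield a zero-growth result with
diagnostics rather than an error. The limiting resource is classified by
μ-elasticity (marginal gain × flux / μ) of the nitrogen, phosphorus and
carbon uptake bounds and of the photon balance shadow price; "none" means
nothing is marginally binding beyond the growth machinery itself.

Populations: each ecotype is represented at each sample by its highest-μ
strain (ties to the lexicographically smallest id); population quantities
are abundance-weighted means, with an explicit missing marker where total
abundance is zero. Volumetric gross O₂ production multiplies each
ecotype's specific rate by abundance × per-cell dry mass.

PI curves use the Webb exponential P = P_max(1 − exp(−αE/P_max)), whose
derived quantities are exactly the reported parameters (α, the assimilation
number P^B_max, and E_k = P^B_max/α); photosynthesis is chlorophyll-
normalized with dv-chl a + b. Density dependence assumes the steady state
of dB/dt = μB − mB^x, i.e. μ = mB^(x−1), fit in log–log space; the
linear-mortality alternative predicts a B-independent μ and is reported via
the linear-space R² of an OLS of μ on B. The f-ratio is
v_NO₃/(v_NO₃ + v_NO₂ + v_NH₄) over the transport fluxes.

## Synthetic fixtures

The toy photoautotroph uses a reduced chemistry — a CH₂O carbon currency, a
single C₄H₇NO₂ amino-acid species, lumped lipid/nucleotide/pigment
precursors, and self-consistent artificial formulas for the NADP(H) couple —
chosen so that every internal reaction balances exactly and all quality
checks pass. Core functions (photosystems, Calvin lump, respiration,
GS-GOGAT, NH₄/PO₄ transport, precursor and pigment syntheses, maintenance
at 0.5 mmol ATP·gDW⁻¹·h⁻¹) are assigned to core clusters; accessory
clusters carry nitrate and nitrite transport/reduction and NADPH-dependent
glutamate dehydrogenase (planted in low-light ecotypes only) and PTOX (in
alternating high-light strains); most accessory clusters encode no
reactions, mirroring the open-genome/closed-metabolism dichotomy. Neutral
cluster frequencies are planned by nonnegative least squares against the
exact expected rarefaction curve so that the realized Heaps exponent
matches the requested α; singleton clusters (rank-flat contribution)
absorb count mismatches.

The environmental section has exponentially attenuated light
E(λ,z) = E₀(λ)e^(−K_d(λ)z) with K_d minimal near 480 nm (hence the blue
shift with depth that favors dv-chl b), a thermocline relaxing to 12 °C at
depth, and nutrients structured by a latitude-dependent nutricline
(shallow at the equator, deep in the gyres): nitrate and phosphate rise
sigmoidally through it, ammonium is a regeneration peak just above it over
a sub-nanomolar background, and nitrite is a thin primary maximum at it.
This N speciation is what produces the subsurface nitrate-fueled f-ratio
maximum: above the nutricline regenerated ammonium covers demand (f ≈ 0),
just below it reduced nitrogen is exhausted while nitrate is abundant.
Steady-state abundances invert the mortality law,
B = (μ/m)^(1/(x−1)) × lognormal noise, with m = 6e−4 and x = 1.6 by
default, scaled so μ ≈ 0.6 d⁻¹ maps to ~10⁵ cells·mL⁻¹.

Default problem sizes are deliberately desk-scale: 6 strains, 40 core + 20
accessory clusters, 3 stations × 10 depth levels (a 32-station,
step-10-depth preset is available). Growth rates land at 0–1.2 d⁻¹,
compensation irradiance near 2 µmol photons·m⁻²·s⁻¹, and maximal growth at
the photosystem/proteome capacity.

What passing tests show — and what they do not: the fixtures demonstrate
that the mechanisms produce the right *orderings and shapes* (depth
partition of ecotypes, photoinhibition, pigment and composition shifts,
f-ratio structure, density-dependence recovery) under controlled
conditions. They do not validate absolute rates against field data, do not
emulate mixing, light history, grazing or mixotrophy, and the reduced
chemistry cannot reproduce pathway-level flux detail of a curated
genome-scale reconstruction.

## Known limitations

- The bilevel acclimations are sequential and heuristic (grid/coordinate
  search), not certified global optima.
- Transporter counts are continuous; stochastic encounter and molecular
  detail of transporter structure are out of scope.
- The essential-core search guarantees superset-minimality only; global
  minimality is verified on small instances by enumeration.
- Uniform thermal scaling of all fluxes; composition is temperature-
  independent.
- The limiting-resource index compares elasticities across qualitatively
  different constraints; near-degenerate cases default to "none".
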