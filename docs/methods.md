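# Methods

This note documents the model equations, the parameters that matter, the
numerical choices, and the limits of what the test suite demonstrates.

## Scope and structure

`erwsim` simulates a single, vertically lumped biogeochemically active
soil layer of depth `z_a` (default 0.30 m).  Lumping is a deliberate
trade: the enhanced-weathering chemistry needs the sub-daily moisture and
CO₂ fluctuations that drive dissolution, not vertical concentration
profiles.  Consequently the hydrology is a one-bucket water balance
rather than a Richards-equation column, and all solutes are expressed per
unit ground area (g m⁻², charge in mol_c m⁻²) with porewater
concentrations derived by dividing by the stored water volume.

Three clocks are nested by operator splitting:

1. **Hourly hydrology.**  Saturation-excess partitioning of rain (and a
   degree-day snow store, factor 0.15 mm °C⁻¹ h⁻¹), Priestley–Taylor
   potential evapotranspiration (α = 1.26, albedo 0.23) on net radiation
   approximated as absorbed shortwave minus a constant 60 W m⁻² longwave
   loss while the sun is up, Beer-law canopy partitioning
   `1 − e^(−0.5·LAI)` into transpiration, linear soil-moisture limitation
   between wilting point and field capacity, and unit-gradient drainage
   `K_s·s_eff^(2b+3)` with Clapp–Hornberger texture parameters from a
   built-in lookup.  Soil temperature is an exponential filter of air
   temperature (e-folding time 10 d).  The balance closes identically:
   Δstorage = infiltration − evaporation − transpiration − leakage.

2. **10-minute reactive chemistry** (six sub-steps per hour), in the
   order: feedstock dissolution at the previous sub-step's pH → solute
   update → coupled exchange/carbonate solve → pedogenic carbonate →
   CO₂ efflux and DIC leaching.  The explicit (lagged-pH) weathering
   coupling is a known O(Δt) splitting error.

3. **Daily biology.**  Soil organic carbon, nutrient budgets and the crop
   run once per day on the *previous* day's aggregated chemistry
   (time-mean pH, summed transpiration, mean saturation) so causality
   within the splitting is unambiguous.

## Weathering

Dissolution rates follow the acid/neutral/base multi-mechanism form with
log₁₀ rate constants at 25 °C, Arrhenius activation energies and H⁺
reaction orders transcribed from the public Palandri–Kharaka (USGS
OFR 2004-1068) compilation into `data/minerals.csv` (one source tag per
row; ferroactinolite is proxied by tremolite kinetics for lack of a
dedicated amphibole entry).  Two factors modify the laboratory law: a
linear effective-saturation factor (only wetted mineral surface
dissolves) and the dimensionless dissolution factor `F_D` for
uncharacterised field effects (`F_D` multiplies the summed rate, which is
algebraically identical to multiplying each mechanism).  A `(1 − min(Ω,1))`
factor shuts dissolution off at saturation; Ω is evaluated only for
calcite — silicates are treated as permanently far from equilibrium,
which is the case with first-order consequences (pedogenic carbonate)
handled explicitly.

Each application event creates per-mineral cohorts with reactive surface
area `rate × fraction × SSA`; area then shrinks as `(m/m₀)^(2/3)`
(shrinking-particle geometry).  Mineral fractions may sum to less than
one; the remainder is inert mass.  The default specific surface area is
3000 m² kg⁻¹ (BET of milled basalt fines; literature values span roughly
1–10 m² g⁻¹) and is an input, not a fitted constant — CDR magnitudes
scale almost linearly with it.  Dissolved moles per sub-step are capped
at the remaining stock, which at 10-minute steps binds only in
deliberately extreme configurations.

## Aqueous chemistry

Solutions are ideal (unit activity coefficients): porewater at the
simulated concentrations is dilute, and no activity-correction hook is
currently implemented.  Alkalinity is always *recomputed* from the solute
pools (the conservative charge balance over Ca, Mg, K, Na, NH₄, NO₃,
residual anions and TPO₄, the last with charge −1 as a documented
simplification of its mixed speciation); it is never integrated as an
independent state, so the alkalinity identity holds to round-off by
construction.  Aluminium is tracked as a conservative mobile pool and
excluded from the charge balance.

The open-system carbonate equilibrium reduces exactly to a cubic in
h = [H⁺]:

    h³ + ALK·h² − (K_H·K₁·pCO₂ + K_w)·h − 2·K_H·K₁·K₂·pCO₂ = 0

with exactly one positive root, found by bracketed Newton with bisection
fallback to machine precision (charge-balance residual ≪ 10⁻¹⁰ mol m⁻³).
Constants at 25 °C (pK_H 1.47, pK₁ 6.35, pK₂ 10.33, pK_w 14, calcite
pK_sp 8.48) are van 't Hoff-corrected with standard reaction enthalpies.

**Cation exchange** is a Gaines–Thomas equilibrium over Ca, Mg, K and Na.
With equivalent fractions `E_j` and activities `a_j` (mol L⁻¹), the
pairwise relations collapse onto a single exchange potential `u`
(`E_j = (k_j·u)^(z_j/2)·a_j`, reference `k_Ca = 1`); for a fixed
potential the per-cation partition between solution and exchanger is
closed-form, so the whole equilibrium is one monotone scalar equation in
`u`, solved by warm-started safeguarded Newton.  Base-cation mass is
conserved exactly by construction.  Shipped selectivities (k_Mg 1.0,
k_K 0.2, k_Na 0.05) preserve the classic Ca > Mg > K > Na retention
sequence.  Exchangeable acidity is an H⁺ species whose solution activity
is set by the ambient pH and is *not* mass-conserved (the carbonate
system buffers protons); its selectivity (default 10⁸) is a calibration
parameter controlling how base saturation responds to pH.

**Exchange–pH coupling.**  Because the exchanger stock (CEC, default
50 mol_c m⁻², i.e. ~15 cmol_c kg⁻¹ over 30 cm) dwarfs the dissolved
stock, lagging exchange behind the pH solve is violently unstable.  The
two are therefore solved together each sub-step as one scalar root find
in pH: a trial pH fixes the exchange state and hence ALK, the charge
balance then yields pCO₂ in closed form, and the only residual is total
inorganic-carbon mass, monotone in pH.  A bracketed Illinois iteration
from the previous sub-step's root converges in a handful of evaluations.

**Gas transport.**  Gas and aqueous CO₂ are equilibrated instantaneously
within each sub-step (their equilibration is much faster than carbonate
mineral kinetics); the finite soil-air reservoir vents by a single
effective conductance — Millington–Quirk diffusivity
`D₀(T)·ε^(10/3)/φ²` over the half-layer length, with advection folded in.
Negative efflux (atmospheric invasion) is allowed.

**Pedogenic carbonate** precipitates at `k_p·(Ω − 1)` and dissolves
existing mineral at `k_p·(1 − Ω)` (k_p default 0.5 g C m⁻² d⁻¹ per unit
saturation departure, a free parameter), Ca and C moving 1:1;
Mg-carbonate is not represented.

## Soil biology and nutrients

The soil organic carbon scheme is MEND-lineage: lignin-like and
cellulose-like particulate C, mineral-associated C, dissolved C,
bacterial and fungal biomass, their extracellular enzymes,
plant-fed mycorrhizae and a POC-grazing earthworm pool.
Depolymerisation fluxes are Michaelis–Menten in substrate and first-order
in the producing enzyme; POC→MAOC routing saturates with MAOC occupancy
(Langmuir-style, half-constant 4000 g C m⁻²); litter (8 above/below
pools carrying their own element stoichiometry) decays linearly.
Microbial carbon-use efficiency emerges from yield (0.40), maintenance
and enzyme production rather than being prescribed.  Environmental
modifiers are Q10 = 2 referenced at 20 °C (capped at 1), a quadratic
moisture optimum at s_eff = 0.6, and a Gaussian pH optimum at 6.5
(σ = 1.5).  All rate parameters live in
`data/biogeochem_params.tsv` with units and a source tag; they are
defaults for a temperate agricultural topsoil, not site calibrations.

Element budgets close a full ledger daily.  Litter-released elements
split λ·(1−f_org,lea) to the mineral pool, λ·f_org,lea to organic
leaching and (1−λ) to a stable organic pool that re-mineralises in
proportion to carbon depolymerisation.  Microbial N and P
immobilisation/mineralisation closes stoichiometry against microbial
C:N = 8 and C:P = 50.  Nitrification, NH₃ volatilisation (rising with pH
through the NH₃/NH₄⁺ speciation fraction, pK_a 9.25), denitrification on
a high-saturation ramp, first-order secondary fixation and slow primary
release, proportional leaching (capped at the pool), and external
deposition/fertilisation complete the budgets.  NH₄⁺ and phosphate clay
exchange are deliberately absent.

## Vegetation

A single canopy with a light-use-efficiency surrogate for
photosynthesis: `GPP = LUE · 0.45·SW·(1−e^(−0.5·LAI)) · f_T · f_water ·
f_nutrient`.  Plant water stress uses a gentler effective-saturation ramp
(0.15–0.50) than the bucket's own transpiration limit, acknowledging
that crops bridge dry spells with water below the lumped layer; the water
*ledger* still only ever supplies what the bucket holds.  Nutrient
stress is the N/P/K structural-stoichiometry satisfaction, floored at
0.25.  Maintenance respiration is paid from the NSC pool (starvation
suppresses growth), growth carries a 25% respiration surcharge, and all
respired C is routed into the soil-air CO₂ pool, so NEE = Re − GPP holds
identically.  Uptake combines a transpiration-stream passive term with
Michaelis–Menten active transport scaled by fine-root mass and demand,
suppressed linearly once a reserve passes 80% of its maximum — Na and
residual anions passive-only, Al never.  Traits for maize, soybean
(higher Ca targets, N fixation), sorghum and grass differ only via their
trait sets; target stoichiometries for Ca, Mg and Si are calibration
parameters.  Harvest exports a configurable fraction of aboveground
carbon and elements and sends the residue to litter.

## Scenario design

`mesocosm_sorghum` applies 5 kg m⁻² of an olivine/anorthite-free
plagioclase(albite-kinetics)/pyroxene/chlorite assemblage at
1.2 m² g⁻¹ with F_D = 0.5.  The assemblage is deliberately in the
non-depleting kinetic regime: olivine and anorthite dissolve 40–100%
within 121 days at any realistic surface area, and once a phase depletes,
cumulative release is sub-linear in F_D for reasons that have nothing to
do with the pH feedback the scenario exists to demonstrate.  With this
assemblage, freezing the weathering pH makes cumulative alkalinity
release scale almost exactly linearly in F_D, so the residual
sub-linearity under the live pH feedback isolates the coupling.

`illinois_maize_soy` (and `_xrd`) encode a four-year maize–soy
rotation with annual 5 kg m⁻² applications to a 30 cm layer, F_D = 1,
and two alternative basalt characterisations (19.6/11.6/25.6/36.3/5.2%
albite/ferroactinolite/epidote/chlorite/quartz, versus
23.3/11.9/17.8/34/9% plus 2.6% calcite, epidote standing in for
piemontite).  Reproducing the original field observations requires the
site's meteorological forcing and measurements, which are external; the
packaged config runs on any user-supplied or synthesised forcing.

## Synthetic forcing

The generator emulates: annual and diurnal temperature sinusoids with
bounded AR(1) noise; marked-Poisson storm arrivals (default 0.3 d⁻¹)
with exponential depths whose mean is fixed by the configured annual
total, so the expected rainfall is exact and sample totals obey the law
of large numbers; a clear-sky-shaped shortwave cycle damped on storm
days; and plausible humidity, wind and pressure.  It does **not** emulate
storm clustering and frontal systems, heat waves, co-variation of
humidity and rain beyond a wet-day offset, interannual climate modes, or
CO₂ trends.  Tests passing on this forcing therefore demonstrate internal
consistency (conservation, causality, monotonicity, coupling behaviour)
under realistic statistics — not agreement with any particular site.

## Numerical choices and problem sizes

* All state is double precision; the simulation itself is deterministic —
  every source of randomness lives in the forcing generator's single seed.
* Spin-up recycles a forcing record with no feedstock, reports per-pool
  relative drift over the final cycle and warns above 1%; the slow
  residual drift is a genuine alkalinisation creep from deposition and
  primary-mineral release, not a solver artefact.
* Pool-depletion guards: every first-order loss is capped at its pool;
  the daily SOC step retries at half the time step (up to 4 halvings)
  before raising an internal conservation error.
* The conservation audit compares the whole-system element inventory
  (soil organic + litter + plant + solution + exchanger + primary +
  secondary + feedstock + inorganic C + pedogenic carbonate) against
  cumulative external inputs minus exports; in the shipped tests the
  residuals sit at 10⁻¹⁴–10⁻¹³ relative against a 10⁻⁶ requirement.
* Test and acceptance problem sizes were chosen for desk-scale runtimes:
  the conservation audit uses a 4-year treated run, the application-rate
  monotonicity experiment five 2-year runs, the spin-up settling check
  1 + 2 + 4 cycles of a 180-day record, and the mesocosm experiment four
  121-day runs.

## Known limitations

* No vertical structure: a single moisture, temperature, pH and
  concentration represents the whole layer; porewater pH stands in for
  bulk-soil pH.
* Ideal-solution chemistry; no ion pairing or Al speciation ladder.
* Silicate saturation states are not computed (no secondary-clay
  thermodynamics beyond a first-order Si fixation sink), so very high
  alkalinity porewaters weather silicates faster than reality would.
* The crop surrogate has no leaf-level biochemistry, phenology detail or
  reproductive allocation dynamics; LUE and tissue stoichiometries are
  the main calibration levers.
* Effective CDR is accounted at the bottom of the active layer; transport
  through deeper soil, aquifers and rivers (where further degassing or
  carbonate precipitation can occur) is out of scope.
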