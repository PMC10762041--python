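# Methods

## Scope and state

The simulator reconstructs phosphorus pools in the 0–0.3 m layer of
cropland and grassland soils on an annual grid, driven by reconstructed P
inputs/outputs and a daily process model of pool exchanges. Per cell and
land cover it tracks seven pools: inorganic P in solution (`i_sol`),
labile inorganic P (`i_lab`), moderately labile inorganic P bound on
secondary minerals (`i_sec`), primary mineral (apatite) P (`i_prim`),
labile and stable organic P (`o_lab`, `o_sta`), and occluded P (`x_occ`).
Internally all pools are concentrations (mgP per kg fine earth); the
external interface uses areal amounts (kgP ha⁻¹) with the conversion
factor `bulk_density × (1 − coarse_fragment_fraction) × 0.3 m × 10⁴ m²/ha
× 10⁻⁶ kg/mg` applied only at module boundaries. The layer depth is fixed
at 0.3 m everywhere; plough-layer thickness data do not exist at the
scales of interest, and the roots of most annual crops are concentrated in
this horizon.

## Daily dynamics

Within each day, gross fluxes are evaluated from start-of-day pools:

- occlusion `k_sec_to_occ · P_i-sec` and de-occlusion
  `k_occ_to_sec · P_x-occ`;
- Freundlich sorption out of solution
  `k_sol_to_sec · (P_i-sol / W_abs)^b` toward the secondary pool, with
  first-order desorption `k_sec_to_sol · P_i-sec` back;
- weathering `k_weathering · g1(T_soil) · g2(W_rel) · P_i-prim` into the
  labile pool, with `g1` a Q₁₀ = 2.4 response referenced at 15 °C and
  `g2 = W_rel`;
- mineralization `k_min · h1(T_soil) · h2(W_rel)` of both organic pools
  into the labile pool, with `h1` a Q₁₀ = 2 response referenced at 30 °C
  and `h2 = max(0, −1.1 W_rel² + 2.4 W_rel − 0.29)`.

`h2` is clamped at zero below `W_rel ≈ 0.13` where the quadratic is
negative: a negative scalar would silently reverse the direction of
mineralization, which the rate law does not intend.

Pools are then updated, and finally the running sum `P_i-sol + P_i-lab` is
redistributed by the assumed instantaneous solution–labile equilibrium
`k_sol_to_lab (P_i-sol/W_abs)^b = k_lab_to_sol P_i-lab`.

### Clamping

Several realistic parameter combinations produce gross daily outflows that
exceed the pool they leave (see "Parameter consistency" below). To keep
pools non-negative without constraining the parameters, each pool's
outflows are rescaled by a common factor so the pool lands exactly at zero
when its start-of-day content plus inflows cannot cover them. Because
rescaling one pool's outflows shrinks another's inflows, the factors are
iterated to a fixed point (they decrease monotonically, so the iteration
converges; in practice two or three sweeps suffice). Scaled fluxes remain
identical on their source and destination sides, so the daily step
conserves total P to float rounding. Alternative semantics (clamping each
gross flux, or each pool-pair net flux) would be order-dependent or could
still drive pools negative; the per-pool proportional rule is the simplest
order-independent choice.

### Equilibrium solver

Substituting `P_i-lab = S − P_i-sol` into the equilibrium condition gives
a scalar root problem in `P_i-sol` on `[0, S]`, strictly increasing with
opposite signs at the ends. It is solved by a bracketed Newton iteration,
vectorised over all cells/members, with two safeguards: tangent steps that
land marginally outside the shrinking bracket are clipped just inside it,
and every third iteration falls back to the bracket midpoint so progress
is guaranteed. Iteration stops when the bracket width reaches float64
spacing or the residual falls below ~32 ulp of the equation's dominant
term; converged cells are removed from the active set, so a whole ensemble
costs little more than its slowest cell. The previous day's solution seeds
the iteration. The returned pair is re-derived so `P_i-sol + P_i-lab`
equals the input sum bit-exactly. The solver is cross-checked in the tests
against scipy's scalar Brent bracketing on random parameter draws (1,000
draws, agreement to 1e-8).

## Annual budget application

On the first day of each year, in order: erosion removes
`frac_loss × pool` from every pool except `i_sol` (dissolved P is not part
of the eroded soil mass), computed from start-of-year pools; inputs are
added (chemical fertilizer to `i_lab`; manure, residues and sludge split
0.8/0.1/0.1 and 0.4/0.4/0.2 over `i_lab`/`o_lab`/`o_sta`, sludge like
manure; deposition split between `i_lab` and `i_prim`); plant uptake is
removed from `i_lab`. If the combined `i_sol + i_lab` would go negative it
is zeroed and the shortfall recorded as unsatisfied uptake (`fP_upns`) —
an expected model outcome, not an error. If `i_lab` alone goes negative
while the pair is still non-negative, the pair is parked in `i_sol` (only
the sum matters before the first equilibrium redistribution). The year
then integrates 365 daily steps; no leap years, since all forcing is
annual and a calendar would add nothing.

The annual mass balance `Δ(total P) = inputs − erosion − satisfied uptake`
closes by construction; the test suite verifies closure to better than
1e-9 relative per cell-year on 20 independently seeded worlds.

## Parameters

Flux parameters are built once per cell and held constant in time:

- `b`, `k_lab_to_sol`, `k_sol_to_sec`, `k_sec_to_occ` come from pedotransfer
  regressions against sand/clay/silt percentages, soil pH, soil carbon,
  mean annual near-surface air temperature, and the steady-state pool
  fractions `f_m = P_m,∞ / (P_i-sol,∞ + P_i-lab,∞ + P_i-sec,∞ + P_x-occ,∞)`
  (oxalate-free variants of the published isotope-exchange calibration,
  since gridded oxalate data are unavailable at scale);
- `k_sol_to_lab`, `k_sec_to_sol`, `k_occ_to_sec` follow from the
  steady-state ratio identities, which then hold to machine precision by
  construction, e.g. `k_occ_to_sec / k_sec_to_occ = f_i-sec / f_x-occ`;
- the steady state is pinned to the natural-soil pools, with the solution
  pool at `P_c,∞ · W̄_abs` where `P_c,∞ = 0.1 mgP L⁻¹` by default
  (configurable; the global averages are known to be sensitive to it at
  its low end) and `W̄_abs` is the temporal mean soil water content over
  the whole simulation period;
- `k_weathering = 2.7e-7 day⁻¹`; mineralization presets
  `v1.0 = (2.7e-5, 2.7e-4)` and `v1.1 = (1.8e-4, 1.4e-3) day⁻¹` for
  (stable, labile) — v1.1 (residence times 15 and 2 years) is the default
  because the longer residence times let grassland pools drift through the
  early simulation decades instead of stabilising.

The linear regression for `k_lab_to_sol` can return non-positive values on
carbon- or silt-rich soils with labile-dominated pools; such cells are
floored at 1e-6 day⁻¹ with a logged warning, because a non-positive
desorption rate makes the equilibrium problem ill-posed. This floor is a
deliberate deviation from leaving parameters unconstrained, and is
reported per cell.

### Parameter consistency

`check_parameter_consistency` flags, without mutating anything, cells
where a daily step could move more than a pool's content through one gross
flux: `k_sec_to_sol ≥ 1 day⁻¹`, and `k_sol_to_sec ≥ W̄_abs · P_c,∞^(1−b)`
(the sorption flux at the steady solution concentration equalling the
solution pool). The second bound is routinely exceeded by orders of
magnitude under realistic parameters — resolving it would need ~5-minute
steps — which is exactly what the clamp absorbs. The practical consequence
of the daily step, verified as a sign property in the tests, is that a
coarse step throttles the solution→secondary cascade and leaves more of a
positive P budget in the labile pool than a refined step would.

## Drivers

Annual P inputs/outputs per cell × land cover are assembled from:

- **manure**: a gridded manure-N field times a P:N ratio of 0.20
  (estimate 1), and the same field rescaled per country so its 1950–2017
  mean matches a national manure-P production table (estimate 2, which by
  construction reproduces the national means); the run uses their mean or
  either estimate;
- **chemical fertilizer**: grassland N fertilizer times P:N = 0.22; the
  cropland field is the total-P map corrected by subtracting the grassland
  share per unit cropland area (floored at zero);
- **grassland uptake/residues**: from total NPP split 0.46/0.54 above/
  belowground, organ P concentrations (aboveground 8.8e-2 gP/100 gFM, the
  mean of the bounds 2.5e-2 and 1.5e-1; belowground half of that), organ
  lifespans 0.8/0.7 yr over a 1-yr season, carbon and dry-matter contents
  0.45 kgC/kgDM and 0.20 kgDM/kgFM; residues are `(1 − GI) × uptake` with
  GI the grazed/mowed share of NPP. Two NPP estimates (a model-based field
  and the same field scaled by 979/460 to a field-derived global mean)
  bracket the uncertainty;
- **cropland uptake/residues**: per crop from fresh-matter yield, harvest
  index, root:shoot ratio (`1/frac_above − 1`) and organ P concentrations
  (root P at 0.75 of non-harvest aboveground P), assuming equal dry-matter
  proportions across organs at harvest so the dry ratios cancel; half of
  the non-harvest aboveground biomass is returned for ordinary crops, none
  for forage crops, and roots always remain. Yields and harvested areas
  extend a reference-year (2000) spatial map with national time series;
  before 1961 yields scale with national population and areas are frozen.
  For root crops the harvested organ is the root: the harvest index is
  applied to root biomass and the residue fraction to aboveground biomass
  — a symmetric variant adopted here because the exact published
  root-crop equations are in supplementary material not available to this
  implementation;
- **deposition**: static dust/sea-salt/biogenic/natural-combustion fields
  plus an anthropogenic-combustion field scaled year-by-year by a
  normalised emission series; a second, later series is spliced on with a
  single multiplicative correction equalising the overlap-period means.
  10% of dust and 50% of the other components enter `i_lab`, the rest
  `i_prim`;
- **sludge** (cropland only): per-capita P excretion times population
  times `Σ_type frac_treat × NR` with removal efficiencies
  NR = (0.10, 0.45, 0.90) for treatment types 1–3, divided by national
  cropland area; anchors at 1970/2010-style years are linearly
  interpolated and held flat outside;
- **erosion**: gross soil loss divided by the 0–0.3 m soil mass per
  hectare, capped at 1 yr⁻¹, constant in time.

## Land-use bookkeeping

Four covers (crop, grass, nonagri, urban) partition each cell; raw
12-class fractions/transitions aggregate onto them. Each year, before the
budget application, the receiving cover's pools become the area-weighted
mix of retained soil and incoming soil, with nonagri sources carrying the
natural-soil pools (solution pool at `P_c,∞ · W̄_abs`) and urban sources
carrying zero. A cover whose fraction reaches zero stores zero pools — its
weight in any later mix is zero, so the convention is observationally
neutral, and re-expansion is fully determined by incoming transitions.
Initial (first-year) cropland and grassland pools equal the natural-soil
pools. Crop↔grass exchanges conserve fraction-weighted P exactly (verified
to 1e-12). Transition uncertainty is not sampled: perturbing transitions
independently would break the fraction-consistency identity.

## Uncertainty propagation

Default family assignment per variable (a configurable mapping, since the
authoritative per-variable table is supplementary material unavailable
here): uniform between the two estimates for manure and for the residue
composition fractions (±50% around their defaults); two-estimate normal
(σ = range/4, so ~95% of draws fall between the estimates) for grassland
NPP and the grass P concentration; relative normal (σ = 15% of the mean)
for grassland chemical fertilizer, cropland uptake, deposition, erosion,
the natural pools, climate and soil properties; σ = 25% for sludge.
Perturbed textures are renormalised to sum to 100. Truncation is at zero
for P fluxes and at the spatial min/max of the mean field for state-like
drivers (natural pools, climate, soil), implemented by re-drawing (up to
100 times, then clipping with a warning) so no probability mass piles up
at the bounds. Cells and years are independent. Cropland uptake and
residues share one multiplicative perturbation because both are linear in
the same underlying yields.

An ensemble stacks all members into one batched state, so the daily
stepping is vectorised over members × covers × cells; a separate mean run
uses every driver's mean. Spread is summarised as the coefficient of
variation with the population standard deviation (fixed choice for
reproducibility), masked where the mean is non-positive. Everything is
driven by one seeded generator: reruns are bit-identical.

## Synthetic world

`make_world` generates the full driver stack on a small grid (default
10×10 cells, 4 contiguous equal-area countries, 1950–2018): white-noise
soil properties and natural pools in field-plausible ranges (chemical
fertilizer up to ~40 kgP ha⁻¹ yr⁻¹, natural total P of order 100–3000
kgP ha⁻¹, NPP 2–8 tC ha⁻¹ yr⁻¹), a land-use history built forward from
random transitions so the fraction-consistency identity holds by
construction, national tables loosely tied to the gridded fields, and two
estimates per uncertain driver. It emulates the shapes, units and
couplings of real data but not spatial covariance, so passing tests
demonstrate correctness of the machinery, not realism of any map.
`make_steady_world` zeroes all inputs/outputs, freezes climate and land
use, and starts pools at the natural values, where occlusion and
de-occlusion balance exactly at t = 0 and the organic pools decay at their
closed-form daily-compounded rates — the harness for the conservation and
decay tests. The default test period (1950 start rather than 1900) keeps
full-pipeline tests fast; a 1900 start is available in the config.

## Numerical and policy choices

- Year length 365 days, no leap years.
- Mass-balance closure asserted to 1e-9 relative; observed ~1e-14.
- Equilibrium solver convergence: bracket at float64 spacing or residual
  ≤ ~32 ulp of the equation scale; oracle agreement asserted to 1e-8.
- The tiny negative remainders that proportional splitting of sampled
  composition fractions can produce (≈1 ulp) are clipped to zero.
- NetCDF output uses the NetCDF-3 classic format via xarray/scipy, with
  `units` attributes (`kgP ha-1`, `kgP ha-1 yr-1`) and a land-area
  variable for computing large-scale averages.
- Decile comparison uses average ranks before the quantile cut, so
  detection-limit plateaus in observational datasets share a label instead
  of being ordered arbitrarily.

## Known limitations

- Organic P dynamics are first-order with fixed rates: no biochemical
  mineralization, no coupling to carbon or microbial pools; the two
  mineralization presets bracket, but do not resolve, that structural
  uncertainty.
- Daily stepping biases the labile/secondary split where the sorption
  coefficient exceeds its consistency bound (the common case); the bias is
  a few percent globally but can reach ±15–20% locally.
- Plant uptake is prescribed annually and removed from the labile pool on
  day one; there is no feedback from simulated availability to uptake
  beyond the shortfall cap.
- Parameters do not distinguish cropland from grassland soils, and the
  steady-state used to pin them is the current unmanaged-soil state.
- The synthetic world has no spatial covariance structure and uniform cell
  areas; country geometries are static.
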