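# Methods

This note documents the models implemented in `dermadose`, the parameter
choices behind them, and what the shipped fixtures and tests do and do not
establish. Every constant discussed here lives in
`src/dermadose/parameters.py`; the package contains no other tuning knobs.

## Skin penetration model

### Geometry and discretization

The skin is a 1-D composite of stratum corneum (SC), viable epidermis
(VE, 100 µm) and dermis, terminated by a perfect sink (concentration zero)
at 2 mm depth, where cleared permeant is credited to the systemic
circulation. The SC is 13 µm thick when partially hydrated and 25 µm when
fully hydrated (occlusion, or aqueous vehicle loads of at least
100 mg/cm²).

Two parallel domains are solved with no mass exchange between them:

* **Lipid pathway** — SC lipid phase, then VE and dermis at full area.
* **Polar pathway** — water-filled pores through the SC at an area
  fraction `f_polar = 1e-5`, opening below the SC into a full-area copy of
  the viable tissue. The polar SC is always fully hydrated.

Because the domains cannot exchange solute, their summed output is an
upper limit on systemic delivery. Each domain is discretized by a
conservative finite-volume method of lines (SC 20, VE 10, dermis 20 cells
by default) on the water-referenced concentration `psi = C/K`, which is
continuous across layer interfaces; inter-cell conductances are harmonic
means of `D·K` over the half-cells. The resulting stiff ODE system
(~100 states including the vehicle and ledger states) is integrated with
an implicit BDF scheme (`scipy.integrate.solve_ivp`), analytic Jacobian,
relative tolerance 1e-6. Application and wipe-off events are exact
integration breakpoints, never smoothed; when a neat vehicle empties, a
terminal integration event switches the surface boundary condition (the
surface activity is *not* switched inside the right-hand side — a
discontinuity there stalls the implicit integrator).

Mass conservation is structural: the ledger (vehicle + evaporated +
removed + layer contents + cleared) closes to solver precision (~1e-14
relative in practice; the contract in the tests is 0.5%). Halving the
spatial step changes the total cleared amount by well under 1%, and a
degenerate single-membrane configuration reproduces the analytic lag-time
series solution to better than 1% (0.01% after refinement).

### Transport parameters

For a permeant with molar mass `MW`, octanol–water partition coefficient
`Kow` and ionizable groups with known pKa:

* **Ionization.** Henderson–Hasselbalch at the skin surface pH 5.5 gives
  the neutral fraction `f_n`. Only the neutral species partitions into SC
  lipids and evaporates; the polar pathway carries total (neutral +
  ionized) permeant.
* **SC lipids.** `K_sc = f_n · Kow^0.69` (the standard SC lipid/water
  power law applied to the neutral species);
  `D_sc = D0 · 10^(−0.0061·MW)` cm²/h — the Potts–Guy molecular-weight
  slope. Full hydration multiplies `D_sc` by 3, a net permeability
  increase of ×1.56 after the swollen thickness.
* **Prefactor `D0 = 2.5e-7 cm²/h`.** This is the package's deliberate,
  conservative in-vivo default, roughly an order of magnitude below the
  value implied by in-vitro permeability correlations. Two considerations
  fix it: in-vivo barriers (desquamation, partial follicle occlusion,
  incomplete hydration) reduce effective permeability relative to excised
  skin, and — decisive for the default — it is the value at which the nine
  reference study designs reproduce their published finite/infinite
  kinetics classes: repeated neat dosing of the most permeable hydrophilic
  solvent in the set accumulates a surface reservoir rather than draining
  it within each dosing interval. Users fitting experimental flux data
  should expect to raise `D0` (all nine reference chemicals then shift
  toward higher absolute fluxes together).
* **Polar pathway.** Free aqueous diffusivity
  `D_free = 0.116 · MW^(−1/3)` cm²/h (Stokes–Einstein-type), hindered by a
  factor 0.05 inside the pores; `K = 1`.
* **Viable tissue.** `D = 0.3 · D_free` (tortuosity and volume
  exclusion); `K_ve = K_de = 0.68 / fu_tissue` with
  `fu_t = 1/(1 + 0.5(1−fu_p)/fu_p)` — tissue binding at half the plasma
  binding-site density, so the model tracks unbound-driven transport.
* **Evaporation.** Gas-side mass transfer from laminar flat-plate
  boundary-layer theory (`Sh = 0.664 Re^1/2 Sc^1/3`, 10 cm plate,
  0.17 m/s wind, 32 °C) combined with Raoult-type vapor–liquid
  equilibrium. The coefficient acts on the water-referenced surface
  concentration, is strictly increasing in vapor pressure, zero for
  non-volatile permeants and zero under occlusion. For a largely ionized
  acid (thioglycolic acid, pKa 3.67, >98% ionized at pH 5.5) the neutral
  fraction suppresses evaporation accordingly; without that factor its
  infinite-dose reference would lose >10% of the applied dose to air and
  be invalid under the 1% vehicle-constancy criterion.

### Vehicle thermodynamics

The surface film is well-stirred. Permeant activity equals its volume
fraction in the (permeant + water) film; the water-referenced driving
concentration is `activity × S_eff`, where `S_eff` is the aqueous
solubility for sparingly soluble chemicals and the neat-liquid
concentration (`density × 1e6` µg/cm³) for water-miscible ones. For a
dilute aqueous solution of a miscible solvent this reduces exactly to the
solution concentration; for a neat sparingly-soluble chemical it is the
saturated aqueous concentration (unit activity). This reproduces the
solubility-driven retention of hydrophilic solvents in large water
vehicles. Limitations: activity coefficients are unity (no enhancement or
salting-out), the water content of the film is constant between events (no
solvent evaporation dynamics), and the 1:1 ethanol–water vehicle of the
thioglycolic acid study is treated as water.

Wipe-off events remove all surface material (vehicle-resident permeant and
water); skin-resident permeant stays. "Semi-occluded" protocols are
simulated as occluded.

## Dosimetry

`K_m` (body weight / body surface area) factors: human 37 (60 kg, 1.6 m²),
rat 6, mouse 3, rabbit 12. Average steady-state flux is the trapezoidal
time-average of the total cleared flux over a dosing interval
`[nτ, (n+1)τ]`, with `n` the last complete interval capped at 10 (the
shipped protocols run 10–24 days, so the window is the n = 7–10 interval
range customary for repeated-dose steady-state reporting); the cumulative
amount uses the final 24 h interval, the maximum cleared per interval. A
finite-dose run is *infinite-dose equivalent* when its average flux is
within 4% of the single 10⁷ µg/cm² reference, which must itself stay
within 1% of the applied dose (otherwise it is rejected as a reference).

Study-design fixtures: the human application areas shipped with the nine
designs are the BSA-scaled areas that close the published dose-conversion
chains; dose-per-area values are computed at run time from the animal
doses. The fixture file flags plasma unbound fractions, pKa, solubility,
density and vehicle loads as assumed values — they are not reported in the
original studies.

## PBPK model

Fifteen perfusion-limited tissue compartments plus venous and arterial
blood; the lung carries total cardiac output (4.83 L/h/kg) in series, and
gut and spleen drain through the liver inlet. Hepatic blood flow
(arterial 0.35 + portal 1.15 L/h/kg) totals 1.5 L/h/kg so that an
extraction ratio of 0.1 gives the default clearance of 0.15 L/h/kg.
Elimination removes a fixed fraction of the permeant *entering* the liver
(well-stirred convention referenced to incoming blood), which makes the
steady state exactly `C_p,ss = R / (24 CL)` for any partition-coefficient
set — the trajectories depend on the Kp values, the steady state does not.
Blood:plasma ratio is 1, so venous blood and plasma concentrations
coincide (the assumption is documented, not estimable from the available
inputs).

Partition coefficients come from a tissue-composition calculation: water,
neutral lipid and phospholipid fractions per tissue, with the neutral
species (ionization at pH 7.4) distributing into neutral lipid plus 30% of
phospholipid according to `Kow` (vegetable-oil lipophilicity
`log P_oil = 1.115 log Kow − 1.35` for adipose) and binding carried by the
`fu_plasma / fu_tissue` ratio. This composition-based scheme was written
for this package; since the steady state is Kp-independent under the
model's own assumptions, the choice affects transient trajectories only.

`simulate_infusion` integrates in 24 h blocks until the venous
concentration changes by <0.1% per block, then reports an
Aitken-extrapolated limit of the geometric tail: for lipophilic chemicals
the slowest (adipose) pole would otherwise leave the raw final value
several tenths of a percent short of the true steady state. The exact
linear-solve steady state (`steady_state_closed_form`) is the default in
the batch workflow; the two agree to the integration tolerance.

## Exposure conversion factor

`ECF = C_p,ss / D_human`, computed against both denominator conventions —
per µg/cm²/day (area basis) and per mg/kg/day (body-weight basis) — and
labelled accordingly, since published usage varies.

## What the fixtures and tests show — and what they do not

The shipped study designs exercise every model feature (occlusion,
volatility, ionization, aqueous vehicles, removal events, finite and
infinite kinetics), and the synthetic-chemical generator spans
logKow ∈ [−2, 4], MW ∈ [70, 350] and vapor pressures up to 10 mmHg for
property-based tests. Passing tests establish internal consistency: exact
dose-conversion arithmetic, mass conservation, agreement with closed-form
diffusion and PBPK limits, and the qualitative ordering of exposure
scenarios (no-removal ≥ removal, finite ≤ infinite, occluded ≥ open for
volatile chemicals, dose-independent plasma levels for all-infinite-dose
designs).

They do **not** validate absolute fluxes against experiment: the
parameterization is a documented reconstruction, and with the conservative
`D0` the absolute fluxes for several reference chemicals sit one to two
orders of magnitude below values obtained from fully calibrated in-vivo
skin models. Relative comparisons between scenarios — the package's
purpose — are far less sensitive to `D0` than absolute fluxes.

## Known limitations

* One-way coupling: the skin model's 2 mm and plasma sinks ignore
  redistribution from the circulation back into skin; `C_p,ss` is an upper
  limit for low-clearance chemicals and the flux an upper limit for
  chemicals with strong dermal binding.
* No cutaneous or extra-hepatic metabolism, no metabolite tracking, no
  saturable clearance.
* No solvent co-diffusion or vehicle evaporation; no appendageal (hair
  follicle, sweat duct) transport beyond the homogenized polar pathway.
* Reversible keratin binding is absorbed into equilibrium partition
  coefficients; no explicit binding kinetics.
* Single deterministic physiology; no population variability.
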