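# dermadose

Forward and reverse dosimetry for the dermal route: a transient
finite-dose skin penetration simulator coupled to a generic whole-body
physiologically based pharmacokinetic (PBPK) model.

## The problem

Dermal toxicity studies apply chemicals to animal skin under very
heterogeneous protocols — neat or in an aqueous vehicle, occluded or open,
wiped off daily or left in place — without considering the kinetics of skin
penetration. Risk assessment based on the *internal* dose (the steady-state
plasma concentration `C_p,ss`) rather than the applied external dose
requires simulating those kinetics explicitly. `dermadose` is for risk
assessors and pharmacokinetic modellers who need to ask: *given this
application protocol, what plasma concentration does a dermal dose produce
— and, in reverse, what external dose corresponds to an internal effect
concentration?*

## The model

**Dose scaling.** Animal doses (mg/kg/day) are converted to human
equivalent doses by body-surface-area scaling, `HED = dose x K_m,a / K_m,h`
with `K_m = BW / BSA` (human: 37, for a 60 kg, 1.6 m² adult; rat: 6), and
expressed per unit application area, `D_human = HED x BW x 1000 / A`
(µg/cm²/day).

**Skin penetration.** A 1-D transient two-pathway model: a well-stirred
surface vehicle (permeant + optional water, Raoult-type activity) on top of
stratum corneum, viable epidermis and dermis, with a perfect sink at 2 mm
depth. The lipid pathway carries the neutral species
(`K_sc = Kow^0.69`, diffusivity decreasing log-linearly with molar mass);
a parallel water-filled polar pathway (area fraction 1e-5) carries
hydrophilic and ionized permeant. Volatile permeant evaporates through a
boundary-layer mass-transfer coefficient (32 °C skin, 0.17 m/s wind);
occlusion zeroes evaporation and fully hydrates the stratum corneum.
Repeated applications and wipe-off events are exact integration
breakpoints of the stiff method-of-lines system.

**Aggregation.** The flux cleared from the dermis is summed over both
pathways, `J = J_lipid + J_polar`, and averaged over a late dosing
interval, `J̄_ss = (1/τ) ∫ J dt` over `[nτ, (n+1)τ]` (τ = 24 h). A run is
classified *infinite-dose* when its `J̄_ss` is within 4% of the flux from a
single 10⁷ µg/cm² application (valid only if that reference stays within
1% of the applied dose).

**PBPK.** `J̄_ss` times the application area becomes a constant infusion
(mg/kg/day) into the venous blood of a 15-compartment perfusion-limited
PBPK model (adipose … thymus, venous/arterial blood, lung in series, gut
and spleen portal). Elimination is linear hepatic extraction (ratio 0.1,
clearance 0.15 L/h/kg), so `C_p,ss = R / (24 CL)` exactly, independent of
the tissue partition coefficients.

**Reverse dosimetry.** The exposure conversion factor is
`ECF = C_p,ss / D_human`, reported per µg/cm²/day and per mg/kg/day.

The nine reference chemicals and study designs (Bayrepel, capsaicin, two
glycol ethers, dimethylformamide, 2-ethylhexanol, 2-methoxypropyl-acetate,
2-methoxyethanol, thioglycolic acid) ship as fixtures.

## Worked example

Convert the capsaicin maternal NOEL (64 mg/kg/day in the rat, applied on a
BSA-scaled human area of 1600 cm²):

```console
$ dermadose convert-dose --dose 64 --species rat --area 1600
{
  "animal_dose_mg_kg_day": 64.0,
  "HED_mg_kg_day": 10.378378378378379,
  "human_dose_ug_cm2_day": 389.1891891891892
}
```

A dermal flux that delivers 0.166 mg/kg/day gives, at a hepatic clearance
of 0.15 L/h/kg:

```console
$ dermadose pbpk-ss --rate 0.166
{
  "C_p_ss_mg_L": 0.04611111069966579
}
```

i.e. `C_p,ss = R / (24 CL) = 0.0461 mg/L`. Running the full chain for the
capsaicin study protocol (11 daily applications of 389.19 µg/cm²,
occluded, wiped 3 h after each application) and its no-removal variant:

```python
import dermadose as dd

design = {d.chemical.name: d for d in dd.load_studies()}["CAP"]
for r in dd.run_workflow(design, variants=("A", "B")).results:
    if r.dose_index == 0:
        print(r.variant, r.dosimetry.J_ss_ave, r.dosimetry.kinetics,
              r.C_p_ss, r.ECF_per_area)
```

```
CAP A: J_ss=0.0255 ug/cm2/h, kinetics=finite,   C_p_ss=4.540e-03 mg/L, ECF=1.167e-05
CAP B: J_ss=0.0386 ug/cm2/h, kinetics=infinite, C_p_ss=6.854e-03 mg/L, ECF=1.761e-05
```

The daily wipe makes the study protocol a finite-dose exposure: its
average steady-state flux (and hence `C_p,ss` and ECF) is about one third
lower than the no-removal protocol, which reaches infinite-dose kinetics.

The whole simulation matrix (scenarios A, B, occlusion toggles, water
dilutions for every chemical and dose) is one command:

```bash
dermadose matrix --out results/
```

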