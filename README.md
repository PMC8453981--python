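# capab

Thermodynamics and coupled-assay kinetics of ATP-dependent caprolactam
hydrolysis by the CapAB caprolactamase.

Caprolactam, the nylon-6 monomer, is opened by caprolactamase to
6-aminocaproic acid (6-ACA). The plain hydrolysis

    caprolactam + H₂O ⇌ 6-ACA

is strongly endergonic near neutral pH, which is why the enzyme couples
ring opening to ATP hydrolysis. This package is for enzymologists and
pathway engineers who want to (i) compute the pH-dependent free energy of
the reaction from microscopic pK constants, (ii) quantify coupled
ATPase/lactamase assays (initial rates, specific activities, coupling
stoichiometry, detection-limit-censored conversions), and (iii) generate
realistic synthetic progress curves for validating such analyses.

## Model

6-ACA has four protonation microspecies (cation, zwitterion, neutral,
anion) governed by three microscopic constants pK_A⁰ = 4.8 (carboxyl of
the neutral form), pK_A⁺ = 4.43 (carboxyl of the cation) and
pK_B⁻ = 10.75 (ammonium of the zwitterion). Relative to the neutral
species,

    6-ACA_tot / 6-ACA⁰ = 10^(pK_B⁻ + pK_A⁺ − pK_A⁰ − pH)
                       + 10^(pK_B⁻ − pK_A⁰) + 10^(pH − pK_A⁰) + 1

and the standard transformed free energy of hydrolysis at a given pH is

    ΔG₀′(pH) = ΔG_neutral − RT·ln[H₂O] − RT·ln(6-ACA_tot / 6-ACA⁰)

with ΔG_neutral = 67 kJ/mol for the uncharged reaction and [H₂O] = 55 M.
At pH 7 this gives ΔG₀′ = +23 kJ/mol; adding ΔG₀′(ATP) = −31 kJ/mol makes
the coupled reaction exergonic (−8 kJ/mol). Keeping only the dominant
microspecies costs at most RT·ln 2 = 1.7 kJ/mol.

The assay side estimates initial rates by ordinary least squares over the
early window (≤ 20 % conversion of the limiting substrate), converts
slopes to specific activities (U/mg, U = µmol/min), and reports coupling
ratios ΔADP/Δ6-ACA, fold-changes across conditions, and endpoint
conversions with values below the detection limit typed as censored
bounds (e.g. `<0.015`). The synthetic generator integrates a minimal
Michaelis-type scheme with saturable bicarbonate activation and
caprolactam-suppressed uncoupled ATPase, calibrated to the reported
reference activities (0.51/0.39 U/mg ADP/6-ACA formation at 50 mM
bicarbonate; 0.44 U/mg ATPase without caprolactam).

## Worked example

```python
>>> from capab import EnergeticsModel, dg_hydrolysis, dg_coupled
>>> model = EnergeticsModel()          # 67 kJ/mol, 55 M water, pK 4.8/4.43/10.75
>>> dg_hydrolysis(7.0, model)          # hydrolysis alone, pH 7
23.098673888825708
>>> dg_coupled(dg_hydrolysis(7.0, model), model)   # coupled to ATP -> ADP + Pi
-7.901326111174292
```

Hydrolysis alone is uphill by 23.1 kJ/mol at pH 7 (equilibrium strongly
favors the lactam); one ATP per turnover pushes it downhill by 7.9 kJ/mol.

The same numbers from the command line, plus the simulated assay panel
and its analysis report:

```sh
$ capab energetics --ph-min 6 --ph-max 8 --step 1
ph,dg_full_kj_mol,dg_dominant_kj_mol,dg_coupled_kj_mol
6.0,23.039897276871187,23.105779108442853,-7.960102723128813
7.0,23.098673888825708,23.105779108442853,-7.901326111174292
8.0,23.10070630559268,23.105779108442853,-7.899293694407319

$ capab run --out demo --seed 1
$ head -7 demo/assay_report.csv
# capab_version: 0.1.0
# lod_mM: 0.0003
# config_hash: 4bd8486c6804
# seed: 1
label,rate_adp_u_mg,rate_aca_u_mg,coupling_ratio,uncoupled_fraction,conversion_pct
entry1,0.535378451482961,0.3674399273785774,1.3349930830839665,0.8142938480817407,75.24296312153618
entry2,0.43595537943810386,—,—,—,—
```

Row `entry1` is the standard condition (2 mM caprolactam, 2 mM ATP,
50 mM bicarbonate): the recovered specific activities scatter around the
calibration targets 0.51 and 0.39 U/mg, the cumulative ATP/6-ACA coupling
ratio exceeds 1 because of uncoupled ATPase turnover, and conversion
plateaus short of 100 % as ATP is exhausted. `entry2` lacks caprolactam,
so ACA-dependent cells are dashed.

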