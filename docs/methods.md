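# Methods

## Speciation model

6-aminocaproic acid (6-ACA) carries a carboxyl and an amine, giving four
protonation microspecies: cation (COOH/NH₃⁺), zwitterion (COO⁻/NH₃⁺),
neutral (COOH/NH₂) and anion (COO⁻/NH₂). Three microscopic constants fix
the network — pK_A⁰ = 4.8 (carboxyl of the neutral form, estimated from
hexanoic acid), pK_A⁺ = 4.43 (carboxyl of the cation) and pK_B⁻ = 10.75
(ammonium of the zwitterion). The fourth constant, the ammonium pK of the
cation, is never accepted as input; it is always derived by thermodynamic
cycle closure as pK_A⁺ + pK_B⁻ − pK_A⁰ (= 10.38 with the defaults), since
only three constants are independent.

Abundances are referenced to the neutral species and handled as log₁₀
values internally; fractions are normalized with a log-sum-exp shift, so
any pH in [−2, 16] and widely spaced pK values cannot overflow. Ratios
are exponentiated only on output. pH is treated as activity-based
−log₁₀[H⁺] with no ionic-strength correction, and the pK values are
treated as temperature-independent.

`dominant_species` breaks exact ties deterministically: lower net-charge
magnitude wins, then neutral over zwitterion, then cation over anion.

## Free-energy model

The reference reaction is ring opening to the **neutral** 6-ACA species,
ΔG_neutral = +67 kJ/mol, consumed as an input constant (it originates
from composite quantum-chemistry calculations that this package does not
perform). Two corrections give the standard transformed free energy at a
stated pH:

    ΔG₀′(pH) = ΔG_neutral − RT·ln[H₂O] − RT·ln r(pH)

where r(pH) is the total-to-neutral speciation ratio. The speciation
exponents are base-10 and the free-energy logs are natural, exactly as
the model is defined. Defaults: [H₂O] = 55 mol/L (55.3/55.5 are common
alternatives and shift the pH 7 result by < 0.1 kJ/mol), T = 298.15 K
(the assay temperature; the ΔG₀′ convention does not state its own), and
ΔG₀′(ATP → ADP + Pi) = −31 kJ/mol, a literature constant stored in the
model so coupled energies are reproducible.

`mode="dominant"` replaces r(pH) by its largest term. Because the
dropped terms are positive, the dominant-mode energy always lies above
the full-mode energy, by at most RT·ln 4 (all four species equal) and by
RT·ln 2 = 1.7 kJ/mol in the classic two-species case pH = pK. Far from
every pK the gap is negligible (< 0.1 kJ/mol at ≥ 2 pH units).

Profile values are computed at full precision; for reporting against
integer-precision literature values a ±0.5 kJ/mol tolerance is used.

## Synthetic assay generator

The generator emulates quantified concentration-versus-time data from
the coupled ATPase/lactamase assay: near-linear early product formation,
caprolactam-independent (uncoupled) ATP hydrolysis, saturable bicarbonate
activation of both activities, a conversion plateau, and measurement
noise. It deliberately encodes no mechanism — the published data are
initial rates and qualitative statements, so the scheme is the minimal
one with the right structure:

    r_cap = v_cap_max · f(HCO₃⁻) · sat(Cap; Km_cap) · sat(ATP; Km_atp)
    r_unc = v_unc_max · f(HCO₃⁻) · sat(ATP; Km_atp) · (1 − s·sat(Cap; Km_cap))

with hyperbolic saturations sat(x;K) = x/(K+x), bicarbonate activation
f(x) = x/(K_hco3 + x), and s ∈ [0,1] the fraction of uncoupled ATPase
suppressed by saturating caprolactam. State variables are ATP and
caprolactam; ADP and 6-ACA follow by exact mass balance, so the sums
ATP+ADP and Cap+6-ACA are conserved to machine precision by construction.

Units are fixed package-wide: concentrations mM, time min, volume mL,
enzyme mg; specific activity U/mg with U = µmol/min, converting to
concentration rates as mM/min = (U/mg)·(mg/mL).

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| v_cap_max | 0.516 U/mg | calibrated (below) |
| v_unc_max | 0.554 U/mg | calibrated (below) |
| s (suppression) | 0.764 | calibrated (below) |
| K_hco3 | 10 mM | hyperbola roughly matching the reported relative rates at 0.5/5/50 mM bicarbonate; a calibration, not a measured constant |
| Km_cap, Km_atp | 0.1 mM | small enough that the first 20 % of conversion is near-linear (OLS window bias < 1 %), matching the observed early-phase linearity; no Km was ever measured for this enzyme |
| noise | σ_abs = 0.02 mM, σ_rel = 0.03 | few-percent HPLC/MS quantification scatter |
| sampling | every 2 min to 120 min | manual time-point sampling on the reported time scale |
| dt | 0.01 min | fixed-step RK4; kinetics are smooth and non-stiff, halving dt moves no sample by > 1e-6 mM |

Calibration: v_cap_max, v_unc_max and s are solved in closed form from
the reference initial activities at 2 mM caprolactam, 2 mM ATP and 50 mM
bicarbonate — 0.39 U/mg 6-ACA formation and 0.51 U/mg ADP formation with
caprolactam, 0.44 U/mg ADP formation without. The calibration equations
are linear in the unknowns, so no numerical root-finding is needed
(`KineticParams.calibrated`).

What the generator does **not** emulate: the small residual ATPase at
zero bicarbonate (0.008 U/mg is reported; the hyperbolic activation gives
exactly zero), buffer chemistry, Mg²⁺ dependence, enzyme inactivation,
and raw chromatograms (data are emulated at the level of quantified
concentrations). Consequently, passing tests show that the analysis
pipeline recovers known ground truth from data with this structure — not
that the kinetic scheme is mechanistically correct for the real enzyme.
The conversion plateau arises purely from ATP exhaustion through
uncoupled hydrolysis (≈ 1.5 mM 6-ACA from 2 mM caprolactam and 2 mM ATP
at default parameters); no inactivation claim is made.

## Assay analysis

Initial rates: ordinary least squares with intercept (robust to small
lags) over the contiguous prefix of samples taken before 20 % conversion
of the limiting substrate, minimum 3 points. The window is a prefix so
noisy excursions cannot re-admit late points.

Coupling ratio: cumulative form ΔADP(t)/Δ6-ACA(t) by default — this is
the form in which an end-of-run stoichiometry like 1.2 is quoted — with
an initial-rate-ratio form available (`method="rate"`). Note the two can
differ: the rate ratio is the t→0 limit, while the cumulative ratio
drifts upward as caprolactam depletion relaxes the suppression of
uncoupled ATPase.

Censoring: quantities below a detection limit (default 3e-4 mM 6-ACA)
are returned as typed `Censored` bounds (`<0.015`-style), never as magic
numbers; fold-changes over an unquantifiable denominator are reported as
censored lower bounds using a supplied detection limit. Not-applicable
report cells (e.g. the 6-ACA rate without caprolactam) render as "—".

The uncoupled fraction pairs each +caprolactam condition with its
−caprolactam control (same bicarbonate and ATP); with the reference
calibration this is 0.44/0.51 ≈ 0.86. Published prose quoting "ca. 70 %"
is not reproducible from the tabulated rates; the report always computes
the ratio from the data it is given.

## Reproducibility and I/O

Long-format CSV (`time_min,analyte,conc_mM`) is canonical; wide format is
accepted on input. Every output embeds a provenance comment block with
the package version, config hash and seed; identical config and seed give
byte-identical outputs. The YAML run configuration rejects unknown keys
by name. All randomness flows through `numpy.random.default_rng` seeded
explicitly; panel conditions get per-condition child seeds recorded in
their files.

## Known limitations

- The speciation model is two-site/four-species; general polyprotic
  ligands, activity coefficients and pK temperature dependence are out of
  scope.
- ΔG_neutral is an input with its own (quantum-chemical) uncertainty of a
  few kJ/mol; the package propagates none of it.
- The kinetic scheme is a data emulator, not a mechanism; fitted Km or
  K_hco3 values have no physical meaning beyond shape calibration.
- Initial-rate OLS carries a small negative bias from curvature inside
  the window (< 1 % at default parameters); tighter windows trade bias
  for variance.
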