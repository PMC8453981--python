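"""pH-dependent Gibbs free energy of caprolactam hydrolysis and ATP coupling.

The reference reaction is the ring opening of caprolactam by water to the
uncharged (non-zwitterionic) form of 6-aminocaproic acid::

    caprolactam + H2O  <=>  6-ACA(neutral)      dG_neutral = +67 kJ/mol

Two corrections give the standard transformed free energy at a stated pH:
subtracting ``RT ln [H2O]`` (water at its ~55 M solution concentration) and
subtracting ``RT ln (6-ACA_tot / 6-ACA_neutral)``, the speciation term that
credits the reaction for the charged microspecies (mostly the zwitterion)
that accumulate alongside the neutral product::

    dG0'(pH) = dG_neutral - RT ln [H2O] - RT ln r(pH)

where ``r(pH)`` is the total-to-neutral ratio from :mod:`capab.speciation`.
At pH 7 with the default constants this gives +23 kJ/mol — hydrolysis is
strongly endergonic, which is why the enzyme consumes ATP. Adding the ATP
hydrolysis free energy (dG0' = -31 kJ/mol) makes the coupled reaction
exergonic.

The ``dominant`` mode replaces the four-term ratio by its largest term
(single-dominant-species approximation); the error of doing so is at most
``RT ln 2`` per pair of co-dominant species, i.e. 1.7 kJ/mol at 25 C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from capab.speciation import MicroPKSet, _log10_ratios, log10_total_to_neutral_ratio

#: Gas constant in kJ/(mol K).
R_KJ_PER_MOL_K = 8.314e-3

_LN10 = math.log(10.0)


def thermal_energy(temperature: float) -> float:
    """RT in kJ/mol at the given temperature (kelvin)."""
    if not (temperature > 0 and math.isfinite(temperature)):
        raise ValueError(f"temperature must be positive and finite, got {temperature!r}")
    return R_KJ_PER_MOL_K * temperature


@dataclass(frozen=True)
class EnergeticsModel:
    """Thermodynamic constants of the caprolactam <=> 6-ACA equilibrium.

    Parameters
    ----------
    dG_neutral : float
        Gibbs free energy (kJ/mol) of caprolactam + H2O <=> neutral 6-ACA,
        for the uncharged species only. Default 67.
    water_molarity : float
        Concentration of water in mol/L. Default 55.
    temperature : float
        Kelvin. Default 298.15.
    dG_atp : float
        Standard transformed free energy of ATP -> ADP + Pi in kJ/mol,
        a literature constant. Default -31.
    pks : MicroPKSet
        Microscopic pK constants of 6-ACA.
    """

    dG_neutral: float = 67.0
    water_molarity: float = 55.0
    temperature: float = 298.15
    dG_atp: float = -31.0
    pks: MicroPKSet = field(default_factory=MicroPKSet)

    def __post_init__(self) -> None:
        if not self.water_molarity > 0:
            raise ValueError(f"water_molarity must be > 0, got {self.water_molarity}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


def dg_hydrolysis(ph: float, model: EnergeticsModel | None = None, mode: str = "full") -> float:
    """Standard transformed Gibbs free energy (kJ/mol) of caprolactam hydrolysis.

    Parameters
    ----------
    ph : float
        pH at which the speciation correction is evaluated.
    model : EnergeticsModel, optional
        Thermodynamic constants; defaults use the printed values
        (67 kJ/mol, 55 M water, 298.15 K, pK 4.8/4.43/10.75).
    mode : {"full", "dominant"}
        ``full`` uses the complete four-term total-to-neutral ratio;
        ``dominant`` keeps only its largest term. Dropping positive terms
        can only raise the result, by at most RT ln 4.
    """
    if model is None:
        model = EnergeticsModel()
    if mode == "full":
        log10_ratio = log10_total_to_neutral_ratio(ph, model.pks)
    elif mode == "dominant":
        log10_ratio = max(_log10_ratios(ph, model.pks).values())
    else:
        raise ValueError(f"mode must be 'full' or 'dominant', got {mode!r}")
    rt = thermal_energy(model.temperature)
    return (
        model.dG_neutral
        - rt * math.log(model.water_molarity)
        - rt * _LN10 * log10_ratio
    )


def dg_coupled(dg_hydrolysis_value: float, model: EnergeticsModel | None = None) -> float:
    """Free energy of hydrolysis coupled 1:1 to ATP -> ADP + Pi."""
    if model is None:
        model = EnergeticsModel()
    if not math.isfinite(dg_hydrolysis_value):
        raise ValueError(f"dg_hydrolysis_value must be finite, got {dg_hydrolysis_value!r}")
    return dg_hydrolysis_value + model.dG_atp


def approximation_error_bound(temperature: float = 298.15, n_coexisting: int = 2) -> float:
    """Maximum error (kJ/mol) of the single-dominant-species approximation.

    Keeping only the largest of ``n_coexisting`` equally-abundant species
    underestimates the total by at most a factor ``n_coexisting``, i.e.
    ``RT ln n``. The classic case is two species at equal concentration
    (pH equal to a pK), giving RT ln 2 = 1.7 kJ/mol at 25 C.
    """
    if n_coexisting < 1:
        raise ValueError(f"n_coexisting must be >= 1, got {n_coexisting}")
    return thermal_energy(temperature) * math.log(n_coexisting)


def dg_profile(
    ph_min: float,
    ph_max: float,
    step: float = 0.1,
    model: EnergeticsModel | None = None,
) -> pd.DataFrame:
    """Tabulate the hydrolysis free energy over a pH grid.

    Returns a DataFrame with columns ``ph``, ``dg_full_kj_mol``,
    ``dg_dominant_kj_mol`` and ``dg_coupled_kj_mol`` (coupled = full +
    dG_atp). A single-point grid (ph_min == ph_max) is allowed.
    """
    if model is None:
        model = EnergeticsModel()
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if ph_min > ph_max:
        raise ValueError(f"ph_min must be <= ph_max, got {ph_min} > {ph_max}")
    grid = np.arange(ph_min, ph_max + step / 2, step)
    if grid.size == 0:
        raise ValueError("empty pH grid")
    full = np.array([dg_hydrolysis(float(p), model, "full") for p in grid])
    dom = np.array([dg_hydrolysis(float(p), model, "dominant") for p in grid])
    return pd.DataFrame(
        {
            "ph": grid,
            "dg_full_kj_mol": full,
            "dg_dominant_kj_mol": dom,
            "dg_coupled_kj_mol": full + model.dG_atp,
        }
    )
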