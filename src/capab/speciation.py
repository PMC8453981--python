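"""pH-dependent microspeciation of 6-aminocaproic acid (6-ACA).

6-ACA is an omega-amino acid with two ionizable sites (carboxyl and amine)
and therefore four protonation microspecies:

* ``cation``     — COOH / NH3+  (net +1, dominant at very low pH)
* ``zwitterion`` — COO- / NH3+  (net 0, dominant near neutral pH)
* ``neutral``    — COOH / NH2   (net 0, always a trace species)
* ``anion``      — COO- / NH2   (net -1, dominant at high pH)

Three microscopic pK constants fix the whole network; the fourth (the amine
pK of the cation) follows from thermodynamic cycle closure. All abundances
are expressed relative to the neutral species, whose concentration enters
the hydrolysis free-energy expression directly. Ratios are handled as
log10 values internally so that extreme pH or pK combinations cannot
overflow; they are exponentiated only on output.

pH is treated as the activity-based -log10[H+] with no ionic-strength
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical species order used everywhere in the package.
SPECIES = ("cation", "zwitterion", "neutral", "anion")

#: Net charge of each microspecies.
NET_CHARGE = {"cation": 1, "zwitterion": 0, "neutral": 0, "anion": -1}

# Tie-break preference for dominant_species: lower |net charge| first,
# then neutral over zwitterion, then cation over anion (documented order).
_TIE_ORDER = {"neutral": 0, "zwitterion": 1, "cation": 2, "anion": 3}


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MicroPKSet:
    """Microscopic pK constants of the 6-ACA protonation network.

    Parameters
    ----------
    pKA0 : float
        Acid constant of the COOH group of the uncharged (non-zwitterionic)
        species; estimated from hexanoic acid. Default 4.8.
    pKAplus : float
        Acid constant of the COOH group of the cation. Default 4.43.
    pKBminus : float
        Acid constant of the NH3+ group of the zwitterion. Default 10.75.
    temperature : float
        Temperature in kelvin (default 298.15). Carried for provenance;
        the pK values themselves are treated as temperature-independent.
    """

    pKA0: float = 4.8
    pKAplus: float = 4.43
    pKBminus: float = 10.75
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("pKA0", "pKAplus", "pKBminus", "temperature"):
            _require_finite(name, getattr(self, name))
        if not self.pKAplus < self.pKBminus:
            raise ValueError(
                "pKAplus must be smaller than pKBminus (the carboxyl "
                f"deprotonates before the amine): got pKAplus={self.pKAplus}, "
                f"pKBminus={self.pKBminus}"
            )


def cycle_closure_pk(pks: MicroPKSet) -> float:
    """Implied pK of the amine site of the cation.

    The four microspecies form a thermodynamic cycle, so only three
    microscopic constants are independent; the amine constant of the
    cation is ``pKAplus + pKBminus - pKA0``.
    """
    return pks.pKAplus + pks.pKBminus - pks.pKA0


def _log10_ratios(ph: float, pks: MicroPKSet) -> dict[str, float]:
    """log10 abundance of each microspecies relative to the neutral form."""
    _require_finite("ph", ph)
    return {
        "cation": pks.pKBminus + pks.pKAplus - pks.pKA0 - ph,
        "zwitterion": pks.pKBminus - pks.pKA0,
        "neutral": 0.0,
        "anion": ph - pks.pKA0,
    }


@dataclass(frozen=True)
class SpeciesDistribution:
    """Relative abundances of the four 6-ACA microspecies at one pH."""

    ph: float
    log10_ratios: dict[str, float] = field(repr=False)

    @property
    def ratios_to_neutral(self) -> dict[str, float]:
        """Abundance of each species relative to neutral (neutral == 1)."""
        return {s: 10.0 ** self.log10_ratios[s] for s in SPECIES}

    @property
    def fractions(self) -> dict[str, float]:
        """Normalized abundances; computed in log-space, sum to 1."""
        logs = np.array([self.log10_ratios[s] for s in SPECIES])
        shifted = np.power(10.0, logs - logs.max())
        frac = shifted / shifted.sum()
        return dict(zip(SPECIES, frac))

    @property
    def dominant(self) -> str:
        """Most abundant microspecies, with the documented tie-break."""
        best = max(self.log10_ratios.values())
        candidates = [s for s in SPECIES if self.log10_ratios[s] == best]
        return min(candidates, key=lambda s: (abs(NET_CHARGE[s]), _TIE_ORDER[s]))


def microspecies_ratios(ph: float, pks: MicroPKSet) -> SpeciesDistribution:
    """Microspecies distribution of 6-ACA at a given pH.

    Relative to the neutral species the abundances are powers of ten of
    simple pK combinations::

        cation     = 10**(pKBminus + pKAplus - pKA0 - ph)
        zwitterion = 10**(pKBminus - pKA0)
        anion      = 10**(ph - pKA0)
        neutral    = 1

    Parameters
    ----------
    ph : float
        pH at which to evaluate the distribution (must be finite).
    pks : MicroPKSet
        Microscopic pK constants.
    """
    return SpeciesDistribution(ph=ph, log10_ratios=_log10_ratios(ph, pks))


def total_to_neutral_ratio(ph: float, pks: MicroPKSet) -> float:
    """Ratio of total 6-ACA (all microspecies) to the neutral form.

    This is the four-term sum over the species ratios; it is the partition
    function of the protonation network referenced to the neutral species
    and is always >= 1.
    """
    logs = _log10_ratios(ph, pks)
    return float(sum(10.0 ** logs[s] for s in SPECIES))


def log10_total_to_neutral_ratio(ph: float, pks: MicroPKSet) -> float:
    """log10 of :func:`total_to_neutral_ratio`, overflow-safe.

    Evaluated with a log-sum-exp shift so that extreme pH/pK combinations
    stay finite.
    """
    logs = np.array(list(_log10_ratios(ph, pks).values()))
    m = logs.max()
    return float(m + np.log10(np.power(10.0, logs - m).sum()))


def dominant_species(ph: float, pks: MicroPKSet) -> tuple[str, float]:
    """Most abundant microspecies at a given pH and its molar fraction.

    Ties are broken toward the species of lower net-charge magnitude,
    then neutral over zwitterion, so degenerate inputs give deterministic
    output.
    """
    dist = microspecies_ratios(ph, pks)
    name = dist.dominant
    return name, dist.fractions[name]


def distribution_grid(
    ph_values: np.ndarray, pks: MicroPKSet
) -> "list[SpeciesDistribution]":
    """Distributions over an array of pH values (helper for CSV export)."""
    return [microspecies_ratios(float(ph), pks) for ph in np.asarray(ph_values)]
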