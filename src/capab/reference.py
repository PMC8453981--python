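"""Published reference data for the CapAB coupled ATPase/lactamase assay.

The reported specific activities of purified CapAB under varying
caprolactam and bicarbonate concentrations (Hepes buffer, pH 8.0,
0.045 mg/mL enzyme, 2 mL reactions at 25 C). These numbers serve two
roles: calibration targets for the synthetic progress-curve generator
and inputs for worked examples (fold-changes, uncoupled fractions).

``rate_adp`` and ``rate_aca`` are initial specific activities in U/mg
(1 U = 1 umol/min); ``None`` marks cells the assay could not report
(no caprolactam present, or product below detection).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Enzyme concentration used in the reported assays, mg/mL.
ENZYME_MG_PER_ML = 0.045

#: Reaction volume, mL (90 ug enzyme in 2 mL).
ASSAY_VOLUME_ML = 2.0

#: Assay temperature, kelvin (25 C).
ASSAY_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class ReferenceActivity:
    """One row of the reported activity panel."""

    entry: int
    cap0: float  # mM caprolactam
    atp0: float  # mM ATP
    hco3: float  # mM bicarbonate
    rate_adp: float | None  # U/mg
    rate_aca: float | None  # U/mg


#: Reported activity panel, entries 1-7 (the eighth row, a no-ATP control
#: from a cell-free extract, is not part of the purified-enzyme panel).
ACTIVITY_TABLE: tuple[ReferenceActivity, ...] = (
    ReferenceActivity(1, 2.0, 2.0, 50.0, 0.51, 0.39),
    ReferenceActivity(2, 0.0, 2.0, 50.0, 0.44, None),
    ReferenceActivity(3, 2.0, 2.0, 0.0, 0.008, None),
    ReferenceActivity(4, 2.0, 2.0, 0.5, 0.021, 0.017),
    ReferenceActivity(5, 0.0, 2.0, 0.5, 0.019, None),
    ReferenceActivity(6, 2.0, 2.0, 5.0, 0.167, 0.190),
    ReferenceActivity(7, 0.0, 2.0, 5.0, 0.158, None),
)


def activity(entry: int) -> ReferenceActivity:
    """Look up a reference panel row by its entry number."""
    for row in ACTIVITY_TABLE:
        if row.entry == entry:
            return row
    raise KeyError(f"no reference activity entry {entry}; have 1-7")
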