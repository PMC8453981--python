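"""Quantitative analysis of coupled ATPase/lactamase progress curves.

Turns concentration-versus-time tables into the assay's headline numbers:

* initial rates by ordinary least squares over the early, near-linear
  window (points up to 20% conversion of the limiting substrate), reported
  both as slopes (mM/min) and specific activities (U/mg, U = umol/min);
* the ATP/6-ACA coupling ratio, cumulative (dADP/dACA at a reference time)
  or as a ratio of initial rates;
* fold-changes between conditions (e.g. bicarbonate removal);
* endpoint conversion with detection-limit censoring;
* a multi-condition summary report pairing +/- caprolactam conditions to
  quantify the uncoupled ATPase fraction.

Values below a detection limit are returned as typed :class:`Censored`
bounds, never as magic numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from capab.assay_sim import ANALYTES, TimeCourse

#: Default detection limit for 6-ACA quantification, mM.
DEFAULT_LOD_MM = 3e-4


@dataclass(frozen=True)
class Censored:
    """A value known only as a bound relative to a detection limit.

    ``direction`` is ``"<"`` (below the limit) or ``">"`` (at least this
    large, the true denominator being unquantifiable).
    """

    bound: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("<", ">"):
            raise ValueError(f"direction must be '<' or '>', got {self.direction!r}")

    def __str__(self) -> str:
        return f"{self.direction}{self.bound:g}"


@dataclass(frozen=True)
class RateEstimate:
    """Initial-rate fit for one analyte of one time course."""

    analyte: str
    slope: float  # mM/min
    stderr: float  # mM/min
    n_points: int
    window_end: float  # min
    specific_activity: float  # U/mg


def specific_activity_from_slope(slope: float, volume_ml: float, enzyme_mg: float) -> float:
    """Convert a concentration slope (mM/min) to specific activity (U/mg).

    mM x mL = umol, so ``U/mg = slope * volume / enzyme_mass``. Exact
    inverse of :func:`slope_from_specific_activity`.
    """
    if enzyme_mg <= 0:
        raise ValueError(f"enzyme mass must be > 0, got {enzyme_mg}")
    return slope * volume_ml / enzyme_mg


def slope_from_specific_activity(activity: float, volume_ml: float, enzyme_mg: float) -> float:
    """Inverse of :func:`specific_activity_from_slope`."""
    if volume_ml <= 0:
        raise ValueError(f"volume must be > 0, got {volume_ml}")
    return activity * enzyme_mg / volume_ml


def _initial_window(tc: TimeCourse, max_conversion: float) -> int:
    """Number of leading points within the conversion window.

    Conversion is tracked for each substrate present at t = 0 (ATP and/or
    caprolactam); the window ends at the first sample where the larger of
    the two fractional conversions exceeds ``max_conversion``. The window
    is a contiguous prefix so that noisy excursions cannot re-admit late
    points.
    """
    conv = np.zeros_like(tc.times)
    cond = tc.condition
    if cond.atp0 > 0:
        conv = np.maximum(conv, (cond.atp0 - tc.analyte("ATP")) / cond.atp0)
    if cond.cap0 > 0:
        conv = np.maximum(conv, (cond.cap0 - tc.analyte("Cap")) / cond.cap0)
    beyond = np.nonzero(conv > max_conversion)[0]
    return int(beyond[0]) if beyond.size else len(tc.times)


def estimate_initial_rate(
    tc: TimeCourse,
    analyte: str,
    max_conversion: float = 0.2,
    min_points: int = 3,
) -> RateEstimate:
    """Initial rate of an analyte by OLS over the early assay window.

    A straight line (with intercept, so small lags or offsets do not bias
    the slope) is fitted to all samples taken before ``max_conversion`` of
    the limiting substrate has been consumed. The slope is the rate in
    mM/min; the specific activity follows from the condition's volume and
    enzyme mass.

    Raises
    ------
    ValueError
        If fewer than ``min_points`` samples fall inside the window.
    """
    if analyte not in ANALYTES:
        raise KeyError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}")
    n = _initial_window(tc, max_conversion)
    if n < min_points:
        raise ValueError(
            f"only {n} points before {max_conversion:.0%} conversion of the "
            f"limiting substrate; the initial-rate window requires at least "
            f"{min_points}"
        )
    t = tc.times[:n]
    y = tc.analyte(analyte)[:n]
    if np.allclose(y, y[0]):
        slope, stderr = 0.0, 0.0
    else:
        fit = stats.linregress(t, y)
        slope, stderr = float(fit.slope), float(fit.stderr)
    return RateEstimate(
        analyte=analyte,
        slope=slope,
        stderr=stderr,
        n_points=n,
        window_end=float(t[-1]),
        specific_activity=specific_activity_from_slope(
            slope, tc.condition.volume, tc.condition.enzyme_mass_mg
        ),
    )


def coupling_ratio(
    tc: TimeCourse,
    t_ref: float | None = None,
    method: str = "cumulative",
    lod: float = DEFAULT_LOD_MM,
    max_conversion: float = 0.2,
) -> float | Censored:
    """Moles of ATP hydrolysed per mole of 6-ACA formed.

    ``cumulative`` (default) divides the ADP and ACA accumulated by
    ``t_ref`` (default: the last sample); ``rate`` divides the two initial
    rates instead. Perfectly coupled turnover gives 1; uncoupled ATPase
    pushes the ratio above 1. If no quantifiable 6-ACA has formed the
    result is censored (``> dADP/lod``) rather than a division error.
    """
    if method == "rate":
        r_adp = estimate_initial_rate(tc, "ADP", max_conversion).slope
        r_aca = estimate_initial_rate(tc, "ACA", max_conversion).slope
        if r_aca <= 0:
            return Censored(r_adp / lod, ">") if r_adp > 0 else Censored(0.0, ">")
        return r_adp / r_aca
    if method != "cumulative":
        raise ValueError(f"method must be 'cumulative' or 'rate', got {method!r}")
    if t_ref is None:
        idx = len(tc.times) - 1
    else:
        at_or_before = np.nonzero(tc.times <= t_ref)[0]
        if at_or_before.size == 0:
            raise ValueError(f"t_ref={t_ref} precedes the first sample")
        idx = int(at_or_before[-1])
    d_adp = tc.analyte("ADP")[idx] - tc.analyte("ADP")[0]
    d_aca = tc.analyte("ACA")[idx] - tc.analyte("ACA")[0]
    if d_aca < lod:
        return Censored(d_adp / lod, ">") if d_adp > 0 else Censored(0.0, ">")
    return float(d_adp / d_aca)


def fold_change(
    rate_a: float, rate_b: float, detection_limit: float | None = None
) -> float | Censored:
    """Ratio ``rate_a / rate_b`` between two activities.

    If ``rate_b`` is zero (below quantification) the result is reported as
    a censored lower bound ``> rate_a / detection_limit``, which requires
    an explicit detection limit.
    """
    if rate_a < 0 or rate_b < 0:
        raise ValueError("rates must be nonnegative")
    if rate_b == 0:
        if detection_limit is None or detection_limit <= 0:
            raise ValueError(
                "rate_b is zero; a positive detection_limit is required to "
                "report a censored fold-change"
            )
        return Censored(rate_a / detection_limit, ">")
    return rate_a / rate_b


def endpoint_conversion(tc: TimeCourse, lod: float = DEFAULT_LOD_MM) -> float | Censored:
    """Percent conversion of caprolactam to 6-ACA at the final sample.

    Returns ``100 * ACA(t_end) / cap0``; if the final 6-ACA concentration
    is below the detection limit the conversion is censored as
    ``< 100 * lod / cap0`` (e.g. 3e-4 mM on 2 mM substrate reads "<0.015").
    """
    cap0 = tc.condition.cap0
    if cap0 <= 0:
        raise ValueError("endpoint conversion is undefined without caprolactam (cap0 = 0)")
    aca_end = float(tc.analyte("ACA")[-1])
    if aca_end < lod:
        return Censored(100.0 * lod / cap0, "<")
    return 100.0 * aca_end / cap0


@dataclass(frozen=True)
class ReportRow:
    """One condition of an assay report."""

    label: str
    rate_adp: RateEstimate
    rate_aca: RateEstimate | None  # None when no caprolactam was present
    coupling_ratio: float | Censored | None
    uncoupled_fraction: float | None
    conversion_pct: float | Censored | None


@dataclass(frozen=True)
class AssayReport:
    """Multi-condition summary of a coupled-assay panel."""

    rows: tuple[ReportRow, ...]
    lod: float = DEFAULT_LOD_MM

    def row(self, label: str) -> ReportRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(f"no report row labelled {label!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tabular report; not-applicable cells carry an em-dash."""

        def cell(v):
            if v is None:
                return "—"
            if isinstance(v, Censored):
                return str(v)
            return v

        records = [
            {
                "label": r.label,
                "rate_adp_u_mg": r.rate_adp.specific_activity,
                "rate_aca_u_mg": cell(
                    r.rate_aca.specific_activity if r.rate_aca is not None else None
                ),
                "coupling_ratio": cell(r.coupling_ratio),
                "uncoupled_fraction": cell(r.uncoupled_fraction),
                "conversion_pct": cell(r.conversion_pct),
            }
            for r in self.rows
        ]
        return pd.DataFrame.from_records(records)


def condition_summary(
    panel: list[TimeCourse],
    pairing: dict[str, str] | None = None,
    max_conversion: float = 0.2,
    lod: float = DEFAULT_LOD_MM,
) -> AssayReport:
    """Summarize a panel of time courses into an assay report.

    For every condition the ADP rate is estimated; conditions containing
    caprolactam additionally get the ACA rate, the cumulative coupling
    ratio and the endpoint conversion. ``pairing`` maps the label of each
    +caprolactam condition to its matched -caprolactam control; the
    uncoupled fraction is the control's ADP rate divided by the paired
    condition's ADP rate. When ``pairing`` is omitted, controls are matched
    automatically by equal bicarbonate and ATP concentrations.
    """
    if not panel:
        raise ValueError("empty panel")
    by_label = {tc.condition.label: tc for tc in panel}
    if pairing is None:
        pairing = {}
        for tc in panel:
            if tc.condition.cap0 <= 0:
                continue
            for other in panel:
                if (
                    other.condition.cap0 == 0
                    and other.condition.hco3 == tc.condition.hco3
                    and other.condition.atp0 == tc.condition.atp0
                ):
                    pairing[tc.condition.label] = other.condition.label
                    break
    else:
        unmatched = [
            lbl for pair in pairing.items() for lbl in pair if lbl not in by_label
        ]
        if unmatched:
            raise ValueError(f"pairing refers to unknown condition labels: {unmatched}")

    rows = []
    for tc in panel:
        rate_adp = estimate_initial_rate(tc, "ADP", max_conversion)
        has_cap = tc.condition.cap0 > 0
        rate_aca = estimate_initial_rate(tc, "ACA", max_conversion) if has_cap else None
        ratio = coupling_ratio(tc, lod=lod) if has_cap else None
        conv = endpoint_conversion(tc, lod=lod) if has_cap else None
        uncoupled = None
        if has_cap and tc.condition.label in pairing:
            control = by_label[pairing[tc.condition.label]]
            control_rate = estimate_initial_rate(control, "ADP", max_conversion)
            if rate_adp.specific_activity > 0:
                uncoupled = control_rate.specific_activity / rate_adp.specific_activity
        rows.append(
            ReportRow(
                label=tc.condition.label,
                rate_adp=rate_adp,
                rate_aca=rate_aca,
                coupling_ratio=ratio,
                uncoupled_fraction=uncoupled,
                conversion_pct=conv,
            )
        )
    return AssayReport(rows=tuple(rows), lod=lod)
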