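"""Synthetic progress-curve generator for the coupled ATPase/lactamase assay.

The generator emulates the structure of the CapAB assay data: near-linear
early-phase formation of 6-ACA and ADP, caprolactam-independent (uncoupled)
ATP hydrolysis, saturable bicarbonate activation of both activities, a
conversion plateau caused by substrate/ATP depletion, and seeded Gaussian
measurement noise. It makes no mechanistic claim; the rate law is a minimal
Michaelis-type scheme whose job is to produce data with the right shape.

Rate law (specific rates in U/mg, i.e. umol min^-1 mg^-1)::

    r_cap = v_cap_max * f(HCO3) * sat(Cap; Km_cap) * sat(ATP; Km_atp)
    r_unc = v_unc_max * f(HCO3) * sat(ATP; Km_atp)
            * (1 - uncoupling_suppression * sat(Cap; Km_cap))

with ``f(x) = x/(K_hco3 + x)`` and ``sat(x; K) = x/(K + x)``. Every coupled
turnover consumes one ATP; the uncoupled ATPase adds on top, so
ADP formation always runs at least as fast as 6-ACA formation. As
caprolactam is depleted the suppression term fades and excess ATP
hydrolysis grows, which is what lets conversion plateau below 100% through
ATP exhaustion.

Specific rates convert to concentration rates as ``mM/min = U/mg x mg/mL``.
Integration is fixed-step classical Runge-Kutta; the kinetics are smooth
and non-stiff, and the scheme conserves the Cap+ACA and ATP+ADP sums to
machine precision by construction of the right-hand side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from capab import reference

ANALYTES = ("ATP", "ADP", "Cap", "ACA")


@dataclass(frozen=True)
class AssayCondition:
    """One assay condition: initial concentrations and bookkeeping."""

    cap0: float  # mM caprolactam
    atp0: float  # mM ATP
    hco3: float  # mM bicarbonate
    enzyme_conc: float = reference.ENZYME_MG_PER_ML  # mg/mL
    volume: float = reference.ASSAY_VOLUME_ML  # mL
    t_end: float = 120.0  # min
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("cap0", "atp0", "hco3", "enzyme_conc"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative finite number, got {v!r}")
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if not self.t_end > 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")

    @property
    def enzyme_mass_mg(self) -> float:
        """Total enzyme in the reaction, mg."""
        return self.enzyme_conc * self.volume


def _sat(x: float, k: float) -> float:
    """Hyperbolic saturation x/(k+x), defined as 0 at x = 0."""
    if x <= 0:
        return 0.0
    return x / (k + x)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the minimal kinetic scheme.

    ``v_cap_max`` / ``v_unc_max`` are maximal specific rates (U/mg) of the
    coupled lactamase reaction and of the uncoupled ATPase; ``K_hco3`` is
    the half-saturation of the bicarbonate activation (mM); ``Km_cap`` and
    ``Km_atp`` are Michaelis constants (mM); ``uncoupling_suppression`` in
    [0, 1] is the fraction of the uncoupled ATPase shut down by saturating
    caprolactam.
    """

    v_cap_max: float
    v_unc_max: float
    K_hco3: float = 10.0
    Km_cap: float = 0.1
    Km_atp: float = 0.1
    uncoupling_suppression: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_cap_max", "v_unc_max", "K_hco3", "Km_cap", "Km_atp"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be nonnegative and finite, got {v!r}")
        if not 0 <= self.uncoupling_suppression <= 1:
            raise ValueError(
                f"uncoupling_suppression must be in [0, 1], got {self.uncoupling_suppression}"
            )

    @classmethod
    def calibrated(
        cls,
        rate_aca: float | None = None,
        rate_adp: float | None = None,
        rate_adp_no_cap: float | None = None,
        cap: float = 2.0,
        atp: float = 2.0,
        hco3: float = 50.0,
        K_hco3: float = 10.0,
        Km_cap: float = 0.1,
        Km_atp: float = 0.1,
    ) -> "KineticParams":
        """Solve the maximal rates from reference initial activities.

        By default the targets are the reported specific activities at
        2 mM caprolactam, 2 mM ATP, 50 mM bicarbonate: 0.39 U/mg 6-ACA
        formation and 0.51 U/mg ADP formation with caprolactam present,
        0.44 U/mg ADP formation without caprolactam. The calibration
        equations are linear in the unknowns and invert in closed form::

            v_cap_max = rate_aca / (f * sc * sa)
            v_unc_max = rate_adp_no_cap / (f * sa)
            suppression = (1 - (rate_adp - rate_aca)/rate_adp_no_cap) / sc

        with f = f(hco3), sc = sat(cap), sa = sat(atp).
        """
        if rate_aca is None:
            rate_aca = reference.activity(1).rate_aca
        if rate_adp is None:
            rate_adp = reference.activity(1).rate_adp
        if rate_adp_no_cap is None:
            rate_adp_no_cap = reference.activity(2).rate_adp
        f = _sat(hco3, K_hco3)
        sc = _sat(cap, Km_cap)
        sa = _sat(atp, Km_atp)
        if min(f, sc, sa) <= 0:
            raise ValueError("calibration point must have nonzero cap, atp and hco3")
        v_cap_max = rate_aca / (f * sc * sa)
        v_unc_max = rate_adp_no_cap / (f * sa)
        suppression = (1.0 - (rate_adp - rate_aca) / rate_adp_no_cap) / sc
        return cls(
            v_cap_max=v_cap_max,
            v_unc_max=v_unc_max,
            K_hco3=K_hco3,
            Km_cap=Km_cap,
            Km_atp=Km_atp,
            uncoupling_suppression=suppression,
        )


def default_params() -> KineticParams:
    """Generator defaults: calibrated against the reference activity panel."""
    return KineticParams.calibrated()


def specific_rates(
    atp: float, cap: float, hco3: float, params: KineticParams
) -> tuple[float, float]:
    """Instantaneous specific rates (r_cap, r_unc) in U/mg."""
    f = _sat(hco3, params.K_hco3)
    sa = _sat(atp, params.Km_atp)
    sc = _sat(cap, params.Km_cap)
    r_cap = params.v_cap_max * f * sc * sa
    r_unc = params.v_unc_max * f * sa * (1.0 - params.uncoupling_suppression * sc)
    return r_cap, r_unc


def analytic_initial_rates(
    condition: AssayCondition, params: KineticParams
) -> dict[str, float]:
    """Exact initial specific rates (U/mg) of the scheme, per analyte.

    This is the generator's ground truth against which estimated initial
    rates can be validated. Signs follow concentration changes (substrates
    negative).
    """
    r_cap, r_unc = specific_rates(condition.atp0, condition.cap0, condition.hco3, params)
    return {
        "ACA": r_cap,
        "Cap": -r_cap,
        "ADP": r_cap + r_unc,
        "ATP": -(r_cap + r_unc),
    }


@dataclass(frozen=True)
class TimeCourse:
    """Concentration-versus-time table for one assay condition.

    ``concentrations`` maps each analyte (ATP, ADP, Cap, ACA) to an array
    of mM values aligned with ``times`` (minutes). ``noise_seed`` is None
    for noiseless model output.
    """

    condition: AssayCondition
    times: np.ndarray
    concentrations: dict[str, np.ndarray] = field(repr=False)
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("times must be strictly increasing and nonnegative")
        missing = [a for a in ANALYTES if a not in self.concentrations]
        if missing:
            raise ValueError(f"missing analytes in time course: {missing}")
        for a, c in self.concentrations.items():
            if np.asarray(c).shape != t.shape:
                raise ValueError(f"analyte {a} has {len(c)} values for {t.size} times")

    def analyte(self, name: str) -> np.ndarray:
        if name not in self.concentrations:
            raise KeyError(f"unknown analyte {name!r}; expected one of {ANALYTES}")
        return np.asarray(self.concentrations[name], dtype=float)

    def to_frame(self, fmt: str = "long") -> pd.DataFrame:
        """Tabular view; ``long`` (time_min, analyte, conc_mM) or ``wide``."""
        if fmt == "long":
            frames = [
                pd.DataFrame(
                    {"time_min": self.times, "analyte": a, "conc_mM": self.analyte(a)}
                )
                for a in ANALYTES
            ]
            return pd.concat(frames, ignore_index=True)
        if fmt == "wide":
            data = {"time_min": self.times}
            data.update({f"{a}_mM": self.analyte(a) for a in ANALYTES})
            return pd.DataFrame(data)
        raise ValueError(f"fmt must be 'long' or 'wide', got {fmt!r}")


def _rhs(
    atp: float, cap: float, hco3: float, enzyme_conc: float, params: KineticParams
) -> tuple[float, float]:
    """Concentration derivatives (dATP/dt, dCap/dt) in mM/min.

    ADP and ACA follow by conservation, which is what keeps the sums exact.
    Concentrations are clamped at zero inside the rate evaluation so RK4
    sub-steps cannot produce negative rates.
    """
    r_cap, r_unc = specific_rates(max(atp, 0.0), max(cap, 0.0), hco3, params)
    scale = enzyme_conc  # U/mg * mg/mL = umol/min/mL = mM/min
    return -(r_cap + r_unc) * scale, -r_cap * scale


#: Conservation tolerance (mM) beyond which the integrator aborts.
CONSERVATION_TOL_MM = 1e-6


def simulate_timecourse(
    condition: AssayCondition,
    params: KineticParams | None = None,
    dt: float = 0.01,
    sample_every: float = 2.0,
) -> TimeCourse:
    """Integrate the kinetic scheme and sample it like an assay.

    Parameters
    ----------
    condition : AssayCondition
        Initial concentrations and enzyme loading.
    params : KineticParams, optional
        Defaults to the calibrated parameter set.
    dt : float
        Fixed Runge-Kutta step in minutes (default 0.01).
    sample_every : float
        Sampling interval in minutes (default 2, mirroring manual
        time-point sampling of the real assay).

    Raises
    ------
    ValueError
        If the step violates mass conservation beyond 1e-6 mM — choose a
        smaller ``dt``.
    """
    if params is None:
        params = default_params()
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if sample_every <= 0:
        raise ValueError(f"sample_every must be > 0, got {sample_every}")

    n_steps = int(round(condition.t_end / dt))
    sample_stride = max(int(round(sample_every / dt)), 1)

    atp, cap = condition.atp0, condition.cap0
    times = [0.0]
    atps, caps = [atp], [cap]
    for i in range(1, n_steps + 1):
        k1a, k1c = _rhs(atp, cap, condition.hco3, condition.enzyme_conc, params)
        k2a, k2c = _rhs(
            atp + dt / 2 * k1a, cap + dt / 2 * k1c, condition.hco3, condition.enzyme_conc, params
        )
        k3a, k3c = _rhs(
            atp + dt / 2 * k2a, cap + dt / 2 * k2c, condition.hco3, condition.enzyme_conc, params
        )
        k4a, k4c = _rhs(
            atp + dt * k3a, cap + dt * k3c, condition.hco3, condition.enzyme_conc, params
        )
        atp += dt / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
        cap += dt / 6 * (k1c + 2 * k2c + 2 * k3c + k4c)
        atp = max(atp, 0.0)
        cap = max(cap, 0.0)
        if i % sample_stride == 0 or i == n_steps:
            times.append(i * dt)
            atps.append(atp)
            caps.append(cap)

    t = np.array(times)
    atp_arr = np.array(atps)
    cap_arr = np.array(caps)
    adp_arr = condition.atp0 - atp_arr
    aca_arr = condition.cap0 - cap_arr
    if np.any(adp_arr < -CONSERVATION_TOL_MM) or np.any(aca_arr < -CONSERVATION_TOL_MM):
        raise ValueError(
            "mass conservation violated beyond tolerance; use a smaller dt"
        )
    return TimeCourse(
        condition=condition,
        times=t,
        concentrations={
            "ATP": atp_arr,
            "ADP": np.maximum(adp_arr, 0.0),
            "Cap": cap_arr,
            "ACA": np.maximum(aca_arr, 0.0),
        },
        noise_seed=None,
    )


def add_measurement_noise(
    tc: TimeCourse,
    sigma_abs: float = 0.02,
    sigma_rel: float = 0.03,
    seed: int = 0,
) -> TimeCourse:
    """Overlay seeded Gaussian measurement noise, clipped at zero.

    Each point gets independent noise with standard deviation
    ``sigma_abs + sigma_rel * value`` (mM). Identical seeds reproduce
    identical output.
    """
    if sigma_abs < 0 or sigma_rel < 0:
        raise ValueError("noise sigmas must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = {}
    for a in ANALYTES:
        clean = tc.analyte(a)
        sd = sigma_abs + sigma_rel * clean
        noisy[a] = np.clip(clean + rng.normal(0.0, 1.0, clean.shape) * sd, 0.0, None)
    return replace(tc, concentrations=noisy, noise_seed=int(seed))


def panel_conditions(t_end: float = 120.0) -> list[AssayCondition]:
    """The seven simulable reference panel conditions.

    Caprolactam 0 or 2 mM crossed with bicarbonate 50 / 0 / 0.5 / 5 mM in
    the combinations of the reported activity panel, at 2 mM ATP and
    0.045 mg/mL enzyme.
    """
    return [
        AssayCondition(
            cap0=row.cap0,
            atp0=row.atp0,
            hco3=row.hco3,
            t_end=t_end,
            label=f"entry{row.entry}",
        )
        for row in reference.ACTIVITY_TABLE
    ]


def generate_condition_panel(
    params: KineticParams | None = None,
    seed: int = 0,
    sigma_abs: float = 0.02,
    sigma_rel: float = 0.03,
    dt: float = 0.01,
    t_end: float = 120.0,
) -> list[TimeCourse]:
    """Simulate the seven-condition reference panel with seeded noise.

    Per-condition noise seeds are drawn from a generator seeded with
    ``seed`` and recorded in each time course's metadata. Passing
    ``sigma_abs = sigma_rel = 0`` yields the noiseless panel (seeds still
    recorded for provenance).
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=7)
    panel = []
    for cond, s in zip(panel_conditions(t_end=t_end), child_seeds):
        tc = simulate_timecourse(cond, params, dt=dt)
        panel.append(add_measurement_noise(tc, sigma_abs, sigma_rel, int(s)))
    return panel
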