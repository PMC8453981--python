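"""CSV readers/writers, run configuration and pipeline orchestration.

All output files are UTF-8, comma-delimited CSV with a required header.
A provenance block of ``# key: value`` comment lines (package version,
config hash, seed, condition metadata) precedes the header; readers skip
and, where relevant, parse it. The long time-course format
(``time_min,analyte,conc_mM``) is canonical; the wide format
(``time_min,ATP_mM,ADP_mM,Cap_mM,ACA_mM``) is accepted on input.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import capab
from capab.assay_analysis import AssayReport, condition_summary
from capab.assay_sim import (
    ANALYTES,
    AssayCondition,
    KineticParams,
    TimeCourse,
    add_measurement_noise,
    default_params,
    panel_conditions,
    simulate_timecourse,
)
from capab.energetics import EnergeticsModel, dg_profile
from capab.speciation import MicroPKSet

logger = logging.getLogger("capab")

_LONG_COLUMNS = ["time_min", "analyte", "conc_mM"]
_WIDE_COLUMNS = ["time_min"] + [f"{a}_mM" for a in ANALYTES]

PROFILE_COLUMNS = ["ph", "dg_full_kj_mol", "dg_dominant_kj_mol", "dg_coupled_kj_mol"]


# ---------------------------------------------------------------------------
# provenance helpers

def _write_csv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    return df, meta


# ---------------------------------------------------------------------------
# time courses

def write_timecourse(tc: TimeCourse, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write a time course as long-format CSV with condition metadata."""
    cond = tc.condition
    meta = {
        "capab_version": capab.__version__,
        "label": cond.label,
        "cap0_mM": cond.cap0,
        "atp0_mM": cond.atp0,
        "hco3_mM": cond.hco3,
        "enzyme_mg_per_ml": cond.enzyme_conc,
        "volume_ml": cond.volume,
        "t_end_min": cond.t_end,
        "noise_seed": tc.noise_seed if tc.noise_seed is not None else "none",
    }
    if extra_meta:
        meta.update(extra_meta)
    _write_csv(Path(path), tc.to_frame("long"), meta)


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a time course from long- or wide-format CSV.

    Condition metadata is recovered from the provenance comments; files
    without them get a generic condition inferred from the first sample.
    """
    df, meta = _read_csv(Path(path))
    cols = list(df.columns)
    if cols == _LONG_COLUMNS:
        wide = df.pivot(index="time_min", columns="analyte", values="conc_mM")
        unknown = set(wide.columns) - set(ANALYTES)
        if unknown:
            raise ValueError(
                f"unknown analytes {sorted(unknown)} in {path}; expected {list(ANALYTES)}"
            )
        missing = set(ANALYTES) - set(wide.columns)
        if missing:
            raise ValueError(f"missing analytes {sorted(missing)} in {path}")
        times = wide.index.to_numpy(dtype=float)
        conc = {a: wide[a].to_numpy(dtype=float) for a in ANALYTES}
    elif cols == _WIDE_COLUMNS:
        times = df["time_min"].to_numpy(dtype=float)
        conc = {a: df[f"{a}_mM"].to_numpy(dtype=float) for a in ANALYTES}
    else:
        raise ValueError(
            f"unrecognized time-course header {cols} in {path}; expected "
            f"{_LONG_COLUMNS} (long) or {_WIDE_COLUMNS} (wide)"
        )

    def _meta_float(key: str, fallback: float) -> float:
        return float(meta[key]) if key in meta else fallback

    condition = AssayCondition(
        cap0=_meta_float("cap0_mM", float(conc["Cap"][0] + conc["ACA"][0])),
        atp0=_meta_float("atp0_mM", float(conc["ATP"][0] + conc["ADP"][0])),
        hco3=_meta_float("hco3_mM", 0.0),
        enzyme_conc=_meta_float("enzyme_mg_per_ml", AssayCondition(0, 0, 0).enzyme_conc),
        volume=_meta_float("volume_ml", 2.0),
        t_end=_meta_float("t_end_min", float(times[-1]) if times[-1] > 0 else 1.0),
        label=meta.get("label", Path(path).stem),
    )
    seed = meta.get("noise_seed", "none")
    return TimeCourse(
        condition=condition,
        times=times,
        concentrations=conc,
        noise_seed=None if seed in ("none", "") else int(seed),
    )


def write_panel(
    panel: list[TimeCourse], outdir: str | Path, extra_meta: dict | None = None
) -> list[Path]:
    """Write one CSV per condition plus a panel manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = []
    for tc in panel:
        name = tc.condition.label or f"condition{len(paths) + 1}"
        path = outdir / f"{name}.csv"
        write_timecourse(tc, path, extra_meta)
        paths.append(path)
        manifest.append(
            {
                "label": tc.condition.label,
                "cap0_mM": tc.condition.cap0,
                "atp0_mM": tc.condition.atp0,
                "hco3_mM": tc.condition.hco3,
                "enzyme_mg_per_ml": tc.condition.enzyme_conc,
                "volume_ml": tc.condition.volume,
                "seed": tc.noise_seed if tc.noise_seed is not None else "none",
            }
        )
    manifest_path = outdir / "panel_manifest.csv"
    _write_csv(
        manifest_path,
        pd.DataFrame.from_records(manifest),
        {"capab_version": capab.__version__, **(extra_meta or {})},
    )
    return paths + [manifest_path]


def read_panel(indir: str | Path) -> list[TimeCourse]:
    """Read every time-course CSV in a directory (manifest excluded)."""
    indir = Path(indir)
    paths = sorted(p for p in indir.glob("*.csv") if p.name != "panel_manifest.csv")
    if not paths:
        raise FileNotFoundError(f"no time-course CSV files in {indir}")
    return [read_timecourse(p) for p in paths]


# ---------------------------------------------------------------------------
# profiles and reports

def write_profile(df: pd.DataFrame, path: str | Path, extra_meta: dict | None = None) -> None:
    if list(df.columns) != PROFILE_COLUMNS:
        raise ValueError(f"profile must have columns {PROFILE_COLUMNS}, got {list(df.columns)}")
    _write_csv(Path(path), df, {"capab_version": capab.__version__, **(extra_meta or {})})


def read_profile(path: str | Path) -> pd.DataFrame:
    df, _ = _read_csv(Path(path))
    if list(df.columns) != PROFILE_COLUMNS:
        raise ValueError(f"expected profile columns {PROFILE_COLUMNS}, got {list(df.columns)}")
    return df


def write_report(report: AssayReport, path: str | Path, extra_meta: dict | None = None) -> None:
    _write_csv(
        Path(path),
        report.to_frame(),
        {"capab_version": capab.__version__, "lod_mM": report.lod, **(extra_meta or {})},
    )


def read_report(path: str | Path) -> pd.DataFrame:
    df, _ = _read_csv(Path(path))
    return df


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    Sections (all optional in the YAML file; defaults are the package
    defaults): ``energetics`` (EnergeticsModel fields plus the pK values
    and the profile grid), ``simulation`` (KineticParams fields, noise
    sigmas, seed, t_end, dt) and ``analysis`` (window, lod).
    """

    # energetics
    dG_neutral: float = 67.0
    water_molarity: float = 55.0
    temperature: float = 298.15
    dG_atp: float = -31.0
    pKA0: float = 4.8
    pKAplus: float = 4.43
    pKBminus: float = 10.75
    ph_min: float = 0.0
    ph_max: float = 14.0
    ph_step: float = 0.1
    # simulation
    params: KineticParams = field(default_factory=default_params)
    sigma_abs: float = 0.02
    sigma_rel: float = 0.03
    seed: int = 0
    t_end: float = 120.0
    dt: float = 0.01
    # analysis
    max_conversion: float = 0.2
    lod: float = 3e-4

    _SECTIONS = {
        "energetics": (
            "dG_neutral", "water_molarity", "temperature", "dG_atp",
            "pKA0", "pKAplus", "pKBminus", "ph_min", "ph_max", "ph_step",
        ),
        "simulation": ("sigma_abs", "sigma_rel", "seed", "t_end", "dt", "params"),
        "analysis": ("max_conversion", "lod"),
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config file, rejecting any key the schema does not name."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
        kwargs: dict = {}
        for section, content in raw.items():
            if section not in cls._SECTIONS:
                raise ValueError(
                    f"unknown config section {section!r}; expected one of "
                    f"{sorted(cls._SECTIONS)}"
                )
            if not isinstance(content, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            allowed = cls._SECTIONS[section]
            for key, value in content.items():
                if key == "params" and section == "simulation":
                    param_fields = {f.name for f in fields(KineticParams)}
                    unknown = set(value) - param_fields
                    if unknown:
                        raise ValueError(
                            f"unknown kinetic parameter(s) {sorted(unknown)}; "
                            f"expected {sorted(param_fields)}"
                        )
                    defaults = asdict(default_params())
                    defaults.update(value)
                    kwargs["params"] = KineticParams(**defaults)
                elif key in allowed:
                    kwargs[key] = value
                else:
                    raise ValueError(
                        f"unknown key {key!r} in config section {section!r}; "
                        f"expected one of {sorted(allowed)}"
                    )
        config = cls(**kwargs)
        config.validate()
        return config

    def validate(self) -> None:
        for name in ("sigma_abs", "sigma_rel", "lod"):
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name} must be nonnegative")
        for name in ("t_end", "dt", "ph_step", "max_conversion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        # constructing the models triggers their own validation
        self.energetics_model()

    def energetics_model(self) -> EnergeticsModel:
        return EnergeticsModel(
            dG_neutral=self.dG_neutral,
            water_molarity=self.water_molarity,
            temperature=self.temperature,
            dG_atp=self.dG_atp,
            pks=MicroPKSet(self.pKA0, self.pKAplus, self.pKBminus, self.temperature),
        )

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full pipeline: energetics profile, simulated panel, report.

    Writes three artifact sets under ``outdir`` and returns their paths.
    Identical config and seed produce byte-identical numeric outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    logger.info("pipeline start: config %s seed %s", config.hash(), config.seed)

    model = config.energetics_model()
    profile = dg_profile(config.ph_min, config.ph_max, config.ph_step, model)
    profile_path = outdir / "energy_profile.csv"
    write_profile(profile, profile_path, meta)
    logger.info("wrote %s (%d pH points)", profile_path, len(profile))

    panel = []
    rng = np.random.default_rng(config.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(panel_conditions()))
    for cond, s in zip(panel_conditions(t_end=config.t_end), child_seeds):
        tc = simulate_timecourse(cond, config.params, dt=config.dt)
        panel.append(add_measurement_noise(tc, config.sigma_abs, config.sigma_rel, int(s)))
    panel_dir = outdir / "panel"
    write_panel(panel, panel_dir, meta)
    logger.info("wrote %d time courses to %s", len(panel), panel_dir)

    report = condition_summary(panel, max_conversion=config.max_conversion, lod=config.lod)
    report_path = outdir / "assay_report.csv"
    write_report(report, report_path, meta)
    logger.info("wrote %s", report_path)

    return {"profile": profile_path, "panel": panel_dir, "report": report_path}
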