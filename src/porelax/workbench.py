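"""End-to-end study orchestration, file dialects, and provenance.

Ties the stages together in the order the analysis runs on real data:
generate (or load) raw traces -> convert to stress -> Savitzky-Golay
smoothing matched to the motor period -> fix E3 from the relaxation tail
-> staged least-squares fit of (E1, nu21, t_g) -> aggregate parameter
table -> rate sweeps and peak-force surface.

Every run is reproducible: a single global seed is fanned out to per-trace
sub-seeds by a counter scheme, the config hash and package version are
recorded in the report, and result files are written with sorted keys so
reruns are byte-identical.

File dialects
-------------
raw trace CSV      : columns ``time_s, signal_V`` + JSON calibration sidecar
processed trace CSV: columns ``time_s, stress_kPa``
parameter JSON     : keys ``E1_kPa, E3_kPa, nu21, nu31, tg_s, porosity, radius_m``
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constitutive import ScaffoldParameters
from .fitting import FitConfig, fit_parameters
from .forward import RampProtocol, RelaxationTrace
from .prediction import fit_peak_surface, interpolate_porosity, peak_load, rate_sweep
from .preprocess import (
    Calibration,
    CalibrationError,
    RawTrace,
    convert_raw,
    frame_length,
    smooth,
)
from .synthetic import REFERENCE_SCAFFOLDS, STUDY_STRAIN_RATES, generate_study

__all__ = [
    "StudyConfig",
    "run_study",
    "load_config",
    "write_trace_csv",
    "read_trace_csv",
    "write_raw_csv",
    "read_raw_csv",
]


# -- file dialects ---------------------------------------------------------

def write_trace_csv(trace: RelaxationTrace, path: str | Path) -> None:
    """Processed-trace CSV: ``time_s, stress_kPa`` (UTF-8, header row)."""
    df = pd.DataFrame({"time_s": trace.time, "stress_kPa": trace.stress})
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, protocol: RampProtocol | None = None) -> RelaxationTrace:
    df = pd.read_csv(path)
    if not {"time_s", "stress_kPa"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time_s, stress_kPa")
    return RelaxationTrace(time=df["time_s"].to_numpy(),
                           stress=df["stress_kPa"].to_numpy(), protocol=protocol)


def write_raw_csv(raw: RawTrace, path: str | Path) -> None:
    """Raw-trace CSV ``time_s, signal_V`` plus ``<stem>.calibration.json``."""
    path = Path(path)
    pd.DataFrame({"time_s": raw.time, "signal_V": raw.signal}).to_csv(path, index=False)
    if raw.calibration is not None:
        sidecar = path.with_suffix(".calibration.json")
        sidecar.write_text(json.dumps({
            "gain_N_per_V": raw.calibration.gain,
            "offset_V": raw.calibration.offset,
            "cross_section_area_m2": raw.calibration.cross_section_area,
            "sample_rate_hz": raw.sample_rate,
        }, indent=2, sort_keys=True) + "\n")


def read_raw_csv(path: str | Path) -> RawTrace:
    """Read a raw trace; raises :class:`CalibrationError` without a sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "signal_V"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time_s, signal_V")
    sidecar = path.with_suffix(".calibration.json")
    if not sidecar.exists():
        raise CalibrationError(f"missing calibration sidecar {sidecar}")
    cal = json.loads(sidecar.read_text())
    return RawTrace(
        time=df["time_s"].to_numpy(),
        signal=df["signal_V"].to_numpy(),
        calibration=Calibration(
            gain=cal["gain_N_per_V"],
            offset=cal["offset_V"],
            cross_section_area=cal["cross_section_area_m2"],
        ),
        sample_rate=cal.get("sample_rate_hz", 100.0),
    )


# -- study configuration ---------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full synthetic study run.

    ``trace_dir`` may point at a directory of raw CSVs with metadata
    sidecars (``<stem>.meta.json``); when None, traces are generated from
    the reference scaffolds with the global seed.
    """

    seed: int = 0
    output_dir: str = "study_out"
    noiseless: bool = False
    trace_dir: str | None = None
    total_strain: float = 0.1
    hold_time: float = 100.0
    sample_rate: float = 100.0
    motor_frequency: float = 1.0
    surface_porosities: tuple = (0.5, 0.55, 0.6, 0.65, 0.7)
    surface_rates: tuple = STUDY_STRAIN_RATES  # 1/s
    fit: FitConfig = field(default_factory=FitConfig)

    def to_canonical_json(self) -> str:
        d = {
            "seed": self.seed,
            "noiseless": self.noiseless,
            "trace_dir": self.trace_dir,
            "total_strain": self.total_strain,
            "hold_time": self.hold_time,
            "sample_rate": self.sample_rate,
            "motor_frequency": self.motor_frequency,
            "surface_porosities": list(self.surface_porosities),
            "surface_rates": list(self.surface_rates),
            "fit": {
                "staged": self.fit.staged,
                "nu21_init": self.fit.nu21_init,
                "nu31": self.fit.nu31,
                "n_tail": self.fit.n_tail,
                "n_roots": self.fit.n_roots,
                "bounds": {k: list(v) for k, v in sorted(self.fit.bounds.items())},
            },
        }
        return json.dumps(d, sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML study configuration."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    fit_d = d.pop("fit", {})
    fit = FitConfig(**fit_d) if fit_d else FitConfig()
    for key in ("surface_porosities", "surface_rates"):
        if key in d:
            d[key] = tuple(d[key])
    return StudyConfig(fit=fit, **d)


# -- the study -------------------------------------------------------------

def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline and write per-trace and aggregate outputs.

    Per trace: smoothed-trace CSV and fit-result JSON.  Aggregate: a
    parameter table (one row per porosity, from the 1%/s trace, matching
    how the reference estimates were produced), rate-sweep tables, and the
    peak-surface coefficients.  Any stage failure is recorded in the report
    under ``errors`` with the trace name; the remaining stages still run.

    Returns the report dict (also written to ``report.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "traces": {},
        "errors": {},
    }

    if config.trace_dir is not None:
        records = _load_trace_dir(Path(config.trace_dir))
    else:
        records = generate_study(
            config.seed,
            noiseless=config.noiseless,
            hold_time=config.hold_time,
            total_strain=config.total_strain,
            sample_rate=config.sample_rate,
        )

    fits: dict[float, dict] = {}  # porosity -> fit dict (1%/s trace)
    for rec in records:
        meta = rec["meta"]
        name = f"phi{int(round(meta['porosity'] * 100))}_rate{meta['strain_rate_per_s'] * 100:g}"
        try:
            protocol = rec["protocol"]
            trace = convert_raw(rec["raw"], protocol=protocol)
            n_cycles = max(1, int(round(protocol.ramp_time * meta.get(
                "motor_frequency_hz", config.motor_frequency))))
            frame = frame_length(protocol.ramp_time, rec["raw"].sample_rate, n_cycles)
            smoothed = smooth(trace, frame)
            write_trace_csv(smoothed, out / f"{name}.csv")
            # the filter is part of the observation operator: the model is
            # passed through the same window inside the fit residual
            fit_cfg = dataclasses.replace(config.fit, filter_frame=frame)
            result = fit_parameters(smoothed, fit_cfg)
            fit_d = result.to_dict()
            fit_d.update({
                "seed": meta.get("seed"),
                "config_hash": config.config_hash,
                "frame_length": frame,
            })
            _json_dump(fit_d, out / f"{name}.fit.json")
            report["traces"][name] = fit_d
            if abs(meta["strain_rate_per_s"] - 0.01) < 1e-12:
                fits[meta["porosity"]] = fit_d
        except Exception as exc:  # record and continue with other traces
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    # aggregate parameter table (one row per porosity)
    if fits:
        table = pd.DataFrame(
            [{"porosity": phi, **{k: v for k, v in d.items()
                                  if k in ("E1_kPa", "tg_s", "nu21", "E3_kPa", "nu31", "r2")}}
             for phi, d in sorted(fits.items())]
        )
        table.to_csv(out / "parameter_table.csv", index=False)
        report["parameter_table"] = table.to_dict(orient="records")

    # prediction layer from the fitted anchors (fall back to reference sets
    # if a fit failed, so the surface is always produced)
    anchors = {}
    for phi, d in fits.items():
        anchors[phi] = ScaffoldParameters(
            E1=d["E1_kPa"], E3=d["E3_kPa"], nu21=d["nu21"], nu31=d["nu31"],
            tg=d["tg_s"], porosity=phi,
        )
    if len(anchors) < 2:
        anchors = dict(REFERENCE_SCAFFOLDS)
        report["anchors"] = "reference"
    else:
        report["anchors"] = "fitted"

    sweeps = {}
    for phi, params in sorted(anchors.items()):
        df = rate_sweep(params, config.surface_rates,
                        total_strain=config.total_strain,
                        hold_time=config.hold_time)
        df.to_csv(out / f"rate_sweep_phi{int(round(phi * 100))}.csv", index=False)
        sweeps[phi] = df
    report["rate_sweep"] = {
        str(phi): df.replace({np.inf: "step"}).to_dict(orient="records")
        for phi, df in sweeps.items()
    }

    rows = []
    for phi in config.surface_porosities:
        params = interpolate_porosity(anchors, phi)
        for rate in config.surface_rates:
            pk = peak_load(params, RampProtocol(rate, config.total_strain,
                                                config.hold_time))
            rows.append({"porosity": phi, "rate": rate * 100.0, "peak_kPa": pk})
    peaks = pd.DataFrame(rows)
    peaks.to_csv(out / "peak_grid.csv", index=False)
    surface = fit_peak_surface(peaks)
    report["peak_surface"] = {
        "m": surface.m, "n": surface.n, "a": surface.a, "b": surface.b,
        "c": surface.c, "d": surface.d, "rms_residual_kPa": surface.residual,
        "axes": "x = porosity fraction, y = strain rate in %/s",
    }

    _json_dump(report, out / "report.json")
    return report


def _load_trace_dir(trace_dir: Path) -> list[dict]:
    """Load raw CSVs + sidecars from a directory written by the synth CLI."""
    records = []
    for csv in sorted(trace_dir.glob("*.csv")):
        if csv.name.endswith(".calibration.csv"):
            continue
        meta_path = csv.with_suffix(".meta.json")
        if not meta_path.exists():
            raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
        meta = json.loads(meta_path.read_text())
        raw = read_raw_csv(csv)
        protocol = RampProtocol(
            strain_rate=meta["strain_rate_per_s"],
            total_strain=meta["total_strain"],
            hold_time=meta["hold_time_s"],
        )
        records.append({"raw": raw, "protocol": protocol, "meta": meta})
    if not records:
        raise FileNotFoundError(f"no raw traces found in {trace_dir}")
    return records
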