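"""File formats and run configuration.

Traces travel as two-column CSV (``abscissa,intensity``); per-trace
metadata (z, angle, abscissa kind, scale) lives in a manifest CSV next to
them, and simulator ground truth in a JSON sidecar.  The run configuration
is a YAML document mirroring the domain types; unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beam_optics import ObjectiveSpec
from .synthetic_data import AcquisitionModel, GridModel, SimulatedSeries
from .trace_analysis import AnalysisConfig, Trace

__all__ = [
    "RunConfig",
    "ConfigError",
    "read_trace_csv",
    "write_trace_csv",
    "write_series",
    "read_manifest",
    "write_report",
    "REPORT_SCHEMA",
]

REPORT_SCHEMA = "edgescan.report/1"

MANIFEST_COLUMNS = [
    "path", "z_um", "angle_deg", "abscissa_kind", "scale_um_per_s", "seed",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    df = pd.DataFrame({"abscissa": trace.abscissa, "intensity": trace.intensity})
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace_csv(
    path: str | Path,
    z: float = 0.0,
    angle: float = 0.0,
    abscissa_kind: str = "distance",
    scale: float | None = None,
) -> Trace:
    df = pd.read_csv(path, usecols=["abscissa", "intensity"])
    df = df.apply(pd.to_numeric, errors="coerce").dropna()
    return Trace(
        abscissa=df["abscissa"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        abscissa_kind=abscissa_kind,  # type: ignore[arg-type]
        scale=scale,
        z=z,
        angle=angle,
    )


def write_series(series: SimulatedSeries, out_dir: str | Path) -> Path:
    """Write traces, manifest and ground truth; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trace in enumerate(series.traces):
        name = f"trace_{i:03d}_z{trace.z:+08.3f}_a{int(trace.angle):02d}.csv"
        write_trace_csv(trace, out / name)
        row = series.manifest.iloc[i].to_dict()
        row["path"] = name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest = manifest[[c for c in MANIFEST_COLUMNS if c in manifest.columns]
                        + [c for c in manifest.columns if c not in MANIFEST_COLUMNS]]
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(series.truth, fh, indent=2, sort_keys=True)
    return manifest_path


def read_manifest(manifest_path: str | Path) -> list[Trace]:
    """Load every trace listed in a manifest, attaching its metadata."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "seed"]
    if missing:
        raise ConfigError(f"manifest is missing columns: {missing}")
    traces = []
    for _, row in df.iterrows():
        scale = row.get("scale_um_per_s")
        scale = None if pd.isna(scale) else float(scale)
        traces.append(
            read_trace_csv(
                manifest_path.parent / str(row["path"]),
                z=float(row["z_um"]),
                angle=float(row["angle_deg"]),
                abscissa_kind=str(row["abscissa_kind"]),
                scale=scale,
            )
        )
    return traces


def write_report(report: dict, path: str | Path) -> None:
    report = {"schema": REPORT_SCHEMA, **report}

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=default)


# --- run configuration -----------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything a simulate/analyze run needs, in one validated object."""

    wavelength: float = 488.0
    objective: ObjectiveSpec = field(
        default_factory=lambda: ObjectiveSpec(magnification=20, na=0.7)
    )
    grid: GridModel = field(default_factory=GridModel)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)
    seed: int = 0
    out_dir: str = "edgescan_out"

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ConfigError("wavelength must be positive")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        sections = {
            "objective": ObjectiveSpec,
            "grid": GridModel,
            "analysis": AnalysisConfig,
            "acquisition": AcquisitionModel,
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in data.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                klass = sections[key]
                names = {f.name for f in dataclasses.fields(klass)}
                bad = set(value) - names
                if bad:
                    raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
                try:
                    kwargs[key] = klass(**value)
                except ValueError as exc:
                    raise ConfigError(f"invalid {key!r}: {exc}") from exc
            else:
                kwargs[key] = value
        try:
            return cls(**kwargs)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_mapping(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
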