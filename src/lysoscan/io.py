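"""Readers and writers for the pipeline's plain-text formats.

All tables are comma-separated UTF-8 with a header row and '.' decimals:
long-format profile CSVs (tubule_id, profile_id, position, time_min,
intensity), waveform CSVs (first column ``position_bin``, one ``t_<min>``
column per time point) with a JSON sidecar (orientation, QC report,
provenance), tubule-series CSVs (segment, channel, time_min, intensity) and
component tables.  Readers validate invariants and name the offending row
and column on failure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import SVDResult, component_readouts
from .preprocess import LineScanProfile, WaveformMatrix
from .simulate import TubuleTimeSeries

PROFILE_COLUMNS = ["tubule_id", "profile_id", "position", "time_min", "intensity"]
SERIES_COLUMNS = ["segment", "channel", "time_min", "intensity"]


# ---------------------------------------------------------------------------
# Line-scan profiles (long format)
# ---------------------------------------------------------------------------

def write_profiles_csv(profiles: list[LineScanProfile], path) -> None:
    sizes = [p.positions.size for p in profiles]
    df = pd.DataFrame({
        "tubule_id": np.repeat([p.tubule_id for p in profiles], sizes),
        "profile_id": np.repeat([p.profile_id for p in profiles], sizes),
        "position": np.concatenate([p.positions for p in profiles]),
        "time_min": np.repeat([p.time for p in profiles], sizes),
        "intensity": np.concatenate([p.intensities for p in profiles]),
    })
    df.to_csv(path, index=False)


def read_profiles(path) -> list[LineScanProfile]:
    """Read a long-format profile CSV into validated profiles, order preserved."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    for col in ("position", "time_min", "intensity"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}")
    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise ValueError(
            f"{path}: negative intensity in row {neg[0] + 2}")
    profiles = []
    for (tub, t, pid), grp in df.groupby(["tubule_id", "time_min", "profile_id"],
                                         sort=False):
        profiles.append(LineScanProfile(str(tub), float(t),
                                        grp["position"].to_numpy(),
                                        grp["intensity"].to_numpy(), int(pid)))
    return profiles


# ---------------------------------------------------------------------------
# Waveform matrices
# ---------------------------------------------------------------------------

def write_waveform_csv(wf: WaveformMatrix, path, sidecar: dict | None = None,
                       orientation: str = "apical_first") -> None:
    path = Path(path)
    cols = {"position_bin": wf.position_bins}
    for j, t in enumerate(wf.times):
        cols[f"t_{t:g}"] = wf.values[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"tubule_id": wf.tubule_id, "orientation": orientation,
            "n_bins": len(wf.position_bins), "n_times": len(wf.times)}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_waveform_csv(path) -> WaveformMatrix:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "position_bin" not in df.columns:
        raise ValueError(f"{path}: missing 'position_bin' column")
    tcols = [c for c in df.columns if c.startswith("t_")]
    if not tcols:
        raise ValueError(f"{path}: no time columns (t_<min>)")
    times = np.array([float(c[2:]) for c in tcols])
    order = np.argsort(times)
    values = df[tcols].to_numpy()[:, order]
    tubule_id = path.stem
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        tubule_id = json.loads(sidecar.read_text()).get("tubule_id", tubule_id)
    return WaveformMatrix(tubule_id, df["position_bin"].to_numpy(),
                          times[order], values)


# ---------------------------------------------------------------------------
# Tubule time series
# ---------------------------------------------------------------------------

def write_series_csv(series: dict[str, TubuleTimeSeries] | list[TubuleTimeSeries],
                     path) -> None:
    items = series.values() if isinstance(series, dict) else series
    frames = [pd.DataFrame({"segment": s.segment, "channel": s.channel,
                            "time_min": s.times, "intensity": s.intensities})
              for s in items]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series_csv(path) -> dict[tuple[str, str], TubuleTimeSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for (seg, chan), grp in df.groupby(["segment", "channel"], sort=False):
        out[(str(seg), str(chan))] = TubuleTimeSeries(
            str(seg), grp["time_min"].to_numpy(), grp["intensity"].to_numpy(),
            channel=str(chan))
    return out


# ---------------------------------------------------------------------------
# Decomposition outputs
# ---------------------------------------------------------------------------

def write_components_csv(result: SVDResult, outdir) -> None:
    """Write diagnostics, spatial shapes and kinetic amplitudes of a decomposition."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.diagnostics.to_csv(outdir / "component_diagnostics.csv", index=False)
    readouts = component_readouts(result)
    if readouts:
        shapes = {"position_bin": result.position_bins}
        amps = {"time_min": result.times}
        for r in readouts:
            shapes[f"component_{r.component + 1}"] = r.spatial_shape
            amps[f"component_{r.component + 1}"] = r.kinetic_amplitude
        pd.DataFrame(shapes).to_csv(outdir / "spatial_shapes.csv", index=False)
        pd.DataFrame(amps).to_csv(outdir / "kinetic_amplitudes.csv", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of one end-to-end pipeline run; fully serializable."""

    seed: int = 0
    scenario_name: str = "healthy-S1"
    scenario_path: str | None = None
    n_bins: int = 100
    ac_min: float = 0.5
    sv_frac_min: float = 0.01
    onset_fraction: float = 0.5
    uptake_threshold: float = 0.25
    qc_corr_min: float = 0.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        for name in ("ac_min", "sv_frac_min", "onset_fraction",
                     "uptake_threshold", "qc_corr_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
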