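"""Session-directory data model: table formats, manifests, provenance.

All interchange uses plain delimited tables (CSV) with ``# key: value``
provenance header lines, plus YAML for arena, threshold, manifest, and
pipeline configuration files. Column names and units:

- trajectory: ``frame, time_s, nose_x, nose_y, earL_x, earL_y, earR_x,
  earR_y, tail_x, tail_y`` (cm, arena frame: origin at the safe short wall,
  x toward the threat)
- epochs / ground truth: ``label, onset_frame, offset_frame, ...``
- photometry: ``time_s, value, channel`` (channel 405 or 470)
- ensemble: ``time_s, cell_0, cell_1, ...`` (one row per frame)
- kinematics: as produced by :func:`escapekit.behavior.compute_kinematics`
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (ArenaSpec, BehaviorThresholds, Trajectory,
                   frame_to_epochs)
from .ensemble import EnsembleRecording
from .errors import AlignmentError, FormatError
from .photometry import PhotometryRecording

REGIMES = ("habituation", "toy_rat", "rat", "pre_shock", "fear_conditioning",
           "fear_retrieval", "synthetic")


def provenance_header(meta: dict | None = None) -> str:
    lines = [f"# escapekit_version: {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(meta))
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# --- typed writers/readers -------------------------------------------------

def write_trajectory(traj: Trajectory, path, meta=None) -> Path:
    meta = {"frame_rate_hz": traj.frame_rate_hz, **(meta or {})}
    return write_table(traj.df, path, meta)


def read_trajectory(path, frame_rate_hz: float | None = None) -> Trajectory:
    df = read_table(path)
    if frame_rate_hz is None:
        with open(path) as fh:
            for line in fh:
                if line.startswith("# frame_rate_hz:"):
                    frame_rate_hz = float(line.split(":")[1])
                    break
                if not line.startswith("#"):
                    break
    return Trajectory(df=df, frame_rate_hz=frame_rate_hz or 30.0)


def write_photometry(rec: PhotometryRecording, path, meta=None) -> Path:
    df = pd.DataFrame({"time_s": rec.times, "value": rec.values,
                       "channel": rec.channel})
    return write_table(df, path, {"rate_hz": rec.rate_hz, **(meta or {})})


def read_photometry(path) -> PhotometryRecording:
    df = read_table(path)
    for col in ("time_s", "value", "channel"):
        if col not in df.columns:
            raise FormatError(f"photometry table missing column {col!r}")
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 20.0
    return PhotometryRecording(times=t, values=df["value"].to_numpy(),
                               channel=df["channel"].to_numpy(dtype=int),
                               rate_hz=rate)


def write_ensemble(rec: EnsembleRecording, path, meta=None) -> Path:
    df = pd.DataFrame({"time_s": rec.times})
    for i, cid in enumerate(rec.cell_ids):
        df[f"cell_{cid}"] = rec.traces[i]
    return write_table(df, path, meta)


def read_ensemble(path) -> EnsembleRecording:
    df = read_table(path)
    cells = [c for c in df.columns if c.startswith("cell_")]
    if not cells:
        raise FormatError("ensemble table has no cell_* columns")
    return EnsembleRecording(
        traces=df[cells].to_numpy().T,
        times=df["time_s"].to_numpy(),
        cell_ids=np.array([int(c.split("_", 1)[1]) for c in cells]))


def write_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_arena(path) -> ArenaSpec:
    return ArenaSpec(**read_yaml(path))


def read_thresholds(path) -> BehaviorThresholds:
    return BehaviorThresholds(**read_yaml(path))


# --- session manifest ------------------------------------------------------

@dataclass
class SessionBundle:
    """Parsed contents of one session directory."""

    session_id: str
    regime: str
    frame_rate_hz: float
    trajectory: Trajectory
    ground_truth: pd.DataFrame | None = None
    photometry: PhotometryRecording | None = None
    ensemble: EnsembleRecording | None = None
    arena: ArenaSpec = ArenaSpec()

    @property
    def ground_truth_epochs(self):
        if self.ground_truth is None:
            return None
        return frame_to_epochs(self.ground_truth)


def _check_overlap(t_a: np.ndarray, t_b: np.ndarray, what: str,
                   min_overlap: float = 0.95):
    lo = max(t_a[0], t_b[0])
    hi = min(t_a[-1], t_b[-1])
    span = t_a[-1] - t_a[0]
    frac = max(0.0, hi - lo) / span if span > 0 else 0.0
    if frac < min_overlap:
        raise AlignmentError(
            f"{what} overlaps only {frac:.0%} of the trajectory time base "
            f"(minimum {min_overlap:.0%})")


def load_session(manifest_path) -> SessionBundle:
    """Load a session from its YAML manifest.

    The manifest maps data kinds to file paths (relative to the manifest's
    directory). Referenced files must exist (a missing file raises an error
    naming the field) and the photometry/ensemble time bases must overlap the
    trajectory span by at least 95%.
    """
    manifest_path = Path(manifest_path)
    m = read_yaml(manifest_path)
    root = manifest_path.parent
    regime = m.get("regime", "synthetic")
    if regime not in REGIMES:
        raise FormatError(f"unknown regime {regime!r}; expected one "
                          f"of {REGIMES}")
    files = m.get("files", {})

    def _path(field, required=False):
        rel = files.get(field)
        if rel is None:
            if required:
                raise FileNotFoundError(f"{field}: not listed in manifest")
            return None
        p = root / rel
        if not p.exists():
            raise FileNotFoundError(f"{field}: {p} does not exist")
        return p

    fps = float(m.get("frame_rate_hz", 30.0))
    traj = read_trajectory(_path("trajectory", required=True), fps)
    bundle = SessionBundle(
        session_id=str(m.get("session_id", manifest_path.stem)),
        regime=regime, frame_rate_hz=fps, trajectory=traj,
        arena=ArenaSpec(**m["arena"]) if "arena" in m else ArenaSpec())
    gt = _path("ground_truth")
    if gt:
        bundle.ground_truth = read_table(gt)
    ph = _path("photometry")
    if ph:
        bundle.photometry = read_photometry(ph)
        _check_overlap(traj.times, bundle.photometry.times, "photometry")
    en = _path("ensemble")
    if en:
        bundle.ensemble = read_ensemble(en)
        _check_overlap(traj.times, bundle.ensemble.times, "ensemble")
    return bundle
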