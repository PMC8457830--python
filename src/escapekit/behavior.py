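"""Kinematics and threshold-based classification of defensive behaviors.

Five behaviors are classified from pose-derived kinematics with explicit
per-clause rules:

- **escape**: speed away from the threat > 2 cm/s, initiated within 30 cm of
  the threat, traversing > 10 cm away from it;
- **approach**: speed toward the threat > 2 cm/s, traversing > 10 cm toward it;
- **stretch** (stretch-attend posture): nose-tailbase distance > 1.2 baseline
  body lengths while tailbase speed < 1 cm/s;
- **freeze**: nose and tailbase speed < 0.25 cm/s for at least 0.33 s;
- **walk**: speed perpendicular to the threat axis > 2 cm/s, traversing > 5 cm
  across the arena.

Labels are not mutually exclusive; each classifier is a pure function of
(kinematics, thresholds). Epochs are half-open frame intervals, and epochs of
the same label separated by fewer than ``merge_gap_frames`` frames are merged
before clause filtering (threshold chatter at frame resolution).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import (ArenaSpec, BehaviorEpoch, BehaviorThresholds,
                   KinematicsSeries, Trajectory, BEHAVIOR_LABELS)
from .errors import InsufficientDataError, ParameterError


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return a.astype(float)
    return uniform_filter1d(a.astype(float), size=window, mode="nearest")


def _diff_speed(xy: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame speed from finite differences; speed[0] copies speed[1]."""
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1) * fps
    return np.concatenate([[d[0] if len(d) else 0.0], d])


def compute_kinematics(traj: Trajectory, arena: ArenaSpec,
                       smoothing_window: int = 5) -> KinematicsSeries:
    """Derive per-frame kinematics from a pose trajectory.

    Coordinates are smoothed with a centered moving average (default 5 frames
    at 30 Hz) before finite differencing; raw 30 Hz pose differences are
    noise-dominated. Frames with missing keypoints propagate as NaN gaps that
    the classifiers treat as non-classifiable (gaps dilate by the smoothing
    window).
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("kinematics needs at least 2 frames")
    fps = traj.frame_rate_hz

    tail = np.column_stack([_smooth(traj.df[c].to_numpy(), smoothing_window)
                            for c in ("tail_x", "tail_y")])
    nose = np.column_stack([_smooth(traj.df[c].to_numpy(), smoothing_window)
                            for c in ("nose_x", "nose_y")])
    earL = np.column_stack([_smooth(traj.df[c].to_numpy(), smoothing_window)
                            for c in ("earL_x", "earL_y")])
    earR = np.column_stack([_smooth(traj.df[c].to_numpy(), smoothing_window)
                            for c in ("earR_x", "earR_y")])

    speed = _diff_speed(tail, fps)
    nose_speed = _diff_speed(nose, fps)

    dx = np.concatenate([[0.0], np.diff(tail[:, 0])]) * fps
    dx[0] = dx[1] if len(dx) > 1 else 0.0
    v_threat = arena.toward_sign * dx
    dy = np.concatenate([[0.0], np.diff(tail[:, 1])]) * fps
    dy[0] = dy[1] if len(dy) > 1 else 0.0

    dist_threat = arena.distance_from_threat(nose[:, 0])
    body_len = np.linalg.norm(nose - tail, axis=1)

    # head direction: line from the inter-ear midpoint through the nose;
    # +1 = facing away from the threat, -1 = facing it
    earmid = 0.5 * (earL + earR)
    u = nose - earmid
    norm = np.linalg.norm(u, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        head_cos = np.where(norm > 0,
                            -arena.toward_sign * u[:, 0] / norm, np.nan)

    df = pd.DataFrame({
        "time_s": traj.times,
        "x": tail[:, 0], "y": tail[:, 1],
        "speed": speed, "nose_speed": nose_speed,
        "v_threat": v_threat, "v_perp": dy,
        "dist_threat": dist_threat,
        "body_len": body_len, "head_cos": head_cos,
    })
    return KinematicsSeries(df=df, frame_rate_hz=fps, arena=arena)


# ---------------------------------------------------------------------------
# run extraction

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) pairs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def _epoch(kin: KinematicsSeries, label: str, s: int, e: int,
           traversal: float = np.nan) -> BehaviorEpoch:
    speed = kin["speed"][s:e]
    return BehaviorEpoch(
        label=label, onset=s, offset=e,
        duration_s=(e - s) / kin.frame_rate_hz,
        mean_speed=float(np.nanmean(speed)) if len(speed) else np.nan,
        traversal_cm=traversal,
    )


# ---------------------------------------------------------------------------
# classifiers

def classify_escapes(kin: KinematicsSeries,
                     thr: BehaviorThresholds = BehaviorThresholds()
                     ) -> list[BehaviorEpoch]:
    """Escape epochs: all three clauses must hold.

    (1) speed away from the threat exceeds ``thr.speed_cms``;
    (2) initiation within ``thr.escape_init_distance_cm`` of the threat
        (inequality direction switchable via ``thr.escape_init_within``);
    (3) distance traversed away from the threat from onset to offset exceeds
        ``thr.escape_min_traversal_cm``.

    Zero epochs is a valid result. Per-epoch escape speed (mean speed from
    onset to offset) and traversal are attached.
    """
    away = -kin["v_threat"]
    with np.errstate(invalid="ignore"):
        mask = away > thr.speed_cms
    dist = kin["dist_threat"]
    out = []
    for s, e in _merge_runs(_runs(mask), thr.merge_gap_frames):
        if thr.escape_init_within:
            init_ok = dist[s] <= thr.escape_init_distance_cm
        else:
            init_ok = dist[s] >= thr.escape_init_distance_cm
        traversal = dist[e - 1] - dist[s]
        if init_ok and traversal > thr.escape_min_traversal_cm:
            out.append(_epoch(kin, "escape", s, e, traversal=float(traversal)))
    return out


def classify_simple_behaviors(kin: KinematicsSeries,
                              thr: BehaviorThresholds,
                              label: str) -> list[BehaviorEpoch]:
    """Classify one of approach / stretch / freeze / walk by its clause set."""
    if label == "approach":
        with np.errstate(invalid="ignore"):
            mask = kin["v_threat"] > thr.speed_cms
        dist = kin["dist_threat"]
        runs = _merge_runs(_runs(mask), thr.merge_gap_frames)
        return [
            _epoch(kin, label, s, e, traversal=float(dist[s] - dist[e - 1]))
            for s, e in runs
            if dist[s] - dist[e - 1] > thr.approach_min_traversal_cm
        ]

    if label == "walk":
        with np.errstate(invalid="ignore"):
            mask = np.abs(kin["v_perp"]) > thr.speed_cms
        y = kin["y"]
        runs = _merge_runs(_runs(mask), thr.merge_gap_frames)
        return [
            _epoch(kin, label, s, e, traversal=float(abs(y[e - 1] - y[s])))
            for s, e in runs
            if abs(y[e - 1] - y[s]) > thr.walk_min_traversal_cm
        ]

    if label == "stretch":
        base = estimate_body_length(kin, thr)
        with np.errstate(invalid="ignore"):
            mask = ((kin["body_len"] > thr.stretch_elongation_factor * base)
                    & (kin["speed"] < thr.stretch_tail_speed_cms))
        runs = _merge_runs(_runs(mask), thr.merge_gap_frames)
        return [_epoch(kin, label, s, e) for s, e in runs]

    if label == "freeze":
        with np.errstate(invalid="ignore"):
            mask = ((kin["speed"] < thr.freeze_speed_cms)
                    & (kin["nose_speed"] < thr.freeze_speed_cms))
        fps = kin.frame_rate_hz
        runs = _merge_runs(_runs(mask), thr.merge_gap_frames)
        eps = 1e-9
        return [
            _epoch(kin, label, s, e) for s, e in runs
            if (e - s) / fps >= thr.freeze_min_duration_s - eps
        ]

    raise ParameterError(f"unknown behavior label {label!r}; "
                         f"expected one of {BEHAVIOR_LABELS[1:]}")


def estimate_body_length(kin: KinematicsSeries,
                         thr: BehaviorThresholds = BehaviorThresholds()
                         ) -> float:
    """Per-session baseline body length for the stretch rule.

    Median nose-tailbase distance over non-stretch frames, found in two
    passes: a provisional median over all frames flags candidate elongated
    frames, which are excluded from the final median.
    """
    bl = kin["body_len"]
    m0 = np.nanmedian(bl)
    keep = ~(bl > thr.stretch_elongation_factor * m0)
    if keep.sum() == 0:
        return float(m0)
    return float(np.nanmedian(bl[keep]))


def classify_all(kin: KinematicsSeries,
                 thr: BehaviorThresholds = BehaviorThresholds()
                 ) -> list[BehaviorEpoch]:
    """All five classifiers, concatenated in label order then by onset."""
    epochs = list(classify_escapes(kin, thr))
    for label in ("approach", "stretch", "freeze", "walk"):
        epochs.extend(classify_simple_behaviors(kin, thr, label))
    return sorted(epochs, key=lambda e: (e.onset, e.label))


def summarize_session(epochs: list[BehaviorEpoch],
                      kin: KinematicsSeries) -> pd.Series:
    """Per-session behavioral summary.

    Counts and total durations per label, mean freeze bout duration, mean
    escape and approach speeds, and mean distance-from-threat. Means over
    zero epochs are NaN.
    """
    out = {}
    for label in BEHAVIOR_LABELS:
        sel = [e for e in epochs if e.label == label]
        out[f"n_{label}"] = len(sel)
        out[f"total_{label}_s"] = float(sum(e.duration_s for e in sel))
    freezes = [e.duration_s for e in epochs if e.label == "freeze"]
    out["mean_freeze_bout_s"] = float(np.mean(freezes)) if freezes else np.nan
    for label in ("escape", "approach"):
        speeds = [e.mean_speed for e in epochs if e.label == label]
        out[f"mean_{label}_speed_cms"] = (float(np.mean(speeds))
                                          if speeds else np.nan)
    out["mean_dist_threat_cm"] = float(np.nanmean(kin["dist_threat"]))
    return pd.Series(out)
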