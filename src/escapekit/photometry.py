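"""Dual-channel fiber-photometry correction and behavior-locked summaries.

The 405 nm isosbestic channel is calcium-insensitive and records the same
non-biological artifacts (photobleaching, motion) as the 470 nm calcium
channel. Correction fits the reference to the signal by ordinary least
squares over the whole session and reports z-scored
df/F = (signal - fitted reference) / fitted reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ArenaSpec, BehaviorEpoch, KinematicsSeries, Trajectory
from .errors import (DegenerateInputError, FormatError,
                     InsufficientDataError, ParameterError)


@dataclass
class PhotometryRecording:
    """Interleaved 405/470 nm recording (alternating samples at 20 Hz)."""

    times: np.ndarray
    values: np.ndarray
    channel: np.ndarray  # 405 or 470 per sample
    rate_hz: float = 20.0

    def __post_init__(self):
        if not (len(self.times) == len(self.values) == len(self.channel)):
            raise FormatError("photometry arrays must share one length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise FormatError("photometry timestamps must be strictly "
                              "increasing")
        if not np.isin(self.channel, (405, 470)).all():
            raise FormatError("channel flags must be 405 or 470")

    @classmethod
    def from_channels(cls, t_ref, ref, t_sig, sig, rate_hz=20.0):
        """Build an interleaved recording from pre-split channel tables."""
        t = np.concatenate([t_ref, t_sig])
        v = np.concatenate([ref, sig])
        ch = np.concatenate([np.full(len(t_ref), 405),
                             np.full(len(t_sig), 470)])
        order = np.argsort(t, kind="stable")
        return cls(times=t[order], values=v[order], channel=ch[order],
                   rate_hz=rate_hz)

    def split(self):
        """(reference times, reference, signal times, signal)."""
        is_ref = self.channel == 405
        return (self.times[is_ref], self.values[is_ref],
                self.times[~is_ref], self.values[~is_ref])


@dataclass
class CorrectedSignal:
    """Artifact-corrected, session-z-scored df/F aligned to signal samples."""

    times: np.ndarray
    z: np.ndarray      # z-scored df/F
    dff: np.ndarray    # df/F before z-scoring

    def sample_at(self, t: np.ndarray) -> np.ndarray:
        """Nearest-timestamp values of the corrected signal at times ``t``."""
        idx = np.clip(np.searchsorted(self.times, t), 0, len(self.times) - 1)
        left = np.clip(idx - 1, 0, len(self.times) - 1)
        use_left = (np.abs(self.times[left] - t)
                    < np.abs(self.times[idx] - t))
        return self.z[np.where(use_left, left, idx)]


def correct_reference_artifacts(rec: PhotometryRecording) -> CorrectedSignal:
    """Remove reference-explained artifacts and z-score the residual df/F.

    De-interleaves the recording, linearly interpolates the 405 nm reference
    onto the 470 nm timestamps, fits ``signal ~ a*reference + b`` by ordinary
    least squares over the session, and returns
    ``(signal - fit)/fit`` z-scored per session.
    """
    t_ref, ref, t_sig, sig = rec.split()
    if len(t_ref) < 100 or len(t_sig) < 100:
        raise InsufficientDataError("need >= 100 samples per channel")
    ref_i = np.interp(t_sig, t_ref, ref)
    if np.std(ref_i) < 1e-12:
        raise DegenerateInputError("constant reference channel; "
                                   "artifact fit is degenerate")
    A = np.column_stack([ref_i, np.ones_like(ref_i)])
    coef, *_ = np.linalg.lstsq(A, sig, rcond=None)
    fit = A @ coef
    if np.any(np.abs(fit) < 1e-9):
        raise DegenerateInputError("fitted reference crosses zero; "
                                   "df/F undefined")
    dff = (sig - fit) / fit
    sd = dff.std()
    z = (dff - dff.mean()) / sd if sd > 1e-15 else np.zeros_like(dff)
    return CorrectedSignal(times=t_sig, z=z, dff=dff)


@dataclass
class TriggeredAverage:
    """Behavior-triggered average of a corrected signal."""

    label: str
    offsets_s: np.ndarray
    mean: np.ndarray | None
    sem: np.ndarray | None
    n: int
    pre_onset_mean: float
    excluded: bool
    reason: str = ""


def behavior_triggered_average(sig: CorrectedSignal,
                               epochs: list[BehaviorEpoch],
                               label: str,
                               frame_rate_hz: float = 30.0,
                               window_s: float = 5.0,
                               min_instances: int = 3,
                               isolation_s: float = 5.0
                               ) -> TriggeredAverage:
    """Mean +- SEM signal around onsets of one behavior.

    Only instances separated from every other classified instance by at least
    ``isolation_s`` enter the average; sessions with fewer than
    ``min_instances`` qualifying instances are marked excluded. The pre-onset
    scalar is the mean over [-2, 0] s from onset.
    """
    sel = [e for e in epochs if e.label == label]
    others = epochs

    def _interval(e):
        return e.onset / frame_rate_hz, e.offset / frame_rate_hz

    def _isolated(e):
        s, t = _interval(e)
        for o in others:
            if o is e:
                continue
            os_, ot = _interval(o)
            gap = max(os_ - t, s - ot)
            if gap < isolation_s:
                return False
        return True

    qualifying = [e for e in sel if _isolated(e)]

    rate = 1.0 / np.median(np.diff(sig.times))
    k = int(round(window_s * rate))
    offsets = np.arange(-k, k + 1) / rate
    snippets = []
    kept = []
    for e in qualifying:
        t_on = e.onset / frame_rate_hz
        i = int(np.argmin(np.abs(sig.times - t_on)))
        if i - k < 0 or i + k + 1 > len(sig.z):
            continue  # window extends beyond the recording; epoch dropped
        snippets.append(sig.z[i - k:i + k + 1])
        kept.append(e)

    if len(snippets) < min_instances:
        return TriggeredAverage(
            label=label, offsets_s=offsets, mean=None, sem=None,
            n=len(snippets), pre_onset_mean=np.nan, excluded=True,
            reason=f"{len(snippets)} qualifying instances "
                   f"< minimum {min_instances}")
    mat = np.array(snippets)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(len(mat))
    pre = (offsets >= -2.0) & (offsets <= 0.0)
    return TriggeredAverage(label=label, offsets_s=offsets, mean=mean,
                            sem=sem, n=len(mat),
                            pre_onset_mean=float(mean[pre].mean()),
                            excluded=False)


def speed_matched_activity(sig: CorrectedSignal, kin: KinematicsSeries,
                           speed_range: tuple[float, float] = (6.0, 10.0)
                           ) -> tuple[float, int]:
    """Mean corrected signal over samples whose speed is in the closed range.

    Comparing regimes at matched speed removes the locomotor confound from
    activity contrasts. Returns (mean, sample count); the mean is NaN when no
    sample falls in the range.
    """
    lo, hi = speed_range
    z = sig.sample_at(kin.times)
    speed = kin["speed"]
    with np.errstate(invalid="ignore"):
        mask = (speed >= lo) & (speed <= hi)
    n = int(mask.sum())
    if n == 0:
        return np.nan, 0
    return float(z[mask].mean()), n


def spatial_activity_map(sig: CorrectedSignal, traj: Trajectory,
                         arena: ArenaSpec, bin_cm: float = 5.0) -> np.ndarray:
    """2-D map of mean signal per visited spatial bin (NaN where unvisited)."""
    if bin_cm <= 0 or bin_cm > min(arena.length_cm, arena.width_cm):
        raise ParameterError("bin_cm must be positive and no larger than the "
                             "arena's smaller dimension")
    nx = int(np.ceil(arena.length_cm / bin_cm))
    ny = int(np.ceil(arena.width_cm / bin_cm))
    tail = traj.keypoint("tail")
    z = sig.sample_at(traj.times)
    ix = np.clip((tail[:, 0] / bin_cm).astype(int), 0, nx - 1)
    iy = np.clip((tail[:, 1] / bin_cm).astype(int), 0, ny - 1)
    total = np.zeros((nx, ny))
    count = np.zeros((nx, ny))
    np.add.at(total, (ix, iy), z)
    np.add.at(count, (ix, iy), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out
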