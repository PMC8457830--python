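"""Core domain types shared by every analysis stage.

Coordinate convention (fixed package-wide): positions in centimeters, origin at
the safe short wall, x increasing along the arena length toward the threat wall,
y across the width. The threat (rat / shock grid) occupies a zone of depth
``threat_zone_depth_cm`` at one short wall; distance-from-threat is measured
along the length axis to the boundary of that zone, clipped at zero inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: column schema of a trajectory table
TRAJECTORY_COLUMNS = (
    "frame", "time_s",
    "nose_x", "nose_y",
    "earL_x", "earL_y",
    "earR_x", "earR_y",
    "tail_x", "tail_y",
)

BEHAVIOR_LABELS = ("escape", "approach", "stretch", "freeze", "walk")


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular arena with a threat zone at one short wall.

    Defaults match a rat-exposure enclosure of 70 cm x 26 cm with the rat
    tethered within roughly 20 cm of one short wall.
    """

    length_cm: float = 70.0
    width_cm: float = 26.0
    threat_end: str = "x_max"  # which short wall the threat occupies
    threat_zone_depth_cm: float = 15.0

    def __post_init__(self):
        if not (self.length_cm > self.width_cm > 0):
            raise ParameterError("arena requires length_cm > width_cm > 0")
        if not (0 < self.threat_zone_depth_cm < self.length_cm):
            raise ParameterError("threat_zone_depth_cm must lie in (0, length_cm)")
        if self.threat_end not in ("x_max", "x_min"):
            raise ParameterError("threat_end must be 'x_max' or 'x_min'")

    @property
    def threat_boundary_x(self) -> float:
        """x coordinate of the threat-zone boundary."""
        if self.threat_end == "x_max":
            return self.length_cm - self.threat_zone_depth_cm
        return self.threat_zone_depth_cm

    @property
    def toward_sign(self) -> float:
        """Sign of dx/dt when moving toward the threat."""
        return 1.0 if self.threat_end == "x_max" else -1.0

    def distance_from_threat(self, x: np.ndarray) -> np.ndarray:
        """Distance along the length axis to the threat-zone boundary (>= 0)."""
        x = np.asarray(x, dtype=float)
        d = self.toward_sign * (self.threat_boundary_x - x)
        return np.clip(d, 0.0, self.length_cm)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trajectory:
    """Timestamped keypoint track of one session.

    ``df`` follows :data:`TRAJECTORY_COLUMNS`; ``frame_rate_hz`` is the video
    frame rate (30 Hz capture by default throughout).
    """

    df: pd.DataFrame
    frame_rate_hz: float = 30.0

    def __post_init__(self):
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"trajectory table missing columns: {missing}")
        t = self.df["time_s"].to_numpy()
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise FormatError("trajectory timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_s"].to_numpy()

    @property
    def duration_s(self) -> float:
        t = self.times
        return float(t[-1] - t[0]) if len(t) > 1 else 0.0

    def keypoint(self, name: str) -> np.ndarray:
        """(n, 2) array of one keypoint ('nose', 'earL', 'earR', 'tail')."""
        return self.df[[f"{name}_x", f"{name}_y"]].to_numpy(dtype=float)


@dataclass
class KinematicsSeries:
    """Per-frame kinematic quantities derived from a trajectory.

    Columns of ``df``:

    - ``time_s``, ``x``, ``y`` -- smoothed tailbase position
    - ``speed`` -- tailbase speed (cm/s, >= 0)
    - ``nose_speed`` -- nose speed (cm/s)
    - ``v_threat`` -- signed tailbase velocity along the threat axis
      (cm/s, positive = toward the threat)
    - ``v_perp`` -- signed tailbase velocity across the arena width (cm/s)
    - ``dist_threat`` -- nose distance-from-threat (cm, in [0, arena length])
    - ``body_len`` -- nose-tailbase distance (cm)
    - ``head_cos`` -- cosine of head direction in [-1, 1]
      (-1 facing the threat, +1 facing away)
    """

    df: pd.DataFrame
    frame_rate_hz: float
    arena: ArenaSpec

    def __getitem__(self, col: str) -> np.ndarray:
        return self.df[col].to_numpy()

    @property
    def n_frames(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_s"].to_numpy()


@dataclass
class BehaviorEpoch:
    """One labeled behavioral episode, frames half-open [onset, offset)."""

    label: str
    onset: int
    offset: int
    duration_s: float
    mean_speed: float = np.nan   # escapes/approaches: mean speed onset->offset
    traversal_cm: float = np.nan

    def __post_init__(self):
        if self.offset <= self.onset:
            raise FormatError("epoch offset must exceed onset")

    @property
    def n_frames(self) -> int:
        return self.offset - self.onset


def epochs_to_frame(epochs) -> pd.DataFrame:
    """Epoch list -> tidy table."""
    return pd.DataFrame(
        [
            {
                "label": e.label,
                "onset_frame": e.onset,
                "offset_frame": e.offset,
                "duration_s": e.duration_s,
                "mean_speed": e.mean_speed,
                "traversal_cm": e.traversal_cm,
            }
            for e in epochs
        ],
        columns=["label", "onset_frame", "offset_frame", "duration_s",
                 "mean_speed", "traversal_cm"],
    )


def frame_to_epochs(df: pd.DataFrame) -> list:
    return [
        BehaviorEpoch(
            label=r["label"],
            onset=int(r["onset_frame"]),
            offset=int(r["offset_frame"]),
            duration_s=float(r.get("duration_s", np.nan)),
            mean_speed=float(r.get("mean_speed", np.nan)),
            traversal_cm=float(r.get("traversal_cm", np.nan)),
        )
        for _, r in df.iterrows()
    ]


@dataclass(frozen=True)
class BehaviorThresholds:
    """Thresholds of the five behavior definitions.

    Defaults are the published rule set: a 2 cm/s speed threshold for escapes,
    approaches, and walks; escapes initiated within 30 cm of the threat and
    traversing > 10 cm; approaches traversing > 10 cm; walks traversing > 5 cm;
    stretch-attend postures at > 1.2 body lengths with tailbase speed < 1 cm/s;
    freezes with nose and tailbase speed < 0.25 cm/s for at least 0.33 s.
    """

    speed_cms: float = 2.0
    escape_init_distance_cm: float = 30.0
    escape_init_within: bool = True  # True: initiation distance <= bound
    escape_min_traversal_cm: float = 10.0
    approach_min_traversal_cm: float = 10.0
    walk_min_traversal_cm: float = 5.0
    stretch_elongation_factor: float = 1.2
    stretch_tail_speed_cms: float = 1.0
    freeze_speed_cms: float = 0.25
    freeze_min_duration_s: float = 0.33
    merge_gap_frames: int = 2

    def __post_init__(self):
        for name in ("speed_cms", "escape_init_distance_cm",
                     "escape_min_traversal_cm", "approach_min_traversal_cm",
                     "walk_min_traversal_cm", "stretch_elongation_factor",
                     "stretch_tail_speed_cms", "freeze_speed_cms",
                     "freeze_min_duration_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)
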