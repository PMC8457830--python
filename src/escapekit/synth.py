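"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here: arena
trajectories with planted behavioral episodes built to satisfy (or, when
flagged, to violate exactly one clause of) the classifier rules; dual-channel
photometry with bleaching and motion artifacts plus planted transients;
calcium-trace ensembles with behavior-, speed-, and position-tuned subsets;
coupled region pairs for mutual-information analyses; and multi-subject
trial x voxel blocks with planted shared latents and confounds.

All randomness flows from one ``numpy.random.default_rng(seed)`` per call;
identical seeds and parameters give bit-identical outputs.

Trajectory model
----------------
The animal is a rigid three-point body (nose, inter-ear midpoint, tailbase)
of ~7 cm. Between planted episodes it mills at sub-threshold speed: slow
circular orbits (0.6 cm/s) interleaved with straight transits (<= 1.7 cm/s)
that deliver it to the next episode's required start point. The orbit keeps
the smoothed displacement speed inside (0.25, 2) cm/s at all times, so the
inter-episode baseline can never cross a freeze, walk, approach, or escape
threshold; a free random walk would plant spurious freezes whenever direction
reversals cancel displacement inside the smoothing window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import compute_kinematics
from .core import ArenaSpec, BEHAVIOR_LABELS, Trajectory
from .errors import ParameterError, ScheduleError

BODY_LEN_CM = 7.0      # nose-to-tailbase
EAR_FRAC = 0.72        # inter-ear midpoint position along the body axis
EAR_HALF_CM = 1.2
MARGIN_CM = BODY_LEN_CM + 1.0   # tailbase clearance keeping all keypoints inside
MILL_SPEED = 0.6       # cm/s, inter-episode orbit speed
TRAVEL_SPEED = 1.4     # cm/s, preferred transit speed
TRAVEL_MAX = 1.7       # cm/s, transit ceiling (stays under the 2 cm/s rules)


# ---------------------------------------------------------------------------
# episode grammar

@dataclass
class Episode:
    """One planted behavioral episode.

    ``violate`` flags a deliberate single-clause violation: the episode is
    shaped to break exactly that clause of its label's rule while satisfying
    the others, and is recorded in the ground truth with ``violate`` set so
    round-trip tests can assert it is rejected.

    Supported violations: escape -- ``proximity``/``speed``/``traversal``;
    approach/walk -- ``speed``/``traversal``; freeze -- ``duration``;
    stretch -- ``tailspeed``/``elongation``.
    """

    label: str
    onset_s: float
    duration_s: float | None = None
    speed_cms: float | None = None
    traversal_cm: float | None = None
    start_dist_cm: float | None = None
    violate: str | None = None

    def __post_init__(self):
        if self.label not in BEHAVIOR_LABELS:
            raise ParameterError(f"unknown episode label {self.label!r}")
        if self.onset_s < 0:
            raise ScheduleError("episode onset must be non-negative")


_DEFAULTS = {
    "escape":   dict(speed_cms=5.0, traversal_cm=25.0, start_dist_cm=12.0),
    "approach": dict(speed_cms=5.0, traversal_cm=25.0, start_dist_cm=38.0),
    "walk":     dict(speed_cms=4.0, traversal_cm=8.0),
    "freeze":   dict(duration_s=None),   # sampled, mean ~2.0 s
    "stretch":  dict(duration_s=2.0),
}

_VIOLATIONS = {
    ("escape", "proximity"): dict(start_dist_cm=35.0, traversal_cm=12.0),
    ("escape", "speed"): dict(speed_cms=1.5, traversal_cm=12.0),
    ("escape", "traversal"): dict(traversal_cm=6.0),
    ("approach", "speed"): dict(speed_cms=1.5, traversal_cm=12.0),
    ("approach", "traversal"): dict(traversal_cm=6.0),
    ("walk", "speed"): dict(speed_cms=1.5, traversal_cm=4.0),
    ("walk", "traversal"): dict(traversal_cm=3.0),
    ("freeze", "duration"): dict(duration_s=0.2),
    ("stretch", "tailspeed"): dict(),
    ("stretch", "elongation"): dict(),
}


@dataclass
class _Resolved:
    label: str
    onset_f: int
    offset_f: int
    speed: float
    traversal: float
    start_dist: float
    violate: str | None


def _resolve(ep: Episode, fps: float, rng: np.random.Generator) -> _Resolved:
    params = dict(_DEFAULTS[ep.label])
    if ep.violate is not None:
        key = (ep.label, ep.violate)
        if key not in _VIOLATIONS:
            raise ParameterError(f"unknown violation {ep.violate!r} "
                                 f"for label {ep.label!r}")
        params.update(_VIOLATIONS[key])
    for name in ("speed_cms", "traversal_cm", "start_dist_cm", "duration_s"):
        v = getattr(ep, name)
        if v is not None:
            params[name] = v

    speed = params.get("speed_cms", 0.0) or 0.0
    traversal = params.get("traversal_cm", 0.0) or 0.0
    start_dist = params.get("start_dist_cm", np.nan)
    dur = params.get("duration_s")
    if ep.label in ("escape", "approach", "walk"):
        if dur is None:
            if speed <= 0:
                raise ParameterError(f"{ep.label} episode needs speed > 0")
            dur = traversal / speed
        else:
            speed = traversal / dur
    elif dur is None:  # freeze: bout durations ~2.0 s on average
        dur = float(np.clip(rng.normal(2.0, 0.5), 0.8, 4.0))
    onset_f = int(round(ep.onset_s * fps))
    offset_f = onset_f + max(1, int(round(dur * fps)))
    return _Resolved(ep.label, onset_f, offset_f, speed, traversal,
                     start_dist, ep.violate)


def make_schedule(labels, start_s: float = 8.0, gap_s: float = 22.0,
                  **episode_kwargs) -> list[Episode]:
    """Space episodes of the given labels sequentially with fixed gaps.

    Gaps default to 22 s, enough for the sub-threshold transit between any
    two episode start points in the default arena.
    """
    out, t = [], start_s
    for label in labels:
        ep = Episode(label=label, onset_s=t, **episode_kwargs)
        out.append(ep)
        dur = ep.duration_s
        if dur is None:
            d = dict(_DEFAULTS[label])
            if label in ("escape", "approach", "walk"):
                dur = d["traversal_cm"] / d["speed_cms"]
            else:
                dur = 4.0  # upper bound on sampled freeze bouts
        t += dur + gap_s
    return out


# ---------------------------------------------------------------------------
# trajectory assembly

def _unit(phi):
    return np.array([math.cos(phi), math.sin(phi)])


class _Body:
    """Sequentially filled per-frame body state."""

    def __init__(self, n):
        self.x = np.empty(n)
        self.y = np.empty(n)
        self.phi = np.empty(n)
        self.bl = np.full(n, BODY_LEN_CM)

    def set_range(self, f0, f1, pos, phi):
        self.x[f0:f1] = pos[:, 0]
        self.y[f0:f1] = pos[:, 1]
        self.phi[f0:f1] = phi


def _orbit_positions(pos0, m, speed, fps, rng, box, r=2.0):
    """Circular orbit passing through pos0, anchored toward the box interior.

    Every orbit point stays within 2r of pos0, so long milling phases cannot
    drift away from a planned episode start."""
    if m <= 0:
        return np.empty((0, 2)), np.empty(0)
    center_box = np.array([(box[0] + box[1]) / 2, (box[2] + box[3]) / 2])
    inward = center_box - pos0
    nrm = np.linalg.norm(inward)
    u = inward / nrm if nrm > 1e-6 else _unit(rng.uniform(0, 2 * math.pi))
    anchor = pos0 + r * u
    anchor[0] = np.clip(anchor[0], box[0] + r, box[1] - r)
    anchor[1] = np.clip(anchor[1], box[2] + r, box[3] - r)
    theta0 = math.atan2(pos0[1] - anchor[1], pos0[0] - anchor[0])
    direction = rng.choice([-1.0, 1.0])
    omega = direction * speed / (r * fps)
    theta = theta0 + omega * np.arange(1, m + 1)
    pos = anchor[None, :] + r * np.column_stack([np.cos(theta), np.sin(theta)])
    heading = theta + direction * math.pi / 2  # tangent
    return pos, heading


def _steer(body, f0, f1, pos, phi, target, tphi, fps, rng, box):
    """Fill frames [f0, f1) with sub-threshold milling that ends within
    ~1.6 cm of ``target`` (if given) with heading ``tphi`` (if given).

    Transit to the target happens first; the remaining frames hold a small
    orbit anchored through the target, blending the heading into ``tphi``
    over the final frames. The hold orbit bounds the end-point offset
    regardless of how long the gap is."""
    m = f1 - f0
    if m <= 0:
        return pos, phi
    dt = 1.0 / fps
    if target is None:
        p, h = _orbit_positions(pos, m, MILL_SPEED, fps, rng, box)
        body.set_range(f0, f1, p, h)
        if tphi is not None:
            k = min(10, m)
            body.phi[f1 - k:f1] = np.linspace(body.phi[f1 - k], tphi, k)
            return p[-1], tphi
        return p[-1], h[-1]

    d = float(np.linalg.norm(target - pos))
    m_travel = 0 if d < 0.5 else int(math.ceil(d / (TRAVEL_SPEED * dt)))
    if m_travel > m:
        m_travel = int(math.ceil(d / (TRAVEL_MAX * dt)))
        if m_travel > m:
            raise ScheduleError(
                f"gap of {m * dt:.1f} s too short to reach the next episode "
                f"start ({d:.1f} cm away) at sub-threshold speed")

    cur = pos
    f = f0
    if m_travel > 0:
        frac = np.arange(1, m_travel + 1) / m_travel
        p = cur[None, :] + frac[:, None] * (target - cur)[None, :]
        h = math.atan2(target[1] - cur[1], target[0] - cur[0])
        body.set_range(f, f + m_travel, p, np.full(m_travel, h))
        cur, f, phi = p[-1].copy(), f + m_travel, h
    m_hold = f1 - f
    if m_hold > 0:
        p, h = _orbit_positions(cur, m_hold, MILL_SPEED, fps, rng, box,
                                r=0.8)
        if tphi is not None:
            k = min(10, m_hold)
            start = h[-k]
            delta = (tphi - start + math.pi) % (2 * math.pi) - math.pi
            h[-k:] = start + delta * np.arange(1, k + 1) / k
        body.set_range(f, f1, p, h)
        cur = p[-1]
    return cur, (tphi if tphi is not None else float(body.phi[f1 - 1]))


def _episode_geometry(res: _Resolved, arena: ArenaSpec, fps: float):
    """Target tailbase position and heading at episode onset (internal
    x_max-threat frame), or (None, None) for place-free episodes."""
    L, W = arena.length_cm, arena.width_cm
    boundary = L - arena.threat_zone_depth_cm
    ymid = W / 2
    if res.label == "escape":
        nose_x = boundary - res.start_dist
        tail = np.array([nose_x + BODY_LEN_CM, ymid])
        return tail, math.pi
    if res.label == "approach":
        nose_x = boundary - res.start_dist
        tail = np.array([nose_x - BODY_LEN_CM, ymid])
        return tail, 0.0
    if res.label == "walk":
        y0 = max(MARGIN_CM, W - MARGIN_CM - res.traversal - 2.0)
        if y0 + res.traversal > W - MARGIN_CM:
            raise ParameterError("walk traversal does not fit the arena width")
        return np.array([20.0, y0]), math.pi / 2
    if res.label == "stretch":
        return np.array([L / 2, ymid]), None
    return None, None  # freeze: wherever the animal is


def _fill_episode(body, res: _Resolved, pos, phi, arena, fps, rng, box):
    f0, f1 = res.onset_f, res.offset_f
    m = f1 - f0
    dt = 1.0 / fps
    if res.label in ("escape", "approach", "walk"):
        direction = _unit(phi)
        end = pos + direction * res.speed * m * dt
        nose_end = end + BODY_LEN_CM * direction
        for pt in (end, nose_end):
            if not (0.3 <= pt[0] <= arena.length_cm - 0.3
                    and 0.3 <= pt[1] <= arena.width_cm - 0.3):
                raise ParameterError(
                    f"{res.label} traversal of {res.traversal:.0f} cm does "
                    f"not fit the arena from its start point")
        frac = np.arange(1, m + 1)[:, None] * dt * res.speed
        p = pos[None, :] + frac * direction[None, :]
        body.set_range(f0, f1, p, np.full(m, phi))
        return p[-1], phi
    if res.label == "freeze":
        body.set_range(f0, f1, np.repeat(pos[None, :], m, axis=0), phi)
        return pos, phi
    # stretch: tailbase micro-motion below 1 cm/s (or 1.5 when violating the
    # tailbase clause), nose elongated unless violating the elongation clause
    tail_speed = 1.5 if res.violate == "tailspeed" else 0.5
    peak = 1.1 if res.violate == "elongation" else 1.35
    p, h = _orbit_positions(pos, m, tail_speed, fps, rng, box)
    body.set_range(f0, f1, p, np.full(m, phi))
    # elongation profile contained entirely within the episode so that the
    # ramp-down never coincides with slow post-episode milling
    ramp = max(1, min(int(round(0.3 * fps)), m // 3))
    prof = np.full(m, peak * BODY_LEN_CM)
    prof[:ramp] = np.linspace(BODY_LEN_CM, peak * BODY_LEN_CM, ramp)
    prof[m - ramp:] = np.linspace(peak * BODY_LEN_CM, BODY_LEN_CM, ramp)
    body.bl[f0:f1] = prof
    return p[-1], phi


def generate_arena_session(arena: ArenaSpec, schedule: list[Episode],
                           frame_rate_hz: float = 30.0, seed: int = 0,
                           duration_s: float | None = None,
                           pose_noise_cm: float = 0.0
                           ) -> tuple[Trajectory, pd.DataFrame]:
    """Generate a pose trajectory with the scheduled episodes planted.

    Returns the trajectory and a ground-truth table
    ``(label, onset_frame, offset_frame, violate)``; ``violate`` is empty for
    episodes built to satisfy their rule and names the broken clause
    otherwise. Raises :class:`ScheduleError` for overlapping episodes or
    unreachable start points, :class:`ParameterError` for episodes that do
    not fit the arena.
    """
    if pose_noise_cm < 0:
        raise ParameterError("pose_noise_cm must be non-negative")
    fps = frame_rate_hz
    rng = np.random.default_rng(seed)
    resolved = sorted((_resolve(ep, fps, rng) for ep in schedule),
                      key=lambda r: r.onset_f)
    for a, b in zip(resolved, resolved[1:]):
        if b.onset_f < a.offset_f:
            raise ScheduleError(
                f"episodes overlap: {a.label}@{a.onset_f} and "
                f"{b.label}@{b.onset_f}")
    if duration_s is None:
        duration_s = (resolved[-1].offset_f / fps + 8.0) if resolved else 60.0
    n = int(round(duration_s * fps))
    if resolved and resolved[-1].offset_f > n:
        raise ScheduleError("schedule does not fit in the session duration")

    L, W = arena.length_cm, arena.width_cm
    box = (MARGIN_CM, L - MARGIN_CM, MARGIN_CM, W - MARGIN_CM)
    body = _Body(n)

    # start at (or near) the first located episode's start point
    pos = None
    for res in resolved:
        tgt, _ = _episode_geometry(res, arena, fps)
        if tgt is not None:
            pos = tgt.copy()
            break
    if pos is None:
        pos = np.array([rng.uniform(box[0] + 4, box[1] - 4),
                        rng.uniform(box[2] + 2, box[3] - 2)])
    phi = rng.uniform(0, 2 * math.pi)
    body.x[0], body.y[0], body.phi[0] = pos[0], pos[1], phi

    cursor = 1
    truth_rows = []
    for res in resolved:
        tgt, tphi = _episode_geometry(res, arena, fps)
        pos, phi = _steer(body, cursor, res.onset_f, pos, phi,
                          tgt, tphi, fps, rng, box)
        pos, phi = _fill_episode(body, res, pos, phi, arena, fps, rng, box)
        cursor = res.offset_f
        truth_rows.append({"label": res.label, "onset_frame": res.onset_f,
                           "offset_frame": res.offset_f,
                           "violate": res.violate or ""})
    pos, phi = _steer(body, cursor, n, pos, phi, None, None, fps, rng, box)

    # body geometry: nose and ears from tailbase, heading, body length
    u = np.column_stack([np.cos(body.phi), np.sin(body.phi)])
    perp = np.column_stack([-np.sin(body.phi), np.cos(body.phi)])
    tail = np.column_stack([body.x, body.y])
    nose = tail + body.bl[:, None] * u
    earmid = tail + (EAR_FRAC * body.bl)[:, None] * u
    earL = earmid + EAR_HALF_CM * perp
    earR = earmid - EAR_HALF_CM * perp
    if pose_noise_cm > 0:
        for arr in (tail, nose, earL, earR):
            arr += rng.normal(0.0, pose_noise_cm, arr.shape)

    if arena.threat_end == "x_min":  # mirror into the requested frame
        for arr in (tail, nose, earL, earR):
            arr[:, 0] = L - arr[:, 0]

    frames = np.arange(n)
    df = pd.DataFrame({
        "frame": frames, "time_s": frames / fps,
        "nose_x": nose[:, 0], "nose_y": nose[:, 1],
        "earL_x": earL[:, 0], "earL_y": earL[:, 1],
        "earR_x": earR[:, 0], "earR_y": earR[:, 1],
        "tail_x": tail[:, 0], "tail_y": tail[:, 1],
    })
    truth = pd.DataFrame(truth_rows, columns=["label", "onset_frame",
                                              "offset_frame", "violate"])
    return Trajectory(df=df, frame_rate_hz=fps), truth


# ---------------------------------------------------------------------------
# tuning specification shared by photometry and ensemble generators

@dataclass(frozen=True)
class CellTuning:
    """Coupling target of one cell (or one photometry site)."""

    target: str = "none"  # behavior label | 'speed' | 'position' | 'none'
    gain: float = 1.0

    def __post_init__(self):
        if self.target not in BEHAVIOR_LABELS + (
                "speed", "velocity_away", "velocity_toward", "position",
                "none"):
            raise ParameterError(f"unknown tuning target {self.target!r}")
        if self.gain < 0:
            raise ParameterError("tuning gain must be >= 0")


@dataclass
class TuningSpec:
    """Per-cell coupling targets plus transient-kernel and noise parameters.

    The calcium kernel is a single-exponential decay (GCaMP6s-like slow
    indicator), default time constant 1.5 s; it integrates to a finite
    positive value.
    """

    tunings: list[CellTuning] = field(default_factory=lambda: [CellTuning()])
    kernel_tau_s: float = 1.5
    noise_sd: float = 0.05
    baseline_rate_hz: float = 0.1

    def __post_init__(self):
        if self.kernel_tau_s <= 0:
            raise ParameterError("kernel_tau_s must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.baseline_rate_hz < 0:
            raise ParameterError("baseline_rate_hz must be non-negative")

    @classmethod
    def uniform(cls, target: str, n: int, gain: float = 1.0, **kw):
        return cls(tunings=[CellTuning(target, gain) for _ in range(n)], **kw)

    @classmethod
    def photometry(cls, target: str = "escape", gain: float = 2.0,
                   noise_sd: float = 0.005, **kw):
        """Default bulk-fluorescence coupling: behavior-locked transients of
        ~5% df/F x gain against 0.5% per-sample measurement noise (z-scored
        transient peaks around 5, typical of a healthy photometry prep)."""
        return cls(tunings=[CellTuning(target, gain)], noise_sd=noise_sd, **kw)


def _kernel(n: int, tau_s: float, fps: float) -> np.ndarray:
    return np.exp(-np.arange(n) / (tau_s * fps))


def _circular_conv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    n = len(x)
    return np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(kernel), n)


def _features(traj: Trajectory, arena: ArenaSpec, epochs: pd.DataFrame | None,
              kernel: np.ndarray, fps: float) -> dict:
    """Normalized per-frame drive features for each tuning target."""
    kin = compute_kinematics(traj, arena)
    feats = {}
    speed = kin["speed"]
    feats["speed"] = speed / max(np.nanpercentile(speed, 95), 1e-9)
    v_away = np.clip(-kin["v_threat"], 0.0, None)
    v_toward = np.clip(kin["v_threat"], 0.0, None)
    feats["velocity_away"] = v_away / max(np.nanpercentile(v_away, 99), 1e-9)
    feats["velocity_toward"] = (v_toward
                                / max(np.nanpercentile(v_toward, 99), 1e-9))
    feats["position"] = 1.0 - kin["dist_threat"] / arena.length_cm
    n = traj.n_frames
    if epochs is not None and len(epochs):
        for label in BEHAVIOR_LABELS:
            sel = epochs[epochs["label"] == label]
            imp = np.zeros(n)
            onsets = sel["onset_frame"].to_numpy(dtype=int)
            imp[onsets[onsets < n]] = 1.0
            feats[label] = _circular_conv(imp, kernel)
    return feats


# ---------------------------------------------------------------------------
# photometry generator

def generate_photometry(traj: Trajectory, coupling: TuningSpec,
                        seed: int = 0, epochs: pd.DataFrame | None = None,
                        arena: ArenaSpec = ArenaSpec(),
                        rate_hz: float = 20.0,
                        bleach_amp: float = 0.3, bleach_tau_s: float = 600.0,
                        motion_amp: float = 0.1, motion_rate_hz: float = 0.05,
                        transient_scale: float = 0.05,
                        sig_scale: float = 1.2, ref_scale: float = 1.0):
    """Interleaved dual-channel photometry with planted transients.

    The 405 nm reference carries slow exponential bleaching plus smooth
    motion bumps; the 470 nm signal carries the same artifacts (scaled) plus
    the planted activity. Returns the recording and the ground-truth clean
    activity trace sampled at the signal-channel timestamps.
    """
    from .photometry import PhotometryRecording

    if traj.duration_s <= 0:
        raise ParameterError("trajectory duration must be positive")
    rng = np.random.default_rng(seed)
    fps = traj.frame_rate_hz
    n_frames = traj.n_frames
    kernel = _kernel(n_frames, coupling.kernel_tau_s, fps)
    feats = _features(traj, arena, epochs, kernel, fps)

    clean_frames = np.zeros(n_frames)
    for t in coupling.tunings:
        if t.target == "none" or t.gain == 0:
            continue
        if t.target not in feats:
            raise ParameterError(
                f"tuning target {t.target!r} needs planted epochs")
        clean_frames += t.gain * feats[t.target]
    clean_frames *= transient_scale

    dur = traj.times[-1]
    t_all = np.arange(0.0, dur, 1.0 / rate_hz)
    channel = np.where(np.arange(len(t_all)) % 2 == 0, 405, 470)

    artifact = 1.0 + bleach_amp * np.exp(-t_all / bleach_tau_s)
    n_bumps = rng.poisson(motion_rate_hz * dur)
    for _ in range(n_bumps):
        t0 = rng.uniform(0, dur)
        w = rng.uniform(0.3, 1.0)
        a = rng.uniform(-motion_amp, motion_amp)
        artifact += a * np.exp(-0.5 * ((t_all - t0) / w) ** 2)

    clean_all = np.interp(t_all, traj.times, clean_frames)
    values = np.where(
        channel == 405,
        ref_scale * artifact,
        sig_scale * (artifact + clean_all),
    ) + coupling.noise_sd * rng.standard_normal(len(t_all))

    rec = PhotometryRecording(times=t_all, values=values, channel=channel,
                              rate_hz=rate_hz)
    sig_t = t_all[channel == 470]
    clean = pd.DataFrame({"time_s": sig_t,
                          "clean": np.interp(sig_t, traj.times, clean_frames)})
    return rec, clean


# ---------------------------------------------------------------------------
# ensemble generator

def generate_ensemble(traj: Trajectory, n_cells: int, tuning: TuningSpec,
                      seed: int = 0, epochs: pd.DataFrame | None = None,
                      arena: ArenaSpec = ArenaSpec()):
    """Cells x frames calcium-trace matrix with planted tuning.

    Each trace is a nonnegative transient train (Poisson events, exponential
    amplitudes) convolved with the calcium kernel, plus the cell's tuned
    drive and white noise. Convolution is circular, making traces circularly
    stationary in time (negligible for sessions much longer than the kernel;
    it makes circular-shift null distributions exactly exchangeable with the
    observed statistic). Returns the recording and a ground-truth tuning
    table (cell, target, gain).
    """
    from .ensemble import EnsembleRecording

    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    tunings = tuning.tunings
    if len(tunings) == 1 and n_cells > 1:
        tunings = tunings * n_cells
    if len(tunings) != n_cells:
        raise ParameterError("tuning list length must be 1 or n_cells")

    rng = np.random.default_rng(seed)
    fps = traj.frame_rate_hz
    n = traj.n_frames
    kernel = _kernel(n, tuning.kernel_tau_s, fps)
    feats = _features(traj, arena, epochs, kernel, fps)

    traces = np.empty((n_cells, n))
    rows = []
    p_event = min(1.0, tuning.baseline_rate_hz / fps)
    for c, ct in enumerate(tunings):
        events = (rng.random(n) < p_event).astype(float)
        events *= rng.exponential(1.0, n) + 0.5
        tr = _circular_conv(events, kernel)
        if ct.target != "none" and ct.gain > 0:
            if ct.target not in feats:
                raise ParameterError(
                    f"tuning target {ct.target!r} needs planted epochs")
            tr = tr + ct.gain * feats[ct.target]
        traces[c] = tr + tuning.noise_sd * rng.standard_normal(n)
        rows.append({"cell": c, "target": ct.target, "gain": ct.gain})

    rec = EnsembleRecording(traces=traces, times=traj.times.copy(),
                            cell_ids=np.arange(n_cells))
    return rec, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coupled region pair

@dataclass
class RegionPair:
    """Two simultaneously recorded region signals with shared-latent coupling."""

    times: np.ndarray
    a: np.ndarray
    b: np.ndarray
    speed: np.ndarray
    escape_mask: np.ndarray
    coupling: float


def _smooth_noise(rng, n, sigma_samples):
    from scipy.ndimage import gaussian_filter1d
    x = gaussian_filter1d(rng.standard_normal(n), sigma_samples, mode="wrap")
    return (x - x.mean()) / max(x.std(), 1e-12)


def generate_coupled_region_pair(duration_s: float, coupling: float,
                                 seed: int = 0, rate_hz: float = 20.0,
                                 noise_sd: float = 0.0) -> RegionPair:
    """Two signals mixing a shared latent; dependence grows with ``coupling``.

    At coupling 0 the signals are independent; at coupling 1 with zero noise
    they are identical. A synthetic speed trace (straddling the 1 cm/s
    analysis floor) and escape mask are returned so the masking rules of the
    mutual-information analysis can be exercised.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ParameterError("coupling must lie in [0, 1]")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    sig = 0.5 * rate_hz  # ~0.5 s correlation time
    z = _smooth_noise(rng, n, sig)
    ea = _smooth_noise(rng, n, sig)
    eb = _smooth_noise(rng, n, sig)
    # variance-preserving mixing: corr(a, b) equals the coupling parameter
    a = math.sqrt(coupling) * z + math.sqrt(1 - coupling) * ea
    b = math.sqrt(coupling) * z + math.sqrt(1 - coupling) * eb
    if noise_sd > 0:
        a = a + noise_sd * rng.standard_normal(n)
        b = b + noise_sd * rng.standard_normal(n)
    speed = 2.0 * np.abs(_smooth_noise(rng, n, 1.0 * rate_hz))
    escape_mask = np.zeros(n, dtype=bool)
    t = 0.0
    while t < duration_s - 5:
        t += rng.uniform(15, 30)
        s = int(t * rate_hz)
        e = min(n, s + int(rng.uniform(2, 4) * rate_hz))
        escape_mask[s:e] = True
        t = e / rate_hz
    times = np.arange(n) / rate_hz
    return RegionPair(times=times, a=a, b=b, speed=speed,
                      escape_mask=escape_mask, coupling=coupling)


# ---------------------------------------------------------------------------
# trial x voxel blocks for the pathway model

def generate_fmri_blocks(n_subjects: int, n_trials: int,
                         n_voxels: tuple[int, int] = (60, 20),
                         n_confound_voxels: int = 0,
                         predictor_loadings: np.ndarray | None = None,
                         outcome_loadings: np.ndarray | None = None,
                         shared_gain: float = 1.0,
                         confound_gain: float = 0.0,
                         confound_block_gain: float = 4.0,
                         noise_sd: float = 1.0,
                         condition_effect: float = 0.0,
                         intensity_slope: float = 0.0,
                         seed: int = 0):
    """Per-subject predictor/outcome (and optional confound) voxel blocks.

    One latent per trial is shared between the predictor and outcome blocks
    through the given loading maps; an optional confound latent drives both
    blocks with ``confound_gain`` and its own region with
    ``confound_block_gain`` (a region represents its own latent more strongly
    than it drives remote regions; a weakly represented confound cannot be
    controlled for, since residualizing on a noisy latent estimate leaves
    shared estimation noise in both pathway scores). Trial
    covariates (condition threat/control, 4-level intensity) modulate the
    shared latent's amplitude via ``condition_effect`` and
    ``intensity_slope``. Returns (blocks, ground-truth dict).
    """
    from .pathway import PathwayBlocks, SubjectBlock

    n_pred, n_out = n_voxels
    for nv in (n_pred, n_out):
        if nv < 2:
            raise ParameterError("each region needs at least 2 voxels")
    if n_confound_voxels and n_confound_voxels < 2:
        raise ParameterError("confound region needs at least 2 voxels")
    rng = np.random.default_rng(seed)

    def _norm(v):
        v = np.asarray(v, dtype=float)
        return v / max(np.linalg.norm(v), 1e-12)

    wx = _norm(predictor_loadings if predictor_loadings is not None
               else rng.standard_normal(n_pred))
    wy = _norm(outcome_loadings if outcome_loadings is not None
               else rng.standard_normal(n_out))
    cx = _norm(rng.standard_normal(n_pred))
    cy = _norm(rng.standard_normal(n_out))
    wc = _norm(rng.standard_normal(n_confound_voxels)) \
        if n_confound_voxels else None

    conditions = np.where(np.arange(n_trials) % 2 == 0, "threat", "control")
    intensity = (np.arange(n_trials) // 2) % 4 + 1
    amp = (shared_gain
           * (1.0 + condition_effect * (conditions == "threat"))
           * (1.0 + intensity_slope * (intensity - 1)))

    subjects = []
    for _ in range(n_subjects):
        u = rng.standard_normal(n_trials)
        latent = amp * u
        conf = rng.standard_normal(n_trials)
        X = np.outer(latent, wx) + confound_gain * np.outer(conf, cx)
        Y = np.outer(latent, wy) + confound_gain * np.outer(conf, cy)
        X = X + noise_sd * rng.standard_normal(X.shape)
        Y = Y + noise_sd * rng.standard_normal(Y.shape)
        C = None
        if wc is not None:
            C = (confound_block_gain * np.outer(conf, wc)
                 + noise_sd * rng.standard_normal((n_trials,
                                                   n_confound_voxels)))
        cov = pd.DataFrame({"condition": conditions, "intensity": intensity})
        subjects.append(SubjectBlock(predictor=X, outcome=Y, confound=C,
                                     covariates=cov))
    truth = {"predictor_loadings": wx, "outcome_loadings": wy,
             "confound_predictor_loadings": cx,
             "confound_outcome_loadings": cy}
    return PathwayBlocks(subjects=subjects), truth
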