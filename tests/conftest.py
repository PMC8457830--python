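"""Shared fixtures: synthetic sessions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import escapekit as ek
from escapekit.core import KinematicsSeries


@pytest.fixture(scope="session")
def arena():
    return ek.ArenaSpec()


@pytest.fixture(scope="session")
def mixed_session(arena):
    """Session with all five behaviors planted (one of each plus extras)."""
    labels = ["escape", "freeze", "approach", "walk", "stretch",
              "escape", "freeze", "walk", "escape", "approach"]
    traj, truth = ek.generate_arena_session(arena, ek.make_schedule(labels),
                                            seed=7)
    kin = ek.compute_kinematics(traj, arena)
    return traj, truth, kin


@pytest.fixture(scope="session")
def escape_session(arena):
    """Varied-speed escapes and approaches (speed variance for tuning and
    decoding analyses; some speeds inside the 6-10 cm/s matching band)."""
    speeds = [3, 4, 5, 6, 7, 8]
    sched = []
    t = 8.0
    for i, lab in enumerate((["escape"] * 2 + ["approach"]) * 6):
        sp = speeds[i % 6]
        sched.append(ek.Episode(lab, onset_s=t, speed_cms=sp))
        t += 25.0 / sp + 22
    traj, truth = ek.generate_arena_session(arena, sched, seed=11)
    kin = ek.compute_kinematics(traj, arena)
    epochs = ek.classify_all(kin)
    return traj, truth, kin, epochs


def make_kin(arena, *, speed=None, nose_speed=None, v_threat=None,
             v_perp=None, dist_threat=None, body_len=None, x=None, y=None,
             n=None, fps=30.0):
    """Hand-built kinematics for classifier unit tests."""
    arrays = [a for a in (speed, nose_speed, v_threat, v_perp, dist_threat,
                          body_len, x, y) if a is not None]
    if n is None:
        n = len(arrays[0])
    zeros = np.zeros(n)

    def _a(v, default):
        return np.asarray(v, dtype=float) if v is not None else default

    speed = _a(speed, zeros)
    df = pd.DataFrame({
        "time_s": np.arange(n) / fps,
        "x": _a(x, zeros), "y": _a(y, zeros),
        "speed": speed,
        "nose_speed": _a(nose_speed, speed),
        "v_threat": _a(v_threat, zeros),
        "v_perp": _a(v_perp, zeros),
        "dist_threat": _a(dist_threat, np.full(n, 20.0)),
        "body_len": _a(body_len, np.full(n, 7.0)),
        "head_cos": zeros,
    })
    return KinematicsSeries(df=df, frame_rate_hz=fps, arena=arena)
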