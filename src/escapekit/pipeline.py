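"""Config-driven pipeline: run analysis stages in dependency order.

A single YAML config describes the stages to run, the synthetic-session
parameters, thresholds, and seeds. Every output table carries a provenance
header (package version, config hash, seed). Stages:

- ``simulate``  -- generate trajectory / photometry / ensemble / region pair
- ``behavior``  -- kinematics, epoch classification, session summary
- ``photometry`` -- artifact correction, escape-triggered average
- ``cells``     -- variance filter, behavior- and speed-tuned classification
- ``decode``    -- ongoing-escape decoding, position decoding
- ``mi``        -- region-pair mutual information (with/without escapes)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import io as ekio
from .core import ArenaSpec, BehaviorThresholds, epochs_to_frame
from .decoding import decode_continuous_variable, decode_ongoing_behavior
from .ensemble import (classify_behavior_tuned_cells,
                       classify_escape_speed_cells, filter_cells_by_variance)
from .errors import ConfigError, DependencyError
from .information import region_pair_mutual_information
from .photometry import behavior_triggered_average, correct_reference_artifacts
from .synth import (CellTuning, Episode, TuningSpec, generate_arena_session,
                    generate_coupled_region_pair, generate_ensemble,
                    generate_photometry, make_schedule)

log = logging.getLogger(__name__)

STAGES = ("simulate", "behavior", "photometry", "cells", "decode", "mi")
_DEPS = {
    "behavior": ("simulate",),
    "photometry": ("simulate", "behavior"),
    "cells": ("simulate", "behavior"),
    "decode": ("simulate", "behavior"),
    "mi": ("simulate",),
}
_STOCHASTIC = ("simulate", "cells", "decode")


def _tuning_from_cfg(cfg: dict) -> TuningSpec:
    tunings = [CellTuning(t.get("target", "none"), t.get("gain", 1.0))
               for t in cfg.get("tunings", [{"target": "none"}])]
    kw = {k: cfg[k] for k in ("kernel_tau_s", "noise_sd", "baseline_rate_hz")
          if k in cfg}
    return TuningSpec(tunings=tunings, **kw)


def run_pipeline(config, out_dir=None) -> Path:
    """Execute the configured stages; returns the results directory."""
    if not isinstance(config, dict):
        config = ekio.read_yaml(config)
    stages = config.get("stages", [])
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; expected one of {STAGES}")
    done = set()
    for s in stages:
        for dep in _DEPS.get(s, ()):
            if dep not in done:
                raise DependencyError(f"stage {s!r} requires {dep!r} first")
        done.add(s)
    if any(s in _STOCHASTIC for s in stages) and "seed" not in config:
        raise ConfigError("stochastic stages require an explicit seed")

    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": ekio.config_hash(config), "seed": seed}

    arena = ArenaSpec(**config.get("arena", {}))
    thr = BehaviorThresholds(**config.get("thresholds", {}))

    state: dict = {}
    for stage in stages:
        log.info("stage %s", stage)
        if stage == "simulate":
            sim = config.get("simulate", {})
            if "schedule" in sim:
                schedule = [Episode(**e) for e in sim["schedule"]]
            else:
                schedule = make_schedule(
                    sim.get("labels", ["escape"] * 6),
                    gap_s=sim.get("gap_s", 22.0))
            traj, truth = generate_arena_session(
                arena, schedule, seed=seed,
                duration_s=sim.get("duration_s"))
            state["traj"], state["truth"] = traj, truth
            ekio.write_trajectory(traj, out / "trajectory.csv", meta)
            ekio.write_table(truth, out / "ground_truth.csv", meta)
            if "photometry" in sim:
                rec, clean = generate_photometry(
                    traj, _tuning_from_cfg(sim["photometry"]), seed=seed + 1,
                    epochs=truth, arena=arena)
                state["photometry"] = rec
                ekio.write_photometry(rec, out / "photometry.csv", meta)
            if "ensemble" in sim:
                ecfg = sim["ensemble"]
                ens, tuning = generate_ensemble(
                    traj, ecfg.get("n_cells", 20), _tuning_from_cfg(ecfg),
                    seed=seed + 2, epochs=truth, arena=arena)
                state["ensemble"] = ens
                ekio.write_ensemble(ens, out / "ensemble.csv", meta)
                ekio.write_table(tuning, out / "ensemble_tuning.csv", meta)
            if "region_pair" in sim:
                rcfg = sim["region_pair"]
                state["pair"] = generate_coupled_region_pair(
                    rcfg.get("duration_s", 300.0),
                    rcfg.get("coupling", 0.5), seed=seed + 3)

        elif stage == "behavior":
            kin = bhv.compute_kinematics(state["traj"], arena)
            epochs = bhv.classify_all(kin, thr)
            state["kin"], state["epochs"] = kin, epochs
            ekio.write_table(kin.df, out / "kinematics.csv", meta)
            ekio.write_table(epochs_to_frame(epochs), out / "epochs.csv",
                             meta)
            summary = bhv.summarize_session(epochs, kin)
            ekio.write_table(summary.to_frame("value").reset_index(
                names="metric"), out / "session_summary.csv", meta)
            log.info("classified %d epochs", len(epochs))

        elif stage == "photometry":
            if "photometry" not in state:
                raise DependencyError("photometry stage needs a simulated "
                                      "photometry recording")
            sig = correct_reference_artifacts(state["photometry"])
            ekio.write_table(pd.DataFrame({"time_s": sig.times, "z": sig.z,
                                           "dff": sig.dff}),
                             out / "corrected_signal.csv", meta)
            bta = behavior_triggered_average(sig, state["epochs"], "escape")
            if not bta.excluded:
                ekio.write_table(
                    pd.DataFrame({"offset_s": bta.offsets_s,
                                  "mean": bta.mean, "sem": bta.sem}),
                    out / "bta_escape.csv", {**meta, "n": bta.n})
            else:
                log.info("escape-triggered average excluded: %s", bta.reason)

        elif stage == "cells":
            if "ensemble" not in state:
                raise DependencyError("cells stage needs a simulated "
                                      "ensemble")
            ens, kept = filter_cells_by_variance(state["ensemble"])
            tuned = classify_behavior_tuned_cells(
                ens, state["epochs"], "escape", seed=seed + 10)
            ekio.write_table(tuned, out / "behavior_tuned_cells.csv", meta)
            if any(e.label == "escape" for e in state["epochs"]):
                speedcells = classify_escape_speed_cells(
                    ens, state["kin"]["speed"], state["epochs"],
                    seed=seed + 11)
                ekio.write_table(speedcells, out / "speed_cells.csv", meta)

        elif stage == "decode":
            if "ensemble" not in state:
                raise DependencyError("decode stage needs a simulated "
                                      "ensemble")
            res = decode_ongoing_behavior(state["ensemble"], state["epochs"],
                                          seed=seed + 20)
            rows = [{"task": res.task, "metric": res.metric,
                     "value": res.value, "excluded": res.excluded,
                     "reason": res.reason}]
            pos = decode_continuous_variable(
                state["ensemble"], state["kin"], "position",
                n_perms=int(config.get("decode", {}).get("n_perms", 20)),
                seed=seed + 21)
            rows.append({"task": pos.task, "metric": pos.metric,
                         "value": pos.value, "excluded": pos.excluded,
                         "reason": pos.reason,
                         "chance_mean": (float(np.mean(pos.chance))
                                         if pos.chance is not None
                                         else np.nan)})
            ekio.write_table(pd.DataFrame(rows), out / "decoding.csv", meta)

        elif stage == "mi":
            if "pair" not in state:
                raise DependencyError("mi stage needs a simulated region "
                                      "pair")
            pair = state["pair"]
            rows = []
            for excl in (False, True):
                r = region_pair_mutual_information(
                    pair.a, pair.b, pair.speed, pair.escape_mask,
                    exclude_escapes=excl)
                rows.append({"exclude_escapes": excl, "mi_bits": r.mi_bits,
                             "n": r.n, "mask": r.mask_note})
            ekio.write_table(pd.DataFrame(rows), out / "mutual_information.csv",
                             meta)
    return out
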