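"""Per-cell classification of calcium-imaging ensembles.

Includes the cell-inclusion variance filter, classification of behavior-tuned
cells against an onset-randomization null, classification of escape-speed
cells against a pooled circular-shift null, and per-cell speed mutual
information during escapes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BehaviorEpoch
from .errors import DegenerateInputError, ParameterError
from .information import mutual_information_binned

log = logging.getLogger(__name__)


@dataclass
class EnsembleRecording:
    """Cells x frames trace matrix aligned to behavior frames."""

    traces: np.ndarray
    times: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ParameterError("traces must be a 2-D cells x frames matrix")
        if self.traces.shape[1] != len(self.times):
            raise ParameterError("trace columns must match timestamps")
        if self.traces.shape[0] != len(self.cell_ids):
            raise ParameterError("trace rows must match cell ids")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def zscored(self) -> np.ndarray:
        m = self.traces.mean(axis=1, keepdims=True)
        s = self.traces.std(axis=1, keepdims=True)
        return (self.traces - m) / np.where(s > 1e-15, s, 1.0)


def filter_cells_by_variance(ens: EnsembleRecording,
                             fraction: float = 0.25,
                             outlier_iqr_factor: float = 1.5
                             ) -> tuple[EnsembleRecording, np.ndarray]:
    """Keep cells with variance >= ``fraction`` of the max among non-outliers.

    Outlier cells (undefined in the source rule) are those whose variance
    exceeds the 75th percentile + ``outlier_iqr_factor`` x IQR of cell
    variances; they are excluded from the maximum but still subject to the
    retention rule. Returns the filtered recording and the kept cell ids.
    """
    if ens.n_cells < 1:
        raise ParameterError("ensemble must contain at least one cell")
    var = ens.traces.var(axis=1)
    q25, q75 = np.percentile(var, [25, 75])
    non_outlier = var <= q75 + outlier_iqr_factor * (q75 - q25)
    max_var = var[non_outlier].max() if non_outlier.any() else var.max()
    if max_var <= 0:
        raise DegenerateInputError("all cells have zero variance")
    keep = var >= fraction * max_var
    if not keep.any():
        raise DegenerateInputError("variance filter removed every cell")
    log.info("variance filter kept %d/%d cells", keep.sum(), ens.n_cells)
    filtered = EnsembleRecording(traces=ens.traces[keep],
                                 times=ens.times,
                                 cell_ids=ens.cell_ids[keep])
    return filtered, ens.cell_ids[keep]


def _epoch_indicator(epochs: list[BehaviorEpoch], n_frames: int,
                     label: str | None = None) -> np.ndarray:
    d = np.zeros(n_frames)
    for e in epochs:
        if label is None or e.label == label:
            d[max(0, e.onset):min(n_frames, e.offset)] = 1.0
    return d


def _random_indicator(durations, n, rng, max_tries: int = 200) -> np.ndarray:
    """Indicator with epochs of the given durations at random onsets.

    Onsets are uniform but non-overlapping (true epoch trains never overlap;
    letting null epochs overlap shrinks the indicator's on-fraction and
    inflates null coefficient variance, biasing the percentile test
    conservative).
    """
    d = np.zeros(n)
    placed: list[tuple[int, int]] = []
    for dur in durations:
        for _ in range(max_tries):
            s = int(rng.integers(0, max(1, n - dur)))
            if all(s + dur <= a or s >= b for a, b in placed):
                placed.append((s, s + dur))
                d[s:s + dur] = 1.0
                break
        else:  # session too crowded: fall back to overlapping placement
            s = int(rng.integers(0, max(1, n - dur)))
            d[s:s + dur] = 1.0
    return d


def _glm_coefs(z: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Least-squares slope of each z-scored trace on the indicator."""
    dc = d - d.mean()
    denom = float(dc @ dc)
    if denom <= 0:
        return np.full(z.shape[0], np.nan)
    return (z @ dc) / denom


def _exceeds_null(observed: np.ndarray, null: np.ndarray,
                  percentile: float) -> np.ndarray:
    """observed > given percentile of its null row, where the percentile is
    taken at the next-higher order statistic (the literal reading of
    "exceeded ``percentile``% of the null values")."""
    thr = np.percentile(null, percentile, axis=-1, method="higher")
    return observed > thr


def classify_behavior_tuned_cells(ens: EnsembleRecording,
                                  epochs: list[BehaviorEpoch],
                                  label: str,
                                  n_shuffles: int = 100,
                                  percentile: float = 95.0,
                                  seed: int = 0) -> pd.DataFrame:
    """Flag cells whose activity increases during one behavior.

    Per cell, an identity-link least-squares GLM of the z-scored trace on the
    behavior indicator gives the observed coefficient. Onset times are
    randomized ``n_shuffles`` times (epoch durations preserved, onsets uniform
    within the session) to build a per-cell null; a cell is flagged when its
    observed coefficient exceeds ``percentile``% of its null coefficients
    (one-sided: activation only).

    Returns a table (cell, coef, null_pct, flag).
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n = ens.n_frames
    sel = [e for e in epochs if e.label == label]
    z = ens.zscored()
    if not sel:
        log.warning("no %r epochs: all cells unflagged", label)
        return pd.DataFrame({"cell": ens.cell_ids,
                             "coef": np.nan, "null_pct": np.nan,
                             "flag": False})
    obs = _glm_coefs(z, _epoch_indicator(sel, n))

    durations = [e.n_frames for e in sel]
    null = np.empty((ens.n_cells, n_shuffles))
    for j in range(n_shuffles):
        null[:, j] = _glm_coefs(z, _random_indicator(durations, n, rng))

    flag = _exceeds_null(obs, null, percentile)
    null_pct = (null < obs[:, None]).mean(axis=1) * 100.0
    return pd.DataFrame({"cell": ens.cell_ids, "coef": obs,
                         "null_pct": null_pct, "flag": flag})


def _masked_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x with y; NaN for zero-variance rows."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[sx < 1e-12] = np.nan
    return r


def classify_escape_speed_cells(ens: EnsembleRecording,
                                speed: np.ndarray,
                                epochs: list[BehaviorEpoch],
                                n_shuffles: int = 100,
                                min_shift_s: float = 30.0,
                                percentile: float = 95.0,
                                seed: int = 0) -> pd.DataFrame:
    """Flag cells whose activity tracks running speed during escapes.

    Per cell, Pearson r between the trace and speed restricted to escape
    samples. The chance distribution pools, across all classifiable cells,
    ``n_shuffles`` circular time-shifts of each trace by random durations in
    [``min_shift_s``, T - ``min_shift_s``]; a cell is flagged when |r| exceeds
    the ``percentile``-th percentile of the pooled null (two-sided via the
    absolute value). Constant-trace cells are marked non-classifiable and
    excluded from pooling.

    Returns a table (cell, r, flag, classifiable) with the pooled threshold
    in ``df.attrs["null_threshold"]``.
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    speed = np.asarray(speed, dtype=float)
    if len(speed) != ens.n_frames:
        raise ParameterError("speed must align to ensemble frames")
    n = ens.n_frames
    fs = ens.frame_rate_hz
    duration_s = n / fs
    if duration_s <= 2 * min_shift_s:
        raise ParameterError("session must be longer than twice min_shift_s")
    esc = [e for e in epochs if e.label == "escape"]
    if not esc:
        raise ParameterError("at least one escape epoch is required")
    mask_idx = np.flatnonzero(_epoch_indicator(esc, n) > 0)
    if len(mask_idx) < 2:
        raise ParameterError("need at least 2 escape samples")

    rng = np.random.default_rng(seed)
    y = speed[mask_idx]
    X = ens.traces
    obs = _masked_corr(X[:, mask_idx], y)
    classifiable = np.isfinite(obs)

    lo = int(round(min_shift_s * fs))
    hi = n - lo
    null = np.empty((ens.n_cells, n_shuffles))
    for j in range(n_shuffles):
        shifts = rng.integers(lo, hi, size=ens.n_cells)
        cols = (mask_idx[None, :] + shifts[:, None]) % n
        shifted = X[np.arange(ens.n_cells)[:, None], cols]
        null[:, j] = _masked_corr(shifted, y)
    pooled = np.abs(null[classifiable]).ravel()
    pooled = pooled[np.isfinite(pooled)]
    thr = float(np.percentile(pooled, percentile, method="higher"))
    flag = np.where(classifiable, np.abs(obs) > thr, False)

    out = pd.DataFrame({"cell": ens.cell_ids, "r": obs, "flag": flag,
                        "classifiable": classifiable})
    out.attrs["null_threshold"] = thr
    out.attrs["shift_range_s"] = (min_shift_s, duration_s - min_shift_s)
    return out


def cell_speed_mutual_information(ens: EnsembleRecording,
                                  speed: np.ndarray,
                                  epochs: list[BehaviorEpoch],
                                  bins: int = 20) -> pd.DataFrame:
    """Per-cell MI (bits) between calcium signal and speed on escape samples.

    Cells with undefined MI (constant on the mask) get NaN; zero escape
    samples give NaN for every cell.
    """
    speed = np.asarray(speed, dtype=float)
    n = ens.n_frames
    mask = _epoch_indicator([e for e in epochs if e.label == "escape"], n) > 0
    n_mask = int(mask.sum())
    if n_mask < bins:
        log.warning("only %d escape samples for %d bins; MI will be biased",
                    n_mask, bins)
    mi = np.full(ens.n_cells, np.nan)
    if n_mask > 1:
        y = speed[mask]
        for c in range(ens.n_cells):
            try:
                mi[c] = mutual_information_binned(ens.traces[c, mask], y,
                                                  bins=bins).mi_bits
            except DegenerateInputError:
                pass
    return pd.DataFrame({"cell": ens.cell_ids, "mi_bits": mi,
                         "n_samples": n_mask})
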