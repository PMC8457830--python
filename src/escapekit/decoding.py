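"""Decoding behavior and kinematic variables from ensemble activity.

Discrete decoding: multinomial logistic classification of behavior timepoints
against an equal number of randomly selected non-behavior timepoints, with
5-fold temporally contiguous cross-validation and a 10 s buffer between
training and validation samples; chance accuracy is 50% by class balance.
Sessions with fewer than five instances of the behavior are excluded.

Continuous decoding: principal components covering >= 80% of variance feed an
identity-link linear model trained on alternating 60 s blocks (10 s gaps) and
tested on the withheld blocks; accuracy is mean squared error, with chance
error from re-running the full pipeline on circularly permuted neural data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, Ridge

from .core import BehaviorEpoch, KinematicsSeries
from .ensemble import EnsembleRecording
from .errors import ParameterError

log = logging.getLogger(__name__)

CONTINUOUS_TARGETS = ("position", "velocity_away", "velocity_toward")


@dataclass
class DecodingResult:
    """Outcome of one decoding task."""

    task: str
    lag_s: float = 0.0
    metric: str = "accuracy"      # 'accuracy' or 'mse'
    fold_values: np.ndarray = field(default_factory=lambda: np.array([]))
    value: float = np.nan         # aggregate over folds / test blocks
    chance: np.ndarray | None = None   # permutation distribution
    n_samples: int = 0
    excluded: bool = False
    reason: str = ""

    def chance_percentile(self) -> float:
        """Percentile of the observed value within its chance distribution."""
        if self.chance is None or not np.isfinite(self.value):
            return np.nan
        return float((self.chance < self.value).mean() * 100.0)


def _positive_mask(times, epochs, window_pre, window_post):
    mask = np.zeros(len(times), dtype=bool)
    dropped = 0
    for e in epochs:
        t0 = times[min(e.onset, len(times) - 1)]
        lo, hi = t0 + window_pre, t0 + window_post
        if lo < times[0]:
            dropped += 1
            continue
        mask |= (times >= lo) & (times < hi)
    if dropped:
        log.info("%d epochs dropped: window precedes session start", dropped)
    return mask, dropped


def _balance(idx_a, idx_b, rng):
    """Downsample the larger set so both have equal size."""
    if len(idx_a) > len(idx_b):
        idx_a = rng.choice(idx_a, len(idx_b), replace=False)
    elif len(idx_b) > len(idx_a):
        idx_b = rng.choice(idx_b, len(idx_a), replace=False)
    return np.sort(idx_a), np.sort(idx_b)


def _classify(ens: EnsembleRecording, epochs, label, window_pre, window_post,
              n_folds, min_instances, separation_s, guard_s, seed,
              permute_labels, task, lag_s) -> DecodingResult:
    sel = [e for e in epochs if e.label == label]
    times = ens.times
    pos_mask, dropped = _positive_mask(times, sel, window_pre, window_post)
    usable = len(sel) - dropped
    if usable < min_instances:
        return DecodingResult(task=task, lag_s=lag_s, excluded=True,
                              reason=f"{usable} usable {label} epochs "
                                     f"< minimum {min_instances}")
    rng = np.random.default_rng(seed)
    guard_mask, _ = _positive_mask(times, sel, window_pre - guard_s,
                                   window_post + guard_s)
    pos_idx = np.flatnonzero(pos_mask)
    neg_pool = np.flatnonzero(~guard_mask)
    if len(neg_pool) == 0 or len(pos_idx) == 0:
        return DecodingResult(task=task, lag_s=lag_s, excluded=True,
                              reason="no usable samples")
    neg_idx = rng.choice(neg_pool, min(len(pos_idx), len(neg_pool)),
                         replace=False)
    pos_idx, neg_idx = _balance(pos_idx, neg_idx, rng)

    samples = np.sort(np.concatenate([pos_idx, neg_idx]))
    y = np.isin(samples, pos_idx).astype(int)
    if permute_labels:
        y = rng.permutation(y)
    Z = ens.zscored()
    X = Z[:, samples].T
    t_s = times[samples]

    if len(samples) < n_folds:
        raise ParameterError("fewer samples than folds")
    fold_ids = np.array_split(np.arange(len(samples)), n_folds)
    accs = []
    for val in fold_ids:
        v_lo, v_hi = t_s[val[0]], t_s[val[-1]]
        train = np.array([i for i in range(len(samples)) if i not in set(val)
                          and not (v_lo - separation_s <= t_s[i]
                                   <= v_hi + separation_s)])
        if len(train) == 0:
            continue
        # re-balance classes inside the fold
        tr_p = train[y[train] == 1]
        tr_n = train[y[train] == 0]
        va_p = val[y[val] == 1]
        va_n = val[y[val] == 0]
        if min(len(tr_p), len(tr_n), len(va_p), len(va_n)) == 0:
            log.info("fold skipped: a class is absent after the buffer")
            continue
        tr_p, tr_n = _balance(tr_p, tr_n, rng)
        va_p, va_n = _balance(va_p, va_n, rng)
        tr = np.concatenate([tr_p, tr_n])
        va = np.concatenate([va_p, va_n])
        # temporal hygiene: no validation sample within the buffer of training
        assert np.min(np.abs(t_s[va][:, None] - t_s[tr][None, :])) \
            >= separation_s
        clf = LogisticRegression(C=10.0, max_iter=2000)
        clf.fit(X[tr], y[tr])
        accs.append(float(clf.score(X[va], y[va])))
    if not accs:
        return DecodingResult(task=task, lag_s=lag_s, excluded=True,
                              reason="no valid folds after buffering")
    return DecodingResult(task=task, lag_s=lag_s, metric="accuracy",
                          fold_values=np.array(accs),
                          value=float(np.mean(accs)),
                          n_samples=len(samples))


def decode_ongoing_behavior(ens: EnsembleRecording,
                            epochs: list[BehaviorEpoch],
                            label: str = "escape",
                            window_s: float = 2.0,
                            n_folds: int = 5,
                            min_instances: int = 5,
                            separation_s: float = 10.0,
                            guard_s: float = 2.0,
                            seed: int = 0,
                            permute_labels: bool = False) -> DecodingResult:
    """Decode ongoing behavior vs matched non-behavior timepoints.

    Positive samples are all timepoints within ``window_s`` after each onset;
    negatives are an equal number of randomly selected timepoints outside the
    positive windows and a ``guard_s`` band around them. Each timepoint is an
    individual data point. ``permute_labels`` shuffles class labels before
    fold construction (chance control).
    """
    return _classify(ens, epochs, label, 0.0, window_s, n_folds,
                     min_instances, separation_s, guard_s, seed,
                     permute_labels, task=f"ongoing_{label}", lag_s=0.0)


def decode_future_escape(ens: EnsembleRecording,
                         epochs: list[BehaviorEpoch],
                         lags_s=(2.0, 4.0, 6.0, 8.0, 10.0),
                         window_s: float = 2.0,
                         n_folds: int = 5,
                         min_instances: int = 5,
                         separation_s: float = 10.0,
                         guard_s: float = 2.0,
                         seed: int = 0,
                         permute_labels: bool = False
                         ) -> dict[float, DecodingResult]:
    """Decode upcoming escape from 2 s windows preceding onset by each lag.

    Positive windows are [onset - lag - window_s, onset - lag]; negatives are
    matched per lag. Epochs whose window precedes the session start are
    dropped with a log notice.
    """
    out = {}
    for lag in lags_s:
        out[lag] = _classify(ens, epochs, "escape",
                             -lag - window_s, -lag, n_folds, min_instances,
                             separation_s, guard_s, seed, permute_labels,
                             task="future_escape", lag_s=lag)
    return out


def _block_masks(times, mask, block_s, gap_s):
    period = block_s + gap_s
    phase = times % period
    block_idx = (times // period).astype(int)
    in_block = phase < block_s
    train = in_block & (block_idx % 2 == 0) & mask
    test = in_block & (block_idx % 2 == 1) & mask
    return train, test


def _pcs_glm_mse(X, y, train, test, variance_kept):
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Xz = (X - mu) / sd
    pca = PCA()
    pca.fit(Xz[train])
    k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_),
                            variance_kept) + 1)
    P = pca.components_[:k]
    model = Ridge(alpha=1e-3)
    model.fit(Xz[train] @ P.T, y[train])
    pred = model.predict(Xz[test] @ P.T)
    return float(np.mean((pred - y[test]) ** 2))


def decode_continuous_variable(ens: EnsembleRecording,
                               kin: KinematicsSeries,
                               target: str = "position",
                               variance_kept: float = 0.80,
                               block_s: float = 60.0,
                               gap_s: float = 10.0,
                               n_perms: int = 100,
                               min_shift_s: float = 30.0,
                               seed: int = 0) -> DecodingResult:
    """Decode position or directional velocity with a PCA-reduced GLM.

    Targets: ``position`` (tailbase coordinate along the threat axis, all
    samples), ``velocity_away``/``velocity_toward`` (speed along the threat
    axis restricted to samples moving in that direction). Training uses
    even-indexed 60 s blocks, testing odd-indexed blocks, with 10 s gaps
    excluded. PCA is fitted on training blocks only. The chance distribution
    re-runs the identical pipeline (PCA refit included) on ``n_perms``
    circular rotations of the neural data by at least ``min_shift_s``.
    """
    if target not in CONTINUOUS_TARGETS:
        raise ParameterError(f"target must be one of {CONTINUOUS_TARGETS}")
    if n_perms < 0:
        raise ParameterError("n_perms must be >= 0")
    times = ens.times
    if len(times) != kin.n_frames:
        raise ParameterError("kinematics must align to ensemble frames")
    v_threat = kin["v_threat"]
    if target == "position":
        y = kin["x"]
        mask = np.isfinite(y)
    elif target == "velocity_away":
        y = -v_threat
        mask = np.isfinite(y) & (y > 0)
    else:
        y = v_threat
        mask = np.isfinite(y) & (y > 0)

    duration = times[-1] - times[0]
    if duration < 2 * block_s + gap_s:
        return DecodingResult(task=target, metric="mse", excluded=True,
                              reason="session shorter than two blocks")
    train, test = _block_masks(times, mask, block_s, gap_s)
    if train.sum() < 2 or test.sum() < 2:
        return DecodingResult(task=target, metric="mse", excluded=True,
                              reason="empty training or testing blocks")
    if np.ptp(y[train]) == 0:
        return DecodingResult(task=target, metric="mse", excluded=True,
                              reason="degenerate (constant) target")
    # temporal hygiene: every train/test pair separated by the gap
    assert np.min(np.abs(times[test][:, None] - times[train][None, :])) \
        >= gap_s - 1e-9

    X = ens.traces.T
    mse = _pcs_glm_mse(X, y, train, test, variance_kept)

    rng = np.random.default_rng(seed)
    fs = ens.frame_rate_hz
    lo = int(round(min_shift_s * fs))
    hi = max(lo + 1, ens.n_frames - lo)
    chance = np.empty(n_perms)
    for j in range(n_perms):
        shift = int(rng.integers(lo, hi))
        chance[j] = _pcs_glm_mse(np.roll(X, shift, axis=0), y,
                                 train, test, variance_kept)
    return DecodingResult(task=target, metric="mse", value=mse,
                          fold_values=np.array([mse]),
                          chance=chance if n_perms else None,
                          n_samples=int(train.sum() + test.sum()))
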