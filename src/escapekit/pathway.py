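"""Two-region latent pathway estimation by first-component PLS.

A partial-least-squares first component identifies the pair of voxel weight
maps maximizing the covariance between a predictor-region block and an
outcome-region block of trial x voxel activations. Pathway strength is the
Pearson correlation between the paired latent scores ("X score" and
"Y score"), estimated with leave-one-subject-out cross-validation. Voxel
contributions are localized by bootstrapping subjects and normal-approximation
inference with Benjamini-Hochberg FDR; pathway specificity is assessed with a
partial correlation controlling the latent source of a confound region.

The first PLS component is computed exactly as the leading singular-vector
pair of the cross-covariance matrix of the column-centered blocks (the NIPALS
first-component solution). Only component 1 is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ParameterError


@dataclass
class SubjectBlock:
    """One subject's trial x voxel matrices plus per-trial covariates."""

    predictor: np.ndarray
    outcome: np.ndarray
    confound: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.predictor = np.asarray(self.predictor, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.predictor.ndim != 2 or self.outcome.ndim != 2:
            raise FormatError("blocks must be 2-D trial x voxel matrices")
        if self.predictor.shape[0] != self.outcome.shape[0]:
            raise FormatError("trial counts must match across regions")
        if self.confound is not None:
            self.confound = np.asarray(self.confound, dtype=float)
            if self.confound.shape[0] != self.predictor.shape[0]:
                raise FormatError("confound trial count must match")

    @property
    def n_trials(self) -> int:
        return self.predictor.shape[0]


@dataclass
class PathwayBlocks:
    """Multi-subject predictor/outcome (and optional confound) blocks."""

    subjects: list[SubjectBlock]

    def __post_init__(self):
        if not self.subjects:
            raise FormatError("at least one subject required")
        np_, no = self.subjects[0].predictor.shape[1], \
            self.subjects[0].outcome.shape[1]
        for s in self.subjects:
            if s.predictor.shape[1] != np_ or s.outcome.shape[1] != no:
                raise FormatError("voxel counts must match across subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def stacked(self, exclude: int | None = None, region: str = "predictor"):
        mats = [getattr(s, region) for i, s in enumerate(self.subjects)
                if i != exclude]
        if any(m is None for m in mats):
            raise ParameterError(f"missing {region} block")
        return np.vstack(mats)

    def stacked_covariates(self) -> pd.DataFrame:
        frames = []
        for i, s in enumerate(self.subjects):
            if s.covariates is None:
                raise ParameterError("missing trial covariates")
            f = s.covariates.copy()
            f["subject"] = i
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def pls_first_component(X: np.ndarray, Y: np.ndarray):
    """First PLS component of two column-centered blocks.

    Returns (x_weights, y_weights, x_mean, y_mean), sign-fixed so the
    largest-magnitude predictor weight is positive. The weights are the
    leading left/right singular vectors of ``Xc.T @ Yc``, the directions
    maximizing score covariance.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < 2:
        raise ParameterError("at least 2 trials required for PLS")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    U, s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    wx, wy = U[:, 0], Vt[0]
    if wx[np.argmax(np.abs(wx))] < 0:
        wx, wy = -wx, -wy
    return wx, wy, mx, my


@dataclass
class PathwayModel:
    """Fitted pathway: weight maps, LOSO correlations, full-data scores."""

    x_weights: np.ndarray
    y_weights: np.ndarray
    loso_correlations: np.ndarray      # one per held-out subject
    x_scores: np.ndarray               # full-data scores, stacked trials
    y_scores: np.ndarray
    subject_index: np.ndarray


def _loso_scores(blocks: PathwayBlocks, predictor_region: str = "predictor",
                 outcome_region: str = "outcome"):
    """Held-out first-component scores for every subject's trials.

    For each held-out subject, PLS is fitted on the remaining subjects'
    stacked trials (column-centered with training means; held-out trials are
    centered with the same means, leakage-safe) and the held-out trials are
    projected onto the first component's weights. Held-out scores carry none
    of the in-sample noise alignment that the covariance-maximizing fit
    induces between the two blocks' scores.
    """
    if blocks.n_subjects < 3:
        raise ParameterError("at least 3 subjects required for "
                             "leave-one-subject-out validation")
    ref_wx, *_ = pls_first_component(blocks.stacked(region=predictor_region),
                                     blocks.stacked(region=outcome_region))
    xs_all, ys_all = [], []
    for i, held in enumerate(blocks.subjects):
        Xtr = blocks.stacked(exclude=i, region=predictor_region)
        Ytr = blocks.stacked(exclude=i, region=outcome_region)
        wx, wy, mx, my = pls_first_component(Xtr, Ytr)
        if wx @ ref_wx < 0:  # keep fold solutions in one sign convention
            wx, wy = -wx, -wy
        xs_all.append((getattr(held, predictor_region) - mx) @ wx)
        ys_all.append((getattr(held, outcome_region) - my) @ wy)
    return xs_all, ys_all


def fit_pls_pathway(blocks: PathwayBlocks) -> PathwayModel:
    """Estimate the pathway with leave-one-subject-out validation.

    Per-subject pathway strength is the Pearson correlation between the
    held-out X and Y scores (see :func:`_loso_scores`); full-data weight maps
    and scores are returned alongside.
    """
    xs_all, ys_all = _loso_scores(blocks)
    rs = []
    for xs, ys in zip(xs_all, ys_all):
        if xs.std() < 1e-12 or ys.std() < 1e-12:
            rs.append(np.nan)
        else:
            rs.append(float(stats.pearsonr(xs, ys)[0]))

    Xall = blocks.stacked(region="predictor")
    Yall = blocks.stacked(region="outcome")
    wx, wy, mx, my = pls_first_component(Xall, Yall)
    subj = np.concatenate([np.full(s.n_trials, i)
                           for i, s in enumerate(blocks.subjects)])
    return PathwayModel(x_weights=wx, y_weights=wy,
                        loso_correlations=np.array(rs),
                        x_scores=(Xall - mx) @ wx,
                        y_scores=(Yall - my) @ wy,
                        subject_index=subj)


def bootstrap_voxel_contributions(blocks: PathwayBlocks, n_boot: int = 1000,
                                  seed: int = 0) -> dict[str, pd.DataFrame]:
    """Localize pathway voxels by bootstrapping subjects.

    Subjects are resampled with replacement ``n_boot`` times; each replicate's
    weight maps are sign-aligned to the full-data solution before
    aggregation. Per voxel: bootstrap mean, sd, z = mean/sd, two-sided normal
    p, and Benjamini-Hochberg q. Returns one table per region
    ('predictor', 'outcome').
    """
    if n_boot < 2:
        raise ParameterError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    ref_wx, ref_wy, *_ = pls_first_component(
        blocks.stacked(region="predictor"), blocks.stacked(region="outcome"))
    n_sub = blocks.n_subjects
    WX = np.empty((n_boot, len(ref_wx)))
    WY = np.empty((n_boot, len(ref_wy)))
    for b in range(n_boot):
        pick = rng.integers(0, n_sub, size=n_sub)
        X = np.vstack([blocks.subjects[i].predictor for i in pick])
        Y = np.vstack([blocks.subjects[i].outcome for i in pick])
        wx, wy, *_ = pls_first_component(X, Y)
        if wx @ ref_wx < 0:
            wx, wy = -wx, -wy
        WX[b], WY[b] = wx, wy

    out = {}
    for region, W in (("predictor", WX), ("outcome", WY)):
        mean = W.mean(axis=0)
        sd = W.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 1e-15, mean / sd, 0.0)
        p = 2 * stats.norm.sf(np.abs(z))
        q = multipletests(p, method="fdr_bh")[1]
        out[region] = pd.DataFrame({"voxel": np.arange(W.shape[1]),
                                    "mean": mean, "sd": sd,
                                    "z": z, "p": p, "q": q})
    return out


def partial_pathway_correlation(blocks: PathwayBlocks
                                ) -> tuple[float, float]:
    """(raw, partial) pathway correlation controlling the confound latent.

    The confound latent is the X score of a confound-region -> outcome PLS
    fitted with the same machinery. All scores are held-out (leave-one-
    subject-out) estimates: in-sample scores of a covariance-maximizing fit
    carry correlated noise between the two blocks, which would leave a
    spurious partial correlation even for a pure confound. The partial
    correlation residualizes both pathway scores on the confound score.
    """
    if any(s.confound is None for s in blocks.subjects):
        raise ParameterError("partial correlation requires a confound block "
                             "for every subject")
    xs, ys = _loso_scores(blocks)
    cs, _ = _loso_scores(blocks, predictor_region="confound")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    c = np.concatenate(cs)
    raw = float(stats.pearsonr(x, y)[0])

    def _resid(v):
        A = np.column_stack([c, np.ones_like(c)])
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    partial = float(stats.pearsonr(_resid(x), _resid(y))[0])
    return raw, partial


def pathway_condition_contrast(model: PathwayModel,
                               covariates: pd.DataFrame,
                               condition_col: str = "condition",
                               intensity_col: str = "intensity",
                               threat_label: str = "threat") -> dict:
    """Per-condition pathway expression and trend over intensity levels.

    Pathway expression per trial is the product of the standardized X and Y
    scores (co-activation of the paired latents). Returns per-subject mean
    expression per condition, a threat-vs-control contrast (Wilcoxon
    signed-rank across subjects), and a monotonic-trend statistic (mean
    per-subject least-squares slope of expression over the intensity levels,
    tested across subjects). Inference is flagged unavailable for a single
    subject.
    """
    for col in (condition_col, intensity_col):
        if col not in covariates.columns:
            raise ParameterError(f"missing trial covariate {col!r}")
    if len(covariates) != len(model.x_scores):
        raise ParameterError("covariates must have one row per trial")

    def _std(v):
        s = v.std()
        return (v - v.mean()) / (s if s > 1e-15 else 1.0)

    df = covariates.copy()
    df["subject"] = model.subject_index
    df["expression"] = _std(model.x_scores) * _std(model.y_scores)

    per_cond = (df.groupby(["subject", condition_col])["expression"]
                .mean().unstack())
    threat = per_cond[threat_label]
    control = per_cond.drop(columns=threat_label).mean(axis=1)
    diffs = (threat - control).to_numpy()

    slopes = []
    for _, sub in df.groupby("subject"):
        lv = sub.groupby(intensity_col)["expression"].mean()
        if len(lv) >= 2:
            slopes.append(float(np.polyfit(lv.index.to_numpy(dtype=float),
                                           lv.to_numpy(), 1)[0]))
        else:
            slopes.append(np.nan)
    slopes = np.array(slopes)

    n = len(diffs)
    inference = n >= 2
    contrast_p = trend_p = np.nan
    if inference:
        if np.any(diffs != 0):
            contrast_p = float(stats.wilcoxon(diffs)[1])
        ok = slopes[np.isfinite(slopes)]
        if len(ok) >= 2 and np.any(ok != 0):
            trend_p = float(stats.wilcoxon(ok)[1])
    return {
        "per_condition_means": per_cond,
        "contrast_stat": float(np.mean(diffs)),
        "contrast_p": contrast_p,
        "trend_slopes": slopes,
        "trend_stat": float(np.nanmean(slopes)),
        "trend_p": trend_p,
        "inference_available": inference,
    }
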