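"""Histogram mutual information between two continuous signals.

Each signal is discretized into equal-width bins over its own observed range
(20 by default), the joint distribution is the normalized 2-D histogram, and

    MI = sum_ij p(i,j) log2[ p(i,j) / (p(i) p(j)) ]

over occupied cells (0 log 0 = 0 by convention). No bias correction is
applied; the analytic first-order bias of the estimator under independence is
(bins_x - 1)(bins_y - 1) / (2 n ln 2) bits and is exposed for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, FormatError, ParameterError


@dataclass
class MIResult:
    mi_bits: float
    bins: int
    n: int
    mask_note: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mi_bits)


def analytic_bias_bits(bins: int, n: int) -> float:
    """First-order positive bias of binned MI under independence (bits)."""
    return (bins - 1) ** 2 / (2 * n * np.log(2))


def mutual_information_binned(x, y, bins: int = 20,
                              strategy: str = "width") -> MIResult:
    """Binned MI (bits) between two equal-length signals.

    ``strategy`` is ``"width"`` (equal-width bins over each signal's observed
    min-max, the default) or ``"frequency"`` (equal-occupancy edges).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatError("signals must be 1-D and equal length")
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise DegenerateInputError("fewer than 2 finite samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant signal: MI undefined under "
                                   "range binning")
    if strategy == "width":
        edges_x = np.linspace(x.min(), x.max(), bins + 1)
        edges_y = np.linspace(y.min(), y.max(), bins + 1)
    elif strategy == "frequency":
        q = np.linspace(0, 100, bins + 1)
        edges_x = np.unique(np.percentile(x, q))
        edges_y = np.unique(np.percentile(y, q))
    else:
        raise ParameterError("strategy must be 'width' or 'frequency'")
    joint, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    mi = float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))
    return MIResult(mi_bits=max(mi, 0.0), bins=bins, n=len(x))


def region_pair_mutual_information(sig_a, sig_b, speed,
                                   escape_mask=None,
                                   speed_floor: float = 1.0,
                                   exclude_escapes: bool = False,
                                   bins: int = 20) -> MIResult:
    """MI between two region signals under the movement mask.

    Retains samples with speed above ``speed_floor`` (1 cm/s), minus
    escape-epoch samples when ``exclude_escapes`` is set. An empty mask gives
    an undefined (NaN) result with ``n = 0`` rather than an error.
    """
    sig_a = np.asarray(sig_a, dtype=float)
    sig_b = np.asarray(sig_b, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if not (len(sig_a) == len(sig_b) == len(speed)):
        raise FormatError("signals and speed must share one time base")
    with np.errstate(invalid="ignore"):
        mask = speed > speed_floor
    note = f"speed>{speed_floor}"
    if exclude_escapes:
        if escape_mask is None:
            raise ParameterError("exclude_escapes requires an escape mask")
        mask &= ~np.asarray(escape_mask, dtype=bool)
        note += ", escapes excluded"
    if mask.sum() == 0:
        return MIResult(mi_bits=np.nan, bins=bins, n=0, mask_note=note)
    res = mutual_information_binned(sig_a[mask], sig_b[mask], bins=bins)
    return MIResult(mi_bits=res.mi_bits, bins=bins, n=res.n, mask_note=note)
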