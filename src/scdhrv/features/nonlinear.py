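"""Nonlinear HRV descriptors: Poincaré plot geometry and DFA.

The Poincaré plot scatters RR(i+1) against RR(i).  SD1 — the spread of
the cloud perpendicular to the identity line y = x — captures fast
beat-to-beat variability; SD2 — the spread along the line
y = -x + 2*mean(RR) — the longer-term variability.  Both are computed as
the RMS of the signed point-to-line distances (the zero-mean population
convention), which makes the identity SD1 = RMSSD / sqrt(2) exact.

Detrended fluctuation analysis (DFA) quantifies long-range correlation:
the centred RR series is integrated to a profile, the profile is split
into boxes of size n, a least-squares line is removed per box, and the
scaling exponent alpha is the log-log slope of the residual RMS F(n)
against n.  alpha = 0.5 for white noise, 1.0 for 1/f noise, 1.5 for a
Brownian profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..io import RrSeries

__all__ = ["PoincareFeatures", "DfaResult", "poincare_features", "dfa_alpha"]


@dataclass(frozen=True)
class PoincareFeatures:
    sd1: float  # ms, short-term variability
    sd2: float  # ms, long-term variability
    ratio: float  # sd1 / sd2


@dataclass(frozen=True)
class DfaResult:
    alpha: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray  # F(n) per box size


def poincare_features(rr: RrSeries) -> PoincareFeatures:
    """SD1, SD2 and their ratio from the Poincaré plot of the RR series."""
    x = rr.rr
    if x.size < 3:
        raise ValueError("need at least 3 RR intervals for a Poincaré plot")
    a, b = x[:-1], x[1:]  # (RR_i, RR_{i+1}) pairs
    mean_rr = x.mean()
    perp = (b - a) / np.sqrt(2.0)  # signed distance from y = x
    along = (a + b - 2.0 * mean_rr) / np.sqrt(2.0)  # from y = -x + 2*mean
    sd1 = float(np.sqrt(np.mean(perp**2)))
    sd2 = float(np.sqrt(np.mean(along**2)))
    if sd2 > 0:
        ratio = sd1 / sd2
    else:
        warnings.warn("SD2 = 0; SD1/SD2 reported as +inf sentinel")
        ratio = np.inf if sd1 > 0 else 0.0
    return PoincareFeatures(sd1=sd1, sd2=sd2, ratio=ratio)


def dfa_alpha(
    rr: RrSeries,
    box_min: int = 4,
    box_max: int | None = None,
    n_boxes: int = 16,
) -> DfaResult:
    """DFA scaling exponent of the RR series (first-order detrending).

    Box sizes are log-spaced between ``box_min`` and ``box_max``
    (default N/4); boxes with zero residual fluctuation are dropped with a
    warning.  A single overall alpha is fitted.
    """
    x = np.asarray(rr.rr, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("DFA needs at least 64 RR intervals")
    if box_max is None:
        box_max = n // 4
    profile = np.cumsum(x - x.mean())
    sizes = np.unique(
        np.round(np.geomspace(box_min, box_max, n_boxes)).astype(int)
    )
    fluctuations = []
    kept = []
    for size in sizes:
        n_full = n // size
        segs = profile[: n_full * size].reshape(n_full, size)
        t = np.arange(size, dtype=float)
        # least-squares line per box, vectorised
        t_mean = t.mean()
        denom = np.sum((t - t_mean) ** 2)
        seg_mean = segs.mean(axis=1, keepdims=True)
        slope = (segs @ (t - t_mean))[:, None] / denom
        resid = segs - seg_mean - slope * (t - t_mean)
        f = np.sqrt(np.mean(resid**2))
        if f == 0:
            warnings.warn(f"F(n) = 0 at box size {size}; dropped")
            continue
        kept.append(size)
        fluctuations.append(f)
    if len(kept) < 2:
        raise ValueError(
            "fluctuations vanish at (nearly) all box sizes; "
            "series has no variability to scale"
        )
    kept_arr = np.array(kept)
    fl = np.array(fluctuations)
    alpha = float(np.polyfit(np.log(kept_arr), np.log(fl), 1)[0])
    return DfaResult(alpha=alpha, box_sizes=kept_arr, fluctuations=fl)
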