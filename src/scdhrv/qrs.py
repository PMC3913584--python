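"""QRS detection (Pan-Tompkins) and tachogram construction.

The detector follows the classic stage sequence: 5-15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration, dual
adaptive thresholds on the filtered and integrated signals, a 200 ms
refractory period, 360 ms T-wave discrimination by slope, and search-back
at 1.66x the running RR average.  All stage lengths are specified in
milliseconds and converted to samples by rounding, so 128 Hz and 256 Hz
records are handled identically.  Filters are applied zero-phase: R-peak
*timing* is the quantity every downstream HRV feature depends on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .io import EcgRecord, RrSeries

__all__ = ["UniformTachogram", "pan_tompkins", "rr_from_beats", "resample_tachogram"]

_REFRACTORY_S = 0.200
_TWAVE_S = 0.360
_INTEGRATION_S = 0.150
_SEARCHBACK_FACTOR = 1.66


@dataclass(frozen=True)
class UniformTachogram:
    """Mean-removed RR deviation series on a uniform time grid.

    ``rate`` must exceed twice the 0.4 Hz HF band edge so the spectral and
    time-frequency features see the full HRV band.
    """

    values: np.ndarray  # ms, mean removed
    rate: float  # Hz
    t0: float  # s, absolute time of the first grid point

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.rate <= 0.8:
            raise ValueError("tachogram rate must exceed 0.8 Hz (2 x HF edge)")
        if v.size < 16:
            raise ValueError("tachogram too short (< 16 samples)")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate


def _stage_signals(record: EcgRecord) -> tuple[np.ndarray, np.ndarray]:
    """Band-passed signal and moving-window-integrated energy signal."""
    fs = record.fs
    sos = signal.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, record.samples)
    # centred five-point derivative (zero phase): offsets k = -2..+2
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    deriv = np.convolve(bp, kernel, mode="same")
    squared = deriv**2
    win = max(3, round(_INTEGRATION_S * fs))
    from scipy.ndimage import uniform_filter1d

    mwi = uniform_filter1d(squared, size=win if win % 2 else win + 1, mode="nearest")
    return bp, mwi


def pan_tompkins(record: EcgRecord) -> np.ndarray:
    """Detect R-peak times (s), strictly increasing.

    Returns an empty array (with a warning) when no beats are found.
    Adaptive thresholds make the detection invariant to overall signal gain.
    """
    fs = record.fs
    if fs < 100:
        raise ValueError("sampling rates below 100 Hz are not supported")
    if record.duration < 5.0:
        raise ValueError("record shorter than 5 s; too short for QRS detection")
    bp, mwi = _stage_signals(record)

    refractory = round(_REFRACTORY_S * fs)
    candidates, _ = signal.find_peaks(mwi, distance=refractory)
    if candidates.size == 0 or np.max(mwi) <= 0:
        warnings.warn("no QRS candidates found")
        return np.array([])

    # threshold initialisation from the first 2 s
    init = slice(0, round(2.0 * fs))
    spki = float(np.max(mwi[init])) * 0.5
    npki = float(np.mean(mwi[init])) * 0.5
    spkf = float(np.max(np.abs(bp[init]))) * 0.5
    npkf = float(np.mean(np.abs(bp[init]))) * 0.5

    accepted: list[int] = []
    rr_history: list[float] = []
    last_unchecked = 0  # index into candidates for search-back

    def thr_i() -> float:
        return npki + 0.25 * (spki - npki)

    def thr_f() -> float:
        return npkf + 0.25 * (spkf - npkf)

    half_int = round(_INTEGRATION_S * fs / 2)

    def fpeak_at(idx: int) -> float:
        lo, hi = max(0, idx - half_int), min(bp.size, idx + half_int + 1)
        return float(np.max(np.abs(bp[lo:hi])))

    def slope_at(idx: int) -> float:
        lo, hi = max(0, idx - refractory // 2), min(bp.size, idx + refractory // 2)
        return float(np.max(np.abs(np.diff(bp[lo:hi])))) if hi - lo > 1 else 0.0

    def accept(idx: int, peak_i: float, peak_f: float) -> None:
        nonlocal spki, spkf
        spki = 0.125 * peak_i + 0.875 * spki
        spkf = 0.125 * peak_f + 0.875 * spkf
        if accepted:
            rr_history.append((idx - accepted[-1]) / fs)
            del rr_history[:-8]
        accepted.append(idx)

    for ci, idx in enumerate(candidates):
        peak_i = mwi[idx]
        peak_f = fpeak_at(idx)
        is_signal = peak_i > thr_i() and peak_f > thr_f()
        if is_signal and accepted and (idx - accepted[-1]) / fs < _TWAVE_S:
            # T-wave discrimination: a T wave has less than half the slope
            if slope_at(idx) < 0.5 * slope_at(accepted[-1]):
                is_signal = False
        if is_signal:
            accept(idx, peak_i, peak_f)
            last_unchecked = ci + 1
        else:
            npki = 0.125 * peak_i + 0.875 * npki
            npkf = 0.125 * peak_f + 0.875 * npkf
        # search-back when the expected beat is overdue
        if accepted and rr_history:
            rr_avg = float(np.mean(rr_history))
            if (idx - accepted[-1]) / fs > _SEARCHBACK_FACTOR * rr_avg:
                window = [
                    j
                    for j in candidates[last_unchecked:ci + 1]
                    if accepted[-1] + refractory < j < idx
                ]
                if window:
                    back = max(window, key=lambda j: mwi[j])
                    if mwi[back] > 0.5 * thr_i():
                        accept(int(back), mwi[back], fpeak_at(int(back)))
                        accepted.sort()
                        last_unchecked = ci + 1

    if not accepted:
        warnings.warn("no QRS complexes passed the adaptive thresholds")
        return np.array([])

    # refine each R time to the band-passed peak near the integrated maximum
    half = round(0.080 * fs)
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(bp.size, idx + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    return refined / fs


def rr_from_beats(beat_times: np.ndarray) -> RrSeries:
    """RR series (ms) from detected beat times."""
    bt = np.asarray(beat_times, dtype=float)
    if bt.size < 2:
        raise ValueError("need at least 2 beats to form RR intervals")
    if np.any(np.diff(bt) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return RrSeries(beat_times=bt, rr=np.diff(bt) * 1000.0)


def resample_tachogram(rr: RrSeries, rate: float = 4.0) -> UniformTachogram:
    """Cubic-spline resampling of the RR series onto a uniform grid.

    Each interval is time-stamped at its terminating beat; the grid spans
    [first, last] of those stamps at ``rate`` Hz and the mean is removed, so
    the result is the zero-mean HRV deviation signal used by the Burg
    spectrum and the time-frequency analysis.
    """
    if len(rr) < 4:
        raise ValueError("need at least 4 RR intervals to resample")
    t_rr = rr.beat_times[1:]
    spline = CubicSpline(t_rr, rr.rr)
    n = int(np.floor((t_rr[-1] - t_rr[0]) * rate)) + 1
    grid = t_rr[0] + np.arange(n) / rate
    values = spline(grid)
    return UniformTachogram(values=values - values.mean(), rate=rate, t0=float(t_rr[0]))
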