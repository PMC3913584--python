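"""Smoothed pseudo Wigner-Ville distribution and its HRV features.

The SPWVD of the analytic tachogram x(n) is

    SPWVD(n, m) = sum_k h(k) [ sum_p g(p) x(n+p+k) x*(n+p-k) ] e^{-j2*pi*k*m/Nf}

with independent frequency-smoothing (h) and time-smoothing (g) windows,
both symmetric and normalised to unit sum.  The inner product
``x(n+p+k) x*(n+p-k)`` is the instantaneous autocorrelation; frequency bin
m maps to ``f = m * rate / (2 * Nf)``, so the map spans [0, rate/2).  The
distribution is real by conjugate symmetry of the lag kernel; small
negative values (cross-term residue) are kept in the map and rectified
only inside the energy features.

Feature set: the time axis is divided into equal segments (5 for a
one-minute HRV window) whose mean rectified energies give MAXw / MINw /
DIFw / STDw; the frequency axis is divided into the VLF/LF/HF bands,
giving band-width-normalised total energies (Evlf, Elf, Ehf) and band
mean energies (Fvlf, Flf, Fhf); and a first-order derivative of the
segment energies summarises how abruptly energy moves between adjacent
windows — the behaviour that distinguishes the pre-arrest heart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, get_window, hilbert

from ..qrs import UniformTachogram
from .linear import HF_BAND, LF_BAND, VLF_BAND

__all__ = [
    "SpwvdConfig",
    "TfMap",
    "TfWindowFeatures",
    "spwvd",
    "tf_window_features",
    "tf_band_features",
    "tf_first_derivative",
]


@dataclass(frozen=True)
class SpwvdConfig:
    """Smoothing windows of the SPWVD.

    ``h_len``/``g_len`` are half-lengths: the windows have ``2*h_len - 1``
    and ``2*g_len - 1`` points.  ``None`` selects the defaults L/4 and L/10
    (L = signal length), forced odd.  ``h_len = g_len = 1`` degenerates to
    the raw Wigner-Ville distribution.
    """

    h_len: int | None = None
    g_len: int | None = None
    h_kind: str = "hamming"
    g_kind: str = "gaussian"
    n_freq: int = 256

    def resolve(self, signal_length: int) -> tuple[int, int]:
        h = self.h_len if self.h_len is not None else max(2, (signal_length // 8) | 1)
        g = self.g_len if self.g_len is not None else max(1, (signal_length // 20) | 1)
        return h, g


@dataclass(frozen=True)
class TfMap:
    times: np.ndarray  # s
    freqs: np.ndarray  # Hz, [0, rate/2)
    energy: np.ndarray  # (n_freq, n_times), real; may hold small negatives

    @property
    def rectified(self) -> np.ndarray:
        return np.maximum(self.energy, 0.0)


@dataclass(frozen=True)
class TfWindowFeatures:
    energies: np.ndarray  # mean rectified energy per time segment
    max_w: float
    min_w: float
    dif_w: float  # max_w - min_w
    std_w: float  # sample SD of the segment energies


def _half_window(kind: str, half_len: int) -> np.ndarray:
    """Right half (lags 0..half_len-1) of a unit-sum symmetric window."""
    full_len = 2 * half_len - 1
    if full_len == 1:
        return np.array([1.0])
    if kind == "gaussian":
        w = get_window(("gaussian", full_len / 6.0), full_len, fftbins=False)
    else:
        w = get_window(kind, full_len, fftbins=False)
    w = w / w.sum()
    return w[half_len - 1 :]


def _full_window(kind: str, half_len: int) -> np.ndarray:
    full_len = 2 * half_len - 1
    if full_len == 1:
        return np.array([1.0])
    if kind == "gaussian":
        w = get_window(("gaussian", full_len / 6.0), full_len, fftbins=False)
    else:
        w = get_window(kind, full_len, fftbins=False)
    return w / w.sum()


def spwvd(tach: UniformTachogram, cfg: SpwvdConfig = SpwvdConfig()) -> TfMap:
    """FFT-based SPWVD of the tachogram's analytic signal.

    Scaled so that, with no smoothing (h = g = delta), the sum of the map
    over frequency at time n equals |x(n)|^2 (time marginal).
    """
    x = np.asarray(tach.values, dtype=float)
    L = x.size
    h_len, g_len = cfg.resolve(L)
    if 2 * h_len - 1 > L or 2 * g_len - 1 > L:
        raise ValueError("smoothing window longer than the signal")
    nf = cfg.n_freq
    if nf < 2 * h_len:
        raise ValueError("n_freq must be at least twice the h half-length")
    xa = hilbert(x)
    h = _half_window(cfg.h_kind, h_len)
    g = _full_window(cfg.g_kind, g_len)

    R = np.zeros((nf, L), dtype=complex)
    for k in range(h_len):
        prod = np.zeros(L, dtype=complex)
        if 2 * k < L:
            prod[k : L - k] = xa[2 * k :] * np.conj(xa[: L - 2 * k])
        smoothed = fftconvolve(prod, g, mode="same") if g.size > 1 else prod
        if k == 0:
            R[0] = h[0] * smoothed
        else:
            R[k] = h[k] * smoothed
            R[nf - k] = np.conj(R[k])
    energy = np.fft.fft(R, axis=0).real / nf
    freqs = np.arange(nf) * tach.rate / (2.0 * nf)
    return TfMap(times=tach.times, freqs=freqs, energy=energy)


def tf_window_features(tfmap: TfMap, n_segments: int = 5) -> TfWindowFeatures:
    """Segment-energy statistics over equal time blocks.

    The time axis is split into ``n_segments`` contiguous equal-width
    blocks (the last absorbs any remainder columns); each block's energy
    is the mean rectified energy over the block and all frequencies.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    n_times = tfmap.energy.shape[1]
    if n_times < n_segments:
        raise ValueError("fewer time columns than segments")
    rect = tfmap.rectified
    width = n_times // n_segments
    energies = np.empty(n_segments)
    for j in range(n_segments):
        lo = j * width
        hi = (j + 1) * width if j < n_segments - 1 else n_times
        energies[j] = rect[:, lo:hi].mean()
    return TfWindowFeatures(
        energies=energies,
        max_w=float(energies.max()),
        min_w=float(energies.min()),
        dif_w=float(energies.max() - energies.min()),
        std_w=float(energies.std(ddof=1)),
    )


def tf_band_features(tfmap: TfMap) -> dict[str, float]:
    """Band energies of the map over the VLF/LF/HF bands.

    ``e_<band>`` = total rectified energy in the band divided by the band
    width in Hz (0.037 / 0.11 / 0.25); ``f_<band>`` = mean rectified
    energy over the band's cells.
    """
    out: dict[str, float] = {}
    rect = tfmap.rectified
    for name, (lo, hi) in (("vlf", VLF_BAND), ("lf", LF_BAND), ("hf", HF_BAND)):
        if lo >= tfmap.freqs[-1]:
            raise ValueError(f"{name} band outside the frequency grid")
        mask = (tfmap.freqs >= lo) & (tfmap.freqs < hi)
        cells = rect[mask, :]
        out[f"e_{name}"] = float(cells.sum() / (hi - lo))
        out[f"f_{name}"] = float(cells.mean()) if cells.size else 0.0
    return out


def tf_first_derivative(
    window_energies: np.ndarray,
    prev_interval_last_energy: float | None = None,
    strategy: str = "mean_abs",
) -> float:
    """Scalar first-order-derivative feature of the segment energies.

    ``d_j = E_j - E_{j-1}``; the first window's derivative uses the last
    segment energy of the *preceding* one-minute interval when available,
    and is omitted otherwise.  The vector of derivatives is summarised to
    a scalar by the mean of absolute differences (default), or max/sum.
    """
    e = np.asarray(window_energies, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 window energies")
    d = np.diff(e)
    if prev_interval_last_energy is not None:
        d = np.concatenate([[e[0] - prev_interval_last_energy], d])
    else:
        logging.getLogger(__name__).debug(
            "no preceding-interval energy; first-window derivative omitted"
        )
    if strategy == "mean_abs":
        return float(np.mean(np.abs(d)))
    if strategy == "max_abs":
        return float(np.max(np.abs(d)))
    if strategy == "sum_abs":
        return float(np.sum(np.abs(d)))
    raise ValueError(f"unknown strategy {strategy!r}")
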