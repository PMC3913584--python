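"""Classical linear HRV features.

Time domain: MNN, SDNN, RMSSD, SDSD and pNN50 computed directly on the
RR-interval series.  Frequency domain: a Burg autoregressive power
spectrum of the uniformly resampled tachogram, integrated over the
standard VLF (0.003-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz)
bands, plus the LF/HF sympathovagal-balance ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg as _burg

from ..io import RrSeries
from ..qrs import UniformTachogram

__all__ = [
    "TimeDomainFeatures",
    "PsdEstimate",
    "BandPowers",
    "time_domain_features",
    "burg_psd",
    "band_powers",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
]

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass(frozen=True)
class TimeDomainFeatures:
    mnn: float  # ms
    sdnn: float  # ms
    rmssd: float  # ms
    sdsd: float  # ms
    pnn50: float  # percent


@dataclass(frozen=True)
class PsdEstimate:
    freqs: np.ndarray  # Hz, [0, rate/2]
    density: np.ndarray  # ms^2/Hz, one-sided
    model_order: int


@dataclass(frozen=True)
class BandPowers:
    vlf: float  # ms^2
    lf: float
    hf: float
    lf_hf: float


def time_domain_features(
    rr: RrSeries,
    population_sd: bool = False,
    pnn50_per_differences: bool = False,
) -> TimeDomainFeatures:
    """MNN, SDNN, RMSSD, SDSD and pNN50 of an RR series.

    SDNN/SDSD use the sample (N-1) convention by default.  pNN50's
    denominator is the number of RR *intervals* N by default (the stated
    definition), switchable to the number of successive differences N-1.
    """
    x = rr.rr
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 RR intervals")
    ddof = 0 if population_sd else 1
    d = np.diff(x)
    mnn = float(x.mean())
    sdnn = float(x.std(ddof=ddof))
    rmssd = float(np.sqrt(np.mean(d**2)))
    if d.size < 2:
        warnings.warn("only one successive difference; SDSD reported as 0")
        sdsd = 0.0
    else:
        sdsd = float(d.std(ddof=ddof))
    denom = d.size if pnn50_per_differences else n
    pnn50 = 100.0 * float(np.count_nonzero(np.abs(d) > 50.0)) / denom
    return TimeDomainFeatures(mnn=mnn, sdnn=sdnn, rmssd=rmssd, sdsd=sdsd, pnn50=pnn50)


def burg_psd(
    tach: UniformTachogram, order: int = 16, n_freq: int = 1024
) -> PsdEstimate:
    """One-sided Burg AR power spectral density of the tachogram.

    The AR coefficients come from the Burg reflection-coefficient
    recursion.  Pole radii are clamped to 0.999 before the transfer
    function is evaluated on an ``n_freq``-point grid over [0, rate/2] —
    without the clamp a noise-free sinusoid puts its poles numerically ON
    the unit circle and the sampled spectrum degenerates to grid-placement
    luck.  The density is scaled so its trapezoidal integral over
    [0, rate/2] equals the sample variance.  A non-finite fit triggers an
    order reduction by 2, at most three times.
    """
    x = np.asarray(tach.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("tachogram contains non-finite values")
    if x.size <= 2 * order:
        order = max(2, x.size // 2 - 1)
    freqs = np.linspace(0.0, tach.rate / 2.0, n_freq)
    if np.allclose(x, x[0]):
        warnings.warn("constant tachogram; returning zero PSD")
        return PsdEstimate(freqs=freqs, density=np.zeros(n_freq), model_order=order)
    # standardise before the recursion: the AR polynomial is scale-invariant
    # in exact arithmetic but not in floating point for near-singular fits.
    # A fixed-seed dither at 1e-6 relative SD (1e-12 in power) keeps the
    # recursion off the singular manifold of purely deterministic inputs.
    xc = (x - x.mean()) / x.std()
    xc = xc + 1e-6 * np.random.default_rng(0).standard_normal(xc.size)
    this_order = order
    for retry in range(4):
        this_order = max(2, order - 2 * retry)
        ar, sigma2 = _burg(xc, order=this_order)
        if np.all(np.isfinite(ar)) and np.isfinite(sigma2):
            break
    poles = np.roots(np.concatenate([[1.0], -ar]))
    radii = np.abs(poles)
    poles = np.where(radii > 0.999, poles / radii * 0.999, poles)
    a_coeffs = np.real(np.poly(poles))  # leading coefficient 1
    z = np.exp(-2j * np.pi * freqs / tach.rate)
    a_of_z = np.polynomial.polynomial.polyval(z, a_coeffs)
    density = 1.0 / np.abs(a_of_z) ** 2
    density *= x.var() / np.trapezoid(density, freqs)
    return PsdEstimate(freqs=freqs, density=density, model_order=this_order)


def band_powers(psd: PsdEstimate) -> BandPowers:
    """Trapezoidal band powers over VLF/LF/HF (half-open bands [lo, hi))."""

    def integrate(lo: float, hi: float) -> float:
        mask = (psd.freqs >= lo) & (psd.freqs < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd.density[mask], psd.freqs[mask]))

    vlf = integrate(*VLF_BAND)
    lf = integrate(*LF_BAND)
    hf = integrate(*HF_BAND)
    if hf > 0:
        lf_hf = lf / hf
    else:
        warnings.warn("zero HF power; LF/HF reported as +inf sentinel")
        lf_hf = np.inf
    return BandPowers(vlf=vlf, lf=lf, hf=hf, lf_hf=lf_hf)
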