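"""Assembly of the 13-feature combinational HRV vector.

Slots, in canonical order: Mean NN, SDNN, RMSSD, pNN50 (time domain);
VLF, HF, LF/HF (Burg spectrum); SD1, SD1/SD2, alpha(DFA) (nonlinear);
DIFw, STDw, Wdif (time-frequency).  Infinite ratio sentinels are clipped
to a large finite value so every vector entry is a number; the per-fold
scaler replaces clipped sentinels by the training-fold maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..io import FEATURE_NAMES, RrSeries
from ..qrs import UniformTachogram, resample_tachogram
from .linear import band_powers, burg_psd, time_domain_features
from .nonlinear import dfa_alpha, poincare_features
from .timefreq import (
    SpwvdConfig,
    TfMap,
    spwvd,
    tf_first_derivative,
    tf_window_features,
)

#: Finite stand-in for an infinite ratio (zero denominator upstream).
SENTINEL = 1.0e9


@dataclass(frozen=True)
class FeatureConfig:
    tachogram_rate: float = 4.0  # Hz
    burg_order: int = 16
    n_segments: int = 5
    spwvd: SpwvdConfig = SpwvdConfig()
    dfa_box_min: int = 4
    dfa_n_boxes: int = 16
    wdif_strategy: str = "mean_abs"


def _clip(value: float) -> float:
    if not np.isfinite(value):
        return SENTINEL if value > 0 else -SENTINEL
    return float(value)


def assemble_feature_vector(
    rr: RrSeries,
    tach: UniformTachogram,
    tfmap: TfMap,
    prev_interval_last_energy: float | None = None,
    cfg: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Map precomputed module outputs onto the 13 named feature slots."""
    features: dict[str, float] = {}
    try:
        td = time_domain_features(rr)
        features["mean_nn"] = td.mnn
        features["sdnn"] = td.sdnn
        features["rmssd"] = td.rmssd
        features["pnn50"] = td.pnn50
    except Exception as exc:
        raise type(exc)(f"time-domain features: {exc}") from exc
    try:
        bands = band_powers(burg_psd(tach, order=cfg.burg_order))
        features["vlf"] = bands.vlf
        features["hf"] = bands.hf
        features["lf_hf"] = _clip(bands.lf_hf)
    except Exception as exc:
        raise type(exc)(f"frequency-domain features: {exc}") from exc
    try:
        pc = poincare_features(rr)
        features["sd1"] = pc.sd1
        features["sd1_sd2"] = _clip(pc.ratio)
        features["alpha_dfa"] = dfa_alpha(
            rr, box_min=cfg.dfa_box_min, n_boxes=cfg.dfa_n_boxes
        ).alpha
    except Exception as exc:
        raise type(exc)(f"nonlinear features: {exc}") from exc
    try:
        wf = tf_window_features(tfmap, n_segments=cfg.n_segments)
        features["difw_tf"] = wf.dif_w
        features["stdw_tf"] = wf.std_w
        features["wdif_tf"] = tf_first_derivative(
            wf.energies, prev_interval_last_energy, strategy=cfg.wdif_strategy
        )
    except Exception as exc:
        raise type(exc)(f"time-frequency features: {exc}") from exc
    assert tuple(features) == FEATURE_NAMES
    return features


def extract_features(
    rr: RrSeries,
    prev_interval_last_energy: float | None = None,
    cfg: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Full 13-feature extraction straight from an RR series.

    Degenerate constant-RR input short-circuits to an all-zero variability
    vector (the spectral and TF stages are undefined on a zero-variance
    tachogram).
    """
    if np.allclose(rr.rr, rr.rr[0]):
        features = {name: 0.0 for name in FEATURE_NAMES}
        features["mean_nn"] = float(rr.rr.mean())
        return features
    tach = resample_tachogram(rr, rate=cfg.tachogram_rate)
    tfmap = spwvd(tach, cfg.spwvd)
    return assemble_feature_vector(
        rr, tach, tfmap, prev_interval_last_energy, cfg
    )
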