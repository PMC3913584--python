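import numpy as np
import pytest

from scdhrv.io import RrSeries
from scdhrv.pipeline import PipelineConfig, cohort_feature_table
from scdhrv.synthetic import RrModelSpec, generate_rr_series, synthesize_ecg


@pytest.fixture(scope="session")
def cohort_table():
    """Default two-class synthetic cohort (35/class, fixed seed)."""
    return cohort_feature_table(PipelineConfig(base_seed=1))


@pytest.fixture(scope="session")
def clean_ecg():
    """Clean 60-beat synthetic ECG at 256 Hz with a 0.5 s lead-in."""
    rr = generate_rr_series(RrModelSpec(mean_rr=800, sd_rr=40, n_beats=60, seed=7))
    rr = RrSeries.from_rr(rr.rr, t0=0.5)
    return synthesize_ecg(rr, fs=256.0)


def match_beats(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.010):
    """Greedy one-to-one matching; returns (sensitivity, ppv)."""
    if detected.size == 0:
        return 0.0, 0.0
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for tb in truth:
        d = np.abs(detected - tb)
        j = int(np.argmin(d))
        if d[j] <= tol_s and not used[j]:
            tp += 1
            used[j] = True
    return tp / truth.size, tp / detected.size
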