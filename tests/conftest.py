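import dataclasses

import numpy as np
import pytest

from eodkit.synth import EODPulseParams
from eodkit.waveform import DetectionConfig


@pytest.fixture
def noise_free_params() -> EODPulseParams:
    return dataclasses.replace(EODPulseParams(), noise_sd=0.0)


@pytest.fixture
def detection_cfg() -> DetectionConfig:
    return DetectionConfig()


def random_pulse_params(rng: np.random.Generator, noise_sd: float = 0.0) -> EODPulseParams:
    """A random valid biphasic pulse, retried until biphasic and contained."""
    from eodkit.synth import SynthError, compute_truth

    while True:
        t1 = rng.uniform(3.4, 4.0)
        p = EODPulseParams(
            a1=rng.uniform(0.30, 0.50),
            a2=rng.uniform(0.50, 0.70),
            t1=t1,
            t2=t1 + rng.uniform(0.20, 0.45),
            w1=rng.uniform(0.03, 0.08),
            w2=rng.uniform(0.03, 0.08),
            tau=rng.uniform(15.0, 40.0),
            noise_sd=noise_sd,
        )
        try:
            compute_truth(p)
            return p
        except SynthError:
            continue


def scan_bounds_oracle(w, cfg: DetectionConfig):
    """Exhaustive per-sample scan for the pulse bounds (loop-based oracle,
    independent of the vectorized implementation)."""
    v = w.values
    thr = cfg.threshold_frac * (v.max() - v.min())
    n = len(v)
    start = None
    for i in range(n - cfg.start_run + 1):
        if all(abs(v[i + k]) > thr for k in range(cfg.start_run)):
            start = i
            break
    imin = min(range(n), key=lambda i: v[i])
    end = None
    for j in range(imin + cfg.end_window - 1, n):
        if np.mean(v[j - cfg.end_window + 1 : j + 1]) > -thr:
            end = j
            break
    if start is None or end is None:
        raise AssertionError("oracle found no bounds")
    return float(w.time[start]), float(w.time[end])
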