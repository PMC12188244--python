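"""Pulse waveform preprocessing and feature extraction.

A recorded electric organ discharge (EOD) snippet is baseline-corrected,
normalized to unit peak-to-peak amplitude and aligned at its head-positive
maximum (vP1).  Repeated snippets are averaged sample-wise, and the seven
waveform parameters (EOD duration, P1/P2 durations, vP2/vP1, P1-P2 delay,
maximum P1 slope sP1 and the P2 decay constant tau) are measured on the
averaged trace.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit


class WaveformError(ValueError):
    """Raised when a trace cannot be preprocessed or measured."""


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds used to locate the pulse bounds on a normalized trace.

    baseline_window
        Number of samples at each end of a snippet pooled for baseline
        estimation.
    threshold_frac
        Detection threshold as a fraction of the peak-to-peak amplitude.
    start_run
        Number of consecutive supra-threshold samples required at onset.
    end_window
        Trailing window (in samples, inclusive of the current one) whose
        mean must exceed the negative threshold at the pulse end.
    """

    baseline_window: int = 512
    threshold_frac: float = 0.005
    start_run: int = 3
    end_window: int = 11

    def __post_init__(self) -> None:
        if self.baseline_window <= 0 or self.start_run <= 0 or self.end_window <= 0:
            raise ValueError("DetectionConfig windows must be positive")
        if not 0.0 < self.threshold_frac < 0.5:
            raise ValueError("threshold_frac must lie in (0, 0.5)")


@dataclass
class Recording:
    """A fixed-length sampled voltage snippet.

    Parameters
    ----------
    samples : array of voltages
    dt : sample interval in seconds
    meta : free-form metadata (fish id, treatment, day, ...)
    """

    samples: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def npts(self) -> int:
        return self.samples.size

    @property
    def dt_ms(self) -> float:
        return self.dt * 1e3


@dataclass
class AlignedWaveform:
    """Baseline-corrected, unit peak-to-peak, peak-aligned average trace."""

    values: np.ndarray
    time: np.ndarray  # milliseconds, 0 at the maximum sample
    n_averaged: int

    @property
    def dt_ms(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class Landmarks:
    """Key time/voltage landmarks of an aligned biphasic pulse (ms)."""

    t_vp1: float
    t_vp2: float
    v_vp1: float
    v_vp2: float
    t_zerocross: float
    t_start: Optional[float] = None
    t_end: Optional[float] = None


@dataclass
class DecayFit:
    """Exponential fit v(t) = a*exp(-tau*(t - t_vp2)) + b over the P2 tail."""

    a: float
    b: float
    tau: float
    rss: float
    converged: bool
    message: str = ""


@dataclass
class WaveformFeatures:
    eod_duration: float
    p1_duration: float
    p2_duration: float
    p1p2_delay: float
    vp2_vp1_ratio: float
    sp1: float
    tau: float
    vp1: float
    vp2: float

    FIELDS = (
        "eod_duration",
        "p1_duration",
        "p2_duration",
        "vp2_vp1_ratio",
        "p1p2_delay",
        "tau",
        "sp1",
        "vp1",
        "vp2",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def _normalize_snippet(samples: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    bw = cfg.baseline_window
    baseline = np.mean(np.concatenate([samples[:bw], samples[-bw:]]))
    v = samples - baseline
    span = v.max() - v.min()
    if span == 0:
        raise WaveformError("flat snippet: peak-to-peak amplitude is zero")
    return v / span


def preprocess(
    recordings: Iterable[Recording], cfg: DetectionConfig = DetectionConfig()
) -> AlignedWaveform:
    """Baseline-correct, normalize and peak-align snippets, then average.

    Each snippet has the pooled mean of its first and last
    ``cfg.baseline_window`` samples subtracted, is divided by its
    peak-to-peak amplitude and shifted so its maximum sits at time 0.
    Snippets are then averaged sample-wise over the overlapping aligned
    window and the average is re-normalized to peak-to-peak 1.
    """
    recs = list(recordings)
    if not recs:
        raise WaveformError("no recordings given")
    npts = recs[0].npts
    dt = recs[0].dt
    for r in recs:
        if r.npts != npts or not np.isclose(r.dt, dt):
            raise WaveformError("recordings must share npts and dt")
    if npts < 2 * cfg.baseline_window:
        raise WaveformError(
            f"snippet length {npts} shorter than 2*baseline_window "
            f"({2 * cfg.baseline_window})"
        )

    normed = [_normalize_snippet(r.samples, cfg) for r in recs]
    peaks = [int(np.argmax(v)) for v in normed]

    lo = -min(peaks)  # relative index range shared by all snippets
    hi = npts - 1 - max(peaks)
    if hi - lo + 1 < 2 * cfg.baseline_window:
        raise WaveformError(
            "alignment pushes the pulse outside the overlapping window"
        )
    rel = np.arange(lo, hi + 1)
    stacked = np.stack([v[p + lo : p + hi + 1] for v, p in zip(normed, peaks)])
    avg = stacked.mean(axis=0)

    span = avg.max() - avg.min()
    if span == 0:
        raise WaveformError("flat average trace")
    avg = avg / span
    j = int(np.argmax(avg))
    dt_ms = dt * 1e3
    time = (rel - rel[j]) * dt_ms
    return AlignedWaveform(values=avg, time=time, n_averaged=len(recs))


def find_landmarks(w: AlignedWaveform) -> Landmarks:
    """Locate vP1, vP2 and the interpolated P1->P2 zero crossing."""
    v = w.values
    i1 = int(np.argmax(v))
    i2 = int(np.argmin(v))
    if i2 <= i1:
        raise WaveformError("not a biphasic pulse: minimum precedes maximum")
    if v[i2] >= 0:
        raise WaveformError("not a biphasic pulse: no negative phase")
    if v[i1] <= 0:
        raise WaveformError("not a biphasic pulse: no positive phase")

    # first sign change scanning from the maximum toward the minimum
    seg = v[i1 : i2 + 1]
    below = np.nonzero(seg <= 0)[0]
    if below.size == 0:
        raise WaveformError("no zero crossing between maximum and minimum")
    k = i1 + below[0] - 1  # v[k] > 0 >= v[k+1]
    t0, t1 = w.time[k], w.time[k + 1]
    y0, y1 = v[k], v[k + 1]
    t_zero = t0 + y0 * (t1 - t0) / (y0 - y1)

    return Landmarks(
        t_vp1=float(w.time[i1]),
        t_vp2=float(w.time[i2]),
        v_vp1=float(v[i1]),
        v_vp2=float(v[i2]),
        t_zerocross=float(t_zero),
    )


def detect_bounds(
    w: AlignedWaveform, cfg: DetectionConfig = DetectionConfig()
) -> tuple[float, float]:
    """Threshold-crossing pulse bounds on the aligned trace.

    Start: the first sample of the first ``start_run`` consecutive samples
    whose absolute voltage exceeds ``threshold_frac`` of the peak-to-peak
    amplitude.  End: scanning forward from the vP2 sample, the first sample
    at which the mean of the trailing ``end_window`` samples (inclusive)
    exceeds the negative threshold.
    """
    v = w.values
    thr = cfg.threshold_frac * (v.max() - v.min())

    above = np.abs(v) > thr
    run = cfg.start_run
    ok = np.convolve(above.astype(int), np.ones(run, dtype=int), mode="valid") == run
    starts = np.nonzero(ok)[0]
    if starts.size == 0:
        raise WaveformError("no qualifying start run found")
    i_start = int(starts[0])

    i_min = int(np.argmin(v))
    win = cfg.end_window
    j0 = i_min + win - 1
    if j0 >= v.size:
        raise WaveformError("end condition never met before trace end")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    j_candidates = np.arange(j0, v.size)
    means = (csum[j_candidates + 1] - csum[j_candidates + 1 - win]) / win
    hits = np.nonzero(means > -thr)[0]
    if hits.size == 0:
        raise WaveformError("end condition never met before trace end")
    i_end = int(j_candidates[hits[0]])

    return float(w.time[i_start]), float(w.time[i_end])


def fit_p2_decay(w: AlignedWaveform, lm: Landmarks) -> DecayFit:
    """Least-squares exponential fit to the voltages between vP2 and the
    pulse end, with the time origin at vP2.

    Initialization comes from a log-linear regression assuming b = 0.  On
    optimizer failure the initial estimate is returned with
    ``converged=False`` rather than raising.
    """
    if lm.t_end is None:
        raise WaveformError("landmarks must carry t_end (run detect_bounds first)")
    # strictly after vP2: the discrete minimum can sit marginally before the
    # true turning point, and that sample is not part of the decay
    mask = (w.time > lm.t_vp2) & (w.time <= lm.t_end)
    t = w.time[mask] - lm.t_vp2
    y = w.values[mask]
    if t.size < 4:
        raise WaveformError("fewer than 4 samples between vP2 and pulse end")

    neg = y < 0
    if neg.sum() >= 2:
        slope, intercept = np.polyfit(t[neg], np.log(-y[neg]), 1)
        tau0 = max(-slope, 1e-6)
        a0 = -np.exp(intercept)
    else:  # pragma: no cover - degenerate tail
        tau0, a0 = 1.0, float(y[0])

    def model(tt, a, tau, b):
        return a * np.exp(-tau * tt) + b

    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, tau0, 0.0), maxfev=5000)
        a, tau, b = (float(x) for x in popt)
        rss = float(np.sum((model(t, *popt) - y) ** 2))
        if tau <= 0:
            return DecayFit(a, b, tau, rss, False, "non-positive rate constant")
        return DecayFit(a, b, tau, rss, True)
    except RuntimeError as exc:
        rss = float(np.sum((model(t, a0, tau0, 0.0) - y) ** 2))
        return DecayFit(float(a0), 0.0, float(tau0), rss, False, str(exc))


def extract_features(
    w: AlignedWaveform, cfg: DetectionConfig = DetectionConfig()
) -> WaveformFeatures:
    """Measure the seven waveform parameters on an aligned average trace."""
    lm = find_landmarks(w)
    t_start, t_end = detect_bounds(w, cfg)
    lm.t_start, lm.t_end = t_start, t_end
    fit = fit_p2_decay(w, lm)

    dv = np.gradient(w.values, w.time)  # central differences, per ms
    rise = (w.time >= t_start) & (w.time <= lm.t_vp1)
    if not rise.any():
        raise WaveformError("no samples on the rising P1 segment")
    sp1 = float(dv[rise].max())

    return WaveformFeatures(
        eod_duration=t_end - t_start,
        p1_duration=lm.t_zerocross - t_start,
        p2_duration=t_end - lm.t_zerocross,
        p1p2_delay=lm.t_vp2 - lm.t_vp1,
        vp2_vp1_ratio=lm.v_vp2 / lm.v_vp1,
        sp1=sp1,
        tau=fit.tau,
        vp1=lm.v_vp1,
        vp2=lm.v_vp2,
    )


def features_from_recordings(
    recordings: Sequence[Recording], cfg: DetectionConfig = DetectionConfig()
) -> WaveformFeatures:
    """Convenience: preprocess a session's snippets and extract features."""
    return extract_features(preprocess(recordings, cfg), cfg)
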