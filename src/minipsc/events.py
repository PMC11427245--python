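"""Candidate event windows, Pearson screening values, and the feature vector.

Each candidate is cut out of the recording as a baseline-subtracted window
spanning 1 ms before the detected onset to one template duration after it.
Two quantities feed the two classification routes:

* the Pearson product-moment correlation of the post-onset window against
  the template kernel (simple threshold screening), and
* a fixed 10-element feature vector (random-forest classification) spanning
  amplitude, kinetics, shape match and noise context. The feature order is
  versioned inside model files so a model is only ever applied to the
  feature set it was trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import pearsonr, skew

from .detection import Candidate
from .template import Template
from .trace_io import Trace

__all__ = [
    "Event",
    "FEATURE_NAMES",
    "extract_event",
    "pearson_vs_template",
    "compute_features",
]

#: Fixed, versioned feature order. Models record this list and refuse to
#: classify events computed under a different version.
FEATURE_NAMES: tuple = (
    "peak_amplitude",
    "rise_time_10_90_ms",
    "half_width_ms",
    "decay_tau_ms",
    "area_pA_ms",
    "pearson_r",
    "baseline_sd",
    "time_to_peak_ms",
    "skewness",
    "detector_peak",
)

PRE_ONSET_S = 1e-3  # window head used for the baseline estimate
FALLBACK_BASELINE_S = 0.25e-3  # head used when the onset sits at sample 0


@dataclass
class Event:
    """A candidate event extracted from a trace."""

    onset_index: int
    fs: float
    window: np.ndarray  # baseline-subtracted, starts pre_samples before onset
    baseline: float
    pre_samples: int  # samples of the window preceding the onset
    detector_peak: float = 0.0
    pearson_r: Optional[float] = None
    features: Optional[np.ndarray] = None
    label: Optional[bool] = None
    truncated: bool = False

    @property
    def onset_time(self) -> float:
        return self.onset_index / self.fs

    def post_onset(self) -> np.ndarray:
        return self.window[self.pre_samples:]


def extract_event(trace: Trace, candidate: Candidate, template: Template) -> Event:
    """Cut the candidate's window out of the trace and subtract baseline.

    The window spans [onset - 1 ms, onset + template duration); the baseline
    is the mean of the 1 ms pre-onset segment. At the trace edges the window
    is truncated and flagged; with no pre-onset samples at all, the baseline
    falls back to the first 0.25 ms after onset.
    """
    onset = candidate.onset_index
    if not 0 <= onset < trace.n:
        raise ValueError(f"candidate onset {onset} outside trace")
    pre_want = int(round(PRE_ONSET_S * trace.fs))
    start = onset - pre_want
    truncated = False
    if start < 0:
        start = 0
        truncated = True
    end = onset + template.n
    if end > trace.n:
        end = trace.n
        truncated = True
    raw = trace.samples[start:end]
    pre = onset - start
    if pre > 0:
        baseline = float(np.mean(raw[:pre]))
    else:
        nfall = max(int(round(FALLBACK_BASELINE_S * trace.fs)), 1)
        baseline = float(np.mean(raw[:nfall]))
    return Event(onset_index=onset, fs=trace.fs, window=raw - baseline,
                 baseline=baseline, pre_samples=pre,
                 detector_peak=candidate.detector_peak, truncated=truncated)


def pearson_vs_template(event: Event, template: Template) -> float:
    """Pearson r of the post-onset window against the kernel (truncating the
    longer of the two). Sets ``event.pearson_r``. Raises on zero-variance
    windows."""
    w = event.post_onset()
    m = min(w.size, template.n)
    w = w[:m]
    k = template.kernel[:m]
    if np.ptp(w) == 0 or np.ptp(k) == 0:
        raise ValueError("zero-variance window: Pearson r undefined")
    r = float(pearsonr(w, k).statistic)
    event.pearson_r = r
    return r


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     rising: bool) -> Optional[float]:
    """First time y crosses ``level`` (linearly interpolated)."""
    if rising:
        hits = np.nonzero((y[:-1] < level) & (y[1:] >= level))[0]
    else:
        hits = np.nonzero((y[:-1] >= level) & (y[1:] < level))[0]
    if hits.size == 0:
        return None
    i = hits[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _decay_tau(t_ms: np.ndarray, y: np.ndarray, amp: float) -> float:
    """Decay time constant of the post-peak segment: exponential fit
    initialized from the 1/e crossing, falling back to that crossing."""
    t_e = _interp_crossing(t_ms, y, amp / np.e, rising=False)
    tau0 = t_e if t_e is not None else max(t_ms[-1], 1e-3)
    if y.size < 4:
        return float(tau0)
    try:
        with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(lambda t, a, tau: a * np.exp(-t / tau), t_ms, y,
                                p0=[amp, tau0], maxfev=500)
        tau = float(popt[1])
        if 0 < tau < 100 * tau0:
            return tau
    except RuntimeError:
        pass
    return float(tau0)


def compute_features(event: Event, template: Template,
                     detector_peak: Optional[float] = None) -> np.ndarray:
    """The 10-element feature vector in :data:`FEATURE_NAMES` order.

    Kinetic features use linear interpolation between samples; the decay time
    constant comes from an exponential fit of the post-peak segment. Sets
    ``event.features``.
    """
    if not np.all(np.isfinite(event.window)):
        raise ValueError("NaN/inf in event window")
    post = event.post_onset()
    if post.size < 3:
        raise ValueError("window too short for feature computation")
    t_ms = np.arange(post.size) / event.fs * 1000.0
    ipk = int(np.argmax(post))
    amp = float(post[ipk])
    time_to_peak = float(t_ms[ipk])

    rise_seg_t, rise_seg_y = t_ms[: ipk + 1], post[: ipk + 1]
    t10 = _interp_crossing(rise_seg_t, rise_seg_y, 0.1 * amp, rising=True)
    t90 = _interp_crossing(rise_seg_t, rise_seg_y, 0.9 * amp, rising=True)
    rise_10_90 = (t90 - t10) if (t10 is not None and t90 is not None) else time_to_peak

    half = 0.5 * amp
    t_half_up = _interp_crossing(rise_seg_t, rise_seg_y, half, rising=True)
    t_half_down = _interp_crossing(t_ms[ipk:], post[ipk:], half, rising=False)
    if t_half_up is not None and t_half_down is not None:
        half_width = t_half_down - t_half_up
    else:
        half_width = t_ms[-1] - (t_half_up if t_half_up is not None else 0.0)

    tau_decay = _decay_tau(t_ms[ipk:] - t_ms[ipk], post[ipk:], amp)
    area = float(np.trapezoid(post, dx=1000.0 / event.fs))  # pA*ms

    if event.pearson_r is None:
        pearson_vs_template(event, template)
    pre = event.window[: event.pre_samples]
    baseline_sd = float(np.std(pre)) if pre.size > 1 else 0.0
    skewness = float(skew(event.window)) if np.ptp(event.window) > 0 else 0.0
    dpk = detector_peak if detector_peak is not None else event.detector_peak

    feats = np.array([amp, rise_10_90, half_width, tau_decay, area,
                      event.pearson_r, baseline_sd, time_to_peak,
                      skewness, dpk], dtype=float)
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite feature computed")
    event.features = feats
    return feats
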