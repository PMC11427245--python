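"""The synaptic event template: a peak-scaled difference of two exponentials.

The canonical postsynaptic-current waveform is modelled as

    f(t) = s * (exp(-t / tau_decay) - exp(-t / tau_rise)),   t >= 0,

with 0 < tau_rise < tau_decay and the scale ``s`` chosen so that the peak is
exactly 1 (Roth & van Rossum parameterization). Peak scaling makes the
multiplying coefficient of the kernel the event's peak amplitude. The peak
occurs at

    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise)
             * ln(tau_decay / tau_rise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = ["Template", "build_kernel", "fit_template", "peak_time", "TemplateFit"]


def peak_time(tau_rise: float, tau_decay: float) -> float:
    """Analytic time of the kernel peak (same units as the time constants)."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def _biexp(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unscaled difference of exponentials, zero for t < 0."""
    out = np.where(
        t_ms >= 0,
        np.exp(-np.clip(t_ms, 0, None) / tau_decay)
        - np.exp(-np.clip(t_ms, 0, None) / tau_rise),
        0.0,
    )
    return out


@dataclass
class Template:
    """Event kernel with its defining constants.

    ``kernel`` is unitless with maximum exactly 1 and ``kernel[0] = 0``
    (event onset at sample 0).
    """

    tau_rise: float  # ms
    tau_decay: float  # ms
    fs: float  # Hz
    kernel: np.ndarray
    duration_ms: float

    @property
    def t_peak_ms(self) -> float:
        return peak_time(self.tau_rise, self.tau_decay)

    @property
    def n(self) -> int:
        return self.kernel.size

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"tau_rise_ms": self.tau_rise, "tau_decay_ms": self.tau_decay,
                       "fs_hz": self.fs, "duration_ms": self.duration_ms}, fh)

    @classmethod
    def from_json(cls, path) -> "Template":
        with open(path) as fh:
            meta = json.load(fh)
        return build_kernel(meta["tau_rise_ms"], meta["tau_decay_ms"],
                            meta["fs_hz"], meta["duration_ms"])


def build_kernel(tau_rise: float, tau_decay: float, fs: float,
                 duration_ms: Optional[float] = None) -> Template:
    """Construct the peak-scaled biexponential kernel sampled at ``fs``.

    The default duration of 8 * tau_decay truncates less than 0.04% of the
    kernel's tail.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be strictly less than tau_decay")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration_ms is None:
        duration_ms = 8.0 * tau_decay
    n = max(int(round(duration_ms * fs / 1000.0)), 2)
    t_ms = np.arange(n) / fs * 1000.0
    kern = _biexp(t_ms, tau_rise, tau_decay)
    kern /= kern.max()
    return Template(tau_rise=float(tau_rise), tau_decay=float(tau_decay),
                    fs=float(fs), kernel=kern, duration_ms=float(duration_ms))


class TemplateFit(NamedTuple):
    tau_rise: float  # ms
    tau_decay: float  # ms
    amplitude: float  # signal units (pA)
    baseline: float  # signal units (pA)
    onset_s: float  # s, within the original trace
    cost: float


def fit_template(trace, window: tuple[float, float]) -> TemplateFit:
    """Fit ``baseline + A * peak-scaled-kernel(t - t0; tau_r, tau_d)`` to an
    exemplar event inside ``window`` (seconds) by trust-region least squares.

    The onset offset ``t0`` is a free parameter. Initialization: baseline from
    the pre-peak head of the window, amplitude from the peak deflection,
    tau_decay from the time from peak to 1/e decay, tau_rise as a tenth of the
    onset-to-peak rise span. Raises on windows shorter than 10 samples and on
    flat windows / non-convergence.
    """
    start, end = window
    i0 = max(int(round(start * trace.fs)), 0)
    i1 = min(int(round(end * trace.fs)), trace.n)
    seg = trace.samples[i0:i1]
    if seg.size < 10:
        raise ValueError("fit window shorter than 10 samples")
    t_ms = np.arange(seg.size) / trace.fs * 1000.0

    head = seg[: max(seg.size // 10, 2)]
    baseline0 = float(np.mean(head))
    dev = seg - baseline0
    # polarity: fit the dominant deflection
    sign = 1.0 if abs(dev.max()) >= abs(dev.min()) else -1.0
    y = sign * dev
    amp0 = float(y.max())
    if amp0 <= 0 or np.ptp(seg) < 1e-12:
        raise RuntimeError("fit_template: no deflection in window (flat trace?)")
    ipk = int(np.argmax(y))
    # onset guess: last sample before the peak below 10% of the peak
    pre = np.nonzero(y[:ipk] < 0.1 * amp0)[0]
    i_on = int(pre[-1]) if pre.size else 0
    t0_0 = t_ms[i_on]
    rise_span = max(t_ms[ipk] - t0_0, 2000.0 / trace.fs)
    tau_r0 = 0.1 * rise_span
    post = np.nonzero(y[ipk:] < amp0 / math.e)[0]
    tau_d0 = float(post[0]) / trace.fs * 1000.0 if post.size else (t_ms[-1] - t_ms[ipk])
    tau_d0 = max(tau_d0, tau_r0 * 2.0)

    def unpack(p):
        b, a, t0, log_tr, log_dd = p
        tr = math.exp(log_tr)
        td = tr + math.exp(log_dd)  # enforces tau_d > tau_r
        return b, a, t0, tr, td

    def model(p):
        b, a, t0, tr, td = unpack(p)
        kern = _biexp(t_ms - t0, tr, td)
        peak = _biexp(np.array([peak_time(tr, td)]), tr, td)[0]
        return b + a * kern / peak

    def resid(p):
        return model(p) - y

    p0 = np.array([0.0, amp0, t0_0, math.log(tau_r0), math.log(max(tau_d0 - tau_r0, 1e-3))])
    sol = least_squares(resid, p0, method="trf", x_scale="jac", max_nfev=2000)
    if not sol.success:
        raise RuntimeError("fit_template did not converge")
    b, a, t0, tr, td = unpack(sol.x)
    if a <= 0:
        raise RuntimeError("fit_template converged to a non-positive amplitude")
    return TemplateFit(
        tau_rise=tr,
        tau_decay=td,
        amplitude=sign * a,
        baseline=baseline0 + sign * b,
        onset_s=i0 / trace.fs + t0 / 1000.0,
        cost=float(sol.cost),
    )
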