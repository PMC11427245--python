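"""Reading, writing, splitting and masking of single-channel recordings.

A recording is represented by :class:`Trace`: a uniformly sampled vector of
current (pA) or fluorescence (a.u.) samples with a sampling rate, optional
half-open exclusion intervals (regions to be ignored by downstream analysis,
e.g. test pulses), and a provenance string.

Supported on-disk formats
-------------------------
``csv`` / ``tsv``
    Waves in columns, optional single header row.
``raw16``
    Little-endian int16 samples plus a JSON sidecar ``<file>.json`` holding
    ``{"fs_hz": ..., "scale": ..., "offset": ..., "units": ...}``; samples are
    reconstructed as ``value * scale + offset``.
``hdf5``
    Datasets ``/waves/000``, ``/waves/001``, ... with file attributes
    ``fs_hz`` and ``units``.

All sample indexing is 0-based and time intervals are half-open
``[start, end)`` in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "EventTable",
    "read_trace",
    "write_trace",
    "split_trace",
    "apply_exclusions",
]


def _normalize_intervals(
    intervals: Sequence[tuple[float, float]], duration: float
) -> list[tuple[float, float]]:
    """Validate, sort and merge half-open intervals within [0, duration)."""
    out: list[tuple[float, float]] = []
    for start, end in intervals:
        start, end = float(start), float(end)
        if not start < end:
            raise ValueError(f"inverted or empty interval ({start}, {end})")
        if start < 0 or end > duration + 1e-12:
            raise ValueError(
                f"interval ({start}, {end}) outside trace bounds [0, {duration})"
            )
        out.append((start, min(end, duration)))
    out.sort()
    merged: list[tuple[float, float]] = []
    for start, end in out:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class Trace:
    """A uniformly sampled single-channel recording.

    Parameters
    ----------
    samples : ndarray
        Signal samples (pA or a.u.); must be finite.
    fs : float
        Sampling rate in Hz; must be positive.
    units : str
        Physical units of the samples.
    excluded : list of (float, float)
        Half-open intervals ``[start, end)`` in seconds to be ignored by
        downstream candidate detection and noise estimation.
    source : str
        Provenance (file path, simulation spec, ...).
    remainder : bool
        True when this trace is the leftover tail of a split that did not
        divide the parent record evenly.
    """

    samples: np.ndarray
    fs: float
    units: str = "pA"
    excluded: list = field(default_factory=list)
    source: str = ""
    remainder: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        self.fs = float(self.fs)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.excluded = _normalize_intervals(self.excluded, self.duration)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs

    def is_excluded(self, t: float | np.ndarray) -> np.ndarray:
        """Boolean mask: does time ``t`` (s) fall in an excluded interval?"""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        mask = np.zeros(t.shape, dtype=bool)
        for start, end in self.excluded:
            mask |= (t >= start) & (t < end)
        return mask

    def sample_mask(self) -> np.ndarray:
        """Boolean mask over samples, True where the sample is excluded."""
        return self.is_excluded(self.times())


@dataclass
class EventTable:
    """Carrier for ground-truth or detected event lists.

    ``onset_times`` is sorted ascending; the optional per-event columns
    (amplitudes in pA, kinetics in ms, boolean labels) must match its length.
    """

    onset_times: np.ndarray
    amplitudes: Optional[np.ndarray] = None
    tau_rise: Optional[np.ndarray] = None
    tau_decay: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if np.any(np.diff(self.onset_times) < 0):
            order = np.argsort(self.onset_times, kind="stable")
            self.onset_times = self.onset_times[order]
            for name in ("amplitudes", "tau_rise", "tau_decay", "labels"):
                col = getattr(self, name)
                if col is not None:
                    setattr(self, name, np.asarray(col)[order])
        for name in ("amplitudes", "tau_rise", "tau_decay", "labels"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col)
                if col.shape != self.onset_times.shape:
                    raise ValueError(f"column {name} length mismatch")
                setattr(self, name, col)

    def __len__(self) -> int:
        return self.onset_times.size

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"onset_time_s": self.onset_times}
        if self.amplitudes is not None:
            data["amplitude_pA"] = self.amplitudes
        if self.tau_rise is not None:
            data["tau_rise_ms"] = self.tau_rise
        if self.tau_decay is not None:
            data["tau_decay_ms"] = self.tau_decay
        if self.labels is not None:
            data["label"] = self.labels.astype(bool)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        df = pd.read_csv(path)
        return cls(
            onset_times=df["onset_time_s"].to_numpy(),
            amplitudes=df["amplitude_pA"].to_numpy() if "amplitude_pA" in df else None,
            tau_rise=df["tau_rise_ms"].to_numpy() if "tau_rise_ms" in df else None,
            tau_decay=df["tau_decay_ms"].to_numpy() if "tau_decay_ms" in df else None,
            labels=df["label"].astype(bool).to_numpy() if "label" in df else None,
        )


_EXTENSION_MAP = {
    ".csv": "csv",
    ".tsv": "tsv",
    ".txt": "tsv",
    ".dat": "raw16",
    ".bin": "raw16",
    ".h5": "hdf5",
    ".hdf5": "hdf5",
}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in {"csv", "tsv", "raw16", "hdf5"}:
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    ext = path.suffix.lower()
    if ext not in _EXTENSION_MAP:
        raise ValueError(f"cannot infer format from extension {ext!r}")
    return _EXTENSION_MAP[ext]


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _read_delimited(path: Path, sep: str, fs: Optional[float], units: str) -> list[Trace]:
    if fs is None:
        raise ValueError("fs must be given when reading csv/tsv (no metadata row)")
    # header detection: if every token of the first row parses as a number,
    # treat the file as headerless
    with open(path) as fh:
        first = fh.readline()
    tokens = [tok.strip() for tok in first.strip().split(sep)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if not all(_numeric(t) for t in tokens if t != "") else None
    df = pd.read_csv(path, sep=sep, header=header)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"non-numeric cells in {path}")
    return [
        Trace(df[col].to_numpy(dtype=float), fs=fs, units=units,
              source=f"{path}#{i}")
        for i, col in enumerate(df.columns)
    ]


def read_trace(path, format: str = "auto", fs: Optional[float] = None,
               units: str = "pA") -> list[Trace]:
    """Read a recording file, returning one :class:`Trace` per wave.

    ``fs``/``units`` are required for csv/tsv (these formats carry no
    metadata); raw16 and hdf5 read them from the sidecar/file attributes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "csv":
        return _read_delimited(path, ",", fs, units)
    if fmt == "tsv":
        return _read_delimited(path, "\t", fs, units)
    if fmt == "raw16":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing raw16 sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        for key in ("fs_hz", "scale", "offset"):
            if key not in meta:
                raise ValueError(f"raw16 sidecar missing key {key!r}")
        raw = np.fromfile(path, dtype="<i2").astype(float)
        samples = raw * float(meta["scale"]) + float(meta["offset"])
        return [Trace(samples, fs=float(meta["fs_hz"]),
                      units=meta.get("units", units), source=str(path))]
    # hdf5
    traces = []
    with h5py.File(path, "r") as fh:
        fs_file = float(fh.attrs["fs_hz"])
        units_file = str(fh.attrs.get("units", units))
        for name in sorted(fh["waves"]):
            traces.append(Trace(fh["waves"][name][...], fs=fs_file,
                                units=units_file, source=f"{path}#{name}"))
    return traces


def write_trace(traces: Trace | Sequence[Trace], path, format: str = "auto") -> None:
    """Write one or more waves; ``read_trace`` of the result reproduces the
    samples (exactly for raw-binary/HDF5, to formatting precision for text)."""
    if isinstance(traces, Trace):
        traces = [traces]
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt in ("csv", "tsv"):
        lengths = {t.n for t in traces}
        if len(lengths) > 1:
            raise ValueError("csv/tsv columns must have equal length")
        df = pd.DataFrame({f"wave{i:03d}": t.samples for i, t in enumerate(traces)})
        df.to_csv(path, sep="," if fmt == "csv" else "\t", index=False,
                  float_format="%.10g")
    elif fmt == "raw16":
        if len(traces) != 1:
            raise ValueError("raw16 holds a single wave")
        t = traces[0]
        lo, hi = float(t.samples.min()), float(t.samples.max())
        offset = (hi + lo) / 2.0
        scale = max(hi - lo, 1e-12) / 65000.0
        ints = np.round((t.samples - offset) / scale).astype("<i2")
        ints.tofile(path)
        _sidecar_path(path).write_text(json.dumps(
            {"fs_hz": t.fs, "scale": scale, "offset": offset, "units": t.units}))
    else:  # hdf5
        with h5py.File(path, "w") as fh:
            fh.attrs["fs_hz"] = traces[0].fs
            fh.attrs["units"] = traces[0].units
            grp = fh.create_group("waves")
            for i, t in enumerate(traces):
                if t.fs != traces[0].fs:
                    raise ValueError("all waves in one hdf5 file share fs")
                grp.create_dataset(f"{i:03d}", data=t.samples)


def split_trace(trace: Trace, epoch_s: float) -> list[Trace]:
    """Split into floor(duration/epoch_s) equal epochs.

    A non-dividing tail is kept as a shorter final wave with
    ``remainder=True`` rather than silently discarded. Concatenating the
    returned sample vectors reproduces the original trace exactly.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    if epoch_s > trace.duration + 1e-12:
        raise ValueError("epoch_s longer than the trace")
    step = int(round(epoch_s * trace.fs))
    n_full = trace.n // step
    out = []
    for i in range(n_full):
        out.append(Trace(trace.samples[i * step:(i + 1) * step], fs=trace.fs,
                         units=trace.units, source=f"{trace.source}#epoch{i}"))
    rem = trace.n - n_full * step
    if rem > 0:
        out.append(Trace(trace.samples[n_full * step:], fs=trace.fs,
                         units=trace.units, source=f"{trace.source}#remainder",
                         remainder=True))
    return out


def apply_exclusions(trace: Trace, intervals: Sequence[tuple[float, float]]) -> Trace:
    """Return a copy of ``trace`` with the intervals added to its exclusion
    mask. Samples are untouched; downstream detection drops candidates whose
    onset falls inside a masked interval, and noise estimation skips masked
    samples."""
    merged = list(trace.excluded) + [tuple(iv) for iv in intervals]
    return replace(trace, excluded=merged)
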