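"""End-to-end analysis runs: detect/screen/classify over waves, training
runs, and a machine-readable settings echo for exact replay.

``run_detect`` executes the full per-wave chain (kernel construction, FFT
deconvolution, noise estimation, thresholding, window extraction, Pearson
correlation, features, and the chosen event criterion) and writes one event
CSV per wave, an ensemble-average waveform CSV, a summary metrics JSON and a
settings echo. ``run_train`` detects candidates, labels them from a labels
CSV or a ground-truth reference table, trains one random forest and writes a
``.evtm`` model file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import Model, classify, load_model, save_model, screen_pearson, train_forest
from .detection import deconvolve, estimate_noise_sd, find_candidates
from .events import FEATURE_NAMES, compute_features, extract_event, pearson_vs_template
from .evaluate import DEFAULT_TOL_S, match_events
from .template import build_kernel
from .trace_io import EventTable, Trace, apply_exclusions, read_trace, split_trace

__all__ = ["RunConfig", "WaveResult", "run_detect", "run_train", "detect_wave"]


@dataclass
class RunConfig:
    """Settings of one analysis run; serialized verbatim into the settings
    echo so a run can be replayed bit-identically."""

    tau_rise: float = 0.44  # ms
    tau_decay: float = 6.12  # ms
    band: tuple = (1.0, 200.0)  # detector band-pass, Hz
    threshold_mode: str = "sd_multiple"
    threshold_k: float = 3.0
    criterion: str = "pearson"  # 'pearson' | 'model' | 'train' | 'none'
    r_threshold: float = 0.5
    model_path: Optional[str] = None
    epoch_s: Optional[float] = None  # split duration, None = no split
    exclusions: list = field(default_factory=list)
    fs: Optional[float] = None  # needed for csv/tsv inputs
    outdir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in ("pearson", "model", "train", "none"):
            raise ValueError(f"unknown criterion {self.criterion!r}")

    def echo(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["version"] = __version__
        d["feature_names"] = list(FEATURE_NAMES)
        return d


@dataclass
class WaveResult:
    wave_index: int
    events: list  # Event objects, features populated
    accepted: np.ndarray  # boolean per event
    sigma: float
    n_candidates: int


def _load_waves(config: RunConfig, paths: Sequence) -> list[Trace]:
    waves: list[Trace] = []
    for path in paths:
        for trace in read_trace(path, fs=config.fs):
            if config.exclusions:
                trace = apply_exclusions(trace, config.exclusions)
            if config.epoch_s:
                waves.extend(split_trace(trace, config.epoch_s))
            else:
                waves.append(trace)
    return waves


def detect_wave(trace: Trace, config: RunConfig) -> WaveResult:
    """Run the detection chain on one wave; the returned events carry
    Pearson r and the full feature vector, with no criterion applied yet."""
    template = build_kernel(config.tau_rise, config.tau_decay, trace.fs)
    detector = deconvolve(trace, template, band=tuple(config.band))
    sigma = estimate_noise_sd(detector)
    candidates = find_candidates(detector, mode=config.threshold_mode,
                                 k=config.threshold_k)
    events = []
    for cand in candidates:
        event = extract_event(trace, cand, template)
        try:
            pearson_vs_template(event, template)
            compute_features(event, template)
        except ValueError:
            continue  # zero-variance / degenerate window: not a usable candidate
        events.append(event)
    return WaveResult(wave_index=0, events=events,
                      accepted=np.ones(len(events), dtype=bool),
                      sigma=sigma, n_candidates=len(candidates))


def _apply_criterion(result: WaveResult, config: RunConfig,
                     model: Optional[Model]) -> None:
    if config.criterion == "pearson":
        accepted, _ = screen_pearson(result.events, config.r_threshold)
        acc_ids = {id(e) for e in accepted}
        result.accepted = np.array([id(e) in acc_ids for e in result.events], dtype=bool)
    elif config.criterion == "model":
        result.accepted = classify(result.events, model) if result.events else np.array([], dtype=bool)
    else:  # 'none': keep everything
        result.accepted = np.ones(len(result.events), dtype=bool)


def _events_frame(result: WaveResult) -> pd.DataFrame:
    rows = []
    for e, acc in zip(result.events, result.accepted):
        row = {"onset_time_s": e.onset_time, "detector_peak": e.detector_peak,
               "pearson_r": e.pearson_r, "accepted": bool(acc)}
        row.update({name: val for name, val in zip(FEATURE_NAMES, e.features)})
        rows.append(row)
    cols = ["onset_time_s", "detector_peak", "pearson_r", "accepted", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def run_detect(config: RunConfig, paths: Sequence) -> list[WaveResult]:
    """Detect and screen/classify events in every wave of the input files;
    writes per-wave event CSVs, an ensemble-average CSV, a metrics JSON and
    a settings echo under ``config.outdir``."""
    model = None
    if config.criterion == "model":
        if config.model_path is None or not Path(config.model_path).exists():
            raise FileNotFoundError(f"model file {config.model_path!r} not found")
        model = load_model(config.model_path)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    waves = _load_waves(config, paths)
    results = []
    metrics: dict = {"waves": []}
    ensemble: list[np.ndarray] = []
    for i, trace in enumerate(waves):
        try:
            result = detect_wave(trace, config)
        except Exception as exc:
            raise RuntimeError(f"wave {i}: {exc}") from exc
        result.wave_index = i
        _apply_criterion(result, config, model)
        results.append(result)
        _events_frame(result).to_csv(outdir / f"wave{i:03d}_events.csv", index=False)
        for e, acc in zip(result.events, result.accepted):
            if acc:
                ensemble.append(e.post_onset())
        metrics["waves"].append({
            "wave": i,
            "n_candidates": result.n_candidates,
            "n_accepted": int(result.accepted.sum()),
            "detector_sigma": result.sigma,
        })
    if ensemble:
        m = min(w.size for w in ensemble)
        avg = np.mean([w[:m] for w in ensemble], axis=0)
        fs = waves[0].fs if waves else 1.0
        pd.DataFrame({"time_ms": np.arange(m) / fs * 1000.0,
                      "mean_pA": avg}).to_csv(outdir / "ensemble_average.csv",
                                              index=False)
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    (outdir / "settings.json").write_text(json.dumps(config.echo(), indent=2, sort_keys=True))
    return results


def _oracle_labels(events, reference: EventTable, tol: float) -> np.ndarray:
    """Label each candidate by whether it matches a ground-truth onset."""
    times = np.array([e.onset_time for e in events])
    order = np.argsort(times)
    m = match_events(times[order], reference.onset_times, tol)
    matched = {round(t, 12) for t, _ in m.pairs}
    return np.array([round(t, 12) in matched for t in times], dtype=bool)


def _labels_from_csv(events, labels_path, tol: float) -> np.ndarray:
    df = pd.read_csv(labels_path)
    if not {"onset_time_s", "label"} <= set(df.columns):
        raise ValueError("labels CSV needs onset_time_s and label columns")
    lab_times = df["onset_time_s"].to_numpy(dtype=float)
    lab_vals = df["label"].astype(bool).to_numpy()
    out = np.zeros(len(events), dtype=bool)
    unlabelled = []
    for i, e in enumerate(events):
        dist = np.abs(lab_times - e.onset_time)
        j = int(np.argmin(dist)) if dist.size else -1
        if j < 0 or dist[j] > tol:
            unlabelled.append(e.onset_time)
        else:
            out[i] = lab_vals[j]
    if unlabelled:
        raise ValueError(
            "labels CSV does not cover candidates at onsets (s): "
            + ", ".join(f"{t:.4f}" for t in unlabelled))
    return out


def run_train(config: RunConfig, paths: Sequence,
              labels_path=None, reference: Optional[EventTable] = None,
              model_out=None, tol: float = DEFAULT_TOL_S,
              n_trees: int = 400) -> Model:
    """Detect candidates in the input waves, label them (from a labels CSV
    or by onset-matching against a ground-truth table), train one forest and
    optionally write it to ``model_out``."""
    if (labels_path is None) == (reference is None):
        raise ValueError("provide exactly one of labels_path or reference")
    waves = _load_waves(config, paths)
    events = []
    for trace in waves:
        events.extend(detect_wave(trace, config).events)
    if labels_path is not None:
        labels = _labels_from_csv(events, labels_path, tol)
    else:
        labels = _oracle_labels(events, reference, tol)
    model = train_forest(
        events, labels, n_trees=n_trees, seed=config.seed,
        template_constants=(config.tau_rise, config.tau_decay),
        detection_threshold=(config.threshold_mode, config.threshold_k),
    )
    if model_out is not None:
        save_model(model, model_out)
    return model
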