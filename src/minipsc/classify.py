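"""Candidate classification: Pearson screening or a trained random forest.

Two mutually exclusive event criteria are supported. The simple route keeps
every candidate whose Pearson correlation against the template reaches a
user threshold in [-1, 1] (a threshold of -1 accepts everything, i.e. no
screening). The supervised route trains a random forest - an ensemble of
decision trees each grown on a bootstrap resample with random feature
subsetting per split - on labelled candidates, with the out-of-bag (OOB)
error reported as an internal estimate of the prediction error. Trained
models are persisted as portable ``.evtm`` files carrying the forest, the
feature-name version, the template constants and the detection settings
they were trained under.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .events import FEATURE_NAMES, Event

__all__ = [
    "Model",
    "screen_pearson",
    "train_forest",
    "classify",
    "save_model",
    "load_model",
]

MODEL_FILE_VERSION = 1


@dataclass
class Model:
    """Trained forest plus the metadata needed to apply it reproducibly."""

    forest: RandomForestClassifier
    n_trees: int
    feature_names: tuple
    oob_error: float
    template_constants: Optional[tuple] = None  # (tau_rise_ms, tau_decay_ms)
    detection_threshold: Optional[tuple] = None  # (mode, k)
    created: str = ""
    training_summary: dict = field(default_factory=dict)


def _as_matrix(events: Sequence) -> np.ndarray:
    if len(events) and isinstance(events[0], Event):
        for e in events:
            if e.features is None:
                raise ValueError("event has no features; run compute_features first")
        return np.vstack([e.features for e in events])
    return np.asarray(events, dtype=float)


def screen_pearson(events: Sequence[Event], r_threshold: float):
    """Partition candidates into (accepted, rejected) by ``pearson_r >=
    r_threshold``. A threshold of -1 switches screening off."""
    if not -1.0 <= r_threshold <= 1.0:
        raise ValueError("r_threshold must lie in [-1, 1]")
    accepted, rejected = [], []
    for e in events:
        if e.pearson_r is None:
            raise ValueError("event has no pearson_r; run pearson_vs_template first")
        (accepted if e.pearson_r >= r_threshold else rejected).append(e)
    return accepted, rejected


def train_forest(events: Sequence, labels: Sequence[bool],
                 n_trees: int = 400, features_per_split: int = 4,
                 seed: int = 0, template_constants: Optional[tuple] = None,
                 detection_threshold: Optional[tuple] = None) -> Model:
    """Train a bagged decision-tree ensemble on labelled candidates.

    Defaults: 400 trees, ceil(sqrt(10)) = 4 features considered per split,
    unlimited depth, Gini impurity. Deterministic given ``seed``. Requires at
    least two examples of each class (OOB votes are meaningless otherwise).
    """
    X = _as_matrix(events)
    y = np.asarray(labels, dtype=bool)
    if y.shape[0] != X.shape[0]:
        raise ValueError("labels length does not match events")
    n_true, n_false = int(y.sum()), int((~y).sum())
    if n_true < 2 or n_false < 2:
        raise ValueError(
            f"need >= 2 examples per class (got {n_true} true, {n_false} false)")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(features_per_split, X.shape[1]),
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X, y)
    return Model(
        forest=forest,
        n_trees=n_trees,
        feature_names=tuple(FEATURE_NAMES),
        oob_error=float(1.0 - forest.oob_score_),
        template_constants=template_constants,
        detection_threshold=detection_threshold,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        training_summary={"n_true": n_true, "n_false": n_false},
    )


def classify(events: Sequence, model: Model) -> np.ndarray:
    """Majority-vote boolean label per event. A tied vote (possible with an
    even tree count) resolves to False, biasing toward false-positive
    suppression."""
    if tuple(model.feature_names) != tuple(FEATURE_NAMES):
        raise ValueError("model was trained on a different feature version")
    X = _as_matrix(events)
    true_col = np.nonzero(model.forest.classes_ == True)[0]  # noqa: E712
    if true_col.size == 0:
        return np.zeros(X.shape[0], dtype=bool)
    proba = model.forest.predict_proba(X)[:, true_col[0]]
    labels = proba > 0.5
    for e, lab in zip(events, labels):
        if isinstance(e, Event):
            e.label = bool(lab)
    return labels


def save_model(model: Model, path) -> None:
    """Write a ``.evtm`` model file (joblib archive of metadata + forest)."""
    payload = {
        "file_version": MODEL_FILE_VERSION,
        "metadata": {
            "n_trees": model.n_trees,
            "feature_names": list(model.feature_names),
            "oob_error": model.oob_error,
            "template_constants": model.template_constants,
            "detection_threshold": model.detection_threshold,
            "created": model.created,
            "training_summary": model.training_summary,
        },
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path) -> Model:
    """Load a ``.evtm`` file; raises on corrupt files, unknown versions or a
    feature set that does not match this package's feature version."""
    try:
        payload = joblib.load(path)
        meta = payload["metadata"]
        forest = payload["forest"]
    except Exception as exc:  # noqa: BLE001 - any unpickling failure is "corrupt"
        raise ValueError(f"corrupt or unreadable model file {path}") from exc
    if payload.get("file_version") != MODEL_FILE_VERSION:
        raise ValueError("model file version mismatch")
    names = tuple(meta["feature_names"])
    if len(names) != len(FEATURE_NAMES):
        raise ValueError(
            f"model has {len(names)} feature names, expected {len(FEATURE_NAMES)}")
    tc = meta.get("template_constants")
    dt = meta.get("detection_threshold")
    return Model(
        forest=forest,
        n_trees=meta["n_trees"],
        feature_names=names,
        oob_error=meta["oob_error"],
        template_constants=tuple(tc) if tc is not None else None,
        detection_threshold=tuple(dt) if dt is not None else None,
        created=meta.get("created", ""),
        training_summary=meta.get("training_summary", {}),
    )
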