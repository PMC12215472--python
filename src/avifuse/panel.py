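"""Prediction data model and exchange-format I/O.

The central container is :class:`PredictionPanel`: per-sample class-probability
vectors from M upstream classifiers over a shared label vocabulary, the unit
every fusion strategy consumes.  Probabilities are stored as a single
``(N, M, K)`` float array; light dataclass views (:class:`ModelPrediction`)
are materialised on demand.

The on-disk exchange format is a long CSV (one row per sample/model pair)::

    sample_id,model_id,true_label,<class_1>,...,<class_K>

with a JSON mirror (list of records with the same field names).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelFormatError",
    "LabelVocabulary",
    "ModelPrediction",
    "PredictionPanel",
    "softmax",
    "predict_label",
    "validate_probs",
    "read_predictions",
    "write_predictions",
]

#: internal tolerance for probability normalisation
PROB_TOL = 1e-9
#: looser tolerance applied when ingesting files; rows inside it are renormalised
INGEST_TOL = 1e-6

_META_COLUMNS = ("sample_id", "model_id", "true_label")


class PanelFormatError(ValueError):
    """Raised when an exchange file or in-memory panel violates the format."""


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered class names; the order is the canonical column order everywhere."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        classes = tuple(str(c) for c in self.classes)
        object.__setattr__(self, "classes", classes)
        if len(classes) < 2:
            raise ValueError(f"need at least 2 classes, got {len(classes)}")
        if len(set(classes)) != len(classes):
            dupes = sorted({c for c in classes if classes.count(c) > 1})
            raise ValueError(f"duplicate class names: {dupes}")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def index(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise KeyError(f"label {name!r} not in vocabulary") from None


def validate_probs(probs: Sequence[float], tol: float = PROB_TOL) -> np.ndarray:
    """Check a class-probability vector: entries in [0, 1], summing to 1.

    Returns the vector as a float array (renormalised exactly to machine sum 1
    only when the deviation is within *tol*).
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError(f"probability vector must be 1-D with K >= 2, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        bad = int(np.flatnonzero(~np.isfinite(p))[0])
        raise ValueError(f"non-finite probability at index {bad}")
    if np.any(p < -tol) or np.any(p > 1 + tol):
        raise ValueError("probabilities must lie in [0, 1]")
    s = float(p.sum())
    if abs(s - 1.0) > tol:
        raise ValueError(f"probabilities sum to {s!r}, not 1 within {tol}")
    return np.clip(p, 0.0, 1.0)


def softmax(logits: Sequence[float]) -> np.ndarray:
    """Normalised exponential of a logit vector (max-subtracted for stability).

    Invariant to adding a constant to every logit.
    """
    z = np.asarray(logits, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError(f"logits must be 1-D with K >= 2, got shape {z.shape}")
    if not np.all(np.isfinite(z)):
        bad = int(np.flatnonzero(~np.isfinite(z))[0])
        raise ValueError(f"non-finite logit at index {bad}: {z[bad]!r}")
    e = np.exp(z - z.max())
    return e / e.sum()


def predict_label(probs: Sequence[float]) -> tuple[int, float]:
    """Top class of a probability vector: (lowest argmax index, its probability)."""
    p = validate_probs(probs)
    idx = int(np.argmax(p))  # np.argmax returns the first maximum
    return idx, float(p[idx])


@dataclass(frozen=True)
class ModelPrediction:
    """One model's output for one sample.

    ``predicted_index`` is the lowest argmax of ``probs``; ``confidence`` is the
    maximum SoftMax entry — the model's belief in its top class.
    """

    model_id: str
    probs: np.ndarray
    predicted_index: int
    confidence: float

    def __post_init__(self) -> None:
        p = validate_probs(self.probs)
        object.__setattr__(self, "probs", p)
        idx, conf = int(np.argmax(p)), float(p[int(np.argmax(p))])
        if not math.isclose(p[self.predicted_index], conf, abs_tol=PROB_TOL):
            raise ValueError(
                f"predicted_index {self.predicted_index} is not an argmax of probs"
            )
        if not math.isclose(self.confidence, float(p[self.predicted_index]), abs_tol=PROB_TOL):
            raise ValueError("confidence must equal probs[predicted_index]")

    @classmethod
    def from_probs(cls, model_id: str, probs: Sequence[float]) -> "ModelPrediction":
        idx, conf = predict_label(probs)
        return cls(model_id=model_id, probs=np.asarray(probs, float),
                   predicted_index=idx, confidence=conf)


@dataclass
class PredictionPanel:
    """Aligned predictions from M models for N samples over one vocabulary.

    ``probs`` has shape ``(N, M, K)``; model order (``model_ids``) is fixed and
    is the order in which weight vectors are interpreted.
    """

    vocabulary: LabelVocabulary
    sample_ids: list[str]
    model_ids: list[str]
    probs: np.ndarray
    true_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n, m, k = self.shape
        if self.probs.ndim != 3:
            raise PanelFormatError(f"probs must be (N, M, K), got shape {self.probs.shape}")
        if k != len(self.vocabulary):
            raise PanelFormatError(
                f"probs last axis {k} != vocabulary size {len(self.vocabulary)}"
            )
        if len(self.sample_ids) != n:
            raise PanelFormatError("sample_ids length mismatch")
        if len(self.model_ids) != m:
            raise PanelFormatError("model_ids length mismatch")
        if len(set(self.model_ids)) != m:
            raise PanelFormatError("duplicate model_ids")
        if self.true_labels is not None:
            if len(self.true_labels) != n:
                raise PanelFormatError("true_labels length mismatch")
            for lab in self.true_labels:
                if lab not in self.vocabulary.classes:
                    raise PanelFormatError(f"true label {lab!r} not in vocabulary")
        if n:
            sums = self.probs.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > INGEST_TOL):
                i, j = map(int, np.argwhere(np.abs(sums - 1.0) > INGEST_TOL)[0])
                raise PanelFormatError(
                    f"probabilities for sample {self.sample_ids[i]!r}, model "
                    f"{self.model_ids[j]!r} sum to {sums[i, j]!r}"
                )
            self.probs = self.probs / sums[..., None]

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.probs.shape[0] if self.probs.ndim == 3 else len(self.sample_ids)
        m = self.probs.shape[1] if self.probs.ndim == 3 else len(self.model_ids)
        k = self.probs.shape[2] if self.probs.ndim == 3 else len(self.vocabulary)
        return n, m, k

    @property
    def n_samples(self) -> int:
        return self.shape[0]

    @property
    def n_models(self) -> int:
        return self.shape[1]

    def row(self, i: int) -> list[ModelPrediction]:
        """Materialise the i-th sample's predictions as ModelPrediction views."""
        return [
            ModelPrediction.from_probs(mid, self.probs[i, j])
            for j, mid in enumerate(self.model_ids)
        ]

    def confidences(self) -> np.ndarray:
        """Per-sample, per-model top probabilities, shape (N, M)."""
        return self.probs.max(axis=2)

    def predicted_indices(self) -> np.ndarray:
        """Per-sample, per-model argmax class indices, shape (N, M)."""
        return self.probs.argmax(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame in exchange-format column order."""
        n, m, k = self.shape
        records = []
        for i, sid in enumerate(self.sample_ids):
            truth = "" if self.true_labels is None else self.true_labels[i]
            for j, mid in enumerate(self.model_ids):
                rec = {"sample_id": sid, "model_id": mid, "true_label": truth}
                for c, cls in enumerate(self.vocabulary.classes):
                    rec[cls] = self.probs[i, j, c]
                records.append(rec)
        cols = list(_META_COLUMNS) + list(self.vocabulary.classes)
        return pd.DataFrame.from_records(records, columns=cols)


def _panel_from_frame(df: pd.DataFrame, source: str) -> PredictionPanel:
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"{source}: missing required column {col!r}")
    class_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if len(class_cols) < 2:
        raise PanelFormatError(f"{source}: fewer than 2 class columns")
    vocab = LabelVocabulary(tuple(class_cols))
    if df.empty:
        return PredictionPanel(vocab, [], [], np.zeros((0, 0, len(vocab))), None)

    sample_ids = list(dict.fromkeys(df["sample_id"].astype(str)))
    model_ids = list(dict.fromkeys(df["model_id"].astype(str)))
    n, m, k = len(sample_ids), len(model_ids), len(vocab)
    sidx = {s: i for i, s in enumerate(sample_ids)}
    midx = {s: i for i, s in enumerate(model_ids)}

    probs = np.full((n, m, k), np.nan)
    truths: dict[str, str] = {}
    try:
        values = df[class_cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise PanelFormatError(f"{source}: non-numeric probability value ({exc})") from exc
    samples = df["sample_id"].astype(str).to_numpy()
    models = df["model_id"].astype(str).to_numpy()
    raw_truth = df["true_label"].to_numpy()
    for pos in range(len(df)):
        line = pos + 2  # header is line 1
        vec = values[pos]
        s = float(vec.sum())
        if not np.all(np.isfinite(vec)) or np.any(vec < -INGEST_TOL):
            raise PanelFormatError(f"{source}, line {line}: invalid probability values")
        if abs(s - 1.0) > INGEST_TOL:
            raise PanelFormatError(
                f"{source}, line {line}: probabilities sum to {s:.6f}, not 1"
            )
        i, j = sidx[samples[pos]], midx[models[pos]]
        probs[i, j] = vec
        truth = raw_truth[pos]
        if truth is not None and not (isinstance(truth, float) and math.isnan(truth)):
            truth = str(truth)
            if truth:
                prev = truths.setdefault(samples[pos], truth)
                if prev != truth:
                    raise PanelFormatError(
                        f"{source}, line {line}: conflicting true labels for sample "
                        f"{samples[pos]!r}"
                    )

    missing = np.argwhere(np.isnan(probs[:, :, 0]))
    if missing.size:
        i, j = map(int, missing[0])
        raise PanelFormatError(
            f"{source}: missing block for sample {sample_ids[i]!r}, model {model_ids[j]!r}"
        )
    true_labels = None
    if truths:
        if set(truths) != set(sample_ids):
            miss = sorted(set(sample_ids) - set(truths))[0]
            raise PanelFormatError(f"{source}: sample {miss!r} has no true label")
        true_labels = [truths[s] for s in sample_ids]
    return PredictionPanel(vocab, sample_ids, model_ids, probs, true_labels)


def read_predictions(path: str | Path) -> PredictionPanel:
    """Read a prediction panel from the CSV exchange format (or its JSON mirror)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "r", encoding="utf-8") as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise PanelFormatError(f"{path}: JSON mirror must be a list of records")
        df = pd.DataFrame.from_records(records)
        if records:
            # preserve field order of the first record as column order
            df = df[list(records[0].keys())]
        else:
            raise PanelFormatError(f"{path}: empty JSON panel must still define fields")
    else:
        try:
            df = pd.read_csv(path, dtype={"sample_id": str, "model_id": str,
                                          "true_label": str}, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise PanelFormatError(f"{path}: unreadable CSV ({exc})") from exc
        df = df.replace({"true_label": {"": None}})
    return _panel_from_frame(df, str(path))


def write_predictions(panel: PredictionPanel, path: str | Path) -> None:
    """Write a panel in the exchange format; round-trips to full float precision."""
    path = Path(path)
    df = panel.to_frame()
    if path.suffix.lower() == ".json":
        records = df.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)
    else:
        df.to_csv(path, index=False, float_format="%.17g")
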