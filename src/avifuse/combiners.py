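"""Fusion strategies: fuzzy dynamic weighting and the fixed-weight baselines.

All strategies combine M per-model class-probability vectors into one fused
vector ``EP(x) = sum_i w_i(x) * p_i(x)``.  They differ only in how the weight
vector ``w(x)`` is obtained:

* :class:`FuzzyCombiner` — per-sample dynamic weights from a Mamdani FIS over
  model confidences (or one panel-wide weight vector from average confidences);
* :class:`WeightedAverageCombiner` — fixed, user-supplied convex weights;
* :class:`MeanVoteCombiner` — uniform weights 1/M (soft mean voting);
* :class:`MajorityVoteCombiner` — modal predicted label; the reported
  "probabilities" are vote shares.

Combiners follow the sklearn estimator protocol (``fit`` validates and freezes
the panel geometry, ``predict_proba``/``transform`` return fused probabilities,
``predict`` returns labels) and compose with sklearn pipelines.  The
module-level functions (:func:`combine_weighted`, :func:`mean_vote`,
:func:`majority_vote`, :func:`fuzzy_combine`) are thin per-row wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .fis import FuzzyInferenceSystem, build_default_fis, normalize_weights
from .panel import (PROB_TOL, ModelPrediction, PredictionPanel, validate_probs)

__all__ = [
    "EnsembleResult",
    "validate_weights",
    "combine_weighted",
    "mean_vote",
    "majority_vote",
    "fuzzy_combine",
    "fuse_panel",
    "FuzzyCombiner",
    "WeightedAverageCombiner",
    "MeanVoteCombiner",
    "MajorityVoteCombiner",
]


def validate_weights(weights: Sequence[float], n_models: int | None = None) -> np.ndarray:
    """Check a weight vector: non-negative, summing to 1 within 1e-9."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError(f"weights must be a non-empty vector, got shape {w.shape}")
    if n_models is not None and w.size != n_models:
        raise ValueError(f"expected {n_models} weights, got {w.size}")
    if np.any(w < -PROB_TOL) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    if abs(float(w.sum()) - 1.0) > PROB_TOL:
        raise ValueError(f"weights sum to {float(w.sum())!r}, not 1")
    return np.clip(w, 0.0, None)


@dataclass(frozen=True)
class EnsembleResult:
    """Fused output for one sample: combined probabilities, the weights used,
    the predicted class index/confidence, and the strategy name."""

    probs: np.ndarray
    weights: np.ndarray
    predicted_index: int
    confidence: float
    strategy: str

    def __post_init__(self) -> None:
        p = validate_probs(self.probs)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if abs(p[self.predicted_index] - p.max()) > PROB_TOL:
            raise ValueError("predicted_index is not an argmax of probs")


def _row_probs(panel_row: Sequence[ModelPrediction]) -> np.ndarray:
    if len(panel_row) == 0:
        raise ValueError("empty panel row")
    return np.stack([validate_probs(mp.probs) for mp in panel_row])


def combine_weighted(panel_row: Sequence[ModelPrediction],
                     weights: Sequence[float],
                     strategy: str = "weighted") -> EnsembleResult:
    """Convex combination of the row's probability vectors with fixed weights."""
    p = _row_probs(panel_row)
    w = validate_weights(weights, n_models=p.shape[0])
    fused = w @ p
    fused = fused / fused.sum()
    idx = int(np.argmax(fused))
    return EnsembleResult(fused, w, idx, float(fused[idx]), strategy)


def mean_vote(panel_row: Sequence[ModelPrediction]) -> EnsembleResult:
    """Soft mean voting: uniform weights 1/M."""
    m = len(panel_row)
    if m == 0:
        raise ValueError("empty panel row")
    return combine_weighted(panel_row, np.full(m, 1.0 / m), strategy="mean")


def majority_vote(panel_row: Sequence[ModelPrediction]) -> EnsembleResult:
    """Hard voting by modal predicted label.

    Ties are broken by the highest single-model confidence among the tied
    labels, then by lowest class index.  The reported probabilities are vote
    shares (votes / M).
    """
    m = len(panel_row)
    if m == 0:
        raise ValueError("empty panel row")
    k = validate_probs(panel_row[0].probs).size
    votes = np.zeros(k)
    best_conf = np.zeros(k)  # best single-model confidence backing each label
    for mp in panel_row:
        votes[mp.predicted_index] += 1
        best_conf[mp.predicted_index] = max(best_conf[mp.predicted_index], mp.confidence)
    shares = votes / m
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    if tied.size > 1:
        winner = int(tied[np.argmax(best_conf[tied])])  # argmax keeps lowest on ties
    else:
        winner = int(tied[0])
    weights = np.full(m, 1.0 / m)
    return EnsembleResult(shares, weights, winner, float(shares[winner]), "majority")


def fuzzy_combine(panel_row: Sequence[ModelPrediction],
                  fis: FuzzyInferenceSystem) -> EnsembleResult:
    """Dynamic-weight fusion: confidences -> FIS -> normalised weights -> EP(x)."""
    p = _row_probs(panel_row)
    if fis.n_inputs != p.shape[0]:
        raise ValueError(f"FIS expects {fis.n_inputs} models, row has {p.shape[0]}")
    confidences = p.max(axis=1)
    weights = normalize_weights(fis.infer(confidences))
    return combine_weighted(panel_row, weights, strategy="fuzzy")


class _BaseCombiner(TransformerMixin, BaseEstimator):
    """Shared estimator mechanics: geometry validation and array plumbing.

    ``X`` is the stacked per-model probability array, either 3-D ``(N, M, K)``
    or flattened 2-D ``(N, M * K)`` (pipeline-friendly) with ``n_classes``
    given at construction.  ``fit`` freezes N-independent geometry
    (``n_models_``, ``n_classes_``); ``predict_proba`` returns the fused
    ``(N, K)`` matrix and ``weights_`` the per-sample ``(N, M)`` weights used.
    """

    def __init__(self, n_classes: int | None = None, classes: Sequence[str] | None = None):
        self.n_classes = n_classes
        self.classes = classes

    # -- geometry ---------------------------------------------------------
    def _coerce(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return X
        if X.ndim == 2:
            k = self.n_classes
            if k is None and self.classes is not None:
                k = len(self.classes)
            if k is None:
                raise ValueError("2-D input needs n_classes (or classes) at construction")
            if X.shape[1] % k:
                raise ValueError(f"cannot split {X.shape[1]} columns into blocks of {k}")
            return X.reshape(X.shape[0], X.shape[1] // k, k)
        raise ValueError(f"X must be 2-D or 3-D, got ndim={X.ndim}")

    def fit(self, X, y=None):
        P = self._coerce(X)
        n, m, k = P.shape
        if m < 1 or k < 2:
            raise ValueError(f"need M >= 1 models and K >= 2 classes, got M={m}, K={k}")
        if n and np.any(np.abs(P.sum(axis=2) - 1.0) > 1e-6):
            raise ValueError("model probability vectors must each sum to 1")
        self.n_models_ = m
        self.n_classes_ = k
        self.classes_ = (np.asarray(list(self.classes)) if self.classes is not None
                         else np.arange(k))
        if len(self.classes_) != k:
            raise ValueError(f"classes has length {len(self.classes_)}, expected {k}")
        self._post_fit(P)
        return self

    def _post_fit(self, P: np.ndarray) -> None:  # noqa: D401 - hook
        pass

    def _check_fitted_geometry(self, P: np.ndarray) -> None:
        if not hasattr(self, "n_models_"):
            raise RuntimeError("combiner is not fitted; call fit(X) first")
        if P.shape[1] != self.n_models_ or P.shape[2] != self.n_classes_:
            raise ValueError(
                f"X has (M, K) = {P.shape[1:]}, fitted for ({self.n_models_}, {self.n_classes_})"
            )

    # -- strategy hook ----------------------------------------------------
    def _weights_for(self, P: np.ndarray) -> np.ndarray:
        """Per-sample weight matrix (N, M); overridden per strategy."""
        raise NotImplementedError

    # -- sklearn surface --------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        P = self._coerce(X)
        self._check_fitted_geometry(P)
        if P.shape[0] == 0:
            self.weights_ = np.zeros((0, self.n_models_))
            return np.zeros((0, self.n_classes_))
        W = self._weights_for(P)
        fused = np.einsum("nm,nmk->nk", W, P)
        fused = fused / fused.sum(axis=1, keepdims=True)
        self.weights_ = W
        return fused

    def transform(self, X) -> np.ndarray:
        return self.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)] if proba.size else self.classes_[:0]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.requires_fit = True
        return tags


class WeightedAverageCombiner(_BaseCombiner):
    """Fixed-weight soft fusion (``weights=None`` gives uniform weights)."""

    def __init__(self, weights: Sequence[float] | None = None,
                 n_classes: int | None = None, classes: Sequence[str] | None = None):
        super().__init__(n_classes=n_classes, classes=classes)
        self.weights = weights

    def _post_fit(self, P: np.ndarray) -> None:
        if self.weights is None:
            self.weight_vector_ = np.full(self.n_models_, 1.0 / self.n_models_)
        else:
            self.weight_vector_ = validate_weights(self.weights, self.n_models_)

    def _weights_for(self, P: np.ndarray) -> np.ndarray:
        return np.broadcast_to(self.weight_vector_, (P.shape[0], self.n_models_)).copy()


class MeanVoteCombiner(WeightedAverageCombiner):
    """Soft mean voting: always uniform weights 1/M."""

    def __init__(self, n_classes: int | None = None, classes: Sequence[str] | None = None):
        super().__init__(weights=None, n_classes=n_classes, classes=classes)


class MajorityVoteCombiner(_BaseCombiner):
    """Hard voting; ``predict_proba`` returns vote shares."""

    def predict_proba(self, X) -> np.ndarray:
        P = self._coerce(X)
        self._check_fitted_geometry(P)
        n, m, k = P.shape
        self.weights_ = np.full((n, m), 1.0 / m) if n else np.zeros((0, m))
        shares = np.zeros((n, k))
        winners = np.zeros(n, dtype=int)
        for i in range(n):
            res = majority_vote([ModelPrediction.from_probs(f"m{j}", P[i, j])
                                 for j in range(m)])
            shares[i] = res.probs
            winners[i] = res.predicted_index
        self._winners = winners
        return shares

    def predict(self, X) -> np.ndarray:
        self.predict_proba(X)
        return self.classes_[self._winners]

    def _weights_for(self, P: np.ndarray) -> np.ndarray:  # pragma: no cover
        return np.full((P.shape[0], self.n_models_), 1.0 / self.n_models_)


class FuzzyCombiner(_BaseCombiner):
    """Fuzzy dynamic-weight fusion.

    Parameters
    ----------
    fis : FuzzyInferenceSystem or None
        The confidence-to-weight inference system; ``None`` builds the default
        symmetric low/medium/high system for the fitted model count.
    mode : {"per_sample", "panel_average"}
        ``per_sample`` infers one weight vector per sample from its own
        confidences; ``panel_average`` feeds the panel-mean confidences through
        the FIS once and applies that single weight vector to every sample.
    """

    def __init__(self, fis: FuzzyInferenceSystem | None = None,
                 mode: str = "per_sample",
                 n_classes: int | None = None, classes: Sequence[str] | None = None):
        super().__init__(n_classes=n_classes, classes=classes)
        self.fis = fis
        self.mode = mode

    def _post_fit(self, P: np.ndarray) -> None:
        if self.mode not in ("per_sample", "panel_average"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_models_ < 2:
            raise ValueError("fuzzy fusion needs at least 2 models")
        fis = self.fis if self.fis is not None else build_default_fis(self.n_models_)
        if fis.n_inputs != self.n_models_:
            raise ValueError(
                f"FIS expects {fis.n_inputs} models, data has {self.n_models_}"
            )
        self.fis_ = fis

    def _weights_for(self, P: np.ndarray) -> np.ndarray:
        conf = P.max(axis=2)  # (N, M)
        if self.mode == "panel_average":
            w = normalize_weights(self.fis_.infer(conf.mean(axis=0)))
            return np.broadcast_to(w, conf.shape).copy()
        # memoise identical confidence vectors (common under coarse rounding)
        W = np.empty_like(conf)
        cache: dict[bytes, np.ndarray] = {}
        rounded = np.round(conf, 12)
        for i in range(conf.shape[0]):
            key = rounded[i].tobytes()
            w = cache.get(key)
            if w is None:
                w = normalize_weights(self.fis_.infer(conf[i]))
                cache[key] = w
            W[i] = w
        return W


_STRATEGIES = {"fuzzy", "weighted", "mean", "majority"}


def fuse_panel(panel: PredictionPanel, strategy: str = "fuzzy",
               weights: Sequence[float] | None = None,
               fis: FuzzyInferenceSystem | None = None,
               mode: str = "per_sample") -> list[EnsembleResult]:
    """Fuse every sample of a panel with the chosen strategy."""
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {sorted(_STRATEGIES)}")
    n, m, _ = panel.shape
    if strategy == "majority":
        return [majority_vote(panel.row(i)) for i in range(n)]
    if strategy == "mean":
        comb: _BaseCombiner = MeanVoteCombiner(classes=list(panel.vocabulary))
    elif strategy == "weighted":
        if weights is None:
            raise ValueError("strategy 'weighted' requires explicit weights")
        comb = WeightedAverageCombiner(weights=weights, classes=list(panel.vocabulary))
    else:
        comb = FuzzyCombiner(fis=fis, mode=mode, classes=list(panel.vocabulary))
    fused = comb.fit(panel.probs).predict_proba(panel.probs)
    out = []
    for i in range(n):
        idx = int(np.argmax(fused[i]))
        out.append(EnsembleResult(fused[i], comb.weights_[i], idx,
                                  float(fused[i][idx]), strategy))
    return out
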