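"""Seeded simulator of multi-model classifier probability outputs.

Emulates a panel of upstream classifiers with controllable per-model
accuracy, confidence profile and inter-model error correlation, so fusion
behaviour is testable end-to-end without trained networks.

Generative model per sample and model:

1. the prediction is correct with probability ``a`` (the model's accuracy
   target); incorrect predictions pick a wrong class uniformly;
2. the probability vector is drawn from a Dirichlet whose concentration is
   peaked on the intended class, with the peak calibrated by Monte-Carlo
   bisection so the expected top probability matches the model's
   mean-confidence target; correct predictions use a higher confidence
   target than incorrect ones (the confidence-correctness link that makes
   confidence informative);
3. with error correlation ``rho > 0``, models share a per-sample
   "hard-sample" latent: each model's correctness draw reuses the shared
   uniform with probability rho, so errors co-occur increasingly often;
   ``rho = 1`` with equal accuracies gives identical error sets, ``rho = 0``
   independent ones.

The argmax of the drawn vector is forced onto the intended class by swapping
the maximal entry into that slot — a measure-preserving relabelling that
keeps accuracy exactly Bernoulli and the confidence distribution intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .panel import LabelVocabulary, PredictionPanel

__all__ = [
    "ModelProfile",
    "PanelSpec",
    "calibrate_concentration",
    "simulate_labels",
    "simulate_model",
    "simulate_panel",
]

_CAL_SAMPLES = 3000
_CAL_TOL = 0.004


@dataclass(frozen=True)
class ModelProfile:
    """Behavioural targets for one simulated classifier.

    ``accuracy``: probability a prediction is correct.  ``mean_confidence``:
    target expected top probability for correct predictions.
    ``incorrect_confidence``: same for incorrect ones; defaults to halfway
    between chance and ``mean_confidence`` (informative confidence).  Setting
    it equal to ``mean_confidence`` makes confidence uninformative.
    """

    model_id: str
    accuracy: float
    mean_confidence: float
    incorrect_confidence: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.accuracy <= 1.0):
            raise ValueError(f"accuracy must lie in (0, 1], got {self.accuracy}")
        if not (0.0 < self.mean_confidence <= 1.0):
            raise ValueError("mean_confidence must lie in (0, 1]")

    def resolved_incorrect_confidence(self, n_classes: int) -> float:
        if self.incorrect_confidence is not None:
            return self.incorrect_confidence
        return 0.5 * (1.0 / n_classes + self.mean_confidence)


@dataclass(frozen=True)
class PanelSpec:
    """Full simulation spec: geometry, class prior, model profiles, rho, seed."""

    n_classes: int
    n_samples: int
    profiles: tuple[ModelProfile, ...]
    class_probs: tuple[float, ...] | None = None
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.profiles) < 2:
            raise ValueError("need at least 2 model profiles")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.class_probs is not None:
            p = tuple(float(v) for v in self.class_probs)
            if len(p) != self.n_classes or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("class_probs must have length K and sum to 1")
            object.__setattr__(self, "class_probs", p)


def _mean_top_prob(kappa: float, n_classes: int, rng: np.random.Generator) -> float:
    alpha = np.ones(n_classes)
    alpha[0] += kappa
    draws = rng.dirichlet(alpha, size=_CAL_SAMPLES)
    return float(draws.max(axis=1).mean())


@lru_cache(maxsize=256)
def calibrate_concentration(n_classes: int, target_conf: float) -> float:
    """Dirichlet peak concentration whose expected top probability hits the target.

    Seeded Monte-Carlo bisection (deterministic: the calibration RNG is derived
    from the arguments, not from the caller's seed).  The attainable floor is
    the mean top probability of the flat Dirichlet, which exceeds 1/K; targets
    below chance are rejected, targets between chance and the floor raise with
    the measured floor in the message.
    """
    if not (1.0 / n_classes < target_conf <= 1.0):
        raise ValueError(
            f"confidence target {target_conf} not attainable: must exceed "
            f"chance 1/K = {1.0 / n_classes:.3f}"
        )
    # stable cross-process calibration seed derived from the arguments
    cal_seed = (977 * n_classes + int(round(target_conf * 1e6))) % (2**31 - 1)
    rng = np.random.default_rng(cal_seed)
    lo, hi = 0.0, 4.0
    floor = _mean_top_prob(lo, n_classes, rng)
    if target_conf < floor - _CAL_TOL:
        raise ValueError(
            f"confidence target {target_conf} below the attainable floor "
            f"{floor:.3f} of the peaked-Dirichlet family for K={n_classes}"
        )
    while _mean_top_prob(hi, n_classes, rng) < target_conf and hi < 1e6:
        hi *= 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _mean_top_prob(mid, n_classes, rng) < target_conf:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_labels(spec: PanelSpec) -> np.ndarray:
    """N true class indices drawn from the class prior (uniform by default)."""
    rng = np.random.default_rng(spec.seed)
    p = spec.class_probs
    return rng.choice(spec.n_classes, size=spec.n_samples, p=p)


def _draw_probs(intended: np.ndarray, kappa: np.ndarray, n_classes: int,
                rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draws peaked (with per-sample kappa) on the intended class."""
    n = intended.size
    # draw peaked on class 0, then swap the peak into the intended slot
    gammas = rng.gamma(np.column_stack([1.0 + kappa,
                                        np.ones((n, n_classes - 1))]))
    probs = gammas / gammas.sum(axis=1, keepdims=True)
    rows = np.arange(n)
    # measure-preserving relabelling: swap the maximal entry into column 0
    # (forcing the argmax onto the peak), then swap column 0 into the
    # intended class slot
    top = probs.argmax(axis=1)
    tmp = probs[rows, top].copy()
    probs[rows, top] = probs[rows, 0]
    probs[rows, 0] = tmp
    tmp = probs[rows, intended].copy()
    probs[rows, intended] = probs[rows, 0]
    probs[rows, 0] = tmp
    return probs


def simulate_model(labels: np.ndarray, profile: ModelProfile, n_classes: int,
                   seed: int, correct_uniforms: np.ndarray | None = None) -> np.ndarray:
    """One model's (N, K) probability matrix for the given true labels.

    ``correct_uniforms`` supplies the per-sample uniforms deciding correctness
    (used by :func:`simulate_panel` to correlate errors across models); by
    default they are drawn independently.
    """
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n) if correct_uniforms is None else np.asarray(correct_uniforms)
    correct = u < profile.accuracy

    intended = labels.copy()
    wrong = ~correct
    if wrong.any():
        # uniform over the K-1 wrong classes
        offsets = rng.integers(1, n_classes, size=int(wrong.sum()))
        intended[wrong] = (labels[wrong] + offsets) % n_classes

    kap_correct = calibrate_concentration(n_classes, profile.mean_confidence)
    inc_conf = profile.resolved_incorrect_confidence(n_classes)
    kap_incorrect = calibrate_concentration(n_classes, inc_conf)
    kappa = np.where(correct, kap_correct, kap_incorrect)
    return _draw_probs(intended, kappa, n_classes, rng)


def simulate_panel(spec: PanelSpec) -> PredictionPanel:
    """Simulate the full (N, M, K) prediction panel.

    Error correlation: a shared per-sample uniform is substituted for each
    model's private correctness draw with probability ``rho``.
    """
    labels = simulate_labels(spec)
    n, m = spec.n_samples, len(spec.profiles)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    hard = rng.uniform(size=n)  # shared hard-sample latent
    probs = np.empty((n, m, spec.n_classes))
    for j, profile in enumerate(spec.profiles):
        mrng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, j]))
        private = mrng.uniform(size=n)
        use_shared = mrng.uniform(size=n) < spec.rho
        u = np.where(use_shared, hard, private)
        probs[:, j] = simulate_model(labels, profile, spec.n_classes,
                                     seed=int(mrng.integers(2**31 - 1)),
                                     correct_uniforms=u)
    vocab = LabelVocabulary(tuple(f"class_{i:02d}" for i in range(spec.n_classes)))
    sample_ids = [f"s{i:06d}" for i in range(n)]
    true_labels = [vocab.classes[t] for t in labels]
    return PredictionPanel(vocabulary=vocab, sample_ids=sample_ids,
                           model_ids=[p.model_id for p in spec.profiles],
                           probs=probs, true_labels=true_labels)
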