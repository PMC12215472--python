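"""Mamdani fuzzy inference mapping model confidences to ensemble weights.

The dynamic-weighting idea: each upstream classifier reports a confidence
(its top SoftMax probability) and a fuzzy inference system (FIS) turns the
vector of confidences into raw per-model weights, which are then normalised
into a convex weight vector.  More confident models receive larger weights,
so the ensemble adaptively leans on whichever classifier is most certain
about the current sample.

Inference is classical Mamdani: rule strength is the minimum of the
antecedent membership degrees, each consequent term is clipped at the rule
strength, per-output clipped terms are aggregated by maximum, and the crisp
weight is the centroid of the aggregated membership function on a discretised
[0, 1] universe.

The default system (:func:`build_default_fis`) gives every model confidence
three triangular terms — low (0, 0, 0.5), medium (0.25, 0.5, 0.75) and
high (0.5, 1, 1) — and one rule per (model, term) mapping the confidence term
to the same-named raw-weight term.  This is the minimal rule base that is
symmetric across models and monotone in each confidence.  Everything is
overridable through a serialized FIS definition (``format: fis/1`` YAML/JSON).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "MembershipFunction",
    "FuzzyVariable",
    "FuzzyRule",
    "FuzzyInferenceSystem",
    "build_default_fis",
    "fuzzify",
    "infer_weights",
    "normalize_weights",
]

_CLAMP_TOL = 1e-9
FORMAT_TAG = "fis/1"


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership function with apex degree 1.

    ``shape`` is ``"triangular"`` (3 breakpoints a <= b <= c) or
    ``"trapezoidal"`` (4 breakpoints a <= b <= c <= d).  Coincident
    breakpoints give shoulders: e.g. (0, 0, 0.5) is a left shoulder.
    """

    shape: str
    points: tuple[float, ...]

    def __post_init__(self) -> None:
        pts = tuple(float(p) for p in self.points)
        object.__setattr__(self, "points", pts)
        expected = {"triangular": 3, "trapezoidal": 4}.get(self.shape)
        if expected is None:
            raise ValueError(f"unknown membership shape {self.shape!r}")
        if len(pts) != expected:
            raise ValueError(f"{self.shape} needs {expected} breakpoints, got {len(pts)}")
        if any(b < a for a, b in zip(pts, pts[1:])):
            raise ValueError(f"breakpoints must be non-decreasing: {pts}")
        if pts[0] < -_CLAMP_TOL or pts[-1] > 1 + _CLAMP_TOL:
            raise ValueError(f"breakpoints must lie in [0, 1]: {pts}")

    def degree(self, x):
        """Membership degree(s) of ``x``; vectorised, values in [0, 1]."""
        x = np.asarray(x, dtype=float)
        if self.shape == "triangular":
            a, b, c = self.points
            left_a, left_b, right_a, right_b = a, b, b, c
        else:
            left_a, left_b, right_a, right_b = self.points
        out = np.zeros_like(x)
        # rising edge
        if left_b > left_a:
            rise = (x - left_a) / (left_b - left_a)
            out = np.where((x >= left_a) & (x < left_b), rise, out)
        else:
            out = np.where(x < left_b, 1.0, out)  # left shoulder
        # plateau / apex
        out = np.where((x >= left_b) & (x <= right_a), 1.0, out)
        # falling edge
        if right_b > right_a:
            fall = (right_b - x) / (right_b - right_a)
            out = np.where((x > right_a) & (x <= right_b), fall, out)
        else:
            out = np.where(x > right_a, 1.0, out)  # right shoulder
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"shape": self.shape, "points": list(self.points)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MembershipFunction":
        return cls(shape=d["shape"], points=tuple(d["points"]))


@dataclass(frozen=True)
class FuzzyVariable:
    """A linguistic variable on the closed universe [0, 1] with named terms."""

    name: str
    terms: tuple[tuple[str, MembershipFunction], ...]

    def __post_init__(self) -> None:
        terms = tuple((str(n), mf) for n, mf in
                      (self.terms.items() if isinstance(self.terms, dict) else self.terms))
        object.__setattr__(self, "terms", terms)
        names = [n for n, _ in terms]
        if len(set(names)) != len(names):
            raise ValueError(f"variable {self.name!r}: duplicate term names")
        if not terms:
            raise ValueError(f"variable {self.name!r}: needs at least one term")
        # complete cover: every universe point has a positive-degree term
        grid = np.linspace(0.0, 1.0, 501)
        cover = np.zeros_like(grid)
        for _, mf in terms:
            cover = np.maximum(cover, mf.degree(grid))
        if np.any(cover <= 0):
            hole = float(grid[int(np.argmin(cover))])
            raise ValueError(
                f"variable {self.name!r}: universe point {hole:.3f} is covered by no term"
            )

    def term(self, name: str) -> MembershipFunction:
        for n, mf in self.terms:
            if n == name:
                return mf
        raise KeyError(f"variable {self.name!r} has no term {name!r}")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.terms)

    def to_dict(self) -> dict:
        return {"name": self.name,
                "terms": {n: mf.to_dict() for n, mf in self.terms}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyVariable":
        terms = tuple((n, MembershipFunction.from_dict(t)) for n, t in d["terms"].items())
        return cls(name=d["name"], terms=terms)


def fuzzify(value: float, variable: FuzzyVariable) -> dict[str, float]:
    """Membership degrees of a crisp value in every term of *variable*.

    Values within 1e-9 outside [0, 1] are clamped; anything further is rejected.
    """
    v = float(value)
    if v < -_CLAMP_TOL or v > 1 + _CLAMP_TOL:
        raise ValueError(f"value {v!r} outside the [0, 1] universe")
    v = min(max(v, 0.0), 1.0)
    return {name: float(mf.degree(v)) for name, mf in variable.terms}


@dataclass(frozen=True)
class FuzzyRule:
    """IF <var IS term> AND ... THEN <out_var IS term> (AND = min)."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: tuple[str, str]

    def __post_init__(self) -> None:
        ant = tuple((str(v), str(t)) for v, t in self.antecedent)
        object.__setattr__(self, "antecedent", ant)
        object.__setattr__(self, "consequent",
                           (str(self.consequent[0]), str(self.consequent[1])))
        if not ant:
            raise ValueError("rule needs at least one antecedent clause")

    def to_dict(self) -> dict:
        return {"if": [{"var": v, "is": t} for v, t in self.antecedent],
                "then": {"var": self.consequent[0], "is": self.consequent[1]}}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyRule":
        ant = tuple((c["var"], c["is"]) for c in d["if"])
        return cls(antecedent=ant, consequent=(d["then"]["var"], d["then"]["is"]))


class FuzzyInferenceSystem:
    """A Mamdani FIS from M confidence inputs to M raw-weight outputs."""

    def __init__(self,
                 inputs: Sequence[FuzzyVariable],
                 outputs: Sequence[FuzzyVariable],
                 rules: Sequence[FuzzyRule],
                 grid_step: float = 0.001):
        self.inputs = list(inputs)
        self.outputs = list(outputs)
        self.rules = list(rules)
        if not (0 < grid_step <= 0.25):
            raise ValueError(f"grid_step must be in (0, 0.25], got {grid_step}")
        self.grid_step = float(grid_step)
        self._validate_references()

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def _validate_references(self) -> None:
        in_vars = {v.name: v for v in self.inputs}
        out_vars = {v.name: v for v in self.outputs}
        if len(in_vars) != len(self.inputs) or len(out_vars) != len(self.outputs):
            raise ValueError("duplicate variable names")
        consequent_targets = set()
        for rule in self.rules:
            for var, term in rule.antecedent:
                if var not in in_vars:
                    raise ValueError(f"rule references unknown input variable {var!r}")
                in_vars[var].term(term)  # raises KeyError on unknown term
            cvar, cterm = rule.consequent
            if cvar not in out_vars:
                raise ValueError(f"rule references unknown output variable {cvar!r}")
            out_vars[cvar].term(cterm)
            consequent_targets.add(cvar)
        missing = set(out_vars) - consequent_targets
        if missing:
            raise ValueError(f"output variables never used as consequents: {sorted(missing)}")

    def infer(self, confidences: Sequence[float]) -> np.ndarray:
        """Raw (un-normalised) weights for a confidence vector.

        Mamdani min/max inference with centroid defuzzification on the
        discretised output universe.
        """
        c = np.asarray(confidences, dtype=float)
        if c.shape != (self.n_inputs,):
            raise ValueError(
                f"expected {self.n_inputs} confidences, got shape {c.shape}"
            )
        degrees = {var.name: fuzzify(ci, var) for ci, var in zip(c, self.inputs)}

        grid = np.arange(0.0, 1.0 + self.grid_step / 2, self.grid_step)
        raw = np.empty(len(self.outputs))
        for j, out_var in enumerate(self.outputs):
            agg = np.zeros_like(grid)
            for rule in self.rules:
                if rule.consequent[0] != out_var.name:
                    continue
                strength = min(degrees[var][term] for var, term in rule.antecedent)
                if strength <= 0:
                    continue
                clipped = np.minimum(strength, out_var.term(rule.consequent[1]).degree(grid))
                agg = np.maximum(agg, clipped)
            mass = agg.sum()
            # an empty aggregate (no rule fired) defuzzifies to the universe midpoint
            raw[j] = float((grid * agg).sum() / mass) if mass > 0 else 0.5
        return raw

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": FORMAT_TAG,
            "grid_step": self.grid_step,
            "defuzzifier": "centroid",
            "inputs": [v.to_dict() for v in self.inputs],
            "outputs": [v.to_dict() for v in self.outputs],
            "rules": [r.to_dict() for r in self.rules],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyInferenceSystem":
        if d.get("format") != FORMAT_TAG:
            raise ValueError(f"unsupported FIS format {d.get('format')!r}")
        if d.get("defuzzifier", "centroid") != "centroid":
            raise ValueError("only centroid defuzzification is supported")
        return cls(
            inputs=[FuzzyVariable.from_dict(v) for v in d["inputs"]],
            outputs=[FuzzyVariable.from_dict(v) for v in d["outputs"]],
            rules=[FuzzyRule.from_dict(r) for r in d["rules"]],
            grid_step=float(d.get("grid_step", 0.001)),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "FuzzyInferenceSystem":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __eq__(self, other) -> bool:
        return isinstance(other, FuzzyInferenceSystem) and self.to_dict() == other.to_dict()


def _default_terms() -> tuple[tuple[str, MembershipFunction], ...]:
    return (
        ("low", MembershipFunction("triangular", (0.0, 0.0, 0.5))),
        ("medium", MembershipFunction("triangular", (0.25, 0.5, 0.75))),
        ("high", MembershipFunction("triangular", (0.5, 1.0, 1.0))),
    )


def build_default_fis(n_models: int, grid_step: float = 0.001) -> FuzzyInferenceSystem:
    """The default symmetric, per-model-independent confidence-to-weight FIS.

    One low/medium/high triangular variable per model confidence, the same
    three terms on each raw-weight output, and the identity rule base
    low->low, medium->medium, high->high per model (M models -> 3M rules).
    """
    if n_models < 2:
        raise ValueError(f"need at least 2 models, got {n_models}")
    inputs = [FuzzyVariable(f"conf_{i + 1}", _default_terms()) for i in range(n_models)]
    outputs = [FuzzyVariable(f"weight_{i + 1}", _default_terms()) for i in range(n_models)]
    rules = [
        FuzzyRule(antecedent=((f"conf_{i + 1}", term),),
                  consequent=(f"weight_{i + 1}", term))
        for i in range(n_models)
        for term in ("low", "medium", "high")
    ]
    return FuzzyInferenceSystem(inputs, outputs, rules, grid_step=grid_step)


def infer_weights(confidences: Sequence[float], fis: FuzzyInferenceSystem) -> np.ndarray:
    """Raw weights for one confidence vector (arity-checked)."""
    return fis.infer(confidences)


def normalize_weights(raw: Sequence[float]) -> np.ndarray:
    """Normalise raw weights to a convex vector; uniform fallback on zero mass."""
    r = np.asarray(raw, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError(f"raw weights must be a non-empty vector, got shape {r.shape}")
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise ValueError("raw weights must be finite and non-negative")
    total = r.sum()
    if total < 1e-12:
        return np.full(r.size, 1.0 / r.size)
    return r / total
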