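"""Constraint: adherence of generated samples to declared validity rules.

Constraints are declarative and conjunctive — interval bounds, allowed
category sets, and implications ("if condition=anemia then hemoglobin in
[0, 12]") — evaluated per sample on either a feature matrix or a tabular
dataset. Missing tabular values fail any constraint on that field
(fail-closed for clinical rules) and are cross-flagged as missing-driven.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DataModelError, FeatureMatrix, MetricResult, TabularDataset


@dataclass
class ConstraintSpec:
    """One declarative rule on a named feature or derived measurement."""

    id: str
    target: str
    kind: str  # interval | category_set | implication
    lo: float | None = None
    hi: float | None = None
    allowed: list | None = None
    antecedent: tuple | None = None  # (feature, category or (lo, hi))
    consequent: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind == "interval":
            lo = -math.inf if self.lo is None else self.lo
            hi = math.inf if self.hi is None else self.hi
            if lo > hi:
                raise DataModelError(f"constraint {self.id}: lo > hi")
            if not (math.isfinite(lo) or math.isfinite(hi)):
                raise DataModelError(f"constraint {self.id}: need a finite bound")
        elif self.kind == "category_set":
            if not self.allowed:
                raise DataModelError(f"constraint {self.id}: empty allowed set")
        elif self.kind == "implication":
            if self.antecedent is None or self.consequent is None:
                raise DataModelError(
                    f"constraint {self.id}: implication needs antecedent and consequent"
                )
        else:
            raise DataModelError(f"constraint {self.id}: unknown kind {self.kind!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintSpec":
        d = dict(d)
        for key in ("antecedent", "consequent"):
            if key in d and isinstance(d[key], dict):
                part = d[key]
                if "allowed" in part or "category" in part:
                    cond = part.get("category", part.get("allowed"))
                else:
                    cond = (part.get("lo"), part.get("hi"))
                d[key] = (part["target"], cond)
        return cls(**d)


@dataclass
class ViolationMatrix:
    """Per-sample x per-constraint violation flags and interval depths."""

    constraint_ids: list[str]
    flags: np.ndarray  # n x m bool
    depths: np.ndarray  # n x m float, >0 iff interval violation
    missing_driven: np.ndarray  # n x m bool
    interval_margins: np.ndarray | None = None  # positive margin for satisfied pairs
    interval_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_samples(self) -> int:
        return self.flags.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, columns=self.constraint_ids)


def _column(data, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, missing mask) for a named feature/column."""
    if isinstance(data, FeatureMatrix):
        if data.feature_names is None or name not in data.feature_names:
            raise DataModelError(f"target {name!r} not found among features")
        col = data.values[:, data.feature_names.index(name)]
        return col, np.zeros(col.shape[0], dtype=bool)
    if isinstance(data, TabularDataset):
        if name not in data.frame.columns:
            raise DataModelError(f"target {name!r} not a column")
        series = data.frame[name]
        return series.to_numpy(), series.isna().to_numpy()
    raise DataModelError("constraints evaluate on FeatureMatrix or TabularDataset")


def _match_condition(values: np.ndarray, missing: np.ndarray, condition) -> np.ndarray:
    """True where the condition holds (missing never matches)."""
    if isinstance(condition, (tuple, list)) and len(condition) == 2 and all(
        c is None or isinstance(c, (int, float)) for c in condition
    ):
        lo = -math.inf if condition[0] is None else condition[0]
        hi = math.inf if condition[1] is None else condition[1]
        num = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy()
        ok = (num >= lo) & (num <= hi)
        return np.where(missing | np.isnan(num), False, ok)
    cats = condition if isinstance(condition, (list, tuple, set)) else [condition]
    cats = {str(c) for c in cats}
    ok = np.array([str(v) in cats for v in values])
    return ok & ~missing


def evaluate_constraints(data, specs: list[ConstraintSpec]) -> ViolationMatrix:
    """Exact per-sample evaluation of every constraint.

    Interval depth is ``max(lo - x, x - hi, 0)``; implications are violated
    when the antecedent holds and the consequent fails.
    """
    n = data.n if isinstance(data, FeatureMatrix) else data.n_rows
    m = len(specs)
    flags = np.zeros((n, m), dtype=bool)
    depths = np.zeros((n, m))
    margins = np.zeros((n, m))
    missing_driven = np.zeros((n, m), dtype=bool)
    interval_mask = np.zeros(m, dtype=bool)
    for j, spec in enumerate(specs):
        if spec.kind == "interval":
            interval_mask[j] = True
            values, missing = _column(data, spec.target)
            lo = -math.inf if spec.lo is None else spec.lo
            hi = math.inf if spec.hi is None else spec.hi
            num = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(dtype=float)
            bad = missing | np.isnan(num)
            num_safe = np.where(bad, (lo + hi) / 2 if math.isfinite(lo + hi) else 0.0, num)
            depth = np.maximum.reduce([lo - num_safe, num_safe - hi, np.zeros(n)])
            depth = np.where(bad, 0.0, depth)
            flags[:, j] = (depth > 0) | bad
            depths[:, j] = depth
            margin = np.minimum(num_safe - lo, hi - num_safe)
            margins[:, j] = np.where(bad | (depth > 0), 0.0, np.maximum(margin, 0.0))
            missing_driven[:, j] = bad
        elif spec.kind == "category_set":
            values, missing = _column(data, spec.target)
            ok = _match_condition(values, missing, list(spec.allowed))
            flags[:, j] = ~ok
            missing_driven[:, j] = missing
        else:  # implication
            a_feat, a_cond = spec.antecedent
            c_feat, c_cond = spec.consequent
            a_vals, a_miss = _column(data, a_feat)
            c_vals, c_miss = _column(data, c_feat)
            antecedent = _match_condition(a_vals, a_miss, a_cond)
            consequent = _match_condition(c_vals, c_miss, c_cond)
            flags[:, j] = antecedent & ~consequent
            missing_driven[:, j] = antecedent & c_miss
    return ViolationMatrix(
        constraint_ids=[s.id for s in specs],
        flags=flags,
        depths=depths,
        missing_driven=missing_driven,
        interval_margins=margins,
        interval_mask=interval_mask,
    )


def metric_violation_rate(vm: ViolationMatrix) -> MetricResult:
    """Fraction of samples violating at least one constraint; per-constraint
    rates in params. Zero constraints means vacuous satisfaction (rate 0)."""
    if vm.n_samples < 1:
        raise DataModelError("violation rate needs at least one sample")
    if vm.flags.shape[1] == 0:
        return MetricResult(
            metric="Constraint Violation Rate", raw_value=0.0,
            params={"per_constraint": {}, "n_constraints": 0},
        )
    any_violation = vm.flags.any(axis=1)
    per_constraint = {
        cid: float(vm.flags[:, j].mean()) for j, cid in enumerate(vm.constraint_ids)
    }
    return MetricResult(
        metric="Constraint Violation Rate",
        raw_value=float(any_violation.mean()),
        params={
            "per_constraint": per_constraint,
            "n_constraints": len(vm.constraint_ids),
            "missing_driven_rate": float(vm.missing_driven.any(axis=1).mean()),
        },
    )


def metric_boundary_distance(vm: ViolationMatrix) -> MetricResult:
    """Mean violation depth over all (sample, interval-constraint) pairs, with
    the mean positive margin of satisfied pairs as context in params."""
    if not vm.interval_mask.any():
        raise DataModelError("no interval constraints present")
    depths = vm.depths[:, vm.interval_mask]
    margins = vm.interval_margins[:, vm.interval_mask]
    satisfied = depths == 0.0
    mean_margin = float(margins[satisfied].mean()) if satisfied.any() else 0.0
    return MetricResult(
        metric="Distance to Constraint Boundary",
        raw_value=float(depths.mean()),
        params={"mean_satisfied_margin": mean_margin,
                "n_interval_constraints": int(vm.interval_mask.sum())},
    )


def metric_nearest_invalid(
    synthetic: FeatureMatrix, invalid_exemplars: FeatureMatrix
) -> MetricResult:
    """Mean distance from each synthetic sample to its nearest invalid
    exemplar (minimum over samples reported in params).

    Larger distances mean samples sit further from known-invalid regions; the
    published direction for this metric is ambiguous, so the normalization
    direction is configurable downstream.
    """
    from scipy.spatial.distance import cdist

    if synthetic.d != invalid_exemplars.d:
        raise DataModelError("feature dimension mismatch")
    d = cdist(synthetic.values, invalid_exemplars.values).min(axis=1)
    return MetricResult(
        metric="Nearest Invalid Datapoint",
        raw_value=float(d.mean()),
        params={"min_distance": float(d.min()), "n_exemplars": invalid_exemplars.n},
    )
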