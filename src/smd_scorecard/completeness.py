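"""Completeness metrics and the Comprehension documentation rubric.

Two disjoint completeness notions: a required field is "present" iff its
column exists at all (proportion-of-required-fields), while cell-level gaps
are counted by the missing-data percentage. The documentation-clarity rubric
quantifies human-assigned 0/1/2 scores over eight required documentation
items; it does not read documents.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import DataModelError, MetricResult, TabularDataset

REQUIRED_RUBRIC_ITEMS = (
    "generation_method",
    "parameters_listed",
    "version_history",
    "license",
    "contact",
    "limitations",
    "preprocessing",
    "intended_use",
)


@dataclass
class ClarityRubric:
    """Ordered (item id, prompt, score in {0,1,2}) documentation checklist."""

    items: list[tuple[str, str, int]]
    rater_role: str = "not provided"

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.items]
        missing = [r for r in REQUIRED_RUBRIC_ITEMS if r not in ids]
        if missing:
            raise DataModelError(f"rubric missing required items: {missing}")
        for item_id, _, score in self.items:
            if score not in (0, 1, 2):
                raise DataModelError(f"rubric item {item_id!r}: score must be 0, 1 or 2")

    @classmethod
    def from_mapping(cls, scores: dict, rater_role: str = "not provided") -> "ClarityRubric":
        items = [(k, k.replace("_", " "), int(v)) for k, v in scores.items()]
        return cls(items=items, rater_role=rater_role)


def metric_required_fields(data: TabularDataset) -> MetricResult:
    """Fraction of declared required fields that exist as columns."""
    if not data.required_fields:
        raise DataModelError("required_fields list is empty")
    present = [f for f in data.required_fields if f in data.frame.columns]
    missing = [f for f in data.required_fields if f not in data.frame.columns]
    return MetricResult(
        metric="Proportion of Required Fields",
        raw_value=len(present) / len(data.required_fields),
        params={"required": list(data.required_fields), "missing_fields": missing},
    )


def metric_missing_pct(data: TabularDataset) -> MetricResult:
    """Percentage of missing cells over the whole table, with a per-column
    breakdown in params."""
    if data.n_rows == 0 or len(data.columns) == 0:
        raise DataModelError("missing percentage needs a non-empty table")
    mask = data.missing_mask()
    total = mask.size
    pct = 100.0 * mask.to_numpy().sum() / total
    per_column = {c: float(100.0 * mask[c].mean()) for c in data.columns}
    return MetricResult(
        metric="Missing Data Percentage",
        raw_value=float(pct),
        params={"per_column_pct": per_column, "n_cells": int(total)},
    )


def metric_doc_clarity(rubric: ClarityRubric) -> MetricResult:
    """Sum of rubric item scores over the maximum (2 per item), in [0, 1]."""
    total = sum(score for _, _, score in rubric.items)
    max_total = 2 * len(rubric.items)
    return MetricResult(
        metric="Documentation Clarity Score",
        raw_value=total / max_total,
        params={
            "per_item": {item_id: score for item_id, _, score in rubric.items},
            "rater_role": rubric.rater_role,
            "origin": "human-assigned rubric scores",
        },
    )


def record_completeness_rating(scale_value: float, scale_max: float = 10) -> MetricResult:
    """Record a human completeness rating on a 1..scale_max scale, normalized
    linearly onto [0, 1]."""
    if not (1 <= scale_value <= scale_max):
        raise DataModelError(f"rating must lie in [1, {scale_max}]")
    return MetricResult(
        metric="Completeness Rating",
        raw_value=float(scale_value),
        normalized=(scale_value - 1.0) / (scale_max - 1.0),
        params={"scale_max": scale_max, "origin": "human-assigned rating"},
    )
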