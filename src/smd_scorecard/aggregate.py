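"""Direction-aware normalization, per-criterion aggregation, and labels.

Raw metric values live on incomparable scales (dB, distances, counts). A
per-metric calibration maps each onto [0, 1]: for maximize/minimize metrics a
linear ramp between configured ``worst`` and ``best`` anchors (clipped); for
band metrics a plateau at 1 inside [band_lo, band_hi] with linear decay to 0
over ``decay_width`` outside. Statistical-significance metrics are reported
but never normalized. Normalized member scores are combined per criterion by
a weighted arithmetic or geometric mean and labeled good (>= 0.80), moderate
(0.70 <= s < 0.80) or low (< 0.70) by default — thresholds are always
task-configurable, and raw values are reported alongside every aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import DataModelError, MetricResult, MetricSpec

DEFAULT_GOOD_MIN = 0.80
DEFAULT_MODERATE_MIN = 0.70


@dataclass
class CalibrationEntry:
    """Anchors mapping one metric's raw scale onto [0, 1]."""

    best: float | None = None
    worst: float | None = None
    band_lo: float | None = None
    band_hi: float | None = None
    decay_width: float | None = None
    direction_override: str | None = None
    source: str = "configured"

    def __post_init__(self) -> None:
        if self.best is not None and self.best == self.worst:
            raise DataModelError("calibration best must differ from worst")
        if self.band_lo is not None and self.band_hi is not None and self.band_lo > self.band_hi:
            raise DataModelError("band_lo must be <= band_hi")
        if self.decay_width is not None and self.decay_width <= 0:
            raise DataModelError("decay_width must be positive")


@dataclass
class Calibration:
    """Per-metric calibration table."""

    entries: dict[str, CalibrationEntry] = field(default_factory=dict)

    def get(self, metric_name: str) -> CalibrationEntry:
        try:
            return self.entries[metric_name]
        except KeyError:
            raise DataModelError(f"no calibration for metric {metric_name!r}") from None

    @classmethod
    def from_config(cls, cfg: dict) -> "Calibration":
        return cls(entries={name: CalibrationEntry(**entry) for name, entry in cfg.items()})


@dataclass
class CriterionScore:
    criterion: str
    score: float | None
    label: str | None
    weights: dict[str, float] = field(default_factory=dict)
    members: list[MetricResult] = field(default_factory=list)
    status: str = "computed"  # computed | not-applicable
    reason: str | None = None
    notes: list[str] = field(default_factory=list)


def normalize_metric(
    result: MetricResult, spec: MetricSpec, cal: CalibrationEntry
) -> MetricResult:
    """Attach a direction-aware normalized score in [0, 1] to a result.

    Stat-sig metrics are returned unchanged (reported only, never scored).
    """
    direction = cal.direction_override or spec.direction
    if direction == "stat_sig":
        return result
    v = result.raw_value
    if direction == "band":
        if cal.band_lo is None or cal.band_hi is None or cal.decay_width is None:
            raise DataModelError(
                f"band calibration for {spec.name!r} needs band_lo, band_hi, decay_width"
            )
        if cal.band_lo <= v <= cal.band_hi:
            score = 1.0
        elif v < cal.band_lo:
            score = 1.0 - (cal.band_lo - v) / cal.decay_width
        else:
            score = 1.0 - (v - cal.band_hi) / cal.decay_width
        score = float(np.clip(score, 0.0, 1.0))
    else:
        if cal.best is None or cal.worst is None:
            raise DataModelError(f"calibration for {spec.name!r} needs best and worst")
        if direction == "maximize":
            score = (v - cal.worst) / (cal.best - cal.worst)
        elif direction == "minimize":
            score = (cal.worst - v) / (cal.worst - cal.best)
        else:
            raise DataModelError(f"unknown direction {direction!r}")
        score = float(np.clip(score, 0.0, 1.0))
    out = replace(result, normalized=score)
    out.params = dict(result.params)
    out.params["calibration"] = {
        "direction": direction,
        "best": cal.best,
        "worst": cal.worst,
        "band": [cal.band_lo, cal.band_hi] if cal.band_lo is not None else None,
        "decay_width": cal.decay_width,
        "source": cal.source,
    }
    return out


def aggregate_criterion(
    criterion: str,
    results: list[MetricResult],
    weights: dict[str, float] | None = None,
    method: str = "arithmetic",
    good_min: float = DEFAULT_GOOD_MIN,
    moderate_min: float = DEFAULT_MODERATE_MIN,
) -> CriterionScore:
    """Combine normalized member metrics into one criterion score.

    Equal weights by default; weights are renormalized to sum to 1. The
    member results are retained verbatim (dual reporting).
    """
    scored = [r for r in results if r.normalized is not None]
    if not scored:
        raise DataModelError(f"criterion {criterion!r} has no normalized members")
    for r in scored:
        if not (0.0 <= r.normalized <= 1.0):
            raise DataModelError(f"member {r.metric!r} is not normalized")
    if weights is None:
        w = {r.metric: 1.0 / len(scored) for r in scored}
    else:
        missing = [r.metric for r in scored if r.metric not in weights]
        if missing:
            raise DataModelError(f"weights missing for members: {missing}")
        raw_w = np.array([float(weights[r.metric]) for r in scored])
        if np.any(raw_w < 0) or raw_w.sum() == 0:
            raise DataModelError("weights must be non-negative and not all zero")
        raw_w = raw_w / raw_w.sum()
        w = {r.metric: float(wi) for r, wi in zip(scored, raw_w)}
    scores = np.array([r.normalized for r in scored])
    wvec = np.array([w[r.metric] for r in scored])
    if method == "arithmetic":
        score = float(wvec @ scores)
    elif method == "geometric":
        score = 0.0 if np.any(scores == 0.0) else float(np.exp(wvec @ np.log(scores)))
    else:
        raise DataModelError(f"method must be arithmetic|geometric, got {method!r}")
    score = float(np.clip(score, 0.0, 1.0))
    return CriterionScore(
        criterion=criterion,
        score=score,
        label=classify_score(score, good_min, moderate_min),
        weights=w,
        members=list(results),
    )


def classify_score(
    score: float,
    good_min: float = DEFAULT_GOOD_MIN,
    moderate_min: float = DEFAULT_MODERATE_MIN,
) -> str:
    """good iff score >= good_min; moderate iff moderate_min <= score <
    good_min (boundary inclusive); low otherwise."""
    for t in (good_min, moderate_min):
        if not (0.0 <= t <= 1.0):
            raise DataModelError("thresholds must lie in [0, 1]")
    if moderate_min >= good_min:
        raise DataModelError("moderate_min must be below good_min")
    if score >= good_min:
        return "good"
    if score >= moderate_min:
        return "moderate"
    return "low"


def reference_derived_best(
    metric_fn, reference, seed: int = 0
) -> float:
    """Self-congruence baseline for reference-derived calibration: the metric
    value of a seeded half-vs-half split of the reference dataset."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(reference.n)
    half = reference.n // 2
    a = reference.take(perm[:half].tolist())
    b = reference.take(perm[half:].tolist())
    return float(metric_fn(a, b).raw_value)
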