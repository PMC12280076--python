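"""The scorecard document: model, validation, rendering, and orchestration.

A scorecard is an eight-section audit document accompanying a synthetic
dataset: general information, the seven-criterion quantitative quality
evaluation, task-based results, human-reader results, ethics notes, usage,
generation process, and reference-dataset provenance. Sections 3-5 are
recorded verbatim from user input — the library computes nothing for them.
Section 2 carries one entry per criterion, each either computed (score,
label, member metrics with raw + normalized values and parameters) or
explicitly not-applicable with a reason.

JSON output is canonical — sorted keys, floats at six significant digits —
so two runs with identical configuration and seeds produce byte-identical
documents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import compliance as compliance_mod
from . import congruence as congruence_mod
from . import constraint as constraint_mod
from . import coverage as coverage_mod
from .aggregate import (
    Calibration,
    CalibrationEntry,
    CriterionScore,
    aggregate_criterion,
    normalize_metric,
)
from .completeness import (
    ClarityRubric,
    metric_doc_clarity,
    metric_missing_pct,
    metric_required_fields,
)
from .consistency import (
    MetricRequest,
    metric_subgroup_anova,
    metric_subgroup_dispersion,
    per_subgroup_metric,
)
from .data_model import (
    CRITERIA,
    DataModelError,
    FeatureMatrix,
    ImageSet,
    MetricResult,
    MetricSpec,
    PrivacyDeclaration,
    TabularDataset,
    builtin_registry,
)
from .features import apply_embedding, fit_embedding_pipeline

SCHEMA_VERSION = "1.0"

SECTION_ORDER = [
    ("section_1_general", "1. Synthetic Data General Information"),
    ("section_2_quality", "2. Data Quality Evaluation (7 Cs Quantitative Results)"),
    ("section_3_task", "3. Task-based Evaluation (Quantitative Results)"),
    ("section_4_human", "4. Human-based Evaluation (Qualitative Results)"),
    ("section_5_ethics", "5. Ethical, Legal, and Practical Considerations"),
    ("section_6_usage", "6. Synthetic Dataset Usage"),
    ("section_7_generation", "7. Synthetic Dataset Training & Validation Process"),
    ("section_8_reference", "8. Reference Dataset General Information"),
]

SECTION_FIELDS = {
    "section_1_general": [
        "name", "release_date", "version_history", "dataset_size",
        "dataset_modality", "dataset_provenance", "intended_use",
        "dataset_labels", "attribution_licensing", "point_of_contact",
    ],
    "section_3_task": ["task_performance", "task_specific_metrics"],
    "section_4_human": ["study_design", "reader_study_results",
                        "observations_failure_cases"],
    "section_5_ethics": ["privacy_anonymization", "biases", "limitations",
                         "recommendations"],
    "section_6_usage": ["repository_access", "preprocessing_requirements",
                        "user_documentation", "intended_audience"],
    "section_7_generation": ["generation_method", "training_validation_process"],
    "section_8_reference": [
        "purpose", "origin_source", "dataset_size", "clinical_population",
        "acquisition_devices", "reference_standard", "ground_truth_labels",
        "metadata", "preprocessing", "known_limitations",
    ],
}

NOT_PROVIDED = "not provided"

FOOTER_NOTE = (
    "The good/moderate/low scheme is applied uniformly to all seven criteria; "
    "thresholds are task-configurable and should be revisited per clinical "
    "application."
)


@dataclass
class Scorecard:
    """In-memory scorecard document."""

    sections: dict = field(default_factory=dict)
    footer: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "sections": self.sections,
            "footer": self.footer,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scorecard":
        return cls(
            sections=d.get("sections", {}),
            footer=d.get("footer", {}),
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )


# --------------------------------------------------------------------------
# Canonical serialization
# --------------------------------------------------------------------------

def _canon(obj):
    """Normalize to plain JSON types; floats to 6 significant digits, NaN to
    null."""
    if isinstance(obj, dict):
        return {str(k): _canon(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canon(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if math.isnan(f) or math.isinf(f):
            return None
        if f == int(f) and abs(f) < 1e15:
            return f  # keep integral floats exact
        return float(f"{f:.6g}")
    return obj


def render_scorecard(doc: Scorecard, format: str = "json") -> str:
    """Render to canonical JSON or to Markdown (all 8 sections in template
    order; not-applicable criteria show their reason, never a blank cell)."""
    report = validate_scorecard(doc)
    if not report["ok"]:
        raise DataModelError(f"invalid scorecard: {report['violations']}")
    if format == "json":
        return json.dumps(_canon(doc.to_dict()), sort_keys=True, indent=2) + "\n"
    if format == "markdown":
        return _render_markdown(doc)
    raise DataModelError(f"format must be json|markdown, got {format!r}")


def _render_markdown(doc: Scorecard) -> str:
    lines = ["# Synthetic Medical Data (SMD) Scorecard", ""]
    for key, title in SECTION_ORDER:
        lines.append(f"## {title}")
        lines.append("")
        section = doc.sections[key]
        if key == "section_2_quality":
            lines += _render_quality_markdown(section)
        else:
            for fname in SECTION_FIELDS.get(key, sorted(section)):
                value = section.get(fname, NOT_PROVIDED)
                label = fname.replace("_", " ").title()
                lines.append(f"- **{label}**: {value}")
        lines.append("")
    note = doc.footer.get("note", FOOTER_NOTE)
    lines += ["---", "", f"*{note}*", ""]
    return "\n".join(lines)


def _render_quality_markdown(section: dict) -> list[str]:
    lines = []
    for criterion in CRITERIA:
        entry = section[criterion]
        title = criterion.capitalize()
        if entry["status"] == "not-applicable":
            lines.append(f"### {title}: not applicable — {entry['reason']}")
            lines.append("")
            continue
        score = entry.get("score")
        label = entry.get("label")
        score_txt = "n/a" if score is None else f"{score:.3f}"
        lines.append(f"### {title}: {score_txt} ({label})")
        lines.append("")
        lines.append("| Metric | Raw value | Normalized | Direction | Label |")
        lines.append("|---|---|---|---|---|")
        for m in entry.get("metrics", []):
            raw = m.get("raw_value")
            raw_txt = "n/a" if raw is None else f"{raw:.4g}"
            norm = m.get("normalized")
            norm_txt = "reported only" if norm is None else f"{norm:.3f}"
            lines.append(
                f"| {m.get('display', m['name'])} | {raw_txt} | {norm_txt} "
                f"| {m.get('direction', '')} | {m.get('note', '')} |"
            )
        lines.append("")
    return lines


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def load_schema() -> dict:
    with resources.files("smd_scorecard").joinpath("schema/scorecard.schema.json").open() as fh:
        return json.load(fh)


def _check_schema(instance, schema: dict, root: dict, path: str, out: list[str]) -> None:
    """Minimal JSON-schema subset checker: $ref, type, required, properties,
    enum, minimum/maximum, items."""
    if "$ref" in schema:
        ref = schema["$ref"]
        node = root
        for part in ref.lstrip("#/").split("/"):
            node = node[part]
        _check_schema(instance, node, root, path, out)
        return
    stype = schema.get("type")
    if stype is not None:
        types = stype if isinstance(stype, list) else [stype]
        type_map = {
            "object": dict, "array": list, "string": str,
            "number": (int, float), "integer": int, "boolean": bool,
            "null": type(None),
        }
        if not any(
            isinstance(instance, type_map[t])
            and not (t == "number" and isinstance(instance, bool))
            for t in types
        ):
            out.append(f"{path}: expected type {stype}")
            return
    if "enum" in schema and instance not in schema["enum"]:
        out.append(f"{path}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            out.append(f"{path}: {instance} below minimum {schema['minimum']}")
        if "maximum" in schema and instance > schema["maximum"]:
            out.append(f"{path}: {instance} above maximum {schema['maximum']}")
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                out.append(f"{path}: missing required field {req!r}")
        for name, sub in schema.get("properties", {}).items():
            if name in instance:
                _check_schema(instance[name], sub, root, f"{path}.{name}", out)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check_schema(item, schema["items"], root, f"{path}[{i}]", out)


def validate_scorecard(doc: Scorecard) -> dict:
    """Check structural invariants plus schema conformance.

    Returns ``{"ok": bool, "violations": [...]}`` — violations are returned,
    never raised.
    """
    violations: list[str] = []
    d = _canon(doc.to_dict())
    schema = load_schema()
    _check_schema(d, schema, schema, "$", violations)
    sections = d.get("sections", {})
    if len(sections) != 8:
        violations.append(f"document has {len(sections)} sections, expected exactly 8")
    quality = sections.get("section_2_quality", {})
    crit_entries = [c for c in quality if c in CRITERIA]
    if len(crit_entries) != 7:
        violations.append(
            f"quality section has {len(crit_entries)} criterion entries, expected 7"
        )
    for criterion, entry in quality.items():
        if not isinstance(entry, dict):
            continue
        if entry.get("status") == "not-applicable" and not entry.get("reason"):
            violations.append(f"{criterion}: not-applicable without a reason")
        if entry.get("status") == "computed":
            score = entry.get("score")
            if score is not None and not (0.0 <= score <= 1.0):
                violations.append(f"{criterion}: score {score} out of range")
            for m in entry.get("metrics", []):
                norm = m.get("normalized")
                if norm is not None and not (0.0 <= norm <= 1.0):
                    violations.append(
                        f"{criterion}/{m.get('name')}: normalized {norm} out of range"
                    )
                if "raw_value" not in m or "params" not in m:
                    violations.append(
                        f"{criterion}/{m.get('name')}: computed metric must carry "
                        "raw value and params"
                    )
    for key, fields_ in SECTION_FIELDS.items():
        section = sections.get(key, {})
        for fname in fields_:
            if fname not in section:
                violations.append(f"{key}: missing field {fname!r}")
    return {"ok": not violations, "violations": violations}


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

# Static calibration defaults; unary coverage metrics are re-anchored on the
# reference at run time (source: reference-derived).
DEFAULT_CALIBRATION = {
    "Fréchet Inception Distance": dict(best=0.0, worst=50.0),
    "Jensen-Shannon Divergence": dict(best=0.0, worst=1.0),
    "Earth Mover's Distance": dict(best=0.0, worst=5.0),
    "Cosine Similarity": dict(best=1.0, worst=0.0),
    "Distance to Centroid": dict(best=0.0, worst=10.0),
    "Precision": dict(best=1.0, worst=0.0),
    "Peak Signal-to-Noise Ratio": dict(best=50.0, worst=10.0),
    "Structural Similarity Index": dict(best=1.0, worst=0.0),
    "Recall": dict(best=1.0, worst=0.0),
    "Coverage": dict(best=1.0, worst=0.0),
    "Convex Hull Volume": dict(best=1.0, worst=0.0),
    "Vendi Score": dict(best=50.0, worst=1.0),
    "Determinantal Point Processes Score": dict(best=0.0, worst=-10.0),
    "Variance": dict(best=1.0, worst=0.0),
    "Entropy": dict(best=5.0, worst=0.0),
    "Clustering-Based Metrics": dict(best=1.0, worst=0.0),
    "Inception Score": dict(best=2.0, worst=1.0),
    "Constraint Violation Rate": dict(best=0.0, worst=1.0),
    "Distance to Constraint Boundary": dict(best=0.0, worst=1.0),
    "Nearest Invalid Datapoint": dict(best=5.0, worst=0.0, direction_override="maximize"),
    "Proportion of Required Fields": dict(best=1.0, worst=0.0),
    "Missing Data Percentage": dict(best=0.0, worst=100.0),
    "Differential Privacy Score": dict(best=0.0, worst=10.0),
    "K-Anonymity Level": dict(best=10.0, worst=1.0),
    "L-Diversity Score": dict(best=3.0, worst=1.0),
    # standard semantics: smaller t is safer, despite the printed direction
    "T-Closeness Level": dict(best=0.0, worst=1.0, direction_override="minimize"),
    "Re-identification Risk": dict(best=0.0, worst=1.0),
    "Documentation Clarity Score": dict(best=1.0, worst=0.0),
    "Subgroup Variance": dict(best=0.0, worst=10.0),
    "Maximum-Minimum Difference": dict(best=0.0, worst=10.0),
}

# Ad-hoc specs for prose metrics that have no registry row.
_EXTRA_SPECS = {
    "Re-identification Risk": MetricSpec(
        name="Re-identification Risk", criterion="compliance",
        space="embedding", arity="binary", direction="minimize",
    ),
}


def build_calibration(config: dict) -> Calibration:
    entries = {
        name: CalibrationEntry(source="default", **kw)
        for name, kw in DEFAULT_CALIBRATION.items()
    }
    for name, kw in (config.get("aggregation", {}).get("calibration", {}) or {}).items():
        entries[name] = CalibrationEntry(source="configured", **kw)
    return Calibration(entries=entries)


@dataclass
class _EvalContext:
    config: dict
    seed: int
    registry: object
    calibration: Calibration
    failures: list[dict] = field(default_factory=list)

    def spec_for(self, name: str) -> MetricSpec:
        if name in self.registry:
            return self.registry.lookup(name)
        spec = _EXTRA_SPECS.get(name)
        if spec is None:
            raise DataModelError(f"no spec for metric {name!r}")
        return spec

    def normalize(self, result: MetricResult) -> MetricResult:
        return normalize_metric(
            result, self.spec_for(result.metric), self.calibration.get(result.metric)
        )

    def record_failure(self, criterion: str, metric: str, stage: str, exc: Exception):
        self.failures.append(
            {"criterion": criterion, "metric": metric, "stage": stage,
             "error": f"{type(exc).__name__}: {exc}"}
        )


def _result_to_dict(r: MetricResult, spec: MetricSpec | None) -> dict:
    return {
        "name": r.metric,
        "display": spec.display if spec else r.metric,
        "raw_value": r.raw_value,
        "normalized": r.normalized,
        "direction": (
            r.params.get("calibration", {}).get("direction")
            or (spec.direction if spec else None)
        ),
        "per_subgroup": r.per_subgroup,
        "params": r.params,
    }


def _criterion_to_dict(ctx: _EvalContext, cs: CriterionScore) -> dict:
    def spec_or_none(name):
        try:
            return ctx.spec_for(name)
        except DataModelError:
            return None

    return {
        "status": cs.status,
        "score": cs.score,
        "label": cs.label,
        "reason": cs.reason,
        "weights": cs.weights,
        "metrics": [_result_to_dict(m, spec_or_none(m.metric)) for m in cs.members],
        "notes": cs.notes,
    }


def _not_applicable(criterion: str, reason: str) -> dict:
    return {"status": "not-applicable", "score": None, "label": None,
            "reason": reason, "weights": {}, "metrics": [], "notes": []}


def _aggregate(ctx: _EvalContext, criterion: str, results: list[MetricResult],
               notes: list[str] | None = None) -> dict:
    agg_cfg = ctx.config.get("aggregation", {}) or {}
    thresholds = agg_cfg.get("thresholds", {}) or {}
    scored = [r for r in results if r.normalized is not None]
    if not scored:
        entry = _not_applicable(criterion, "no normalizable metric succeeded")
        entry["metrics"] = [_result_to_dict(r, None) for r in results]
        return entry
    cs = aggregate_criterion(
        criterion,
        results,
        weights=(agg_cfg.get("weights", {}) or {}).get(criterion),
        method=agg_cfg.get("method", "arithmetic"),
        good_min=thresholds.get("good_min", 0.80),
        moderate_min=thresholds.get("moderate_min", 0.70),
    )
    if notes:
        cs.notes.extend(notes)
    return _criterion_to_dict(ctx, cs)


def _run_metric(ctx, criterion, name, fn, results):
    """Run one metric, normalize, and append; failures never block."""
    try:
        results.append(ctx.normalize(fn()))
    except Exception as exc:  # graceful degradation by design
        ctx.record_failure(criterion, name, "compute", exc)


def _eval_congruence(ctx, ref_emb, syn_emb, ref_images, syn_images,
                     ref_raw=None, syn_raw=None) -> dict:
    cfg = ctx.config.get("congruence", {}) or {}
    metrics = cfg.get(
        "metrics", ["fid", "jsd", "emd", "cosine", "centroid_distance", "precision"]
    )
    k = cfg.get("k", 3)
    bins = cfg.get("bins", 32)
    results: list[MetricResult] = []
    if ref_emb is None or syn_emb is None:
        return _not_applicable("congruence", "no paired embeddings available")
    table = {
        "fid": lambda: congruence_mod.metric_fid(ref_emb, syn_emb),
        "jsd": lambda: congruence_mod.metric_marginal_divergence(
            ref_emb, syn_emb, kind="jsd", bins=bins),
        "emd": lambda: congruence_mod.metric_marginal_divergence(
            ref_emb, syn_emb, kind="emd"),
        # centroid cosine on the raw feature scale: standardization zeroes the
        # reference centroid and makes the angle meaningless
        "cosine": lambda: congruence_mod.metric_centroid_alignment(
            ref_raw if ref_raw is not None else ref_emb,
            syn_raw if syn_raw is not None else syn_emb, kind="cosine"),
        "centroid_distance": lambda: congruence_mod.metric_centroid_alignment(
            ref_emb, syn_emb, kind="distance"),
        "precision": lambda: congruence_mod.metric_knn_precision(ref_emb, syn_emb, k=k),
    }
    if ref_images is not None and syn_images is not None:
        table["psnr"] = lambda: congruence_mod.metric_paired_image_similarity(
            ref_images, syn_images, kind="psnr")
        table["ssim"] = lambda: congruence_mod.metric_paired_image_similarity(
            ref_images, syn_images, kind="ssim")
    for name in metrics:
        if name in table:
            _run_metric(ctx, "congruence", name, table[name], results)
    return _aggregate(ctx, "congruence", results)


def _eval_coverage(ctx, ref_emb, syn_emb, class_probs) -> dict:
    cfg = ctx.config.get("coverage", {}) or {}
    metrics = cfg.get(
        "metrics",
        ["recall", "coverage", "hull", "vendi", "dpp", "variance", "entropy",
         "occupancy"],
    )
    if syn_emb is None:
        return _not_applicable("coverage", "no synthetic embedding available")
    k = cfg.get("k", 3)
    results: list[MetricResult] = []
    # Reference-derived anchors for unary diversity metrics: the reference's
    # own value maps to score 1.
    if ref_emb is not None:
        for name, fn in [
            ("Vendi Score", lambda: coverage_mod.metric_kernel_diversity(ref_emb, "vendi")),
            ("Variance", lambda: coverage_mod.metric_dispersion(None, ref_emb, "variance")),
            ("Entropy", lambda: coverage_mod.metric_dispersion(None, ref_emb, "entropy")),
        ]:
            try:
                base = fn().raw_value
                worst = {"Vendi Score": 1.0}.get(name, 0.0)
                if base != worst:
                    ctx.calibration.entries[name] = CalibrationEntry(
                        best=base, worst=worst, source="reference-derived")
            except Exception as exc:
                ctx.record_failure("coverage", name, "calibration", exc)
    table = {}
    if ref_emb is not None:
        table.update({
            "recall": lambda: coverage_mod.metric_knn_support(
                ref_emb, syn_emb, k=k, mode="recall"),
            "coverage": lambda: coverage_mod.metric_knn_support(
                ref_emb, syn_emb, k=k, mode="coverage"),
            "hull": lambda: coverage_mod.metric_hull_ratio(
                ref_emb, syn_emb, dims=cfg.get("hull_dims", 2)),
            "occupancy": lambda: coverage_mod.metric_cluster_occupancy(
                ref_emb, syn_emb, n_clusters=cfg.get("n_clusters", 8), seed=ctx.seed),
        })
    table.update({
        "vendi": lambda: coverage_mod.metric_kernel_diversity(syn_emb, "vendi"),
        "dpp": lambda: coverage_mod.metric_kernel_diversity(syn_emb, "dpp_logdet"),
        "variance": lambda: coverage_mod.metric_dispersion(ref_emb, syn_emb, "variance"),
        "entropy": lambda: coverage_mod.metric_dispersion(ref_emb, syn_emb, "entropy"),
    })
    if class_probs is not None:
        table["inception"] = lambda: coverage_mod.metric_inception_style_score(class_probs)
    for name in metrics:
        if name in table:
            _run_metric(ctx, "coverage", name, table[name], results)
    return _aggregate(ctx, "coverage", results)


def _eval_constraint(ctx, constraint_data, invalid_exemplars, syn_emb) -> dict:
    specs_cfg = ctx.config.get("constraints", []) or []
    if not specs_cfg or constraint_data is None:
        return _not_applicable("constraint", "no constraints declared")
    specs = [constraint_mod.ConstraintSpec.from_dict(s) for s in specs_cfg]
    results: list[MetricResult] = []
    notes = []
    try:
        vm = constraint_mod.evaluate_constraints(constraint_data, specs)
    except Exception as exc:
        ctx.record_failure("constraint", "evaluate_constraints", "evaluate", exc)
        return _not_applicable("constraint", f"constraint evaluation failed: {exc}")
    _run_metric(ctx, "constraint", "violation_rate",
                lambda: constraint_mod.metric_violation_rate(vm), results)
    if vm.interval_mask.any():
        _run_metric(ctx, "constraint", "boundary_distance",
                    lambda: constraint_mod.metric_boundary_distance(vm), results)
    if invalid_exemplars is not None and syn_emb is not None:
        _run_metric(
            ctx, "constraint", "nearest_invalid",
            lambda: constraint_mod.metric_nearest_invalid(syn_emb, invalid_exemplars),
            results)
        notes.append(
            "Nearest Invalid Datapoint is reported as a distance and normalized "
            "with larger-is-safer semantics by default; the printed direction "
            "for this metric is ambiguous and the normalization is configurable."
        )
    return _aggregate(ctx, "constraint", results, notes=notes)


def _eval_completeness(ctx, tabular) -> dict:
    if tabular is None:
        return _not_applicable("completeness", "no tabular dataset provided")
    results: list[MetricResult] = []
    if tabular.required_fields:
        _run_metric(ctx, "completeness", "required_fields",
                    lambda: metric_required_fields(tabular), results)
    _run_metric(ctx, "completeness", "missing_pct",
                lambda: metric_missing_pct(tabular), results)
    return _aggregate(ctx, "completeness", results)


def _eval_compliance(ctx, tabular, ref_emb, syn_emb) -> dict:
    cfg = ctx.config.get("compliance", {}) or {}
    results: list[MetricResult] = []
    have_any = False
    if tabular is not None and tabular.quasi_identifiers:
        have_any = True
        _run_metric(ctx, "compliance", "anonymity",
                    lambda: compliance_mod.metric_anonymity_profile(tabular), results)
        # surface l and t as their own registry metrics for dual reporting
        if results and results[-1].metric == "K-Anonymity Level":
            profile = results[-1].params["profile"]
            if profile.get("l") is not None:
                _run_metric(
                    ctx, "compliance", "l_diversity",
                    lambda: MetricResult("L-Diversity Score", float(profile["l"]),
                                         params={"from": "anonymity profile"}),
                    results)
            if profile.get("t") is not None:
                _run_metric(
                    ctx, "compliance", "t_closeness",
                    lambda: MetricResult("T-Closeness Level", float(profile["t"]),
                                         params={"from": "anonymity profile",
                                                 "semantics": "smaller is safer"}),
                    results)
    if cfg.get("dp"):
        have_any = True
        dp = cfg["dp"]
        _run_metric(
            ctx, "compliance", "dp",
            lambda: compliance_mod.record_dp_declaration(
                PrivacyDeclaration(
                    epsilon=dp.get("epsilon", 0.0), delta=dp.get("delta", 0.0),
                    mechanism=dp.get("mechanism", ""))),
            results)
    if ref_emb is not None and syn_emb is not None:
        have_any = True
        _run_metric(
            ctx, "compliance", "reid",
            lambda: compliance_mod.metric_reidentification_risk(
                ref_emb, syn_emb, theta=cfg.get("theta", 0.1)),
            results)
    if not have_any:
        return _not_applicable("compliance", "no tabular data or privacy declaration")
    return _aggregate(ctx, "compliance", results)


def _eval_comprehension(ctx) -> dict:
    cfg = ctx.config.get("comprehension", {}) or {}
    if not cfg.get("rubric"):
        return _not_applicable("comprehension", "no documentation rubric supplied")
    results: list[MetricResult] = []
    _run_metric(
        ctx, "comprehension", "doc_clarity",
        lambda: metric_doc_clarity(
            ClarityRubric.from_mapping(
                cfg["rubric"], rater_role=cfg.get("rater_role", NOT_PROVIDED))),
        results)
    return _aggregate(ctx, "comprehension", results)


def _eval_consistency(ctx, ref_emb, syn_emb) -> dict:
    cfg = ctx.config.get("consistency", {}) or {}
    if syn_emb is None or syn_emb.subgroups is None:
        return _not_applicable("consistency", "no subgroup labels on the synthetic data")
    request = MetricRequest(
        name=cfg.get("wrapped_metric_name", "Fréchet Inception Distance"),
        fn=lambda ref, syn: congruence_mod.metric_fid(ref, syn),
        binary=True,
        min_subgroup_size=cfg.get("min_subgroup_size", 5),
    )
    try:
        per_group = per_subgroup_metric(request, syn_emb, ref_emb)
    except Exception as exc:
        ctx.record_failure("consistency", request.name, "per-subgroup", exc)
        return _not_applicable("consistency", f"per-subgroup evaluation failed: {exc}")
    results: list[MetricResult] = []
    for kind in cfg.get("dispersion", ["variance", "maxmin"]):
        _run_metric(
            ctx, "consistency", kind,
            lambda kind=kind: metric_subgroup_dispersion(per_group.per_subgroup, kind),
            results)
    if cfg.get("anova", True):
        try:
            anova = metric_subgroup_anova(
                request, syn_emb, ref_emb, B=cfg.get("B", 30), seed=ctx.seed)
            results.append(anova)  # stat-sig: reported, never normalized
        except Exception as exc:
            ctx.record_failure("consistency", "anova", "compute", exc)
    entry = _aggregate(ctx, "consistency", results)
    if entry["status"] == "computed":
        entry["per_subgroup"] = {
            request.name: per_group.per_subgroup,
        }
    return entry


def _load_inputs(config: dict, data: dict | None):
    """Resolve in-memory data objects or file paths from the config."""
    data = dict(data or {})
    paths = config.get("data", {}) or {}
    feat_cfg = config.get("features", {}) or {}

    def get(key):
        return data.get(key)

    if get("reference_features") is None and paths.get("reference_features"):
        data["reference_features"] = FeatureMatrix.from_csv(paths["reference_features"])
    if get("synthetic_features") is None and paths.get("synthetic_features"):
        data["synthetic_features"] = FeatureMatrix.from_csv(paths["synthetic_features"])
    if get("reference_images") is None and paths.get("reference_images"):
        data["reference_images"] = ImageSet.from_directory(paths["reference_images"])
    if get("synthetic_images") is None and paths.get("synthetic_images"):
        data["synthetic_images"] = ImageSet.from_directory(paths["synthetic_images"])
    if get("tabular") is None and paths.get("tabular"):
        tab = paths["tabular"]
        data["tabular"] = TabularDataset.from_csv(
            tab["path"],
            required_fields=tab.get("required_fields", []),
            quasi_identifiers=tab.get("quasi_identifiers", []),
            sensitive_attribute=tab.get("sensitive_attribute"),
        )
    if get("class_probabilities") is None and paths.get("class_probabilities"):
        data["class_probabilities"] = np.loadtxt(
            paths["class_probabilities"], delimiter=",", ndmin=2)

    ref = data.get("reference_features")
    syn = data.get("synthetic_features")
    k = feat_cfg.get("embedding_dim")
    if ref is not None and syn is not None and feat_cfg.get("standardize", True):
        pipeline = fit_embedding_pipeline(ref, k=k)
        data["reference_embedding"] = apply_embedding(pipeline, ref)
        data["synthetic_embedding"] = apply_embedding(pipeline, syn)
    else:
        data["reference_embedding"] = ref
        data["synthetic_embedding"] = syn
    return data


def run_evaluation(config: dict, data: dict | None = None) -> Scorecard:
    """Run the full evaluation and assemble a scorecard.

    ``config`` is the parsed YAML mapping; ``data`` optionally supplies
    in-memory inputs (keys: reference_features, synthetic_features,
    reference_images, synthetic_images, tabular, constraint_data,
    invalid_exemplars, class_probabilities) overriding file paths. A failed
    metric never blocks the run: it is recorded as a failure note and the
    remaining metrics proceed. Deterministic given config seeds.
    """
    seed = int(config.get("seed", 0))
    ctx = _EvalContext(
        config=config, seed=seed, registry=builtin_registry(),
        calibration=build_calibration(config),
    )
    data = _load_inputs(config, data)
    ref_emb = data.get("reference_embedding")
    syn_emb = data.get("synthetic_embedding")
    constraint_data = data.get("constraint_data")
    if constraint_data is None:
        constraint_data = data.get("tabular") if (
            ctx.config.get("constraints_on", "tabular") == "tabular"
        ) else syn_emb
    quality = {
        "congruence": _eval_congruence(
            ctx, ref_emb, syn_emb,
            data.get("reference_images"), data.get("synthetic_images"),
            ref_raw=data.get("reference_features"),
            syn_raw=data.get("synthetic_features")),
        "coverage": _eval_coverage(ctx, ref_emb, syn_emb,
                                   data.get("class_probabilities")),
        "constraint": _eval_constraint(ctx, constraint_data,
                                       data.get("invalid_exemplars"), syn_emb),
        "completeness": _eval_completeness(ctx, data.get("tabular")),
        "compliance": _eval_compliance(ctx, data.get("tabular"), ref_emb, syn_emb),
        "comprehension": _eval_comprehension(ctx),
        "consistency": _eval_consistency(ctx, ref_emb, syn_emb),
    }
    card_cfg = config.get("scorecard", {}) or {}

    def section(key, cfg_key):
        fields_ = SECTION_FIELDS[key]
        given = card_cfg.get(cfg_key, {}) or {}
        return {f: given.get(f, NOT_PROVIDED) for f in fields_}

    doc = Scorecard(
        sections={
            "section_1_general": section("section_1_general", "general"),
            "section_2_quality": quality,
            "section_3_task": section("section_3_task", "task"),
            "section_4_human": section("section_4_human", "human"),
            "section_5_ethics": section("section_5_ethics", "ethics"),
            "section_6_usage": section("section_6_usage", "usage"),
            "section_7_generation": section("section_7_generation", "generation"),
            "section_8_reference": section("section_8_reference", "reference"),
        },
        footer={
            "note": FOOTER_NOTE,
            "seed": seed,
            "failures": ctx.failures,
        },
    )
    return doc


def write_scorecard(doc: Scorecard, path: str | Path, format: str = "json") -> None:
    Path(path).write_text(render_scorecard(doc, format=format))


def read_scorecard(path: str | Path) -> Scorecard:
    return Scorecard.from_dict(json.loads(Path(path).read_text()))
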