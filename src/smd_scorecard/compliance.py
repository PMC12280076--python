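"""Compliance: privacy metrics and declared differential-privacy budgets.

k-anonymity / l-diversity / t-closeness are computed exactly from the
equivalence classes of the quasi-identifier tuples. The differential-privacy
"score" is a declared, validated attribute of the generation process, never
an estimate from data. A nearest-neighbor memorization proxy quantifies
re-identification risk against the reference records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .data_model import (
    AnonymityProfile,
    DataModelError,
    FeatureMatrix,
    MetricResult,
    PrivacyDeclaration,
    TabularDataset,
)


def _sensitive_distance(class_values: pd.Series, global_values: pd.Series, kind: str) -> float:
    """Bounded [0,1] distance between a class's sensitive distribution and the
    global one: total variation for categorical, 1-D Wasserstein on
    rank-normalized values for numeric."""
    if kind == "categorical":
        p = class_values.value_counts(normalize=True)
        q = global_values.value_counts(normalize=True)
        support = p.index.union(q.index)
        return float(
            0.5 * sum(abs(p.get(v, 0.0) - q.get(v, 0.0)) for v in support)
        )
    # numeric: map every value to its normalized rank among the global values
    ranks = global_values.rank(method="average")
    n = len(global_values)
    norm = (ranks - 1.0) / (n - 1.0) if n > 1 else ranks * 0.0
    lookup = pd.Series(norm.to_numpy(), index=global_values.to_numpy())
    lookup = lookup[~lookup.index.duplicated()]
    class_norm = lookup.loc[class_values.to_numpy()].to_numpy()
    return float(wasserstein_distance(class_norm, norm.to_numpy()))


def metric_anonymity_profile(data: TabularDataset) -> MetricResult:
    """k, l and t of the release.

    Equivalence classes group identical quasi-identifier tuples; k is the
    minimum class size, l the minimum number of distinct sensitive values in
    a class, t the maximum class-vs-global sensitive-distribution distance.
    Rows with missing quasi-identifier values are excluded (count in params).
    """
    if not data.quasi_identifiers:
        raise DataModelError("anonymity profile needs quasi-identifiers")
    qi = data.quasi_identifiers
    df = data.frame
    complete = ~df[qi].isna().any(axis=1)
    excluded = int((~complete).sum())
    df = df[complete]
    if len(df) == 0:
        raise DataModelError("no rows with complete quasi-identifiers remain")
    groups = df.groupby(qi, dropna=False, sort=False, observed=True)
    sizes = groups.size()
    k = int(sizes.min())
    l_val = None
    t_val = None
    sens = data.sensitive_attribute
    if sens is not None:
        sens_kind = data.column_kinds.get(sens, "categorical")
        global_values = df[sens].dropna()
        l_val = int(min(g[sens].dropna().nunique() for _, g in groups))
        l_val = max(1, min(l_val, k))
        t_val = max(
            _sensitive_distance(g[sens].dropna(), global_values, sens_kind)
            for _, g in groups
        )
        t_val = float(min(max(t_val, 0.0), 1.0))
    profile = AnonymityProfile(k=k, l=l_val, t=t_val)
    return MetricResult(
        metric="K-Anonymity Level",
        raw_value=float(k),
        params={
            "profile": {"k": profile.k, "l": profile.l, "t": profile.t},
            "n_classes": int(len(sizes)),
            "excluded_rows_missing_qi": excluded,
            "quasi_identifiers": list(qi),
        },
    )


def record_dp_declaration(decl: PrivacyDeclaration) -> MetricResult:
    """Validate and store a declared (epsilon, delta, mechanism); the value is
    a property of the generation process, marked declared, not measured."""
    return MetricResult(
        metric="Differential Privacy Score",
        raw_value=float(decl.epsilon),
        params={
            "epsilon": decl.epsilon,
            "delta": decl.delta,
            "mechanism": decl.mechanism,
            "provenance": "declared",
        },
    )


def metric_reidentification_risk(
    reference: FeatureMatrix, synthetic: FeatureMatrix, theta: float = 0.1
) -> MetricResult:
    """Memorization proxy: the fraction of synthetic samples whose nearest
    reference record lies closer than ``theta`` times the reference's own
    median nearest-neighbor distance."""
    from scipy.spatial.distance import cdist

    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    if reference.n < 2:
        raise DataModelError("re-identification risk needs reference n >= 2")
    within = cdist(reference.values, reference.values)
    np.fill_diagonal(within, np.inf)
    baseline = float(np.median(within.min(axis=1)))
    nearest = cdist(synthetic.values, reference.values).min(axis=1)
    flagged = nearest < theta * baseline
    return MetricResult(
        metric="Re-identification Risk",
        raw_value=float(flagged.mean()),
        params={
            "theta": theta,
            "baseline_median_nn": baseline,
            "min_synthetic_to_reference": float(nearest.min()),
        },
    )
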