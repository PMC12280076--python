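"""Consistency: stability of any quality metric across subgroups or time.

Any metric callable can be wrapped and evaluated once per subgroup (binary
metrics pair like-labeled subgroups of the synthetic and reference sets).
Dispersion of the per-subgroup values is summarized by population variance or
max-min difference; statistical significance of between-subgroup differences
is assessed with a seeded bootstrap one-way ANOVA. Temporal stability uses
the same machinery with time slices as labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import f_oneway

from .data_model import DataModelError, FeatureMatrix, MetricResult


@dataclass
class MetricRequest:
    """A wrapped metric: ``fn(reference, synthetic) -> MetricResult``.

    ``reference`` is None for unary metrics. ``min_subgroup_size`` guards the
    wrapped metric's preconditions (kNN metrics need n > k)."""

    name: str
    fn: Callable[[FeatureMatrix | None, FeatureMatrix], MetricResult]
    binary: bool = True
    min_subgroup_size: int = 5


def _split_by_subgroup(data: FeatureMatrix) -> dict[str, FeatureMatrix]:
    if data.subgroups is None:
        raise DataModelError("subgroup labels are required")
    order = list(dict.fromkeys(data.subgroups))
    return {
        g: data.take([i for i, s in enumerate(data.subgroups) if s == g])
        for g in order
    }


def per_subgroup_metric(
    request: MetricRequest,
    synthetic: FeatureMatrix,
    reference: FeatureMatrix | None = None,
) -> MetricResult:
    """Evaluate the wrapped metric once per subgroup.

    raw_value is the unweighted mean of the subgroup values; the per-subgroup
    table is retained for reporting.
    """
    syn_groups = _split_by_subgroup(synthetic)
    ref_groups = _split_by_subgroup(reference) if request.binary else {}
    if request.binary:
        if reference is None:
            raise DataModelError(f"metric {request.name!r} is binary; reference required")
        unmatched = set(syn_groups) - set(ref_groups)
        if unmatched:
            raise DataModelError(f"unmatched subgroup labels: {sorted(unmatched)}")
    per_subgroup: dict[str, float] = {}
    for label, syn_g in syn_groups.items():
        if syn_g.n < request.min_subgroup_size:
            raise DataModelError(
                f"subgroup {label!r} has {syn_g.n} samples; "
                f"metric {request.name!r} needs >= {request.min_subgroup_size}"
            )
        ref_g = ref_groups.get(label) if request.binary else None
        per_subgroup[label] = request.fn(ref_g, syn_g).raw_value
    return MetricResult(
        metric=request.name,
        raw_value=float(np.mean(list(per_subgroup.values()))),
        per_subgroup=per_subgroup,
        params={"n_subgroups": len(per_subgroup)},
    )


def metric_subgroup_dispersion(
    values: dict[str, float] | list[float], kind: str = "variance"
) -> MetricResult:
    """Dispersion of per-subgroup metric values.

    ``kind='variance'`` uses the population (divide-by-m) convention — the
    subgroups are the whole population of interest, not a sample.
    ``kind='maxmin'`` is max - min.
    """
    vals = np.asarray(
        list(values.values()) if isinstance(values, dict) else values, dtype=float
    )
    if vals.size < 2:
        raise DataModelError("dispersion needs at least 2 subgroup values")
    if kind == "variance":
        value = float(vals.var(ddof=0))
        name = "Subgroup Variance"
        params = {"convention": "population", "n_subgroups": int(vals.size)}
    elif kind == "maxmin":
        value = float(vals.max() - vals.min())
        name = "Maximum-Minimum Difference"
        params = {"n_subgroups": int(vals.size)}
    else:
        raise DataModelError(f"kind must be variance|maxmin, got {kind!r}")
    return MetricResult(metric=name, raw_value=value, params=params)


def anova_from_replicates(groups: list[np.ndarray]) -> MetricResult:
    """One-way ANOVA across replicate groups; F statistic as raw value,
    p-value in params. Identical constant groups (zero between- and
    within-variance) are flagged not assessable instead of returning 0/0."""
    if len(groups) < 2:
        raise DataModelError("ANOVA needs at least 2 groups")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return MetricResult(
            metric="Analysis of Variance",
            raw_value=float("nan"),
            params={"not_assessable": True,
                    "reason": "all replicates identical across groups"},
        )
    f_stat, p_value = f_oneway(*groups)
    return MetricResult(
        metric="Analysis of Variance",
        raw_value=float(f_stat),
        params={"p_value": float(p_value), "not_assessable": False,
                "group_sizes": [int(len(g)) for g in groups]},
    )


def metric_subgroup_anova(
    request: MetricRequest,
    synthetic: FeatureMatrix,
    reference: FeatureMatrix | None = None,
    B: int = 100,
    seed: int = 0,
) -> MetricResult:
    """Bootstrap one-way ANOVA of a metric across subgroups.

    A metric yields one number per subgroup, so significance needs
    replicates: B seeded within-subgroup bootstrap resamples (rows drawn with
    replacement) give B replicate metric values per subgroup. Replicates of
    one subgroup are resamples of the same data, not independent samples, so
    the classic ANOVA F on the replicate table overstates evidence by a
    factor of about B; the reported F therefore uses the bootstrap as a
    variance estimate — between-subgroup mean square of the replicate means
    over the pooled within-subgroup replicate variance (equivalently the
    classic F divided by B), with (G-1, G(B-1)) degrees of freedom. This
    keeps the type-I rate near nominal under exchangeable subgroups.
    """
    if B < 2:
        raise DataModelError("B must be >= 2")
    syn_groups = _split_by_subgroup(synthetic)
    if len(syn_groups) < 2:
        raise DataModelError("ANOVA needs at least 2 subgroups")
    ref_groups = _split_by_subgroup(reference) if request.binary else {}
    rng = np.random.default_rng(seed)
    replicates: list[np.ndarray] = []
    for label, syn_g in syn_groups.items():
        if syn_g.n < 2:
            raise DataModelError(f"subgroup {label!r} too small to bootstrap")
        ref_g = ref_groups.get(label) if request.binary else None
        if request.binary and ref_g is None:
            raise DataModelError(f"unmatched subgroup label {label!r}")
        vals = np.empty(B)
        for b in range(B):
            idx = rng.integers(0, syn_g.n, size=syn_g.n)
            vals[b] = request.fn(ref_g, syn_g.take(idx)).raw_value
        replicates.append(vals)
    flat = np.concatenate(replicates)
    if np.all(flat == flat[0]):
        result = MetricResult(
            metric="Analysis of Variance",
            raw_value=float("nan"),
            params={"not_assessable": True,
                    "reason": "all replicates identical across groups"},
        )
    else:
        from scipy.stats import f as f_dist

        G = len(replicates)
        means = np.array([r.mean() for r in replicates])
        pooled_var = float(np.mean([r.var(ddof=1) for r in replicates]))
        msb = float(((means - means.mean()) ** 2).sum() / (G - 1))
        f_stat = msb / pooled_var
        p_value = float(f_dist.sf(f_stat, G - 1, G * (B - 1)))
        result = MetricResult(
            metric="Analysis of Variance",
            raw_value=float(f_stat),
            params={"p_value": p_value, "not_assessable": False,
                    "df": [G - 1, G * (B - 1)],
                    "dependence_correction": "replicate means vs pooled "
                                             "bootstrap variance"},
        )
    result.params.update(
        {"B": B, "seed": seed, "metric": request.name,
         "replication": "within-subgroup bootstrap"}
    )
    return result
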