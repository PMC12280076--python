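"""Coverage: does the synthetic data span the reference data's variability?

Recall/coverage on kNN manifolds, convex-hull volume ratio in a PCA plane,
kernel diversity (Vendi, DPP log-determinant), dispersion (variance trace,
histogram entropy), cluster occupancy, and an inception-style score on
user-supplied class probabilities.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .congruence import knn_radii
from .data_model import DataModelError, FeatureMatrix, MetricResult
from .features import apply_embedding, fit_embedding_pipeline


def metric_knn_support(
    reference: FeatureMatrix,
    synthetic: FeatureMatrix,
    k: int = 3,
    mode: str = "recall",
) -> MetricResult:
    """kNN-manifold recall or coverage.

    ``mode='recall'``: fraction of reference samples inside the synthetic
    kNN-radius manifold (radii from the synthetic set).
    ``mode='coverage'``: fraction of reference samples whose own kNN ball
    (radius from the reference set) contains at least one synthetic sample.
    """
    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    if mode not in ("recall", "coverage"):
        raise DataModelError(f"mode must be recall|coverage, got {mode!r}")
    radius_set = synthetic if mode == "recall" else reference
    if radius_set.n <= k:
        raise DataModelError(
            f"kNN support needs n > k on the radius-defining set "
            f"(n={radius_set.n}, k={k})"
        )
    if mode == "recall":
        radii = knn_radii(synthetic.values, k)
        d = cdist(reference.values, synthetic.values)
        inside = (d <= radii[None, :]).any(axis=1)
    else:
        radii = knn_radii(reference.values, k)
        d = cdist(reference.values, synthetic.values)
        inside = (d.min(axis=1) <= radii)
    name = "Recall" if mode == "recall" else "Coverage"
    return MetricResult(
        metric=name,
        raw_value=float(inside.mean()),
        params={"k": k, "mode": mode, "construction": "knn-manifold"},
    )


def metric_hull_ratio(
    reference: FeatureMatrix, synthetic: FeatureMatrix, dims: int = 2
) -> MetricResult:
    """Convex-hull volume of the synthetic set relative to the reference, in
    a PCA-reduced space fitted on the reference (default 2-D).

    Hull volume in the full embedding dimension is degenerate and
    exponentially costly; the reduced plane keeps the spread-proxy reading.
    """
    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    k = min(dims, reference.d)
    pipeline = fit_embedding_pipeline(reference, k=k)
    ref_z = apply_embedding(pipeline, reference).values
    syn_z = apply_embedding(pipeline, synthetic).values
    try:
        vol_ref = float(ConvexHull(ref_z).volume)
        vol_syn = float(ConvexHull(syn_z).volume)
    except QhullError as exc:
        raise DataModelError(f"degenerate point set for convex hull: {exc}") from None
    if vol_ref == 0.0:
        raise DataModelError("reference hull has zero volume")
    return MetricResult(
        metric="Convex Hull Volume",
        raw_value=vol_syn / vol_ref,
        params={"dims": k, "volume_reference": vol_ref, "volume_synthetic": vol_syn},
    )


def _cosine_kernel(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise DataModelError("zero-norm row: cosine kernel undefined")
    unit = values / norms
    return unit @ unit.T


def metric_kernel_diversity(data: FeatureMatrix, kind: str = "vendi") -> MetricResult:
    """Kernel-based diversity of a single dataset.

    The kernel is cosine similarity of L2-normalized rows (unit diagonal, so
    the eigenvalues of K/n sum to 1). ``kind='vendi'`` is the effective number
    of distinct samples exp(-sum lambda_i ln lambda_i), in [1, n];
    ``kind='dpp_logdet'`` is (1/n) ln det(K + 1e-6 I).
    """
    if kind not in ("vendi", "dpp_logdet"):
        raise DataModelError(f"kind must be vendi|dpp_logdet, got {kind!r}")
    K = _cosine_kernel(data.values)
    n = data.n
    if kind == "vendi":
        lam = np.linalg.eigvalsh(K / n)
        lam = np.clip(lam, 0.0, None)
        nz = lam[lam > 0]
        value = float(np.exp(-(nz * np.log(nz)).sum()))
        name = "Vendi Score"
        params = {"kernel": "cosine"}
    else:
        sign, logdet = np.linalg.slogdet(K + 1e-6 * np.eye(n))
        if sign <= 0:
            raise DataModelError("regularized kernel is not positive definite")
        value = float(logdet / n)
        name = "Determinantal Point Processes Score"
        params = {"kernel": "cosine", "ridge": 1e-6}
    return MetricResult(metric=name, raw_value=value, params=params)


def metric_dispersion(
    reference: FeatureMatrix | None,
    synthetic: FeatureMatrix,
    kind: str = "variance",
    bins: int = 32,
) -> MetricResult:
    """Spread of the synthetic data.

    ``kind='variance'``: trace of the synthetic sample covariance (ratio to
    the reference trace reported in params when a reference is given).
    ``kind='entropy'``: mean per-feature Shannon entropy (bits) of a 32-bin
    histogram over the synthetic range (pooled range when a reference is
    given).
    """
    if kind not in ("variance", "entropy"):
        raise DataModelError(f"kind must be variance|entropy, got {kind!r}")
    if kind == "variance":
        if synthetic.n < 2:
            raise DataModelError("variance needs n >= 2")
        value = float(np.trace(np.cov(synthetic.values, rowvar=False, ddof=1).reshape(synthetic.d, -1)))
        params: dict = {"kind": kind}
        if reference is not None:
            ref_tr = float(
                np.trace(np.cov(reference.values, rowvar=False, ddof=1).reshape(reference.d, -1))
            )
            params["reference_variance"] = ref_tr
            if ref_tr > 0:
                params["ratio_to_reference"] = value / ref_tr
        return MetricResult(metric="Variance", raw_value=value, params=params)
    entropies = []
    for j in range(synthetic.d):
        s = synthetic.values[:, j]
        lo, hi = s.min(), s.max()
        if reference is not None:
            r = reference.values[:, j]
            lo, hi = min(lo, r.min()), max(hi, r.max())
        if hi == lo:
            entropies.append(0.0)
            continue
        hist, _ = np.histogram(s, bins=bins, range=(lo, hi))
        p = hist / hist.sum()
        p = p[p > 0]
        entropies.append(float(-(p * np.log2(p)).sum()))
    return MetricResult(
        metric="Entropy",
        raw_value=float(np.mean(entropies)),
        params={"kind": kind, "bins": bins, "log_base": 2},
    )


def metric_cluster_occupancy(
    reference: FeatureMatrix,
    synthetic: FeatureMatrix,
    n_clusters: int = 8,
    seed: int = 0,
) -> MetricResult:
    """Fraction of reference-fitted k-means clusters that the synthetic data
    occupies (synthetic share >= half the uniform share 1/n_clusters)."""
    from sklearn.cluster import KMeans

    if n_clusters < 1:
        raise DataModelError("n_clusters must be >= 1")
    if reference.n < n_clusters:
        raise DataModelError("reference smaller than n_clusters")
    if synthetic.n < 1:
        raise DataModelError("synthetic set is empty")
    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(reference.values)
    labels = km.predict(synthetic.values)
    shares = np.bincount(labels, minlength=n_clusters) / synthetic.n
    threshold = 0.5 / n_clusters
    occupied = int((shares >= threshold).sum())
    return MetricResult(
        metric="Clustering-Based Metrics",
        raw_value=occupied / n_clusters,
        params={
            "n_clusters": n_clusters,
            "seed": seed,
            "occupancy_threshold": threshold,
            "cluster_shares": shares.tolist(),
        },
    )


def metric_inception_style_score(class_probabilities: np.ndarray) -> MetricResult:
    """exp of the mean KL divergence between per-sample class distributions
    and their marginal, in [1, C].

    The class-probability matrix comes from any user-chosen classifier, so the
    score is decoupled from a specific pretrained network.
    """
    P = np.asarray(class_probabilities, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise DataModelError("class probabilities must be n x C with C >= 2")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise DataModelError("rows must be probability vectors summing to 1")
    marginal = P.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(P > 0, np.log(P / marginal[None, :]), 0.0)
    kl = (P * log_ratio).sum(axis=1)
    return MetricResult(
        metric="Inception Score",
        raw_value=float(np.exp(kl.mean())),
        params={"n_classes": P.shape[1], "log": "natural"},
    )
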