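"""Congruence: alignment between the synthetic and reference distributions.

All metrics here are binary (they compare against patient data): Fréchet
distance between Gaussian moment fits, per-marginal JSD/EMD, centroid
alignment, paired image similarity (PSNR/SSIM), and kNN-manifold precision.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist, jensenshannon
from scipy.stats import wasserstein_distance

from .data_model import DataModelError, FeatureMatrix, ImageSet, MetricResult

_EIG_CLAMP = -1e-8


def metric_fid(reference: FeatureMatrix, synthetic: FeatureMatrix) -> MetricResult:
    """Fréchet distance between Gaussian fits of the two embeddings.

    ``||mu_r - mu_s||^2 + tr(S_r + S_s - 2 (S_r S_s)^{1/2})`` with sample
    means and covariances (denominator n-1). The matrix square root is
    symmetrized; tiny negative eigenvalues from finite precision are clamped
    to zero, so the value is always non-negative.
    """
    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    if reference.n < 2 or synthetic.n < 2:
        raise DataModelError("FID needs n >= 2 on both sides (covariance)")
    mu_r = reference.values.mean(axis=0)
    mu_s = synthetic.values.mean(axis=0)
    cov_r = np.cov(reference.values, rowvar=False, ddof=1).reshape(reference.d, -1)
    cov_s = np.cov(synthetic.values, rowvar=False, ddof=1).reshape(synthetic.d, -1)
    diff = mu_r - mu_s
    prod = cov_r @ cov_s
    sqrt_prod = linalg.sqrtm(prod)
    if np.iscomplexobj(sqrt_prod):
        if np.abs(sqrt_prod.imag).max() > 1e-6:
            raise DataModelError("covariance square root failed beyond tolerance")
        sqrt_prod = sqrt_prod.real
    sqrt_prod = (sqrt_prod + sqrt_prod.T) / 2.0
    eigvals = np.linalg.eigvalsh(sqrt_prod)
    if eigvals.min() < _EIG_CLAMP * max(1.0, np.abs(eigvals).max()):
        eigvals = np.clip(eigvals, 0.0, None)
        trace_sqrt = float(eigvals.sum())
    else:
        trace_sqrt = float(np.clip(eigvals, 0.0, None).sum())
    fid = float(diff @ diff + np.trace(cov_r) + np.trace(cov_s) - 2.0 * trace_sqrt)
    fid = max(fid, 0.0)
    return MetricResult(
        metric="Fréchet Inception Distance",
        raw_value=fid,
        params={"estimator": "gaussian-moment", "ddof": 1},
    )


def metric_marginal_divergence(
    reference: FeatureMatrix,
    synthetic: FeatureMatrix,
    kind: str = "jsd",
    bins: int = 32,
) -> MetricResult:
    """Mean per-feature marginal divergence.

    ``kind='jsd'``: Jensen-Shannon divergence (log base 2, each feature in
    [0, 1]) of histograms on shared bin edges spanning the pooled min-max; a
    feature whose pooled range has zero width contributes 0 and is flagged.
    ``kind='emd'``: exact 1-D Wasserstein-1 between the empirical marginals
    (sorted samples, not binned).
    """
    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    if kind not in ("jsd", "emd"):
        raise DataModelError(f"kind must be jsd|emd, got {kind!r}")
    values = []
    degenerate: list[int] = []
    for j in range(reference.d):
        r = reference.values[:, j]
        s = synthetic.values[:, j]
        if kind == "emd":
            values.append(float(wasserstein_distance(r, s)))
            continue
        lo = min(r.min(), s.min())
        hi = max(r.max(), s.max())
        if hi == lo:
            degenerate.append(j)
            values.append(0.0)
            continue
        edges = np.linspace(lo, hi, bins + 1)
        p, _ = np.histogram(r, bins=edges)
        q, _ = np.histogram(s, bins=edges)
        # jensenshannon returns the distance (sqrt of the divergence)
        values.append(float(jensenshannon(p, q, base=2) ** 2))
    name = "Jensen-Shannon Divergence" if kind == "jsd" else "Earth Mover's Distance"
    params: dict = {"kind": kind}
    if kind == "jsd":
        params.update({"bins": bins, "log_base": 2, "degenerate_features": degenerate})
    return MetricResult(metric=name, raw_value=float(np.mean(values)), params=params)


def metric_centroid_alignment(
    reference: FeatureMatrix, synthetic: FeatureMatrix, kind: str = "cosine"
) -> MetricResult:
    """Centroid-level alignment.

    ``kind='cosine'``: cosine of the angle between the two centroid vectors
    (requires both nonzero). ``kind='distance'``: mean Euclidean distance from
    synthetic samples to the reference centroid, with the reference's own mean
    distance-to-centroid reported as a baseline in params.
    """
    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    c_ref = reference.values.mean(axis=0)
    c_syn = synthetic.values.mean(axis=0)
    if kind == "cosine":
        nr, ns = np.linalg.norm(c_ref), np.linalg.norm(c_syn)
        if nr == 0.0 or ns == 0.0:
            raise DataModelError("cosine centroid alignment undefined for zero centroid")
        value = float(np.clip(c_ref @ c_syn / (nr * ns), -1.0, 1.0))
        return MetricResult(
            metric="Cosine Similarity",
            raw_value=value,
            params={"construction": "centroid-cosine"},
        )
    if kind == "distance":
        dist = float(np.linalg.norm(synthetic.values - c_ref, axis=1).mean())
        baseline = float(np.linalg.norm(reference.values - c_ref, axis=1).mean())
        return MetricResult(
            metric="Distance to Centroid",
            raw_value=dist,
            params={"reference_self_distance": baseline},
        )
    raise DataModelError(f"kind must be cosine|distance, got {kind!r}")


def metric_paired_image_similarity(
    reference: ImageSet, synthetic: ImageSet, kind: str = "ssim"
) -> MetricResult:
    """Mean paired PSNR (dB, capped at 100 for identical pairs) or mean SSIM
    (Gaussian window 11, sigma 1.5, K1=0.01, K2=0.03)."""
    from skimage.metrics import structural_similarity

    if len(reference) != len(synthetic):
        raise DataModelError("paired image metrics require equal counts")
    if reference.dynamic_range != synthetic.dynamic_range:
        raise DataModelError("paired image metrics require a shared dynamic range")
    if kind not in ("psnr", "ssim"):
        raise DataModelError(f"kind must be psnr|ssim, got {kind!r}")
    L = reference.dynamic_range
    per_pair = []
    for a, b in zip(reference.images, synthetic.images):
        if a.shape != b.shape:
            raise DataModelError("paired images must have equal shapes")
        if kind == "psnr":
            mse = float(np.mean((a - b) ** 2))
            per_pair.append(100.0 if mse == 0.0 else float(10.0 * np.log10(L * L / mse)))
        else:
            per_pair.append(
                float(
                    structural_similarity(
                        a,
                        b,
                        data_range=L,
                        gaussian_weights=True,
                        sigma=1.5,
                        win_size=11,
                        use_sample_covariance=False,
                        K1=0.01,
                        K2=0.03,
                    )
                )
            )
    name = "Peak Signal-to-Noise Ratio" if kind == "psnr" else "Structural Similarity Index"
    params: dict = {"per_pair": per_pair}
    if kind == "psnr":
        params["cap_db"] = 100.0
    else:
        params.update({"window": 11, "sigma": 1.5, "K1": 0.01, "K2": 0.03})
    return MetricResult(metric=name, raw_value=float(np.mean(per_pair)), params=params)


def knn_radii(points: np.ndarray, k: int) -> np.ndarray:
    """Distance from each point to its k-th nearest neighbor within the set
    (self excluded)."""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    return dist[:, k]


def metric_knn_precision(
    reference: FeatureMatrix, synthetic: FeatureMatrix, k: int = 3
) -> MetricResult:
    """kNN-manifold precision: the fraction of synthetic samples lying inside
    the union of balls centered at reference points with radius equal to each
    point's distance to its k-th nearest reference neighbor."""
    if reference.d != synthetic.d:
        raise DataModelError("feature dimension mismatch")
    if reference.n <= k:
        raise DataModelError(f"precision needs reference n > k (n={reference.n}, k={k})")
    radii = knn_radii(reference.values, k)
    d = cdist(synthetic.values, reference.values)
    inside = (d <= radii[None, :]).any(axis=1)
    return MetricResult(
        metric="Precision",
        raw_value=float(inside.mean()),
        params={"k": k, "construction": "knn-manifold"},
    )
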