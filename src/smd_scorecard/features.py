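"""Feature-space construction: standardization, PCA, simple extractors.

The evaluation convention is fit-on-reference-only: the embedding pipeline
(per-feature centering/scaling and optional PCA projection) is estimated from
the reference (patient) data alone and applied identically to both datasets,
so the synthetic data cannot influence the space it is judged in.

The image and text extractors are deterministic and training-free; externally
computed embeddings (e.g. from a pretrained network) can always be supplied
as a feature CSV instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .data_model import DataModelError, FeatureMatrix, ImageSet

IMAGE_FEATURE_NAMES = [
    "mean_intensity",
    "std_intensity",
    "p05_intensity",
    "p95_intensity",
    "histogram_entropy_bits",
    "grad_h_mean_abs",
    "grad_v_mean_abs",
    "foreground_fraction",
]


@dataclass
class EmbeddingPipeline:
    """Standardize-then-project transform fitted on reference data only."""

    per_feature_center: np.ndarray
    per_feature_scale: np.ndarray
    projection: np.ndarray | None = None  # d x k orthonormal columns
    fitted_on: str = "reference"

    def __post_init__(self) -> None:
        self.per_feature_center = np.asarray(self.per_feature_center, dtype=float)
        self.per_feature_scale = np.asarray(self.per_feature_scale, dtype=float)
        if self.projection is not None:
            self.projection = np.asarray(self.projection, dtype=float)
            gram = self.projection.T @ self.projection
            if not np.allclose(gram, np.eye(self.projection.shape[1]), atol=1e-8):
                raise DataModelError("projection columns must be orthonormal")

    @property
    def d(self) -> int:
        return self.per_feature_center.shape[0]

    @property
    def k(self) -> int:
        return self.projection.shape[1] if self.projection is not None else self.d


def fit_embedding_pipeline(
    reference: FeatureMatrix, k: int | None = None
) -> EmbeddingPipeline:
    """Fit centering/scaling and, when ``k`` is given, a top-``k`` PCA
    projection on the reference.

    Zero-variance features get unit scale (their standardized values are 0).
    The eigen-sign of each principal direction is fixed by making its
    largest-magnitude loading positive, so outputs are bit-stable.
    """
    if reference.n < 2:
        raise DataModelError("pipeline fitting needs n >= 2 reference samples")
    d = reference.d
    if k is not None and not (1 <= k <= d):
        raise DataModelError(f"k must lie in [1, {d}], got {k}")
    center = reference.values.mean(axis=0)
    scale = reference.values.std(axis=0, ddof=1)
    scale = np.where(scale == 0.0, 1.0, scale)
    projection = None
    if k is not None:
        z = (reference.values - center) / scale
        # SVD of the centered standardized matrix; right singular vectors are
        # the principal directions.
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        comps = vt[:k]
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        projection = comps.T
    return EmbeddingPipeline(
        per_feature_center=center, per_feature_scale=scale, projection=projection
    )


def apply_embedding(pipeline: EmbeddingPipeline, data: FeatureMatrix) -> FeatureMatrix:
    """Standardize then (optionally) project; ids and subgroups carry through."""
    if data.d != pipeline.d:
        raise DataModelError(
            f"dimension mismatch: data d={data.d}, pipeline d={pipeline.d}"
        )
    z = (data.values - pipeline.per_feature_center) / pipeline.per_feature_scale
    if pipeline.projection is not None:
        z = z @ pipeline.projection
        names = [f"pc{i + 1}" for i in range(z.shape[1])]
    else:
        names = data.feature_names
    return FeatureMatrix(
        values=z,
        sample_ids=data.sample_ids,
        subgroups=data.subgroups,
        feature_names=names,
    )


def extract_image_features(images: ImageSet) -> FeatureMatrix:
    """Fixed 8-feature descriptor per image.

    Order-stable: mean, standard deviation, 5th and 95th percentile, Shannon
    entropy of the 32-bin intensity histogram over [0, L] in bits, mean
    absolute horizontal gradient, mean absolute vertical gradient, and
    foreground fraction (pixels above the image's Otsu threshold; 0 for a
    constant image, where no threshold exists).
    """
    from skimage.filters import threshold_otsu

    L = images.dynamic_range
    rows = []
    for im in images.images:
        if im.ndim != 2:
            raise DataModelError("image descriptor requires 2-D images")
        hist, _ = np.histogram(im, bins=32, range=(0.0, L))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy_bits = float(-(p * np.log2(p)).sum())
        grad_h = float(np.abs(np.diff(im, axis=1)).mean()) if im.shape[1] > 1 else 0.0
        grad_v = float(np.abs(np.diff(im, axis=0)).mean()) if im.shape[0] > 1 else 0.0
        if im.min() == im.max():
            fg = 0.0
        else:
            fg = float((im > threshold_otsu(im)).mean())
        rows.append(
            [
                float(im.mean()),
                float(im.std()),
                float(np.percentile(im, 5)),
                float(np.percentile(im, 95)),
                entropy_bits,
                grad_h,
                grad_v,
                fg,
            ]
        )
    return FeatureMatrix(
        values=np.asarray(rows),
        sample_ids=images.ids,
        feature_names=list(IMAGE_FEATURE_NAMES),
    )


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def extract_text_features(
    documents: list[str], vocabulary: list[str] | None = None
) -> FeatureMatrix:
    """Bag-of-token-count features, rows L2-normalized.

    Tokenization lowercases and splits on non-alphanumeric characters. When no
    vocabulary is given it is built from the corpus, sorted lexicographically.
    All-zero rows (no in-vocabulary tokens) are left as zeros.
    """
    if not documents:
        raise DataModelError("document list must be non-empty")
    token_lists = [_TOKEN_RE.findall(doc.lower()) for doc in documents]
    if vocabulary is None:
        vocabulary = sorted({t for toks in token_lists for t in toks})
    if not vocabulary:
        raise DataModelError("empty vocabulary after tokenization")
    index = {t: i for i, t in enumerate(vocabulary)}
    counts = np.zeros((len(documents), len(vocabulary)))
    for r, toks in enumerate(token_lists):
        for t in toks:
            i = index.get(t)
            if i is not None:
                counts[r, i] += 1.0
    norms = np.linalg.norm(counts, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return FeatureMatrix(values=counts / norms, feature_names=list(vocabulary))


def select_local(data, selector):
    """Subset samples for local (region/cohort-specific) assessment.

    ``selector`` is either a list of sample ids or a boolean mask. The subset
    keeps the original order; running any metric on it constitutes the local
    assessment.
    """
    n = data.n if isinstance(data, FeatureMatrix) else len(data)
    selector = list(selector)
    if all(isinstance(s, (bool, np.bool_)) for s in selector) and selector:
        if len(selector) != n:
            raise DataModelError("boolean mask length mismatch")
        indices = [i for i, keep in enumerate(selector) if keep]
    else:
        ids = data.sample_ids if isinstance(data, FeatureMatrix) else data.ids
        if ids is None:
            raise DataModelError("id selection requires sample ids")
        pos = {s: i for i, s in enumerate(ids)}
        try:
            indices = sorted(pos[str(s)] for s in selector)
        except KeyError as exc:
            raise DataModelError(f"unknown sample id {exc.args[0]!r}") from None
    if not indices:
        raise DataModelError("empty selection: metrics need at least one sample")
    return data.take(indices)
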