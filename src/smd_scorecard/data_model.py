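"""Core containers, the built-in metric registry, and request validation.

Every quality metric in this package operates on one of three containers:

* :class:`FeatureMatrix` — an ``n x d`` numeric embedding of a dataset, the
  space where distributional metrics (FID, precision/recall, Vendi, ...) live;
* :class:`ImageSet` — paired grayscale images for pixel-space metrics
  (PSNR, SSIM);
* :class:`TabularDataset` — typed records with declared column roles for
  completeness and privacy metrics.

The registry mirrors one row per published example metric, grouped under the
seven evaluation criteria: congruence, coverage, constraint, completeness,
compliance, comprehension and consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CRITERIA = (
    "congruence",
    "coverage",
    "constraint",
    "completeness",
    "compliance",
    "comprehension",
    "consistency",
)

SPACES = (
    "embedding",
    "image",
    "metadata",
    "data_attribute",
    "documentation",
    "quality_metrics",
)

DIRECTIONS = ("maximize", "minimize", "band", "stat_sig")

# Reserved column names in FeatureMatrix CSV files.
RESERVED_COLUMNS = ("sample_id", "subgroup")

MISSING_MARKER = ""  # empty CSV field


class DataModelError(ValueError):
    """Raised on malformed containers or invalid metric requests."""


@dataclass
class FeatureMatrix:
    """An ``n x d`` numeric embedding with optional sample metadata.

    Missingness is a tabular concept: feature matrices must be finite
    everywhere.
    """

    values: np.ndarray
    sample_ids: list[str] | None = None
    subgroups: list[str] | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        if self.values.ndim != 2:
            raise DataModelError("FeatureMatrix values must be 2-D")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise DataModelError("FeatureMatrix needs n >= 1 and d >= 1")
        if not np.all(np.isfinite(self.values)):
            raise DataModelError("FeatureMatrix values must be finite (no NaN/Inf)")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise DataModelError("sample_ids length mismatch")
            if len(set(self.sample_ids)) != n:
                raise DataModelError("sample_ids must be unique")
        if self.subgroups is not None:
            self.subgroups = [str(s) for s in self.subgroups]
            if len(self.subgroups) != n:
                raise DataModelError("subgroups length mismatch")
        if self.feature_names is not None:
            self.feature_names = [str(s) for s in self.feature_names]
            if len(self.feature_names) != d:
                raise DataModelError("feature_names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def take(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx] if self.sample_ids else None,
            subgroups=[self.subgroups[i] for i in idx] if self.subgroups else None,
            feature_names=self.feature_names,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        """Load from CSV: optional ``sample_id``/``subgroup`` columns, the
        rest numeric features."""
        df = pd.read_csv(path)
        sample_ids = df["sample_id"].astype(str).tolist() if "sample_id" in df else None
        subgroups = df["subgroup"].astype(str).tolist() if "subgroup" in df else None
        feats = df.drop(columns=[c for c in RESERVED_COLUMNS if c in df])
        return cls(
            values=feats.to_numpy(dtype=float),
            sample_ids=sample_ids,
            subgroups=subgroups,
            feature_names=list(feats.columns),
        )

    def to_csv(self, path: str | Path) -> None:
        names = self.feature_names or [f"f{i}" for i in range(self.d)]
        df = pd.DataFrame(self.values, columns=names)
        if self.subgroups is not None:
            df.insert(0, "subgroup", self.subgroups)
        if self.sample_ids is not None:
            df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)


@dataclass
class ImageSet:
    """Grayscale images with a shared dynamic range ``L``."""

    images: list[np.ndarray]
    dynamic_range: float = 255.0
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.images:
            raise DataModelError("ImageSet must contain at least one image")
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        for im in self.images:
            if im.ndim != 2:
                raise DataModelError("images must be 2-D grayscale arrays")
            if im.min() < 0 or im.max() > self.dynamic_range:
                raise DataModelError("intensities must lie in [0, dynamic_range]")
        if self.ids is not None and len(self.ids) != len(self.images):
            raise DataModelError("ids length mismatch")

    def __len__(self) -> int:
        return len(self.images)

    def take(self, indices: Sequence[int]) -> "ImageSet":
        idx = list(indices)
        return ImageSet(
            images=[self.images[i] for i in idx],
            dynamic_range=self.dynamic_range,
            ids=[self.ids[i] for i in idx] if self.ids else None,
        )

    @classmethod
    def from_directory(
        cls,
        directory: str | Path,
        dynamic_range: float = 255.0,
        manifest: Sequence[str] | None = None,
    ) -> "ImageSet":
        """Load PNGs from a directory, lexicographic order unless an explicit
        filename manifest is given."""
        from PIL import Image

        directory = Path(directory)
        if manifest is None:
            files = sorted(directory.glob("*.png"))
        else:
            files = [directory / name for name in manifest]
        if not files:
            raise DataModelError(f"no PNG images found in {directory}")
        images, ids = [], []
        for f in files:
            with Image.open(f) as im:
                images.append(np.asarray(im.convert("L"), dtype=float))
            ids.append(f.stem)
        return cls(images=images, dynamic_range=dynamic_range, ids=ids)

    def to_directory(self, directory: str | Path) -> None:
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ids = self.ids or [f"img_{i:04d}" for i in range(len(self.images))]
        for name, im in zip(ids, self.images):
            arr = np.clip(np.round(im), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(directory / f"{name}.png")


@dataclass
class TabularDataset:
    """Typed records with declared roles for completeness/privacy metrics.

    ``required_fields`` may name absent columns — that absence is exactly what
    the completeness metric measures. Missing cells are represented as NaN /
    None in the underlying frame.
    """

    frame: pd.DataFrame
    column_kinds: dict[str, str] = field(default_factory=dict)
    required_fields: list[str] = field(default_factory=list)
    quasi_identifiers: list[str] = field(default_factory=list)
    sensitive_attribute: str | None = None

    def __post_init__(self) -> None:
        cols = set(self.frame.columns)
        for qi in self.quasi_identifiers:
            if qi not in cols:
                raise DataModelError(f"quasi-identifier {qi!r} not a column")
        if self.sensitive_attribute is not None and self.sensitive_attribute not in cols:
            raise DataModelError(
                f"sensitive attribute {self.sensitive_attribute!r} not a column"
            )
        for name, kind in self.column_kinds.items():
            if kind not in ("numeric", "categorical"):
                raise DataModelError(f"unknown column kind {kind!r} for {name!r}")
        # Infer kinds for undeclared columns from dtypes.
        for c in self.frame.columns:
            if c not in self.column_kinds:
                self.column_kinds[c] = (
                    "numeric" if pd.api.types.is_numeric_dtype(self.frame[c]) else "categorical"
                )

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        required_fields: Sequence[str] = (),
        quasi_identifiers: Sequence[str] = (),
        sensitive_attribute: str | None = None,
        missing_alias: str | None = None,
    ) -> "TabularDataset":
        na_values = [MISSING_MARKER]
        if missing_alias:
            na_values.append(missing_alias)
        df = pd.read_csv(path, na_values=na_values, keep_default_na=False)
        return cls(
            frame=df,
            required_fields=list(required_fields),
            quasi_identifiers=list(quasi_identifiers),
            sensitive_attribute=sensitive_attribute,
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, na_rep=MISSING_MARKER)


@dataclass(frozen=True)
class MetricSpec:
    """One registry row: what a metric measures and how to interpret it."""

    name: str
    criterion: str
    space: str
    arity: str  # "unary" | "binary"
    direction: str
    image_only: bool = False
    display_name: str | None = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise DataModelError(f"unknown criterion {self.criterion!r}")
        if self.space not in SPACES:
            raise DataModelError(f"unknown space {self.space!r}")
        if self.arity not in ("unary", "binary"):
            raise DataModelError(f"arity must be unary|binary, got {self.arity!r}")
        if self.direction not in DIRECTIONS:
            raise DataModelError(f"unknown direction {self.direction!r}")

    @property
    def display(self) -> str:
        return self.display_name or self.name


@dataclass
class MetricResult:
    """A computed metric value with full provenance.

    ``params`` records every tunable that affected ``raw_value`` — the
    reproducibility contract behind dual reporting.
    """

    metric: str
    raw_value: float
    per_subgroup: dict[str, float] | None = None
    normalized: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.normalized is not None and not (0.0 <= self.normalized <= 1.0):
            raise DataModelError("normalized score must lie in [0, 1]")


@dataclass
class PrivacyDeclaration:
    """Declared differential-privacy budget of the generation process."""

    epsilon: float
    delta: float
    mechanism: str = ""

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise DataModelError("epsilon must be non-negative")
        if not (0.0 <= self.delta < 1.0):
            raise DataModelError("delta must lie in [0, 1)")


@dataclass
class AnonymityProfile:
    """k-anonymity / l-diversity / t-closeness of a tabular release."""

    k: int
    l: int | None = None
    t: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DataModelError("k must be >= 1")
        if self.l is not None and not (1 <= self.l <= self.k):
            raise DataModelError("l must satisfy 1 <= l <= k")
        if self.t is not None and not (0.0 <= self.t <= 1.0):
            raise DataModelError("t must lie in [0, 1]")


# --------------------------------------------------------------------------
# Metric registry
# --------------------------------------------------------------------------

def _spec(name, criterion, space, arity, direction, image_only=False, display=None):
    return MetricSpec(
        name=name,
        criterion=criterion,
        space=space,
        arity=arity,
        direction=direction,
        image_only=image_only,
        display_name=display,
    )


_BUILTIN_ROWS = [
    # congruence (8)
    _spec("Cosine Similarity", "congruence", "embedding", "binary", "maximize"),
    _spec("Earth Mover's Distance", "congruence", "embedding", "binary", "minimize"),
    _spec("Jensen-Shannon Divergence", "congruence", "embedding", "binary", "minimize"),
    _spec("Peak Signal-to-Noise Ratio", "congruence", "image", "binary", "maximize", True),
    _spec("Structural Similarity Index", "congruence", "image", "binary", "maximize", True),
    _spec("Fréchet Inception Distance", "congruence", "embedding", "binary", "minimize", True),
    _spec("Distance to Centroid", "congruence", "embedding", "binary", "minimize"),
    _spec("Precision", "congruence", "embedding", "binary", "maximize"),
    # coverage (9)
    _spec("Inception Score", "coverage", "image", "unary", "maximize", True),
    _spec("Recall", "coverage", "embedding", "binary", "maximize"),
    _spec("Coverage", "coverage", "embedding", "binary", "maximize"),
    _spec("Convex Hull Volume", "coverage", "embedding", "unary", "maximize"),
    _spec("Determinantal Point Processes Score", "coverage", "embedding", "unary", "maximize"),
    _spec("Vendi Score", "coverage", "embedding", "unary", "maximize"),
    _spec("Variance", "coverage", "embedding", "unary", "maximize"),
    _spec("Entropy", "coverage", "embedding", "unary", "maximize"),
    _spec("Clustering-Based Metrics", "coverage", "embedding", "unary", "maximize"),
    # constraint (3)
    _spec("Nearest Invalid Datapoint", "constraint", "embedding", "binary", "minimize"),
    _spec("Distance to Constraint Boundary", "constraint", "embedding", "binary", "minimize"),
    _spec("Constraint Violation Rate", "constraint", "embedding", "binary", "minimize"),
    # completeness (2)
    _spec("Proportion of Required Fields", "completeness", "metadata", "binary", "maximize"),
    _spec("Missing Data Percentage", "completeness", "metadata", "binary", "minimize"),
    # compliance (4)
    _spec("Differential Privacy Score", "compliance", "data_attribute", "unary", "minimize"),
    _spec("K-Anonymity Level", "compliance", "data_attribute", "unary", "maximize"),
    _spec("L-Diversity Score", "compliance", "data_attribute", "unary", "maximize"),
    _spec("T-Closeness Level", "compliance", "data_attribute", "unary", "maximize"),
    # comprehension (1)
    _spec("Documentation Clarity Score", "comprehension", "documentation", "unary", "maximize"),
    # consistency (3); "Variance" is already taken by the coverage row, so the
    # quality-metrics dispersion row gets a qualified registry key.
    _spec("Subgroup Variance", "consistency", "quality_metrics", "unary", "minimize",
          display="Variance"),
    _spec("Maximum-Minimum Difference", "consistency", "quality_metrics", "unary", "minimize"),
    _spec("Analysis of Variance", "consistency", "quality_metrics", "unary", "stat_sig"),
]


class MetricRegistry:
    """Name-keyed collection of :class:`MetricSpec`, extensible by users."""

    def __init__(self, specs: Iterable[MetricSpec]):
        self._specs: dict[str, MetricSpec] = {}
        for s in specs:
            self.register(s)

    def register(self, spec: MetricSpec) -> None:
        if spec.name in self._specs:
            raise DataModelError(f"metric {spec.name!r} is already registered")
        self._specs[spec.name] = spec

    def lookup(self, name: str) -> MetricSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise DataModelError(f"unknown metric {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def by_criterion(self, criterion: str) -> list[MetricSpec]:
        return [s for s in self._specs.values() if s.criterion == criterion]


def builtin_registry() -> MetricRegistry:
    """The built-in registry: 30 example metrics partitioned over the seven
    criteria as 8/9/3/2/4/1/3."""
    return MetricRegistry(_BUILTIN_ROWS)


# --------------------------------------------------------------------------
# Request validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidatedRequest:
    spec: MetricSpec
    synthetic: object
    reference: object | None


def validate_request(spec: MetricSpec, synthetic, reference=None) -> ValidatedRequest:
    """Check a metric request against the metric's declared arity and space.

    Idempotent and side-effect-free: binary metrics need a reference, image
    metrics need ImageSets, embedding metrics need FeatureMatrices of equal
    feature dimension.
    """
    if synthetic is None:
        raise DataModelError("synthetic dataset is required")
    if spec.arity == "binary" and reference is None:
        raise DataModelError(
            f"metric {spec.name!r} is binary and requires a reference dataset"
        )
    if spec.space == "image":
        for obj, label in ((synthetic, "synthetic"), (reference, "reference")):
            if obj is not None and not isinstance(obj, ImageSet):
                raise DataModelError(
                    f"metric {spec.name!r} operates on images; {label} is not an ImageSet"
                )
    elif spec.space == "embedding":
        for obj, label in ((synthetic, "synthetic"), (reference, "reference")):
            if obj is not None and not isinstance(obj, FeatureMatrix):
                raise DataModelError(
                    f"metric {spec.name!r} operates on embeddings; {label} is not a FeatureMatrix"
                )
        if isinstance(reference, FeatureMatrix) and synthetic.d != reference.d:
            raise DataModelError(
                f"feature dimension mismatch: synthetic d={synthetic.d}, "
                f"reference d={reference.d}"
            )
    return ValidatedRequest(spec=spec, synthetic=synthetic, reference=reference)
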