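# Methods

This note documents the statistical procedures, the tunable parameters that
matter, the numerical conventions, and the limits of what the test suite can
show. It is the package's own account of its choices; configuration keys
named below live in the evaluation YAML.

## Feature space

Most metrics operate on an `n × d` feature embedding. The embedding pipeline
(per-feature centering and scaling, optional top-k PCA projection) is fitted
on the **reference data only** and applied identically to both datasets, so
the synthetic data cannot influence the frame it is judged in. Zero-variance
features get unit scale (their standardized values are 0). PCA is computed
by SVD of the standardized reference with the eigen-sign fixed by making
each component's largest-magnitude loading positive, which makes outputs
bit-stable across runs. The built-in image descriptor (8 deterministic
intensity/gradient/shape features) and bag-of-token text features are
training-free stand-ins chosen so the artifact needs no model weights; any
externally computed embedding can be supplied as a feature CSV instead, and
every result records the extractor identity in its parameters rather than
claiming canonical values. Local (region- or cohort-specific) assessment is
plain row subsetting before metric evaluation.

## Metric conventions

- **FID** uses sample moments (denominator `n − 1`) and a symmetrized matrix
  square root with tiny negative eigenvalues (> −1e−8 relative) clamped to
  zero; it is computed on whatever embedding is supplied, not tied to a
  specific pretrained network.
- **JSD** bins each marginal on shared edges spanning the pooled min–max
  (default 32 bins, log base 2, so each feature's value lies in [0, 1]); a
  zero-width pooled range contributes 0 and is flagged. **EMD** is the exact
  1-D Wasserstein-1 per marginal, averaged over features.
- **PSNR** is capped at 100 dB for identical pairs; **SSIM** uses the
  de-facto standard parameterization (Gaussian window 11, σ = 1.5,
  K1 = 0.01, K2 = 0.03), frozen in the result parameters.
- **kNN precision / recall / coverage** use the kNN-radius manifold
  construction with k = 3 by default (self excluded from neighbor counts).
- **Convex-hull volume** is a ratio (synthetic/reference) in a PCA plane
  (default 2-D) fitted on the reference: full-dimensional hulls are
  degenerate and exponentially costly, while the reduced plane keeps the
  spread-proxy reading.
- **Vendi / DPP** share a cosine-similarity kernel on L2-normalized rows;
  the unit diagonal makes the eigenvalues of `K/n` sum to 1. The DPP score
  is `(1/n) log det(K + 1e−6 I)`.
- **Cluster occupancy**: k-means (seeded, 10 restarts) fitted on the
  reference; a cluster counts as occupied when the synthetic share reaches
  half the uniform share `0.5/n_clusters` — a scale-free threshold recorded
  in the parameters.
- **Centroid cosine** is computed on the raw feature scale: after
  standardization the reference centroid is the origin and the angle is
  meaningless. Whether "cosine similarity" should mean centroid cosine or
  mean pairwise cosine is ambiguous; the construction used is recorded in
  the result parameters.
- **Constraints** are conjunctive, declarative rules (interval, category
  set, implication). Interval depth is `max(lo − x, x − hi, 0)`. Missing
  tabular values fail any constraint on that field (fail-closed for clinical
  rules) and are cross-flagged as missing-driven. The violation rate with
  zero declared constraints is 0 (vacuous satisfaction).
- **Anonymity**: equivalence classes are groups of identical
  quasi-identifier tuples; rows with missing quasi-identifiers are excluded
  and counted. t-closeness uses total variation distance for categorical
  sensitive attributes and 1-D Wasserstein on rank-normalized values for
  numeric ones — both bounded in [0, 1] so direction normalization is
  well-defined. The differential-privacy entry is a *declared, validated*
  (ε, δ, mechanism) attribute of the generation process, never an estimate
  from data. Re-identification risk is a memorization proxy: the fraction of
  synthetic samples whose nearest reference record lies closer than
  θ (default 0.1) times the reference's own median nearest-neighbor
  distance.
- **Consistency** wraps any metric and evaluates it once per subgroup
  (binary metrics pair like-labeled subgroups). Dispersion uses the
  population (divide-by-m) variance convention — the subgroups are the whole
  population of interest — or max − min. Temporal stability is the same
  machinery with time slices as labels.

## Bootstrap ANOVA

A metric yields one number per subgroup, so statistical significance needs
replicates: B (default 100) seeded within-subgroup bootstrap resamples give
B replicate metric values per subgroup. Replicates of one subgroup are
resamples of the same data, not independent observations; the classic
one-way F on the replicate table overstates evidence by a factor of roughly
B and rejects a true null far too often. The reported statistic therefore
uses the bootstrap as a variance estimate: the between-subgroup mean square
of the replicate means divided by the pooled within-subgroup replicate
variance (equivalently the classic F divided by B), with (G − 1, G(B − 1))
degrees of freedom. Simulation puts the type-I rate near the nominal 5%
with full power against a planted subgroup shift. Groups whose replicates
are all identical are flagged *not assessable* rather than scored 0/0, and
significance metrics are reported but never folded into criterion scores.

Note that for a binary wrapped metric the bootstrap captures within-subgroup
sampling variability only; genuine between-subgroup heterogeneity of the
underlying populations (each clinical site having its own case mix) will
register as significant, which is exactly what the consistency criterion is
meant to surface.

## Normalization, aggregation, thresholds

Each metric carries a calibration: `best`/`worst` anchors for a linear
clipped ramp (maximize/minimize), or a `[band_lo, band_hi]` plateau with a
linear decay over `decay_width` for band-type targets (e.g. a coverage
target range of 80–85% scoring 1 inside the band). Built-in defaults exist
for every bundled metric; unary diversity metrics (Vendi, variance, entropy)
are re-anchored at run time on the reference's own value (source:
reference-derived) when a reference is present, since their natural "best"
depends on the data. Two printed directions are deliberately overridden,
with the divergence noted in the scorecard entry: t-closeness is normalized
smaller-is-safer (the standard semantics), and nearest-invalid-datapoint is
normalized larger-is-safer (never silently invert a safety-relevant
distance); both overrides are configurable. Criterion scores are weighted
arithmetic (default) or geometric means of member scores, with weights
renormalized to sum to 1, and labels use good ≥ 0.80 / moderate ≥ 0.70 /
low otherwise — defaults from the worked threshold example, always
overridable per task, and applied uniformly to all seven criteria (a
generalization flagged in the scorecard footer).

## Scorecard document

The document has exactly eight sections; the quality section has exactly
seven criterion entries, each either *computed* (score, label, member
metrics with raw value, normalized score, direction and parameters) or
*not-applicable* with a reason. Task-based, human-reader and ethics sections
are recorded verbatim from user input — the library computes nothing for
them. A failed metric never blocks the run; it is recorded as a failure note
in the footer. JSON output is canonical (sorted keys, floats at six
significant digits, NaN → null), so identical configuration and seeds give
byte-identical documents; validation checks the structural invariants plus
conformance to the published schema with a built-in checker covering the
schema subset used.

## Phantom generators and what passing tests show

The fixture generators are metrological phantoms, pure functions of
(parameters, seed) with per-generator derived streams, planting ground truth
exactly wherever the consuming metric is deterministic:

- Gaussian-mixture embedding pairs (default 4 equal-weight unit-variance
  components, d = 8) with a controllable mean shift δ along a fixed unit
  vector, a component-noise scale, and removed components as coverage gaps.
- Toy lesion images (noisy background + disk) with exactly ⌊f·n⌋ planted
  violations — an oversized lesion or a second lesion, alternating — plus a
  ground-truth table; lesion count and equivalent diameter are re-measured
  from the pixels by connected-component analysis.
- Tables whose minimum quasi-identifier class has exactly k\* rows, with an
  independent sensitive attribute and exactly ⌊rate·cells⌋ planted missing
  cells (never in quasi-identifiers).

The default end-to-end bundle uses three site subgroups of 120 samples
(one drifting site), 8 image pairs at 48×48, and a 60-row table with k\* = 3
and 2% missingness — sizes chosen so the whole suite runs in seconds while
the planted effects dominate sampling noise.

One statistical caveat: with a shared seed the synthetic mean moves as
μ₀ + δu, so FID as a function of δ is a quadratic whose minimum sits at
−Δμ₀·u — slightly above 0 for unlucky seeds. Monotone-response checks over
δ ∈ {0, 0.5, 1, 2} are therefore statistical rather than construction
guarantees and are pinned to fixed seeds; dips of order 0.01–0.1 at small δ
occur for a minority of seeds.

These phantoms exercise metric correctness, sensitivity direction and exact
ground-truth recovery. They do not emulate realistic medical image content,
inter-feature clinical correlations, coded terminologies, or real missing-
not-at-random patterns — passing tests show the metrics measure what they
claim on controlled inputs, not that any particular synthetic generator is
clinically adequate.

## Known limitations

- The built-in extractors are deliberately simple; results depend on the
  chosen embedding, which is why the extractor identity travels with every
  result.
- The DP entry validates and records a declared budget; it cannot detect an
  incorrect declaration.
- High-dimensional hull volume is only assessed in a PCA plane; structure
  orthogonal to the top components is invisible to that one metric.
- Aggregation is arithmetic/geometric only; fuzzy or learned aggregation is
  out of scope (the registry and calibration tables are the extension
  points).
- Documentation clarity quantifies a human-scored rubric; it does not read
  documents.
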