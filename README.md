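# smd-scorecard

Quality evaluation and scorecard generation for **synthetic medical data
(SMD)** — artificially generated imaging, tabular or text-embedding datasets
that mimic patient data. The package is aimed at synthetic-data developers
who need to document dataset quality, and at researchers deciding whether a
synthetic dataset is fit for a training or testing task.

A synthetic dataset is evaluated along seven criteria (the "7 Cs"):

| Criterion | Question it answers | Example metrics |
|---|---|---|
| **Congruence** | Does the synthetic distribution align with the patient data? | FID, EMD, JSD, cosine similarity, PSNR/SSIM, kNN precision |
| **Coverage** | Does it span the variability and modes of the patient data? | kNN recall/coverage, convex-hull volume, Vendi score, DPP, variance, entropy, cluster occupancy |
| **Constraint** | Does every sample respect known clinical/technical rules? | violation rate, distance to constraint boundary, nearest invalid datapoint |
| **Completeness** | Are required fields and values present? | proportion of required fields, missing-data percentage |
| **Compliance** | Does it meet privacy requirements? | k-anonymity, l-diversity, t-closeness, declared (ε, δ), re-identification risk |
| **Comprehension** | Is the generation process clearly documented? | documentation clarity rubric |
| **Consistency** | Is quality stable across subgroups or time? | per-subgroup dispersion, bootstrap one-way ANOVA |

Raw metric values are normalized onto [0, 1] with direction-aware
calibrations, aggregated per criterion by weighted arithmetic or geometric
means, and labeled **good** (score ≥ 0.80), **moderate** (0.70 ≤ score <
0.80) or **low** (score < 0.70); thresholds are task-configurable. Raw
values are always reported alongside the aggregate (dual reporting). The
result is an eight-section **scorecard** document — general information, the
quantitative quality table, task-based and human-reader results, ethics
notes, usage, generation process, and reference-dataset provenance —
validated against a published schema and rendered as canonical JSON or
Markdown.

Key formulas, in the field's standard notation:

- Fréchet distance between Gaussian moment fits:
  `d² = ‖μ_r − μ_s‖² + tr(Σ_r + Σ_s − 2(Σ_r Σ_s)^{1/2})`
- kNN-manifold precision: fraction of synthetic points within the union of
  balls `B(x_i, r_i)` over reference points, `r_i` = distance of `x_i` to its
  k-th nearest reference neighbor (recall/coverage swap the roles)
- Vendi score: `exp(−Σ_i λ_i log λ_i)` over eigenvalues of `K/n`, `K` the
  cosine-similarity kernel of L2-normalized rows
- k-anonymity: minimum equivalence-class size over identical
  quasi-identifier tuples; t-closeness: maximum class-vs-global
  sensitive-distribution distance (total variation / rank-normalized
  Wasserstein)

## Worked example

All metrics run on built-in seeded phantom generators, so the example needs
no data download:

```python
from smd_scorecard import run_evaluation
from smd_scorecard.fixtures import default_fixture_inputs

config, data = default_fixture_inputs(seed=1)
card = run_evaluation(config, data)
for criterion, entry in card.sections["section_2_quality"].items():
    print(f"{criterion:13s} {entry['score']:.3f}  {entry['label']}")
```

prints

```
congruence    0.860  good
coverage      0.826  good
constraint    0.967  good
completeness  0.992  good
compliance    0.610  low
comprehension 0.875  good
consistency   0.970  good
```

The phantom synthetic data has a mild planted distribution shift (hence
congruence below 1), a table whose smallest quasi-identifier class has only
3 rows (k = 3 drags compliance down to *low*), and three site subgroups with
one drifting site (consistency reports the dispersion and a bootstrap ANOVA
of per-site FID). Every criterion entry also carries its member metrics with
raw values, normalization anchors and parameters.

The same pipeline runs from the shell:

```sh
smd-scorecard simulate --seed 1 --out fixtures/        # write CSV/PNG fixtures + config
smd-scorecard evaluate --config fixtures/config.yaml --out card.json
smd-scorecard validate card.json
smd-scorecard render card.json --format markdown --out card.md
```

For real data, point the `data:` block of the YAML config at your own
feature CSVs (optional `sample_id`/`subgroup` columns), PNG directories and
tabular CSV, declare constraints and column roles, and override calibration
anchors, weights and thresholds under `aggregation:`.

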