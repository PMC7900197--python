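# immunodecon

Digital cytometry for bulk tumor expression: estimate the immune-cell
composition of each tumor from its bulk RNA profile, discover recurring
immune patterns across a cohort, and test how those patterns relate to
clinical features. The package is aimed at computational biologists who
want an end-to-end, fully testable reference pipeline for
deconvolution-based immune classification — exercisable entirely on
synthetic cohorts with known ground truth, with no downloads.

## What it computes

Bulk expression is modelled as a linear mixture **A x = b**: `A` is a
signature matrix of reference profiles (genes × cell types, e.g. the
22-type leukocyte taxonomy), `b` a bulk sample, `x` the unknown cell-type
proportions. Per sample, a linear-kernel ν-support-vector regression of
`b` on the columns of `A` yields raw weights; negative weights are clamped
to zero and the rest renormalized so fractions sum to 1. ν is selected
from {0.25, 0.5, 0.75} by lowest reconstruction RMSE, and each sample gets
a gene-permutation p-value for fit significance; samples with p ≥ 0.05 are
filtered out.

Downstream, fine cell types are summed into families (five CD4 subtypes →
CD4 T cells, M0/M1/M2 → macrophages, …), samples are clustered by K-means
on family fractions with the number of clusters chosen by the elbow of the
inertia curve, clusters are named by their CD4/CD8/macrophage ordering
(e.g. `CD8<CD4<MΦ`), and associations with grade, stage and tumor status
are tested with Mann–Whitney–Wilcoxon and chi-squared tests, annotated
with the usual significance stars.

A synthetic-data module generates the whole study — marker-block
signature, four immune-pattern archetypes, noisy mixtures, marker-gene
tracks with target correlations (PDCD1/INFG vs CD8 fraction at r = 0.85 /
0.79), and clinical covariates with configurable effect directions — so
every stage is testable against ground truth. See `docs/methods.md` for
the model details and design choices.

## Worked example

```python
from immunodecon import (
    GeneratorConfig, generate_cohort, DeconvolutionConfig, deconvolve,
    filter_by_pvalue, aggregate, default_lm22_map, select_k_elbow,
    kmeans_fit, name_clusters, compare_fraction_by_clinical,
)

cohort = generate_cohort(GeneratorConfig(n_samples=500, seed=0))
est = deconvolve(cohort.signature, cohort.mixture,
                 DeconvolutionConfig(n_permutations=50, seed=0))
kept = filter_by_pvalue(est, alpha=0.05)
fam = aggregate(kept, default_lm22_map())

k, profile = select_k_elbow(fam.fractions, range(1, 11), seed=0)
model = kmeans_fit(fam.fractions, k, seed=0)
print("selected k:", k)
print("immune classes:", name_clusters(model))

res = compare_fraction_by_clinical(fam, cohort.clinical,
                                   "CD8 T cells", "grade")["all"]
print(f"CD8 fraction, G1-2 vs G3-4: direction={res.effect_direction} "
      f"p={res.p_value:.2e} {res.stars}")
```

Output:

```
selected k: 4
immune classes: {1: 'CD4<CD8≈MΦ', 2: 'CD8<CD4<MΦ', 3: 'CD4<MΦ<CD8', 4: 'CD8<CD4≈MΦ'}
CD8 fraction, G1-2 vs G3-4: direction=G3-4 p=6.58e-52 ****
```

The elbow finds the four immune patterns planted by the generator, the
recovered class names are the four focal orderings of the CD4 T / CD8 T /
macrophage centroid fractions, and the CD8 fraction is significantly
higher in high-grade tumors — the direction the generator encodes.

The same pipeline runs from the shell:

```bash
immunodecon simulate --out-dir run --seed 0 --n-samples 500
immunodecon deconvolve --signature run/signature.tsv --mixture run/mixture.tsv \
    --out run/fractions.tsv --permutations 50 --seed 0
immunodecon aggregate --fractions run/fractions.filtered.tsv --out run/fam.tsv
immunodecon cluster --fractions run/fam.tsv --k auto --seed 0 --out run/model.json
immunodecon associate --fractions run/fam.tsv --clinical run/clinical.csv \
    --model run/model.json --out run/assoc.json
# or everything at once:
immunodecon run --out-dir run --seed 0
```

Expression matrices are tab-delimited text (genes as rows), clinical
tables CSV, fitted models and test results JSON.

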