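# Methods

## Model

Bulk tumor expression is modelled as a linear mixture

    A x = b

where `A` (genes × cell types) is a signature matrix of reference
expression profiles, `b` (genes) is one bulk sample in linear (non-log)
space and `x` is the unknown vector of cell-type proportions. The package
solves for `x` per sample with a linear-kernel ν-support-vector regression
of `b` on the columns of `A`; the regression coefficients are the raw
cell-type weights. Negative weights are clamped to zero and the remainder
renormalized to sum to one, so estimates always live on the probability
simplex.

### Standardization

Before the regression, each sample is centered and scaled over the shared
genes, and the signature matrix is standardized by its **global** mean and
standard deviation. Global (rather than per-column) standardization
preserves the relative scale of the signature columns, which is what makes
the exact proportions a feasible solution of the regression on a noiseless
mixture: with per-column z-scoring the linear mixture relation is
destroyed and the estimates drift from the non-negative-least-squares
solution by up to 0.1 in individual fractions (measured on 200-gene,
5-type noiseless mixtures). Per-sample centering/scaling makes the
fractions invariant to any positive rescaling of a sample, so results do
not depend on library-size-style global factors.

A degenerate corner is worth knowing about: for any ν-SVR with an
intercept, the dual constraint Σβ = 0 forces the fitted weights to sum to
zero whenever all signature rows have an identical row sum (e.g. an
identity matrix). Such designs cannot be deconvolved by SVR regardless of
standardization; real marker-block signatures, whose row sums vary, do not
hit this corner.

### ν selection

ν bounds the support-vector fraction from below and the training-error
fraction from above; it controls the ε-tube implicitly, so no ε parameter
is exposed. The solver fits ν ∈ {0.25, 0.5, 0.75} and keeps the fit whose
reconstruction `A·w` has the lowest RMSE against the standardized sample
(ties break toward the smallest ν). RMSE and the Pearson correlation of
the reconstruction are reported per sample as fit diagnostics.

### Fit significance and sample filtering

Each sample gets an empirical p-value: the sample's gene labels are
permuted (breaking the gene ↔ signature correspondence), the regression is
refit at the selected ν, and

    p = (1 + #{null r ≥ fitted r}) / (n_permutations + 1).

The add-one smoothing means p is never exactly 0 and its floor is
1/(n_permutations + 1) — with the default 100 permutations the floor is
0.0099, comfortably below the conventional 0.05 filter; configurations
with fewer than 20 permutations make p < 0.05 unattainable and are flagged
with a warning by the pipeline. Permutation refits use only the selected ν
(not the whole grid): three times cheaper, and the null statistic stays
comparable with the fitted correlation. Downstream analysis retains
samples with p < 0.05, and the retained/dropped counts are always logged.

### Cross-platform harmonization

An optional pre-processing stage quantile-maps each mixture sample onto
the pooled empirical distribution of the signature matrix (gene ranked
i-th gets the ((i+0.5)/G)-quantile of the pooled signature values). It
removes gross platform and scale differences while preserving
within-sample ranks. It is **off by default**: replacing each sample's
value distribution wholesale discards the magnitude information the
regression uses, which is the wrong trade when signature and mixture
already share a platform — as the synthetic cohorts do by construction
(measured on noiseless mixtures: recovery RMSE 0.15 with mapping vs 7e-5
without). Enable it (`harmonize=True`, `--harmonize`) only for genuinely
cross-platform inputs, e.g. a microarray-derived signature against RNA-seq
mixtures. Whether public RNA-seq matrices arrive log-transformed varies by
portal; the deconvolution requires linear-space input, and a `delog`
option (2^x − 1) is provided without any claim about what a particular
upstream pipeline did.

## Aggregation

The 22-type leukocyte taxonomy is collapsed into 12 families before
pattern analysis: five CD4 subtypes (naive, memory resting, memory
activated, follicular helper, regulatory) sum into CD4 T cells; B, NK,
dendritic, macrophage (M0/M1/M2) and mast subtypes sum likewise; CD8
T-cells, plasma cells, γδ T-cells, monocytes, eosinophils and neutrophils
pass through as singleton families. Monocytes deliberately stay separate
from macrophages. Aggregation is a partition, so per-sample mass is
conserved exactly.

## Pattern discovery

K-means (Lloyd, 10 seeded restarts, best inertia kept) clusters samples by
their raw family fractions. No re-standardization is applied: fractions
are already commensurate — each in [0,1], each row summing to 1 — and
rescaling would inflate the low-variance minor families into the distance.

k is chosen by the elbow rule: fit every k in 1..10 and take the k whose
(k, inertia) point lies farthest (perpendicular distance) from the chord
joining the first and last points of the inertia profile; ties break
toward the smallest k. Two properties of this rule matter in practice.
On well-separated structure it is sharp (four archetypes → k = 4
essentially always). On structureless data it is conservative but not
minimal: a smooth convex inertia curve always has its farthest-from-chord
point at an interior k, so a single Gaussian or single-Dirichlet blob
yields k ≈ 3–4, not k = 1 — the rule bounds spurious structure (never a
large k) rather than detecting its absence. Absence-of-structure testing
(gap statistic, consensus clustering) is out of scope.

Clusters are named by ordering their CD4 T / CD8 T / macrophage centroid
fractions, e.g. `CD8<CD4<MΦ`; two fractions closer than τ = 0.02 (absolute
fraction, configurable) are tied with `≈`, and tied symbols are displayed
in the conventional CD4, CD8, MΦ order. Names depend only on centroid
values, so they are invariant to cluster index permutation.

Descriptive structure operations: the pairwise Pearson correlation map of
family fractions across samples (zero-variance families reported missing),
and an agglomerative dendrogram of families with distance 1 − r and
average linkage (the common choice for correlation-based clustering of
feature tracks; both are exposed as options), emitted as Newick text.

## Statistics

Two-group comparisons of continuous variables use the Mann–Whitney–
Wilcoxon rank-sum test: the exact null for tieless pooled samples of size
≤ 12, otherwise the normal approximation with midrank tie correction and
continuity correction. The two paths agree within 0.01 wherever the exact
p ≤ 0.1 (and within 0.016 uniformly) at the switchover size. Tests are
two-sided by default and every result carries the direction of the larger
group, since the scientific claims are directional. Categorical
cross-tabulations (clusters × grade/stage/tumor status/…) use Pearson's
chi-squared test with margin-derived expectations, df = (r−1)(c−1);
zero-margin rows/columns are dropped with a warning. Gene–fraction
associations are Pearson correlations across samples.

Significance stars follow the five-level convention with right-inclusive
boundaries: ns (0.05 < p ≤ 1), * (0.01 < p ≤ 0.05), ** (0.001 < p ≤ 0.01),
*** (0.0001 < p ≤ 0.001), **** (p ≤ 0.0001). Raw p-values are reported
(no multiple-testing correction) to match the analysis style the package
reproduces; a Benjamini–Hochberg helper exists as a clearly marked
extension. Grade and stage are dichotomized G1–2 vs G3–4 and T1–T2 vs
T3–T4 for the headline comparisons; the full 4-level tables are kept for
the chi-squared cross-tabulations.

## Synthetic cohorts

The generator emulates the study's inputs end to end; its defaults are the
study conditions, not tuning knobs.

**Signature.** Each of the 22 cell types gets a disjoint block of
⌊n_genes/22⌋ dedicated marker genes drawn log-normal around 50 (σ_log
0.25) in its own column, on a shared log-normal baseline around 1
elsewhere; leftover genes are baseline-only. Defaults: 200 genes for
speed; `GeneratorConfig.lm22_scale()` gives the 547-gene configuration
matching the published signature size.

**Proportions.** Each sample draws an archetype (default weights ¼ each),
then family fractions from a Dirichlet centered on that archetype's mean
vector with concentration 400, then splits each family across its member
fine types by a flat Dirichlet (concentration 5). The four archetype means
satisfy the published focal orderings (CD4<CD8≈MΦ, CD8<CD4<MΦ, CD4<MΦ<CD8,
CD8<CD4≈MΦ), and the fourth archetype carries the highest mast, monocyte,
B and NK means. Each archetype also has a distinctive minor-family profile
(neutrophils/eosinophils; monocytes/DC; plasma/γδ; mast/B/NK) so that
cluster separation does not ride on the CD8–macrophage contrast alone.
The means were calibrated once, by simulating the mixture at n = 200 000,
so that the cohort-level corr(CD8, MΦ) ≈ −0.46, the value reported for
the real cohort the generator emulates; the calibrated empirical value is
−0.466, and at n = 500 the sampling standard error of the estimate is
≈ 0.035. The concentrations were fixed at the same time so the four
patterns are cleanly separable at default noise (ARI ≈ 1); no published
within-cluster dispersion exists to match, and this is documented as a
choice.

**Mixtures.** `b = A x` per sample, multiplied gene-wise by
exp(N(0, σ²)) noise, σ = 0.1 by default (multiplicative log-normal noise:
expression is positive and heteroskedastic). σ = 0 gives exact linear
mixtures.

**Marker tracks.** A track targeting correlation r with family f is
r·z(f) + √(1−r²)·ε with ε independent standard normal, then mapped onto a
positive expression scale (Pearson r is affine-invariant; the clip at 0.01
is beyond 6σ and has no measurable effect). Correlation is achieved by
construction, not post-hoc tuning; the sampling error of the recovered r
at n = 500 is ≈ (1−r²)/√n. Defaults: PDCD1-like → CD8 T cells at 0.85,
INFG-like → CD8 T cells at 0.79 (both published values), RGS5-like → mast
cells at 0.60 (direction published, magnitude not; 0.60 chosen as a
clearly-detectable association). Residuals are independent across tracks,
so the implied PDCD1–INFG cross-correlation is 0.85·0.79 ≈ 0.67; the
generator targets gene–fraction correlations only.

**Clinical covariates.** Grade and stage follow proportional-odds models
whose cutpoints reproduce the emulated cohort's marginal category counts
and whose latent is β₁·z(CD8) + β₂·z(mast) + β₃·z(monocytes) with defaults
(+1.2, −0.6, −0.6) per SD — directions published, magnitudes chosen to
give clearly detectable effects at n = 500. Tumor status is Bernoulli with
log-odds of tumor-free increasing in mast (+0.8/SD) and NK (+0.5/SD)
fractions. Survival status depends on tumor status (P(alive) 0.85 vs
0.40); gender and laterality are independent coin flips at the emulated
cohort's observed rates; age is N(61, 12²) truncated to [26, 90] years;
overall survival is Gamma(1.5) with scale 35 months (alive) or 18
(deceased). A few grades (~1.3%) and tumor statuses (~6%) are set missing
to mirror the original table's missingness; every consumer reports
excluded counts. Setting `ClinicalEffects.null()` zeroes every link for
calibration runs.

**What the generator does not emulate:** gene-length and library-size
effects, count noise, correlated marker residuals, signature/mixture
platform mismatch (unless harmonization is being exercised), survival-time
dependence on fractions, and any mass-cytometry-style reference cohort.
Passing tests therefore demonstrate correctness of the pipeline's
machinery and its behaviour under the stated generative model — not
performance on real tumors.

## Problem sizes used in the checks

The shipped checks run, per invocation: noiseless recovery on 50 samples;
NNLS-oracle agreement on 20; p-value calibration on 200 structureless
samples at 100 permutations plus retention on 50 well-formed samples;
pattern discovery on deconvolved n = 500 cohorts with the elbow run under
multiple clustering seeds; null clinical calibration over 200 replicates
of n = 120; marker-track fidelity at n = 500. These sizes keep a full run
in the minutes range on one CPU while leaving every estimate's sampling
error well inside the asserted tolerances.

## Known limitations

- The SVR coefficients are a biased estimator of the proportions when the
  signature is ill-conditioned; the NNLS agreement bound (L∞ ≤ 0.02) is
  verified on well-conditioned marker-block signatures only.
- The empirical p-value's permutation null assumes exchangeable gene
  labels under the null; structured noise (e.g. co-expressed gene modules)
  would make it anti-conservative.
- The elbow rule cannot return "no structure"; see Pattern discovery.
- Absolute (non-relative) cell scores, single-cell-derived custom
  signatures, and expression purification are out of scope.
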