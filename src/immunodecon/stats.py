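"""Association statistics for cell fractions, gene expression and clinic.

Group comparisons of continuous variables use the non-parametric
Mann-Whitney-Wilcoxon (MWW) rank-sum test: the exact null distribution of
U is used for small tieless samples (n_a + n_b <= 12), the normal
approximation with midrank tie correction and continuity correction
otherwise. Categorical cross-tabulations use Pearson's chi-squared test.
Gene-fraction associations are Pearson correlations across samples. Every
result carries a significance-star annotation:

    ns: 0.05 < p <= 1, *: 0.01 < p <= 0.05, **: 0.001 < p <= 0.01,
    ***: 0.0001 < p <= 0.001, ****: p <= 0.0001.

Raw p-values are reported (no multiple-testing correction); an optional
Benjamini-Hochberg helper is provided as a clearly marked extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import ImmuneClassModel
from .datatypes import (
    ClinicalTable,
    MixtureProfile,
    ProportionEstimate,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "stars",
    "mww_test",
    "chi_squared_test",
    "compare_fraction_by_clinical",
    "crosstab_cluster_vs_clinical",
    "gene_fraction_correlation",
    "benjamini_hochberg",
    "GROUPINGS",
]

EXACT_MWW_MAX_N = 12  # exact null enumeration below this total, if tieless


@dataclass
class TestResult:
    """One statistical test outcome."""

    test_name: str  # mww | chi_squared | pearson
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    effect_direction: Optional[str] = None  # label of the larger group (mww)
    stars: str = ""
    computable: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.computable:
            if not (0.0 <= self.p_value <= 1.0):
                raise ValidationError(f"p_value outside [0,1]: {self.p_value}")
            expected = stars(self.p_value)
            if self.stars == "":
                self.stars = expected
            elif self.stars != expected:
                raise ValidationError("stars inconsistent with p_value")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": None if np.isnan(self.statistic) else float(self.statistic),
            "p_value": None if np.isnan(self.p_value) else float(self.p_value),
            "n_per_group": self.n_per_group,
            "effect_direction": self.effect_direction,
            "stars": self.stars,
            "computable": self.computable,
            "extra": self.extra,
        }


def _not_computable(test_name: str, n_per_group: dict, why: str) -> TestResult:
    logger.warning("%s not computable: %s", test_name, why)
    return TestResult(
        test_name=test_name, statistic=float("nan"), p_value=float("nan"),
        n_per_group=n_per_group, stars="", computable=False,
        extra={"reason": why},
    )


def stars(p: float) -> str:
    """Five-level significance annotation, boundaries inclusive on the right."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p must lie in [0,1], got {p}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def mww_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    labels: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test.

    ``alternative`` is 'two-sided', 'greater' (a tends larger) or 'less'.
    The statistic reported is U for group_a. Exact enumeration is used for
    tieless samples with n_a + n_b <= 12, otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    tieless = np.unique(pooled).size == pooled.size
    method = "exact" if (tieless and pooled.size <= EXACT_MWW_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method,
                           use_continuity=True)
    u_a = float(res.statistic)
    mid = a.size * b.size / 2.0
    direction = labels[0] if u_a > mid else labels[1] if u_a < mid else "none"
    return TestResult(
        test_name="mww",
        statistic=u_a,
        p_value=float(res.pvalue),
        n_per_group={labels[0]: int(a.size), labels[1]: int(b.size)},
        effect_direction=direction,
        extra={"method": method, "alternative": alternative},
    )


def chi_squared_test(table: pd.DataFrame | np.ndarray) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table.

    Expected counts come from the row/column margins; df = (r-1)(c-1).
    Zero-margin rows/columns are dropped with a warning; an all-zero table
    is an error.
    """
    tab = pd.DataFrame(table)
    vals = tab.to_numpy(dtype=float)
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        raise ValidationError("contingency table must hold non-negative integers")
    if vals.sum() == 0:
        raise ValidationError("all-zero contingency table")
    keep_rows = vals.sum(axis=1) > 0
    keep_cols = vals.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.warning(
            "dropping %d zero-margin row(s) and %d zero-margin column(s)",
            int((~keep_rows).sum()), int((~keep_cols).sum()),
        )
        tab = tab.loc[keep_rows, keep_cols]
        vals = tab.to_numpy(dtype=float)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValidationError("need >= 2 rows and >= 2 columns with positive margins")
    res = sps.chi2_contingency(vals, correction=False)
    return TestResult(
        test_name="chi_squared",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group={str(r): int(n) for r, n in zip(tab.index, vals.sum(axis=1))},
        extra={"df": int(res.dof)},
    )


# headline clinical dichotomies: low grade/stage vs high, and the binary flags
GROUPINGS = {
    "grade": ("grade", {"G1": "G1-2", "G2": "G1-2", "G3": "G3-4", "G4": "G3-4"},
              ("G1-2", "G3-4")),
    "stage": ("stage", {"T1": "T1-2", "T2": "T1-2", "T3": "T3-4", "T4": "T3-4"},
              ("T1-2", "T3-4")),
    "tumor_status": ("tumor_status", None, ("tumor-free", "with-tumor")),
    "gender": ("gender", None, ("female", "male")),
    "laterality": ("laterality", None, ("left", "right")),
}


def _grouping_labels(clinical: ClinicalTable, grouping: str) -> tuple[pd.Series, tuple[str, str]]:
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}")
    column, recode, labels = GROUPINGS[grouping]
    series = clinical.data[column]
    if recode is not None:
        series = series.map(recode)
    return series, labels


def compare_fraction_by_clinical(
    est: ProportionEstimate,
    clinical: ClinicalTable,
    family: str,
    grouping: str,
    stratify_by_cluster: Optional[ImmuneClassModel] = None,
    alternative: str = "two-sided",
) -> dict[str, TestResult]:
    """MWW comparison of a family fraction between two clinical groups.

    ``grouping`` is one of ``grade`` (G1-2 vs G3-4), ``stage`` (T1-2 vs
    T3-4), ``tumor_status``, ``gender`` or ``laterality``. Returns one
    TestResult per stratum: the whole cohort under key ``"all"``, or one
    per cluster when ``stratify_by_cluster`` is given. Samples with a
    missing grouping value are excluded with a logged count; a stratum
    with an empty group is marked not-computable rather than dropped.
    """
    if family not in est.cell_types:
        raise ValidationError(f"family {family!r} absent from estimate")
    groups, labels = _grouping_labels(clinical, grouping)
    shared = est.sample_ids.intersection(clinical.sample_ids)
    frac = est.fractions.loc[shared, family]
    groups = groups.loc[shared]
    n_missing = int(groups.isna().sum())
    if n_missing:
        logger.info("%s: excluding %d sample(s) with missing %s",
                    grouping, n_missing, grouping)
    keep = groups.notna()
    frac, groups = frac[keep], groups[keep]
    strata: dict[str, pd.Index] = {"all": frac.index}
    if stratify_by_cluster is not None:
        strata = {
            f"cluster_{cid}": frac.index.intersection(
                stratify_by_cluster.labels.index[stratify_by_cluster.labels == cid]
            )
            for cid in range(1, stratify_by_cluster.k + 1)
        }
    out: dict[str, TestResult] = {}
    for name, idx in strata.items():
        g = groups.loc[idx]
        a = frac.loc[idx][g == labels[0]].to_numpy()
        b = frac.loc[idx][g == labels[1]].to_numpy()
        if a.size == 0 or b.size == 0:
            out[name] = _not_computable(
                "mww", {labels[0]: int(a.size), labels[1]: int(b.size)},
                f"empty group in stratum {name}",
            )
            continue
        out[name] = mww_test(a, b, alternative=alternative, labels=labels)
    return out


def crosstab_cluster_vs_clinical(
    model: ImmuneClassModel,
    clinical: ClinicalTable,
    variable: str,
) -> tuple[TestResult, pd.DataFrame]:
    """Chi-squared test of cluster membership against a categorical variable.

    Returns the TestResult and the full clusters x categories count table;
    per-cluster category percentages ride along in ``extra``.
    """
    if variable not in clinical.data.columns:
        raise ValidationError(f"clinical variable {variable!r} absent")
    shared = model.labels.index.intersection(clinical.sample_ids)
    lab = model.labels.loc[shared]
    var = clinical.data.loc[shared, variable]
    n_missing = int(var.isna().sum())
    if n_missing:
        logger.info("crosstab %s: excluding %d sample(s) with missing value",
                    variable, n_missing)
    keep = var.notna()
    table = pd.crosstab(lab[keep], var[keep])
    table.index = [f"cluster_{c}" for c in table.index]
    result = chi_squared_test(table)
    pct = table.div(table.sum(axis=1), axis=0) * 100
    result.extra["percent_within_cluster"] = {
        r: {c: float(pct.loc[r, c]) for c in pct.columns} for r in pct.index
    }
    result.extra["variable"] = variable
    return result, table


def gene_fraction_correlation(
    mix: MixtureProfile,
    est: ProportionEstimate,
    gene: str,
    family: str,
) -> TestResult:
    """Pearson correlation between a gene's expression and a family fraction."""
    if gene not in mix.gene_ids:
        raise ValidationError(f"gene {gene!r} absent from mixture")
    if family not in est.cell_types:
        raise ValidationError(f"family {family!r} absent from estimate")
    shared = est.sample_ids.intersection(mix.sample_ids)
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared samples")
    x = mix.data.loc[gene, shared].to_numpy(dtype=float)
    y = est.fractions.loc[shared, family].to_numpy(dtype=float)
    n = {"samples": int(len(shared))}
    if x.std() == 0 or y.std() == 0:
        return _not_computable("pearson", n, "zero variance on one side")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        test_name="pearson", statistic=float(r), p_value=float(p),
        n_per_group=n, effect_direction="positive" if r > 0 else "negative",
        extra={"gene": gene, "family": family},
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values. Extension: the headline analysis reports raw p."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.clip(q, 0, 1)
    return out
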