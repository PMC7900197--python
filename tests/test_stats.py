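"""Statistics layer: MWW vs enumeration, chi-squared vs hand formula,
star thresholds, clinical associations against the generator."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from immunodecon.clustering import kmeans_fit
from immunodecon.datatypes import ProportionEstimate, ValidationError
from immunodecon.stats import (
    benjamini_hochberg,
    chi_squared_test,
    compare_fraction_by_clinical,
    crosstab_cluster_vs_clinical,
    gene_fraction_correlation,
    mww_test,
    stars,
)
from immunodecon.synthetic import (
    ClinicalEffects,
    GeneratorConfig,
    aggregate_to_families,
    generate_cohort,
    make_clinical,
    make_proportions,
)


def mww_exact_oracle(a, b, alternative="two-sided"):
    """Brute force: enumerate all rank assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = sum(ranks[list(combo)]) - n_a * (n_a + 1) / 2
        us.append(u)
    us = np.array(us)
    if alternative == "greater":
        return u_obs, float((us >= u_obs).mean())
    if alternative == "less":
        return u_obs, float((us <= u_obs).mean())
    lo = min(float((us >= u_obs).mean()), float((us <= u_obs).mean()))
    return u_obs, min(1.0, 2 * lo)


class TestMWW:
    def test_textbook_separated_groups(self):
        res = mww_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 20)
        assert res.effect_direction == "b"
        assert res.extra["method"] == "exact"

    def test_identical_groups_two_sided(self):
        res = mww_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n_a*n_b/2
        assert res.p_value == pytest.approx(1.0)
        assert res.effect_direction == "none"

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 5), (5, 5)])
    def test_exact_path_equals_enumeration(self, n_a, n_b, alternative):
        rng = np.random.default_rng(n_a * 10 + n_b)
        a = rng.permutation(np.arange(1.0, n_a + n_b + 1))[:n_a]
        b = np.setdiff1d(np.arange(1.0, n_a + n_b + 1), a)
        rng.shuffle(b)
        res = mww_test(a, b, alternative=alternative)
        u_oracle, p_oracle = mww_exact_oracle(a, b, alternative)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle)

    def test_asymptotic_close_to_exact_on_borderline_n(self):
        """At the exact/asymptotic switchover (n=12) the continuity-
        corrected normal approximation tracks the exact null: within 0.01
        everywhere it matters (exact p <= 0.1) and 0.016 uniformly."""
        from scipy.stats import mannwhitneyu

        ranks = np.arange(1.0, 13.0)
        seen = set()
        for combo in itertools.combinations(range(12), 6):
            a = ranks[list(combo)]
            u = a.sum() - 21.0
            if u in seen:
                continue
            seen.add(u)
            b = np.setdiff1d(ranks, a)
            exact = mannwhitneyu(a, b, method="exact").pvalue
            approx = mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(exact - approx) < 0.016
            if exact <= 0.1:
                assert abs(exact - approx) < 0.01
        assert len(seen) == 37  # every achievable U value covered
        long_a = np.concatenate([ranks[:6], [50.0]])
        assert mww_test(long_a, ranks[6:]).extra["method"] == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mww_test([], [1.0])


class TestChiSquared:
    def test_independent_table(self):
        res = chi_squared_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_hand_formula(self):
        # E = 10 everywhere; sum (O-E)^2/E = 4 * 100/10 = 40, df = 1
        res = chi_squared_test([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)
        assert res.extra["df"] == 1

    def test_matches_hand_formula_on_random_2x2(self):
        rng = np.random.default_rng(0)
        tab = rng.integers(1, 30, size=(2, 2)).astype(float)
        res = chi_squared_test(tab)
        row, col, n = tab.sum(1), tab.sum(0), tab.sum()
        expected = np.outer(row, col) / n
        stat = ((tab - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(stat)

    def test_permutation_invariance(self):
        tab = np.array([[5, 9, 2], [7, 1, 12]])
        base = chi_squared_test(tab).statistic
        assert chi_squared_test(tab[::-1]).statistic == pytest.approx(base)
        assert chi_squared_test(tab[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = chi_squared_test([[5, 0, 5], [5, 0, 5]])
        assert any("zero-margin" in r.message for r in caplog.records)
        assert res.statistic == pytest.approx(0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            chi_squared_test([[0, 0], [0, 0]])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.03, "*"),
            (0.05, "*"),       # boundary: 0.01 < p <= 0.05
            (0.0001, "****"),  # boundary inclusive
            (0.01, "**"),
            (0.001, "***"),
            (0.2, "ns"),
            (1.0, "ns"),
            (0.00005, "****"),
        ],
    )
    def test_printed_thresholds(self, p, expected):
        assert stars(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            stars(1.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_total_step_function(self, p1, p2):
        order = ["****", "***", "**", "*", "ns"]
        s1, s2 = stars(p1), stars(p2)
        if p1 <= p2:
            assert order.index(s1) <= order.index(s2)


@pytest.fixture(scope="module")
def clinical_cohort():
    cfg = GeneratorConfig(n_samples=500, seed=0)
    c = generate_cohort(cfg)
    est = ProportionEstimate(fractions=c.true_family_fractions)
    return c, est


class TestClinicalAssociations:
    def test_cd8_higher_at_high_grade(self, clinical_cohort):
        c, est = clinical_cohort
        res = compare_fraction_by_clinical(est, c.clinical, "CD8 T cells",
                                           "grade")["all"]
        assert res.effect_direction == "G3-4"
        assert res.p_value < 0.01

    def test_mast_higher_when_tumor_free(self, clinical_cohort):
        c, est = clinical_cohort
        res = compare_fraction_by_clinical(est, c.clinical, "Mast cells",
                                           "tumor_status")["all"]
        assert res.effect_direction == "tumor-free"
        assert res.p_value < 0.01

    def test_null_generator_rejects_at_nominal_rate(self):
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            cfg = GeneratorConfig(
                n_samples=120, clinical_effects=ClinicalEffects.null(),
                seed=30_000 + rep,
            )
            frac, labels = make_proportions(cfg)
            clinical = make_clinical(frac, labels, cfg)
            est = ProportionEstimate(fractions=aggregate_to_families(frac))
            res = compare_fraction_by_clinical(est, clinical, "CD8 T cells",
                                               "grade")["all"]
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_reps <= 0.08

    def test_permuted_labels_destroy_significance(self, clinical_cohort):
        c, est = clinical_cohort
        rng = np.random.default_rng(1)
        insignificant = 0
        for _ in range(20):
            permuted = c.clinical.data.copy()
            permuted["grade"] = rng.permutation(permuted["grade"].to_numpy())
            from immunodecon.datatypes import ClinicalTable

            res = compare_fraction_by_clinical(
                est, ClinicalTable(permuted), "CD8 T cells", "grade"
            )["all"]
            insignificant += res.p_value > 0.05
        assert insignificant >= 18

    def test_empty_stratum_marked_not_computable(self, clinical_cohort):
        c, est = clinical_cohort
        only_low = c.clinical.data.copy()
        only_low["grade"] = "G1"
        from immunodecon.datatypes import ClinicalTable

        res = compare_fraction_by_clinical(
            est, ClinicalTable(only_low), "CD8 T cells", "grade"
        )["all"]
        assert not res.computable


class TestCrosstab:
    def test_archetype_grade_enrichment_detected(self, clinical_cohort):
        c, est = clinical_cohort
        model = kmeans_fit(est.fractions, 4, seed=0)
        res, table = crosstab_cluster_vs_clinical(model, c.clinical, "grade")
        assert res.p_value < 0.05
        # row sums equal per-cluster sample counts (among graded samples)
        graded = c.clinical.data["grade"].notna()
        counts = model.labels[graded.reindex(model.labels.index, fill_value=False)]
        for cid, n in counts.value_counts().items():
            assert table.loc[f"cluster_{cid}"].sum() == n

    def test_shuffled_cluster_labels_uniform_p(self, clinical_cohort):
        c, est = clinical_cohort
        model = kmeans_fit(est.fractions, 4, seed=0)
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(40):
            shuffled = model.labels.copy()
            shuffled[:] = rng.permutation(shuffled.to_numpy())
            m2 = kmeans_fit(est.fractions, 4, seed=0)
            m2.labels = shuffled
            res, _ = crosstab_cluster_vs_clinical(m2, c.clinical, "grade")
            pvals.append(res.p_value)
        assert np.mean(np.array(pvals) < 0.05) <= 0.15

    def test_absent_variable_rejected(self, clinical_cohort):
        c, est = clinical_cohort
        model = kmeans_fit(est.fractions, 2, seed=0)
        with pytest.raises(ValidationError):
            crosstab_cluster_vs_clinical(model, c.clinical, "florp")


class TestGeneFractionCorrelation:
    def test_recovers_generator_target(self, clinical_cohort):
        c, est = clinical_cohort
        res = gene_fraction_correlation(c.mixture, est, "PDCD1", "CD8 T cells")
        assert res.statistic == pytest.approx(0.85, abs=0.05)
        assert res.effect_direction == "positive"

    def test_gene_equal_to_fraction_gives_unit_r(self, clinical_cohort):
        c, est = clinical_cohort
        from immunodecon.datatypes import MixtureProfile

        data = c.mixture.data.copy()
        data.loc["SELF"] = est.fractions["CD8 T cells"].reindex(data.columns)
        res = gene_fraction_correlation(
            MixtureProfile(data), est, "SELF", "CD8 T cells"
        )
        assert res.statistic == pytest.approx(1.0)

    def test_affine_invariance(self, clinical_cohort):
        c, est = clinical_cohort
        from immunodecon.datatypes import MixtureProfile

        data = c.mixture.data.copy()
        data.loc["PDCD1"] = 3.0 * data.loc["PDCD1"] + 7.0
        res = gene_fraction_correlation(
            MixtureProfile(data), est, "PDCD1", "CD8 T cells"
        )
        base = gene_fraction_correlation(c.mixture, est, "PDCD1", "CD8 T cells")
        assert res.statistic == pytest.approx(base.statistic, abs=1e-12)


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.02, 0.04, 0.5, 0.9])
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-15).all()
    assert (q <= 1.0).all()
    assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()
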