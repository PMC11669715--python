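"""Expression statistics: DE thresholding, correlation, dosage, PCA."""

import numpy as np
import pandas as pd
import pytest

from gstnull.expression import (
    ExpressionMatrix,
    bh_adjust,
    call_degs,
    dosage_analysis,
    mutual_exclusivity,
    pca_embed,
    pearson_with_ci,
    presence_absence,
    relative_expression,
)


def matrix_from(values, genes, samples, groups=None):
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
    )


def bh_bruteforce(p):
    """Step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        adj_sorted[rank - 1] = min(
            min(p[order[j - 1]] * m / j for j in range(rank, m + 1)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestRelativeExpression:
    def test_self_ratio_is_1000(self):
        em = matrix_from([[2.0, 5.0]], ["GAPDH"], ["S1", "S2"])
        assert (relative_expression(em, "GAPDH", "GAPDH") == 1000.0).all()

    def test_zero_numerator(self):
        em = matrix_from([[0.0, 0.0], [2.0, 4.0]], ["G", "GAPDH"], ["S1", "S2"])
        assert (relative_expression(em, "G") == 0.0).all()

    def test_closed_form(self):
        em = matrix_from([[5.0], [2.0]], ["G", "GAPDH"], ["S1"])
        assert relative_expression(em, "G")["S1"] == pytest.approx(2500.0)

    def test_zero_reference_names_sample(self):
        em = matrix_from([[5.0, 1.0], [2.0, 0.0]], ["G", "GAPDH"], ["S1", "S2"])
        with pytest.raises(ValueError, match="S2"):
            relative_expression(em, "G")


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_property(self):
        """Hypothesis property: BH equals the step-up oracle for any short vector."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=200, derandomize=True, deadline=None)
        @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
        def check(p):
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

        check()

    def test_matches_bruteforce_on_short_vectors(self):
        """Seeded property: BH equals the step-up definition, lengths 1-10."""
        rng = np.random.default_rng(77)
        for _ in range(400):
            n = int(rng.integers(1, 11))
            p = np.round(rng.random(n), 3)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


def two_group_matrix(rng, n_genes=300, n_per_group=20, planted=0, lfc=2.0, log_sd=0.25):
    base = rng.lognormal(3.0, 1.0, size=n_genes)
    X = base[:, None] * 2.0 ** rng.normal(0.0, log_sd, size=(n_genes, 2 * n_per_group))
    X[:planted, n_per_group:] *= 2.0**lfc
    samples = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    groups = {s: ("a" if s.startswith("A") else "b") for s in samples}
    return matrix_from(X, [f"G{i}" for i in range(n_genes)], samples, groups)


class TestCallDegs:
    def test_identical_gene_not_significant(self):
        em = matrix_from(
            [[5.0] * 4, [1.0, 2.0, 3.0, 4.0]],
            ["flat", "noisy"],
            ["A1", "A2", "B1", "B2"],
            {"A1": "a", "A2": "a", "B1": "b", "B2": "b"},
        )
        rec = {d.gene: d for d in call_degs(em, "a", "b")}
        assert rec["flat"].log2_fold_change == 0.0
        assert not rec["flat"].significant

    def test_planted_four_fold_shift_detected(self, rng):
        em = two_group_matrix(rng, planted=1, lfc=2.0, log_sd=0.2)
        rec = {d.gene: d for d in call_degs(em, "a", "b")}
        assert rec["G0"].significant
        assert rec["G0"].log2_fold_change == pytest.approx(2.0, abs=0.5)

    def test_both_criteria_required(self):
        # large fold change but hopeless variance: FDR fails, so not significant
        rng = np.random.default_rng(5)
        X = rng.lognormal(1.0, 2.5, size=(30, 8))
        X[0, 4:] *= 4.0
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        em = matrix_from(X, [f"G{i}" for i in range(30)], samples,
                         {s: s[0].lower() for s in samples})
        rec = {d.gene: d for d in call_degs(em, "a", "b")}
        noisy = [d for d in rec.values() if abs(d.log2_fold_change) >= 1 and d.fdr > 0.05]
        assert noisy and all(not d.significant for d in noisy)

    def test_small_group_rejected(self, rng):
        em = two_group_matrix(rng, n_genes=5, n_per_group=20)
        em.groups = {s: ("a" if s == "A0" else "b") for s in em.values.columns}
        with pytest.raises(ValueError):
            call_degs(em, "a", "b")

    def test_null_simulation_fdr_and_power(self):
        """Type-I: on fully null cohorts the mean number of significant genes
        stays at the nominal level; power at a planted 4-fold shift with low
        noise is >= 90%."""
        n_seeds = 200
        false_calls = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            em = two_group_matrix(rng, n_genes=2000, n_per_group=8, planted=0)
            false_calls += sum(d.significant for d in call_degs(em, "a", "b"))
        assert false_calls / n_seeds <= 0.05

        rng = np.random.default_rng(42)
        hits = total = 0
        for _ in range(10):
            em = two_group_matrix(rng, n_genes=200, n_per_group=20, planted=20,
                                  lfc=2.0, log_sd=0.3)
            recs = call_degs(em, "a", "b")
            hits += sum(d.significant for d in recs[:20])
            total += 20
        assert hits / total >= 0.90


class TestPresenceAbsence:
    GROUPS = {"A1": "a", "A2": "a", "B1": "b", "B2": "b"}

    def test_all_zero_matrix(self):
        em = matrix_from(np.zeros((4, 4)), list("wxyz"), list(self.GROUPS), self.GROUPS)
        out = presence_absence(em, "a", "b", 1.0)
        assert out == {"both": 0, "group_a_only": 0, "group_b_only": 0, "neither": 4}

    def test_toy_partition(self):
        X = [[5, 5, 5, 5], [5, 5, 0, 0], [0, 0, 5, 5]]
        em = matrix_from(X, ["both", "a_only", "b_only"], list(self.GROUPS), self.GROUPS)
        out = presence_absence(em, "a", "b", 1.0)
        assert out == {"both": 1, "group_a_only": 1, "group_b_only": 1, "neither": 0}

    def test_vacuous_threshold(self):
        X = np.full((3, 4), 2.0)
        em = matrix_from(X, list("abc"), list(self.GROUPS), self.GROUPS)
        assert presence_absence(em, "a", "b", 0.0)["both"] == 3

    def test_partition_sums_to_gene_count(self, rng):
        X = rng.lognormal(0, 2, size=(50, 4))
        em = matrix_from(X, [f"G{i}" for i in range(50)], list(self.GROUPS), self.GROUPS)
        out = presence_absence(em, "a", "b", 1.0)
        assert sum(out.values()) == 50


class TestPearson:
    def test_cohort_gstm1_gstt1(self, panel):
        """The published no-correlation result is recomputable from the panel."""
        res = pearson_with_ci(
            panel.expression("GSTM1").to_numpy(), panel.expression("GSTT1").to_numpy()
        )
        assert res.n == 16
        assert res.r == pytest.approx(-0.0232, abs=0.0005)
        assert res.ci_low == pytest.approx(-0.5130, abs=0.001)
        assert res.ci_high == pytest.approx(0.4780, abs=0.001)
        assert res.p_value == pytest.approx(0.9321, abs=0.001)

    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2, 3], [3, 2, 1])

    def test_ci_symmetric_in_z_space(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_with_ci(x, y)
        z = np.arctanh(res.r)
        assert np.arctanh(res.ci_high) - z == pytest.approx(z - np.arctanh(res.ci_low), abs=1e-9)

    def test_zero_correlation_p_is_one(self):
        res = pearson_with_ci([1.0, 2.0, 3.0, 4.0], [1.0, -1.0, -1.0, 1.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)


class TestDosage:
    def test_cohort_gstm2_two_fold_effect(self, panel):
        groups, ratios = dosage_analysis(
            panel.expression("GSTM2").to_numpy(), panel.copies("GSTM2").to_numpy()
        )
        assert groups[2]["n"] == 4 and groups[1]["n"] == 12
        assert ratios[(1, 2)] == pytest.approx(1.874, abs=0.005)

    def test_single_group_has_no_ratio(self):
        groups, ratios = dosage_analysis([3.0, 4.0], [1, 1])
        assert ratios == {} and groups[1]["n"] == 2

    def test_strict_dosage_is_exactly_two_fold(self):
        copies = np.array([1, 1, 2, 2])
        groups, ratios = dosage_analysis(5.0 * copies, copies)
        assert ratios[(1, 2)] == 2.0


class TestExclusivity:
    def test_cohort_style_no_double_low(self, panel):
        gstm1 = panel.expression("GSTM1")
        high = pd.Series(100.0, index=gstm1.index)
        em = ExpressionMatrix(values=pd.DataFrame({"GSTM1": gstm1, "OTHER": high}).T)
        res = mutual_exclusivity(em, "GSTM1", "OTHER", 0.0, 10.0)
        assert res.exclusive and res.low_low == 0

    def test_double_low_breaks_exclusivity(self):
        em = matrix_from([[0.0, 9.0], [0.0, 9.0]], ["A", "B"], ["S1", "S2"])
        res = mutual_exclusivity(em, "A", "B", 1.0, 1.0)
        assert not res.exclusive and res.low_low == 1

    def test_quadrants_sum_to_samples(self, rng):
        X = rng.lognormal(0, 1, size=(2, 25))
        em = matrix_from(X, ["A", "B"], [f"S{i}" for i in range(25)])
        res = mutual_exclusivity(em, "A", "B", 1.0, 1.0)
        assert res.low_low + res.low_high + res.high_low + res.high_high == 25


class TestPca:
    def test_duplicate_samples_coincide(self, rng):
        X = rng.lognormal(0, 1, size=(20, 4))
        X[:, 3] = X[:, 0]
        em = matrix_from(X, [f"G{i}" for i in range(20)], list("wxyz"))
        coords, _ = pca_embed(em, 2)
        np.testing.assert_allclose(coords.loc["w"], coords.loc["z"], atol=1e-10)

    def test_rank_one_matrix(self, rng):
        gene_profile = rng.lognormal(0, 1, size=30)
        weights = rng.uniform(0.5, 2.0, size=6)
        em = matrix_from(np.outer(gene_profile, weights),
                         [f"G{i}" for i in range(30)], [f"S{i}" for i in range(6)])
        _, explained = pca_embed(em, 2)
        assert explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA

        X = rng.lognormal(0, 1, size=(50, 16))
        em = matrix_from(X, [f"G{i}" for i in range(50)], [f"S{i}" for i in range(16)])
        coords, explained = pca_embed(em, 3)
        ref = PCA(n_components=3, svd_solver="full").fit(X.T)
        ref_coords = ref.transform(X.T)
        for k in range(3):
            a, b = coords.iloc[:, k].to_numpy(), ref_coords[:, k]
            if np.dot(a, b) < 0:
                b = -b
            np.testing.assert_allclose(a, b, atol=1e-8)
        np.testing.assert_allclose(explained, ref.explained_variance_ratio_, atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        em = matrix_from(rng.random((5, 3)), list("abcde"), list("xyz"))
        with pytest.raises(ValueError):
            pca_embed(em, 4)
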