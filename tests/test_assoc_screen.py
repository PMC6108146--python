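import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from id4screen import (
    SyntheticConfig,
    generate_cohort,
    pearson_correlation,
    run_screen,
    standardize,
    svd_assoc_score,
    venn_partition,
)
from id4screen.assoc_screen import AssociationResult, selected_genes
from id4screen.errors import DegenerateInputError, ValidationError
from id4screen.panel import PANEL_66


def brute_force_r(x, y):
    """Double-loop covariance Pearson r, independent of numpy vector paths."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / (sxx * syy) ** 0.5


class TestStandardize:
    def test_closed_form(self):
        np.testing.assert_allclose(
            standardize([1, 2, 3]), [-1 / np.sqrt(2), 0, 1 / np.sqrt(2)],
            atol=1e-15,
        )

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_mean_zero_unit_norm(self, values):
        arr = np.asarray(values)
        if np.ptp(arr) == 0:
            with pytest.raises(DegenerateInputError):
                standardize(arr)
            return
        try:
            out = standardize(arr)
        except DegenerateInputError:
            # numerically constant after centering: legal degenerate outcome
            return
        # tolerance allows for cancellation on near-constant inputs
        assert abs(out.mean()) < 1e-9
        assert abs(np.linalg.norm(out) - 1) < 1e-12

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            standardize([5, 5, 5])


class TestSvdScore:
    def test_anticorrelated_pair_scores_sqrt_two(self):
        x = np.arange(10.0)
        score, r = svd_assoc_score(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)
        assert score == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_orthogonal_pair_scores_one(self):
        # exactly uncorrelated fixture
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        score, r = svd_assoc_score(x, y)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_and_full_svd(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.normal(size=30)
            y = 0.3 * x + rng.normal(size=30)
            score, r = svd_assoc_score(x, y)
            r_bf = brute_force_r(list(x), list(y))
            assert score == pytest.approx(np.sqrt(1 - r_bf), abs=1e-10)
            m = np.column_stack([standardize(x), standardize(y)])
            sv = np.linalg.svd(m, compute_uv=False)
            np.testing.assert_allclose(
                sorted(sv), sorted([np.sqrt(1 - r_bf), np.sqrt(1 + r_bf)]),
                atol=1e-10,
            )

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base, _ = svd_assoc_score(x, y)
        scaled, _ = svd_assoc_score(5 * x - 2, -0.1 * y + 7)
        # flipping the gene's sign flips r, hence the score moves to sqrt(1+r)
        _, r = svd_assoc_score(x, y)
        assert scaled == pytest.approx(np.sqrt(1 + r), abs=1e-10)
        same, _ = svd_assoc_score(2 * x + 1, 3 * y + 4)
        assert same == pytest.approx(base, abs=1e-12)

    def test_abs_correlation_mode(self):
        x = np.arange(12.0)
        score, r = svd_assoc_score(x, -x, mode="abs_correlation")
        assert score == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            svd_assoc_score([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValidationError):
            svd_assoc_score([1, 2, 3], [1, 2, 3, 4])


class TestPearson:
    def test_affine_relations(self):
        x = np.arange(10.0)
        r_pos, p_pos, n = pearson_correlation(x, 2 * x + 1)
        r_neg, _, _ = pearson_correlation(x, -x)
        assert r_pos == pytest.approx(1.0)
        assert r_neg == pytest.approx(-1.0)
        assert n == 10 and 0 < p_pos <= 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, p, n = pearson_correlation(x, y)
        assert r == pytest.approx(brute_force_r(list(x), list(y)), abs=1e-12)

    def test_symmetric_and_pairwise_complete(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6])
        y = np.array([2.0, 1, 3, np.nan, 4, 8])
        r_xy, p_xy, n = pearson_correlation(x, y)
        r_yx, p_yx, _ = pearson_correlation(y, x)
        assert n == 4
        assert r_xy == pytest.approx(r_yx) and p_xy == pytest.approx(p_yx)


def _screen_cohort(scores_by_gene):
    """Build a 2-stratum cohort whose ER+ screen sees prescribed genes."""
    from conftest import make_clinical, make_expression, make_methylation

    rng = np.random.default_rng(0)
    n = 40
    samples = [f"S{i}" for i in range(2 * n)]
    target = rng.normal(size=2 * n)
    rows = {"ID4": target}
    for gene, r in scores_by_gene.items():
        eps = rng.normal(size=2 * n)
        rows[gene] = r * target + np.sqrt(1 - r * r) * eps
    expr = make_expression(list(rows), samples, np.array(list(rows.values())))
    meth = make_methylation(["P1"], samples, [[0.5] * 2 * n])
    clin = make_clinical(samples, ["ER+"] * n + ["ER-"] * n)
    from id4screen import Cohort

    return Cohort(expression=expr, methylation=meth, clinical=clin)


class TestRunScreen:
    def test_median_rule_selects_strict_top_half(self):
        cohort = _screen_cohort({"G1": 0.9, "G2": 0.5, "G3": -0.5, "G4": -0.9})
        results = run_screen(cohort, "ID4", ["G1", "G2", "G3", "G4"])
        sel = selected_genes(results, "ER+")
        # jacobi score sqrt(1-r): the two negative correlates rank highest
        assert sel == {"G3", "G4"}
        assert len(sel) <= 2  # floor(panel/2) with distinct scores

    def test_all_equal_scores_select_nothing(self):
        cohort = _screen_cohort({})
        target = cohort.expression.values.loc["ID4"]
        for gene in ["C1", "C2", "C3"]:
            cohort.expression.values.loc[gene] = target.to_numpy()
        results = run_screen(cohort, "ID4", ["C1", "C2", "C3"])
        assert selected_genes(results, "ER+") == frozenset()
        assert selected_genes(results, "ER-") == frozenset()

    def test_missing_gene_listed(self, tiny_cohort):
        with pytest.raises(ValidationError, match="NOPE"):
            run_screen(tiny_cohort, "ID4", ["G1", "NOPE"])

    def test_deterministic_ordering(self, tiny_cohort):
        results = run_screen(tiny_cohort, "ID4", ["G2", "G1"])
        assert [(r.stratum, r.gene) for r in results] == [
            ("ER+", "G1"), ("ER+", "G2"), ("ER-", "G1"), ("ER-", "G2")
        ]

    def test_planted_stratum_specific_recovery(self):
        """6 genes planted in ER+ only vs a 60-gene null panel are recovered."""
        planted = dict.fromkeys(
            ["FOXA1", "GATA3", "ESR1", "CCND1", "AKT1", "IGF1R"], -0.4
        )
        config = SyntheticConfig(
            n_samples_per_stratum={"ER+": 500, "ER-": 500},
            planted_correlations={("ER+", g): r for g, r in planted.items()},
            seed=100,
        )
        cohort, _ = generate_cohort(config)
        results = run_screen(
            cohort, "ID4", PANEL_66, selection_quantile=0.92,
            mode="abs_correlation",
        )
        sel_pos = selected_genes(results, "ER+")
        sel_neg = selected_genes(results, "ER-")
        assert set(planted) <= sel_pos
        assert not (set(planted) & sel_neg)


class TestVenn:
    def _results(self, stratum, selected, panel=("E", "F", "G", "V")):
        return [
            AssociationResult(g, stratum, 1.0 + (g in selected), 0.0, 1.0, 10,
                              g in selected)
            for g in panel
        ]

    def test_set_algebra(self):
        part = venn_partition(self._results("A", {"F", "G", "E"}),
                              self._results("B", {"E", "V"}))
        assert part.only_a == {"F", "G"}
        assert part.only_b == {"V"}
        assert part.shared == {"E"}

    def test_disjoint_and_identical(self):
        disjoint = venn_partition(self._results("A", {"E"}),
                                  self._results("B", {"V"}))
        assert disjoint.shared == frozenset()
        same = venn_partition(self._results("A", {"E", "F"}),
                              self._results("B", {"E", "F"}))
        assert same.only_a == same.only_b == frozenset()
        assert same.shared == {"E", "F"}

    def test_panel_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            venn_partition(self._results("A", {"E"}),
                           self._results("B", {"E"}, panel=("E", "F")))
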