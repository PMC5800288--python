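"""Statistics layer against independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy import stats as sps

from pmhd.simulate import simulate_strain_panel
from pmhd.stats import (
    hcluster,
    label_phenotype,
    multiple_regression,
    pearson,
    t_test,
)


def _pearson_oracle(x, y):
    """Longhand covariance / (sd * sd) with the t-based p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (n - 1)
    r = cov / (x.std(ddof=1) * y.std(ddof=1))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


class TestPearson:
    def test_exact_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p, n = pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_reversal_gives_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        r, _, _ = pearson(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_matches_longhand_oracle_on_random_instances(self, rng):
        for _ in range(25):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            r, p, _ = pearson(x, y)
            r0, p0 = _pearson_oracle(x, y)
            assert r == pytest.approx(r0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_zero_variance_fails(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _ols_oracle(y, Z):
    """Normal equations on the intercept-augmented design."""
    X = np.column_stack([np.ones(len(y)), Z])
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    return beta, t, p, df


class TestRegression:
    def test_planted_coefficients_recovered_exactly(self, rng):
        z1 = rng.normal(size=8)
        z2 = rng.normal(size=8)

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        y = -3.0 * z(z1) - 1.0 * z(z2)
        reg = multiple_regression(y, np.column_stack([z1, z2]))
        assert reg.coef[0] == pytest.approx(-3.0, abs=1e-10)
        assert reg.coef[1] == pytest.approx(-1.0, abs=1e-10)

    def test_identity_predictor_dominates(self, rng):
        x1 = rng.normal(size=10)
        x2 = rng.normal(size=10)
        x2 -= x2 @ x1 / (x1 @ x1) * x1  # orthogonalize

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        y = z(x1)
        reg = multiple_regression(y, np.column_stack([x1, x2]))
        assert reg.std_coef[0] == pytest.approx(1.0, abs=1e-8)
        assert abs(reg.std_coef[1]) < 1e-8

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 12))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
            beta, t, pv, df = _ols_oracle(y, Z)
            reg = multiple_regression(y, X)
            assert np.allclose(reg.coef, beta[1:], atol=1e-10)
            assert np.allclose(reg.t_values, t[1:], atol=1e-10)
            assert np.allclose(reg.p_values, pv[1:], atol=1e-10)
            assert reg.df_resid == df
            # partial correlation from t and df
            assert np.allclose(
                reg.partial_corr, t[1:] / np.sqrt(t[1:] ** 2 + df), atol=1e-12
            )

    def test_single_predictor_standardized_coefficient_equals_pearson(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9) + 0.5 * x
        reg = multiple_regression(y, x[:, None])
        r, _, _ = pearson(x, y)
        assert reg.std_coef[0] == pytest.approx(r, abs=1e-12)

    def test_five_strains_two_predictors_is_accepted(self, rng):
        reg = multiple_regression(rng.normal(size=5), rng.normal(size=(5, 2)))
        assert reg.df_resid == 2

    def test_rank_deficiency_fails(self, rng):
        x = rng.normal(size=8)
        with pytest.raises(ValueError):
            multiple_regression(rng.normal(size=8), np.column_stack([x, 2 * x]))

    def test_all_p_values_in_unit_interval(self, rng):
        for _ in range(10):
            reg = multiple_regression(rng.normal(size=7), rng.normal(size=(7, 2)))
            assert all(0.0 <= p <= 1.0 for p in reg.p_values)


def _partition_sequence(merges, labels):
    """Sets merged at each step, for order-insensitive dendrogram comparison."""
    groups = {lab: frozenset([lab]) for lab in labels}
    out = []
    for m in merges:
        joined = groups[m.left] | groups[m.right]
        out.append((joined, m.height))
        keep = min(m.left, m.right)
        groups[keep] = joined
        del groups[max(m.left, m.right)]
    return out


def _scipy_partition_sequence(points, labels):
    Z = linkage(points, method="complete")
    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
    out = []
    for step, (a, b, h, _) in enumerate(Z):
        joined = clusters[int(a)] | clusters[int(b)]
        out.append((joined, h))
        clusters[len(labels) + step] = joined
    return out


class TestHcluster:
    def test_coincident_pair_merges_first_at_height_zero(self):
        d = hcluster([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]], labels=["a", "b", "c"],
                     zscore=False)
        assert (d.merges[0].left, d.merges[0].right) == ("a", "b")
        assert d.merges[0].height == 0.0

    def test_line_geometry_pairs_before_final_join(self):
        d = hcluster([[0.0], [1.0], [10.0], [11.0]], labels=list("abcd"),
                     zscore=False)
        first_two = {frozenset((m.left, m.right)) for m in d.merges[:2]}
        assert first_two == {frozenset("ab"), frozenset("cd")}

    def test_matches_scipy_complete_linkage_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 8))
            pts = rng.normal(size=(n, 3))
            labels = [f"s{i}" for i in range(n)]
            ours = _partition_sequence(hcluster(pts, labels, zscore=False).merges, labels)
            ref = _scipy_partition_sequence(pts, labels)
            for (ga, ha), (gb, hb) in zip(ours, ref):
                assert ga == gb
                assert ha == pytest.approx(hb, abs=1e-10)

    def test_input_order_invariance(self, rng):
        pts = rng.normal(size=(6, 2))
        labels = [f"s{i}" for i in range(6)]
        perm = rng.permutation(6)
        a = hcluster(pts, labels)
        b = hcluster(pts[perm], [labels[i] for i in perm])
        pa = _partition_sequence(a.merges, labels)
        pb = _partition_sequence(b.merges, labels)
        for (ga, ha), (gb, hb) in zip(pa, pb):
            assert ga == gb
            assert ha == pytest.approx(hb, abs=1e-9)

    def test_newick_output_is_well_formed(self):
        d = hcluster([[0.0], [1.0], [10.0]], labels=list("abc"), zscore=False)
        nwk = d.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c"]


def _ttest_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_separation_is_significant(self):
        t, p = t_test([1.0, 2.0, 3.0], [1001.0, 1002.0, 1003.0])
        assert p < 1e-6

    def test_matches_pooled_variance_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(size=3)
            b = rng.normal(loc=0.5, size=3)
            t, p = t_test(a, b)
            t0, p0 = _ttest_oracle(a, b)
            assert t == pytest.approx(t0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_welch_option_matches_scipy(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=6, scale=3.0)
        t, p = t_test(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_equal_constant_groups(self):
        assert t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


class TestPhenotypeLabel:
    @pytest.mark.parametrize(
        "gd,cross,expected",
        [
            (0.0, "A", ("low", "inducibility")),
            (9.999, "A", ("low", "inducibility")),
            (10.0, "A", ("high", "inducibility")),
            (100.0, "A", ("high", "inducibility")),
            (5.0, "A*", ("low", "susceptibility")),
            (50.0, "A*", ("high", "susceptibility")),
        ],
    )
    def test_threshold_is_strict_at_10(self, gd, cross, expected):
        assert label_phenotype(gd, cross) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_phenotype(101.0, "A")
        with pytest.raises(ValueError):
            label_phenotype(50.0, "B")


class TestStrainPanel:
    def test_gd_strictly_decreasing_in_pirna_when_only_suppressor(self):
        panel, _ = simulate_strain_panel(
            6, beta_pirna=-3.0, beta_kp=0.0, noise_sd=0.0, seed=3
        )
        ordered = panel.sort_values("pirna_rpm")
        gd = ordered["gd_f1_cross_a"].to_numpy()
        assert np.all(np.diff(gd) < 0)

    def test_null_model_gives_constant_gd(self):
        panel, _ = simulate_strain_panel(
            5, beta_pirna=0.0, beta_kp=0.0, noise_sd=0.0, seed=4
        )
        assert panel["gd_f1_cross_a"].nunique() == 1
        assert panel["gd_f1_cross_a"].iloc[0] == pytest.approx(50.0)

    def test_labels_follow_threshold(self):
        panel, _ = simulate_strain_panel(8, noise_sd=1.0, seed=5)
        for _, row in panel.iterrows():
            expected = "low" if row["gd_f1_cross_a"] < 10.0 else "high"
            assert row["inducibility"] == expected

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            simulate_strain_panel(3)

    def test_reproducible_under_seed(self):
        a, _ = simulate_strain_panel(5, seed=9)
        b, _ = simulate_strain_panel(5, seed=9)
        assert a.equals(b)
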