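"""Association statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from hlburden import assoc


# ---------------------------------------------------------------- oracles


def ols_oracle(y, X):
    """Normal-equations OLS: beta, classical SE, two-sided Wald p."""
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    t = beta / se
    p = 2 * st.t.sf(np.abs(t), dof)
    return beta, se, p


def fisher_oracle(table):
    """Full hypergeometric enumeration with the probability-mass rule."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs = st.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pr = st.hypergeom.pmf(x, n, r1, c1)
        if pr <= obs * (1 + 1e-9):
            total += pr
    return min(total, 1.0)


def bh_oracle(p, m=None):
    """O(m^2) literal step-up definition."""
    p = np.asarray(p, float)
    m = m or len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(len(p))
    for i, idx in enumerate(order):
        q[idx] = min(min(m * p[order[j]] / (j + 1) for j in range(i, len(p))), 1.0)
    return q


def logistic_oracle_2param(y, x):
    """Grid-refined maximum likelihood for intercept + slope."""

    def nll(b0, b1):
        eta = b0 + b1 * x
        return np.sum(np.log1p(np.exp(eta))) - np.sum(y * eta)

    b0, b1, width = 0.0, 0.0, 4.0
    for _ in range(40):
        g0 = np.linspace(b0 - width, b0 + width, 21)
        g1 = np.linspace(b1 - width, b1 + width, 21)
        vals = [(nll(a, b), a, b) for a in g0 for b in g1]
        _, b0, b1 = min(vals)
        width *= 0.45
    return b0, b1


# ---------------------------------------------------------------- linear


class TestLinear:
    def test_exact_line(self):
        res = assoc.linear_test([1, 3, 5, 7], [0, 1, 2, 3])
        assert res["beta"] == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_predictor_gives_zero_beta(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, -1.0, -1.0])
        assert assoc.linear_test(y, x)["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        cov = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        x = rng.normal(size=n)
        y = 0.5 * x + cov @ [0.2, -0.1, 0.3, 0.0] + rng.normal(size=n)
        res = assoc.linear_test(y, x, cov)
        X = np.column_stack([np.ones(n), x, cov.to_numpy()])
        beta, se, p = ols_oracle(np.asarray(y), X)
        assert res["beta"] == pytest.approx(beta[1], abs=1e-8)
        assert res["se"] == pytest.approx(se[1], abs=1e-8)
        assert res["p"] == pytest.approx(p[1], abs=1e-8)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            assoc.linear_test([1, 2, 3], [5, 5, 5])

    def test_collinear_column_named(self, rng):
        n = 30
        cov = pd.DataFrame({"dup": rng.normal(size=n)})
        cov["copy"] = cov["dup"] * 2
        with pytest.raises(ValueError, match="copy"):
            assoc.linear_test(rng.normal(size=n), rng.normal(size=n), cov)

    def test_scan_matches_per_column_fits(self, rng):
        n, m = 120, 8
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        X = rng.normal(size=(n, m))
        y = X[:, 0] * 0.3 + rng.normal(size=n)
        scan = assoc.linear_scan(y, X, cov)
        for j in range(m):
            single = assoc.linear_test(y, X[:, j], cov)
            assert scan["beta"][j] == pytest.approx(single["beta"], abs=1e-10)
            assert scan["se"][j] == pytest.approx(single["se"], abs=1e-10)
            assert scan["p"][j] == pytest.approx(single["p"], abs=1e-10)

    def test_scan_degenerate_column_nan(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        scan = assoc.linear_scan(rng.normal(size=20), X)
        assert np.isnan(scan["beta"][0]) and np.isfinite(scan["beta"][1])


# ---------------------------------------------------------------- logistic


class TestLogistic:
    def test_two_by_two_equals_log_odds_ratio(self):
        # 40 exposed (12 cases), 60 unexposed (6 cases)
        x = np.r_[np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(12), np.zeros(28), np.ones(6), np.zeros(54)]
        res = assoc.logistic_test(y, x)
        odds_ratio = (12 * 54) / (28 * 6)
        assert res["beta"] == pytest.approx(np.log(odds_ratio), abs=1e-6)

    def test_matches_grid_likelihood_oracle(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        res = assoc.logistic_test(y, x)
        _, b1 = logistic_oracle_2param(y, x)
        assert res["beta"] == pytest.approx(b1, abs=1e-4)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        res = assoc.logistic_test(x.copy(), x)
        assert res["separation"] and np.isnan(res["p"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            assoc.logistic_test(np.zeros(10), np.arange(10))

    def test_null_beta_near_zero(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(float)
        res = assoc.logistic_test(y, x)
        assert abs(res["beta"]) < 3 * res["se"] + 0.05


def test_degree_level_effects_positive_injected_effect(small_cohort):
    """With a strong injected gene effect, moderate+ degrees show positive burden betas."""
    from hlburden import phenotype as ph
    from hlburden.burden import gene_burden, total_burden
    from hlburden.qualify import cohort_allele_frequency, qualify_variants

    c = small_cohort
    af = cohort_allele_frequency(c.rare_genotypes)
    qual = qualify_variants(c.rare_variants, af)
    b = gene_burden(c.rare_genotypes, c.rare_variants["variant_id"].tolist(), qual, c.individual_ids)
    phen = ph.assign_phenotype(c.audiograms, c.phecodes, c.individual_ids, phecode="389")
    cov = assoc.build_covariates(c.covariates.set_index("individual_id"), n_pcs=5)
    res = assoc.degree_level_effects(phen, {"all": total_burden(b)}, cov)
    assert set(res["degree"]) <= {1, 2, 3, 4}
    assert {"beta", "se", "p"} <= set(res.columns)


# ---------------------------------------------------------------- fisher


class TestFisher:
    def test_symmetric_table(self):
        assert assoc.fisher_carrier_test([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        from math import comb

        p = assoc.fisher_carrier_test([[0, 10], [10, 0]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_matches_enumeration(self):
        p = assoc.fisher_carrier_test([[1, 9], [11, 3]])
        assert p == pytest.approx(fisher_oracle([[1, 9], [11, 3]]), rel=1e-9)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning):
            assert assoc.fisher_carrier_test([[0, 0], [3, 4]]) == 1.0

    def test_enumeration_equivalence_random_tables(self, rng):
        for _ in range(40):
            t = rng.integers(0, 16, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert assoc.fisher_carrier_test(t) == pytest.approx(fisher_oracle(t.tolist()), rel=1e-8)


# ---------------------------------------------------------------- lambda / FDR / replication


class TestGenomicLambda:
    def test_chi2_one_gives_closed_form(self):
        p = np.full(10, 2 * st.norm.sf(1.0))  # chi2 = 1 exactly
        assert assoc.genomic_lambda(p) == pytest.approx(1 / 0.4549364231, rel=1e-6)

    def test_uniform_null_is_calibrated(self, rng):
        p = rng.random(100_000)
        assert assoc.genomic_lambda(p) == pytest.approx(1.0, abs=0.02)

    def test_scale_equivariance(self, rng):
        chi2 = st.chi2.rvs(1, size=20_000, random_state=123)
        p1 = st.chi2.sf(chi2, 1)
        p2 = st.chi2.sf(2 * chi2, 1)
        lam1 = assoc.genomic_lambda(p1)
        lam2 = assoc.genomic_lambda(p2)
        assert lam2 / lam1 == pytest.approx(2.0, rel=0.05)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            assoc.genomic_lambda([])
        with pytest.raises(ValueError):
            assoc.genomic_lambda([0.0, 0.5])


class TestBH:
    def test_known_gene_scan_values(self):
        # two observed p-values among 169 tests (the rest at 1)
        q = assoc.bh_adjust([5.20e-6, 7.00e-4], m=169)
        assert q[0] == pytest.approx(0.0008788, abs=5e-8)
        assert q[1] == pytest.approx(0.05915, abs=5e-6)

    def test_exome_wide_scan_values_with_stepup_minimum(self):
        q = assoc.bh_adjust([3.31e-5, 6.89e-5, 1.88e-4, 2.03e-4], m=373)
        assert np.round(q, 4).tolist() == [0.0123, 0.0128, 0.0189, 0.0189]
        # rank 3 is pulled down to the rank-4 value by the step-up minimum
        assert q[2] == pytest.approx(q[3])

    def test_single_p_identity(self):
        assert assoc.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_oracle_equivalence_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(assoc.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_permutation_invariance_and_monotonicity(self, rng):
        p = rng.random(25)
        q = assoc.bh_adjust(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(assoc.bh_adjust(p[perm]), q[perm], atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_effective_m_cannot_shrink(self):
        with pytest.raises(ValueError):
            assoc.bh_adjust([0.1, 0.2], m=1)


class TestReplication:
    def test_bonferroni_min_p_decisions(self):
        assert assoc.bonferroni_min_p_replication(np.r_[8.0e-4, np.ones(23)])["replicated"]
        assert not assoc.bonferroni_min_p_replication(np.r_[0.011, np.ones(23)])["replicated"]
        assert assoc.bonferroni_min_p_replication([0.04])["replicated"]

    def test_binomial_tail(self):
        assert assoc.binomial_replication(9, 45, 0.05) == pytest.approx(3.35e-4, rel=0.01)
        assert assoc.binomial_replication(0, 45, 0.05) == 1.0
        assert assoc.binomial_replication(3, 3, 0.5) == pytest.approx(0.125)

    def test_binomial_input_validation(self):
        with pytest.raises(ValueError):
            assoc.binomial_replication(2, 1)
        with pytest.raises(ValueError):
            assoc.binomial_replication(1, 10, p0=0.0)


# ---------------------------------------------------------------- permutation calibration


class TestPermutationCalibration:
    @staticmethod
    def make_runner(rng, n=800, m=150):
        X = (rng.random((n, m)) < 0.05).astype(float)
        carriers = X.sum(axis=0)

        def runner(threshold, y_perm):
            keep = carriers > threshold
            if not keep.any():
                return np.array([])
            return assoc.linear_scan(y_perm, X[:, keep])["p"].to_numpy()

        return runner

    def test_null_lambda_near_one_and_threshold_chosen(self, rng):
        runner = self.make_runner(rng)
        y = rng.normal(size=800)
        rep = assoc.permutation_calibration(runner, y, start=0, increment=5, stop=30, n_perms=5, seed=9)
        assert rep.chosen_threshold is not None
        lam = rep.trajectory[-1][1]
        assert 0.8 < lam < 1.2

    def test_trajectory_thresholds_increase_and_tests_shrink(self, rng):
        runner = self.make_runner(rng)
        y = rng.normal(size=800)
        rep = assoc.permutation_calibration(
            runner, y, start=0, increment=10, stop=40, lambda_max=0.0, n_perms=2, seed=3
        )
        thr = [t for t, _, _ in rep.trajectory]
        ntests = [n for _, _, n in rep.trajectory]
        assert thr == sorted(thr)
        assert all(b <= a for a, b in zip(ntests, ntests[1:]))

    def test_seed_reproducibility(self, rng):
        runner = self.make_runner(rng)
        y = rng.normal(size=800)
        r1 = assoc.permutation_calibration(runner, y, start=0, increment=5, stop=10, n_perms=3, seed=42)
        r2 = assoc.permutation_calibration(runner, y, start=0, increment=5, stop=10, n_perms=3, seed=42)
        assert r1.trajectory == r2.trajectory and r1.chosen_threshold == r2.chosen_threshold


# ---------------------------------------------------------------- gwas filters


class TestGwas:
    def test_filters_exclude_variants(self, rng):
        n = 300
        D = np.column_stack(
            [
                rng.binomial(2, 0.005, n),  # MAF below 1%
                rng.binomial(2, 0.3, n),  # passes
                rng.binomial(2, 0.3, n),  # fails imputation quality
            ]
        ).astype(float)
        variants = pd.DataFrame({"variant_id": ["low_maf", "ok", "low_rsq"], "rsq": [0.9, 0.9, 0.2]})
        y = rng.normal(size=n)
        res = assoc.gwas(D, variants, y)
        assert list(res["unit"]) == ["ok"]

    def test_causal_variant_detected(self, rng):
        n = 2000
        m = 30
        D = rng.binomial(2, 0.25, size=(n, m)).astype(float)
        y = 0.4 * D[:, 7] + rng.normal(size=n)
        variants = pd.DataFrame({"variant_id": [f"v{j}" for j in range(m)], "rsq": 0.99})
        res = assoc.gwas(D, variants, y)
        assert res.loc[res["p"].idxmin(), "unit"] == "v7"
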