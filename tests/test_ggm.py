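"""Shrinkage covariance, partial correlations, bootstrap and edge calling."""

import numpy as np
import pytest
from scipy import stats

import coexnet as cx
from coexnet import ggm
from coexnet.synthetic import ExpressionMatrix, PhenotypeVector


def _expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
    )


def residual_pcor(X: np.ndarray, i: int, j: int) -> float:
    """Independent oracle: partial correlation via residual regression.

    Regress variables i and j (rows of X) on all remaining variables and
    correlate the residuals.
    """
    p, n = X.shape
    others = [k for k in range(p) if k not in (i, j)]
    Z = np.vstack([np.ones(n), X[others]]).T
    ri = X[i] - Z @ np.linalg.lstsq(Z, X[i], rcond=None)[0]
    rj = X[j] - Z @ np.linalg.lstsq(Z, X[j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


class TestShrinkCovariance:
    def test_full_shrinkage_is_diagonal(self):
        rng = np.random.default_rng(0)
        X = _expr(rng.standard_normal((4, 30)))
        C = cx.shrink_covariance(X, intensity=1.0)
        S = np.cov(X.values)
        assert np.allclose(C.matrix, np.diag(np.diag(S)))

    def test_zero_shrinkage_is_empirical_covariance(self):
        rng = np.random.default_rng(1)
        X = _expr(rng.standard_normal((3, 50)))
        C = cx.shrink_covariance(X, intensity=0.0)
        assert np.allclose(C.matrix, np.cov(X.values))

    def test_half_shrinkage_matches_hand_arithmetic(self):
        rng = np.random.default_rng(2)
        X = _expr(rng.standard_normal((3, 20)))
        S = np.cov(X.values)
        expected = 0.5 * S + 0.5 * np.diag(np.diag(S))
        C = cx.shrink_covariance(X, intensity=0.5)
        assert np.allclose(C.matrix, expected)

    def test_analytic_intensity_in_unit_interval_and_pd(self):
        rng = np.random.default_rng(3)
        X = _expr(rng.standard_normal((40, 10)))  # p >> n
        C = cx.shrink_covariance(X)
        assert 0.0 <= C.shrinkage_intensity <= 1.0
        assert np.linalg.eigvalsh(C.matrix).min() > 0

    def test_constant_gene_raises_with_name(self):
        values = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="g0"):
            cx.shrink_covariance(_expr(values))


class TestPartialCorrelations:
    def test_diagonal_covariance_gives_zero_offdiagonal(self):
        C = cx.ShrunkCovariance(np.diag([1.0, 2.0, 3.0]), 0.5, ["a", "b", "c"])
        P = cx.partial_correlations(C)
        off = P.matrix - np.eye(3)
        assert np.allclose(off, 0.0)

    def test_two_variables_pcor_equals_correlation(self):
        r = 0.63
        C = cx.ShrunkCovariance(np.array([[1.0, r], [r, 1.0]]), 0.0, ["a", "b"])
        P = cx.partial_correlations(C)
        assert P.matrix[0, 1] == pytest.approx(r, abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        # matrix-inversion route vs the regression-residual definition
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = int(rng.integers(3, 7))
            n = 200
            A = rng.standard_normal((p, p))
            cov = A @ A.T + p * np.eye(p)
            X = np.linalg.cholesky(cov) @ rng.standard_normal((p, n))
            S = np.cov(X)
            P = cx.partial_correlations(cx.ShrunkCovariance(S, 0.0, None))
            for i in range(p):
                for j in range(i + 1, p):
                    assert P.matrix[i, j] == pytest.approx(
                        residual_pcor(X, i, j), abs=1e-8
                    )

    def test_output_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((5, 5))
        C = cx.ShrunkCovariance(A @ A.T + 5 * np.eye(5), 0.0, None)
        P = cx.partial_correlations(C)
        assert np.allclose(P.matrix, P.matrix.T)
        assert np.allclose(np.diag(P.matrix), 1.0)


class TestBootstrap:
    def test_identity_resample_equals_plain_estimate(self, monkeypatch):
        rng = np.random.default_rng(6)
        X = _expr(rng.standard_normal((5, 24)))
        monkeypatch.setattr(ggm, "_resample_indices", lambda r, n, size: np.arange(n))
        boot = cx.bootstrap_partial_correlations(X, n_bootstrap=1, bootstrap_size=24, seed=0)
        plain = cx.partial_correlations(cx.shrink_covariance(X))
        assert np.allclose(boot.matrix, plain.matrix)

    def test_paper_defaults(self):
        import inspect

        sig = inspect.signature(cx.bootstrap_partial_correlations)
        assert sig.parameters["n_bootstrap"].default == 4000
        assert sig.parameters["bootstrap_size"].default == 20

    def test_recovers_planted_structure(self, small_study):
        truth, expr, _ = small_study
        est = cx.bootstrap_partial_correlations(expr, n_bootstrap=400, bootstrap_size=20, seed=9)
        iu, ju = np.triu_indices(30, k=1)
        r = np.corrcoef(est.matrix[iu, ju], truth.true_partial_correlations()[iu, ju])[0, 1]
        assert r > 0.45  # ceiling set by sampling noise at n=56; see docs

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(7)
        X = _expr(rng.standard_normal((4, 15)))
        perm = rng.permutation(15)
        Xp = ExpressionMatrix(
            values=X.values[:, perm],
            gene_ids=X.gene_ids,
            sample_ids=[X.sample_ids[k] for k in perm],
        )
        a = cx.bootstrap_partial_correlations(X, n_bootstrap=20, bootstrap_size=10, seed=3)
        b = cx.bootstrap_partial_correlations(Xp, n_bootstrap=20, bootstrap_size=10, seed=3)
        assert np.array_equal(a.matrix, b.matrix)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(8)
        X = _expr(rng.standard_normal((4, 15)))
        a = cx.bootstrap_partial_correlations(X, n_bootstrap=10, bootstrap_size=8, seed=1)
        b = cx.bootstrap_partial_correlations(X, n_bootstrap=10, bootstrap_size=8, seed=1)
        assert np.array_equal(a.matrix, b.matrix)

    def test_shrinkage_to_one_kills_offdiagonals(self):
        rng = np.random.default_rng(9)
        X = _expr(rng.standard_normal((4, 30)))
        P = cx.partial_correlations(cx.shrink_covariance(X, intensity=1.0))
        assert np.allclose(P.matrix, np.eye(4))


class TestEdgeSignificance:
    def test_all_zero_pcor_gives_empty_edge_set(self):
        P = cx.PartialCorrelationEstimate(np.eye(12), [f"g{i}" for i in range(12)])
        E = cx.edge_significance(P, cutoff=0.2)
        assert len(E) == 0

    def test_planted_signal_is_retained(self):
        # 999 null draws at kappa = 50 plus one strong value of 0.9
        rng = np.random.default_rng(10)
        a = (50 - 1) / 2
        null = 2 * rng.beta(a, a, size=999) - 1
        values = np.concatenate([null, [0.9]])
        p = 46  # 46*45/2 = 1035 >= 1000 slots
        mat = np.eye(p)
        iu, ju = np.triu_indices(p, k=1)
        mat[iu[: len(values)], ju[: len(values)]] = values
        mat = np.triu(mat) + np.triu(mat, 1).T
        P = cx.PartialCorrelationEstimate(mat, [f"g{i:02d}" for i in range(p)])
        E = cx.edge_significance(P, cutoff=0.2)
        strong = iu[len(values) - 1], ju[len(values) - 1]
        names = {(a_, b_) for a_, b_, _, _ in E.edges}
        assert (f"g{strong[0]:02d}", f"g{strong[1]:02d}") in names

    def test_few_pairs_falls_back_to_quantile(self):
        mat = np.eye(4)
        mat[0, 1] = mat[1, 0] = 0.9
        mat[2, 3] = mat[3, 2] = 0.05
        P = cx.PartialCorrelationEstimate(mat, list("abcd"))
        with pytest.warns(UserWarning, match="fewer than 10"):
            E = cx.edge_significance(P, cutoff=0.2)
        assert ("a", "b") in {(x, y) for x, y, _, _ in E.edges}

    def test_support_recovery_precision(self, small_study):
        truth, expr, _ = small_study
        est = cx.bootstrap_partial_correlations(expr, n_bootstrap=400, bootstrap_size=20, seed=11)
        E = cx.edge_significance(est, cutoff=0.2)
        sup = truth.support()
        gi = {g: i for i, g in enumerate(expr.gene_ids)}
        tp = sum(1 for a, b, _, _ in E.edges if sup[gi[a], gi[b]])
        assert len(E) >= 1
        assert tp / len(E) >= 0.8

    def test_bad_cutoff_raises(self):
        P = cx.PartialCorrelationEstimate(np.eye(5), [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="cutoff"):
            cx.edge_significance(P, cutoff=1.5)


class TestPhenotypePcor:
    def test_misaligned_samples_raise_with_names(self, small_study):
        _, expr, pheno = small_study
        bad = PhenotypeVector(values=pheno.values, sample_ids=["x" + s for s in pheno.sample_ids])
        with pytest.raises(ValueError, match="xs"):
            cx.phenotype_partial_correlations(expr, bad, n_bootstrap=5)

    def test_sample_order_of_phenotype_is_aligned_by_id(self, small_study):
        _, expr, pheno = small_study
        perm = np.random.default_rng(0).permutation(len(pheno.values))
        shuffled = PhenotypeVector(
            values=pheno.values[perm],
            sample_ids=[pheno.sample_ids[k] for k in perm],
        )
        a = cx.phenotype_partial_correlations(expr, pheno, n_bootstrap=30, seed=2)
        b = cx.phenotype_partial_correlations(expr, shuffled, n_bootstrap=30, seed=2)
        assert np.array_equal(a.rho, b.rho)

    def test_duplicate_of_gene_never_silently_nan(self, small_study):
        _, expr, _ = small_study
        dup = PhenotypeVector(values=expr.values[0].copy(), sample_ids=list(expr.sample_ids))
        rho = cx.phenotype_partial_correlations(expr, dup, n_bootstrap=30, seed=3)
        assert np.all(np.isfinite(rho.rho))
        assert np.abs(rho.rho).max() <= 1.0
        # the duplicated gene carries by far the strongest partial correlation
        assert rho.gene_ids[int(np.argmax(np.abs(rho.rho)))] == expr.gene_ids[0]

    def test_pure_noise_phenotype_has_small_pcor(self, small_study):
        _, expr, _ = small_study
        rng = np.random.default_rng(12)
        noise = PhenotypeVector(values=rng.standard_normal(56), sample_ids=list(expr.sample_ids))
        rho = cx.phenotype_partial_correlations(expr, noise, n_bootstrap=100, seed=4)
        assert np.abs(rho.rho).mean() < 0.15

    def test_phenotype_module_enrichment(self):
        truth = cx.make_precision_matrix(p=30, module_sizes=[10, 10, 10], seed=20)
        expr = cx.sample_expression(truth, n=200, seed=21)
        pheno = cx.attach_phenotype(expr, truth, effect_size=1.0, noise_sd=0.2, seed=22)
        rho = cx.phenotype_partial_correlations(expr, pheno, n_bootstrap=150, seed=23)
        labels = np.array([truth.true_partition[g] for g in rho.gene_ids])
        inside = rho.abs_rho[labels == truth.phenotype_module]
        outside = rho.abs_rho[labels != truth.phenotype_module]
        assert inside.mean() > outside.mean()


class TestModelFacade:
    def test_fit_returns_results_with_summary(self, small_study):
        _, expr, pheno = small_study
        res = cx.CoexpressionGGM(expr, pheno).fit(n_bootstrap=60, seed=1)
        text = res.summary()
        assert "genes" in text and "edges retained" in text
        assert res.network().n_nodes == 30
        assert res.phenotype_pcor is not None

    def test_from_dataframe_round_trip(self, small_study):
        import pandas as pd

        _, expr, pheno = small_study
        df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
        s = pd.Series(pheno.values, index=pheno.sample_ids)
        model = cx.CoexpressionGGM.from_dataframe(df, s)
        assert model.expression.gene_ids == expr.gene_ids
        assert np.array_equal(model.expression.values, expr.values)


class TestNullMixture:
    def test_kappa_estimate_close_to_truth_on_pure_null(self):
        rng = np.random.default_rng(13)
        a = (200 - 1) / 2
        values = 2 * rng.beta(a, a, size=5000) - 1
        eta0, kappa = ggm.fit_null_mixture(values)
        assert eta0 > 0.9
        assert 140 <= kappa <= 280  # truth 200, ML spread at n=5000

    def test_local_fdr_monotone_in_magnitude(self):
        scores = ggm.local_fdr_scores(np.array([0.0, 0.1, 0.3, 0.6, 0.9]), 0.9, 50.0)
        assert np.all(np.diff(scores) <= 1e-12)
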