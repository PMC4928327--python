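"""Periodic template bases and per-gene regression feature extraction."""

import numpy as np
import pytest
import statsmodels.api as sm

from cyclefe import (
    embed_genes,
    fit_periodic,
    fit_to_loadings,
    make_periodic_basis,
    rank_equal_count,
)
from cyclefe.periodic import _wave, ols_f_test

from conftest import make_matrix


class TestBasisConstruction:
    def test_sin_peaks_at_quarter_period(self):
        b = make_periodic_basis("sin", T=12, M=36)
        f = b.regressors[:, 0]
        assert f[2] == pytest.approx(1.0)  # t=3 = T/4
        assert f[8] == pytest.approx(-1.0)  # t=9 = 3T/4

    def test_triangle_rises_linearly(self):
        b = make_periodic_basis("triangle", T=8, M=16)
        f = b.regressors[:, 0]
        assert f[0] == pytest.approx(0.5)  # halfway up the rise to t=2
        assert f[1] == pytest.approx(1.0)
        assert f[5] == pytest.approx(-1.0)

    def test_square_boundary_convention(self):
        b = make_periodic_basis("square", T=8, M=16)
        f = b.regressors[:, 0]
        assert f[1] == 1.0  # t=2
        assert f[5] == -1.0  # t=6
        assert f[3] == 0.0  # t=4: sin crossing -> 0

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            make_periodic_basis("sawtooth", T=8, M=16)

    @pytest.mark.parametrize("kind", ["sin", "square", "triangle"])
    @pytest.mark.parametrize("T", [8.0, 12.0])
    def test_symmetry_identities(self, kind, T):
        # periodicity, half-period antisymmetry, mirror symmetry about T/4
        t = np.linspace(0.05, 4 * T, 640)
        f = lambda x: _wave(kind, np.atleast_1d(x), T)
        np.testing.assert_allclose(f(t + T), f(t), atol=1e-10)
        np.testing.assert_allclose(f(t + T / 2), -f(t), atol=1e-10)
        np.testing.assert_allclose(f(T / 4 - t), f(T / 4 + t), atol=1e-10)
        assert np.max(np.abs(f(t))) <= 1 + 1e-12

    @pytest.mark.parametrize("kind", ["sin", "square", "triangle"])
    def test_quarter_shift_regressors_orthogonal_on_whole_periods(self, kind):
        b = make_periodic_basis(kind, T=12, M=36)  # three whole periods
        f, g = b.regressors.T
        assert abs(f @ g) < 1e-10


class TestFitPeriodic:
    def grid(self, M=36, T=12):
        return np.arange(1, M + 1), T

    def test_exact_sinusoid_recovery(self):
        t, T = self.grid()
        X = make_matrix((3 + 2 * np.sin(2 * np.pi * t / T))[None, :].repeat(2, 0))
        res = fit_periodic(X, make_periodic_basis("sin", T=T, M=len(t)))
        np.testing.assert_allclose(res.coef[0], [3, 2, 0], atol=1e-10)
        assert res.pvalues[0] < 1e-30

    def test_constant_gene_has_no_fit(self):
        t, T = self.grid()
        X = make_matrix(np.vstack([np.full(len(t), 4.0), np.sin(t)]))
        res = fit_periodic(X, make_periodic_basis("sin", T=T, M=len(t)))
        assert res.fvalues[0] == 0.0
        assert res.pvalues[0] == 1.0

    def test_cosine_loads_on_quarter_shift_regressor(self):
        t, T = self.grid()
        X = make_matrix(np.cos(2 * np.pi * t / T)[None, :].repeat(2, 0))
        res = fit_periodic(X, make_periodic_basis("sin", T=T, M=len(t)))
        np.testing.assert_allclose(res.coef[0], [0, 0, 1], atol=1e-10)

    def test_grid_length_mismatch_errors(self, rng):
        X = make_matrix(rng.normal(size=(3, 20)))
        with pytest.raises(ValueError, match="grid length"):
            fit_periodic(X, make_periodic_basis("sin", T=12, M=36))

    def test_matches_statsmodels_f_test(self, rng):
        t, T = self.grid(M=24, T=8)
        basis = make_periodic_basis("sin", T=T, M=24)
        X = rng.normal(size=(10, 24))
        res = fit_periodic(make_matrix(X), basis)
        design = sm.add_constant(basis.regressors)
        for i in range(10):
            fit = sm.OLS(X[i], design).fit()
            assert res.fvalues[i] == pytest.approx(fit.fvalue, rel=1e-8)
            assert res.pvalues[i] == pytest.approx(fit.f_pvalue, rel=1e-6, abs=1e-12)
            np.testing.assert_allclose(res.coef[i], fit.params, atol=1e-8)

    def test_collinear_regressors_rejected(self, rng):
        from cyclefe.periodic import PeriodicBasis

        col = rng.normal(size=12)
        basis = PeriodicBasis(
            kind="sin", period=4, regressors=np.column_stack([col, 2 * col]),
            labels=["a", "b"],
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_periodic(make_matrix(rng.normal(size=(3, 12))), basis)

    def test_period_grids_cover_whole_cycles(self):
        # 36 points at T=12 span three periods; 16 points at T=8 span two
        for T, M, cycles in [(12, 36, 3), (8, 16, 2)]:
            b = make_periodic_basis("sin", T=T, M=M)
            f = b.regressors[:, 0]
            np.testing.assert_allclose(np.roll(f, T), f, atol=1e-10)
            assert M / T == cycles


class TestFitToLoadings:
    def test_gene_equal_to_loading_fits_perfectly(self, rng):
        X = rng.normal(size=(40, 12))
        X -= X.mean(axis=0)
        E = embed_genes(X, K=3)
        v2 = E.loadings[:, 1]
        Y = np.vstack([v2, rng.normal(size=12)])
        res = fit_to_loadings(make_matrix(Y), E, omega=(2,))
        assert res.pvalues[0] < 1e-12

    def test_residualized_gene_has_no_fit(self, rng):
        X = rng.normal(size=(40, 12))
        X -= X.mean(axis=0)
        E = embed_genes(X, K=3)
        v = E.loadings[:, :2]
        v = v - v.mean(axis=0)
        design = np.column_stack([np.ones(12), v])
        y = rng.normal(size=12)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        y_orth = y - design @ beta  # project out intercept and regressors
        res = fit_to_loadings(make_matrix(np.vstack([y_orth, y])), E, omega=(1, 2))
        assert res.fvalues[0] == pytest.approx(0.0, abs=1e-8)
        assert res.pvalues[0] == pytest.approx(1.0, abs=1e-6)

    def test_empty_omega_errors(self, rng):
        X = rng.normal(size=(20, 10))
        E = embed_genes(X, K=3)
        with pytest.raises(ValueError):
            fit_to_loadings(make_matrix(X), E, omega=())


class TestRankEqualCount:
    def make_result(self, pvals, fvals=None):
        from cyclefe.periodic import PeriodicFitResult

        pvals = np.asarray(pvals, dtype=float)
        fvals = np.asarray(
            fvals if fvals is not None else 1 / (pvals + 1e-9), dtype=float
        )
        return PeriodicFitResult(
            gene_ids=[f"g{i + 1}" for i in range(len(pvals))],
            coef=np.zeros((len(pvals), 3)),
            fvalues=fvals,
            pvalues=pvals,
            basis="sin(T=12)",
        )

    def test_zero_returns_empty(self):
        assert rank_equal_count(self.make_result([0.1, 0.2]), 0).gene_ids == []

    def test_full_count_returns_all_ordered_by_p(self):
        res = rank_equal_count(self.make_result([0.5, 0.001, 0.2]), 3)
        assert res.gene_ids == ["g2", "g3", "g1"]

    def test_top_two(self):
        res = rank_equal_count(self.make_result([0.5, 0.001, 0.2]), 2)
        assert res.gene_ids == ["g2", "g3"]

    def test_tie_broken_by_larger_f_then_input_order(self):
        res = rank_equal_count(
            self.make_result([0.1, 0.1, 0.1], fvals=[2.0, 5.0, 5.0]), 3
        )
        assert res.gene_ids == ["g2", "g3", "g1"]

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            rank_equal_count(self.make_result([0.1]), -1)


def test_harmonic_regression_equivalence(rng):
    """The sin-basis fit ranks genes exactly as single-frequency harmonic
    regression solved by explicit normal equations."""
    M, T = 24, 8
    t = np.arange(1, M + 1)
    basis = make_periodic_basis("sin", T=T, M=M)
    X = rng.normal(size=(30, M))
    res = fit_periodic(make_matrix(X), basis)
    design = np.column_stack(
        [np.ones(M), np.sin(2 * np.pi * t / T), np.cos(2 * np.pi * t / T)]
    )
    xtx_inv = np.linalg.inv(design.T @ design)
    F = np.empty(30)
    for i in range(30):
        beta = xtx_inv @ design.T @ X[i]
        rss = ((X[i] - design @ beta) ** 2).sum()
        tss = ((X[i] - X[i].mean()) ** 2).sum()
        F[i] = ((tss - rss) / 2) / (rss / (M - 3))
    np.testing.assert_allclose(res.fvalues, F, rtol=1e-8)
    assert list(np.argsort(res.pvalues)) == list(np.argsort(-F))
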