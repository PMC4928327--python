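"""Regression-based feature extraction with periodic templates.

The comparator to projection-based selection: each gene is fitted by
ordinary least squares to

    x(t) = C₀ + C₁ f(t) + C₂ f(t + T/4)

where f is a fixed periodic template with period T (in time-point units) and
the quarter-period shift lets the two coefficients encode an arbitrary
phase. Templates satisfy f(t+T) = f(t), f(t+T/2) = −f(t) and mirror symmetry
about T/4; the implemented shapes are the sinusoid, the square wave (zero at
its crossings) and the triangle wave, all with unit amplitude. Genes are
ranked by the overall F-test P-value of the regression.

Alternatively the regressors can be the centred PC loadings of selected
components, which measures how well a gene tracks the extracted temporal
profiles directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import ExpressionMatrix, GeneList
from .embedding import EmbeddingResult

_ZERO_TOL = 1e-12


@dataclass
class PeriodicBasis:
    """Regressor sequences evaluated on the time grid t_j = j, j = 1..M."""

    kind: str
    period: float | None
    regressors: np.ndarray  # (M, p)
    labels: list[str]

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]


@dataclass
class PeriodicFitResult:
    """Per-gene OLS coefficients and overall-F fit P-values."""

    gene_ids: list[str]
    coef: np.ndarray  # (N, 1 + p): intercept C0 first
    fvalues: np.ndarray
    pvalues: np.ndarray
    basis: str

    def ranked_order(self) -> np.ndarray:
        """Gene order by ascending P, ties by descending F, then input order."""
        n = len(self.pvalues)
        return np.lexsort((np.arange(n), -self.fvalues, self.pvalues))

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = {f"C{j}": self.coef[:, j] for j in range(self.coef.shape[1])}
        pd.DataFrame(
            {"gene_id": self.gene_ids, **cols, "F": self.fvalues, "p": self.pvalues}
        ).to_csv(path, sep="\t", index=False)


def _wave(kind: str, t: np.ndarray, T: float) -> np.ndarray:
    phase = 2 * np.pi * t / T
    if kind == "sin":
        return np.sin(phase)
    if kind == "square":
        s = np.sin(phase)
        out = np.sign(s)
        out[np.abs(s) < _ZERO_TOL] = 0.0  # odd-symmetric boundary convention
        return out
    if kind == "triangle":
        return (2 / np.pi) * np.arcsin(np.sin(phase))
    raise ValueError(f"unknown basis kind {kind!r}")


def make_periodic_basis(kind: str, T: float, M: int) -> PeriodicBasis:
    """Build the two-regressor template basis f(t), f(t + T/4) on t = 1..M."""
    if T <= 0:
        raise ValueError(f"period must be positive, got {T}")
    if M < 3:
        raise ValueError(f"need at least 3 grid points, got M={M}")
    t = np.arange(1, M + 1, dtype=float)
    f = _wave(kind, t, T)
    f_shift = _wave(kind, t + T / 4, T)
    return PeriodicBasis(
        kind=kind,
        period=T,
        regressors=np.column_stack([f, f_shift]),
        labels=["f(t)", "f(t+T/4)"],
    )


def basis_from_loadings(E: EmbeddingResult, omega: Sequence[int]) -> PeriodicBasis:
    """Centred PC-loading columns as regressors."""
    omega = tuple(omega)
    if not omega:
        raise ValueError("omega must contain at least one component")
    if max(omega) > E.n_components or min(omega) < 1:
        raise ValueError(f"omega {omega} outside available components")
    v = E.loadings[:, [k - 1 for k in omega]]
    return PeriodicBasis(
        kind="loadings",
        period=None,
        regressors=v - v.mean(axis=0),
        labels=[f"PC{k}" for k in omega],
    )


def ols_f_test(Y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row OLS of Y (N×M) on a shared design Z (M×p, no intercept
    column) with intercept, returning (coef, F, p).

    coef has shape (N, 1+p) with the intercept first. F is the overall test of
    the p slope coefficients against the intercept-only model; a constant row
    yields F = 0 and P = 1, a perfect fit yields P = 0.
    """
    n_obs, p = Z.shape
    design = np.column_stack([np.ones(n_obs), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear regressors in basis")
    df_resid = n_obs - p - 1
    if df_resid <= 0:
        raise ValueError(f"not enough observations ({n_obs}) for {p} regressors")
    coef, _, _, _ = np.linalg.lstsq(design, Y.T, rcond=None)
    fitted = design @ coef
    resid = Y.T - fitted
    rss = (resid**2).sum(axis=0)
    tss = ((Y.T - Y.T.mean(axis=0)) ** 2).sum(axis=0)
    ess = np.maximum(tss - rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ess / p) / (rss / df_resid)
    # degenerate rows: constant gene (tss ~ 0) -> no signal; exact fit -> F = inf
    F = np.where(tss <= _ZERO_TOL * np.maximum(1.0, np.abs(Y).max()), 0.0, F)
    F = np.where(np.isnan(F), np.inf, F)
    pvals = stats.f.sf(F, p, df_resid)
    pvals = np.where(np.isinf(F), 0.0, pvals)
    return coef.T, F, pvals


def fit_periodic(X: ExpressionMatrix | np.ndarray, basis: PeriodicBasis) -> PeriodicFitResult:
    """Fit every gene to the basis regressors plus intercept by OLS."""
    gene_ids = None
    if isinstance(X, ExpressionMatrix):
        gene_ids, values = X.gene_ids, X.values
    else:
        values = np.asarray(X, dtype=float)
    if basis.regressors.shape[0] != values.shape[1]:
        raise ValueError(
            f"basis grid length {basis.regressors.shape[0]} != {values.shape[1]} time points"
        )
    coef, F, p = ols_f_test(values, basis.regressors)
    desc = basis.kind if basis.period is None else f"{basis.kind}(T={basis.period:g})"
    return PeriodicFitResult(
        gene_ids=list(gene_ids) if gene_ids else [f"g{i+1}" for i in range(len(F))],
        coef=coef,
        fvalues=F,
        pvalues=p,
        basis=desc,
    )


def fit_to_loadings(
    X: ExpressionMatrix | np.ndarray, E: EmbeddingResult, omega: Sequence[int]
) -> PeriodicFitResult:
    """Fit every gene to the centred loadings of the components in Ω."""
    return fit_periodic(X, basis_from_loadings(E, omega))


def rank_equal_count(F: PeriodicFitResult, n: int) -> GeneList:
    """The n best-fitting genes, for like-for-like comparison with a
    projection-based selection of the same size."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n > len(F.gene_ids):
        raise ValueError(f"n={n} exceeds gene count {len(F.gene_ids)}")
    order = F.ranked_order()[:n]
    return GeneList(
        gene_ids=[F.gene_ids[i] for i in order],
        provenance=f"top {n} by {F.basis} fit",
    )
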