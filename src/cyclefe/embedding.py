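"""Gene embedding by principal component analysis.

In the usual orientation of PCA on expression data the samples receive
low-dimensional coordinates. Here the orientation is reversed: the genes are
embedded. Writing X for the N×M gene × time-point matrix, the k-th PC score
vector u_k (one coordinate per gene) is the k-th eigenvector of the Gram
matrix X Xᵀ, with eigenvalue λ_k, and the k-th PC loading vector v_k = Xᵀ u_k
(one coordinate per time point) is the corresponding eigenvector of Xᵀ X.
The loadings trace the temporal profile each component captures; the scores
measure how strongly each gene projects onto that profile.

Computationally the eigenproblem is solved through a thin SVD of X rather
than by materializing the N×N Gram matrix, which is intractable for
N ~ 10⁴: u_k is the k-th left singular vector and λ_k the squared singular
value. The two routes are algebraically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix

#: eigenvalues below this fraction of the largest are treated as numerically zero
_RANK_RTOL = 1e-12


@dataclass
class EmbeddingResult:
    """PC scores, loadings and spectrum of a gene embedding.

    scores : (N, K) — u_ki, orthonormal columns (one coordinate per gene)
    loadings : (M, K) — v_kj = (Xᵀ u_k)_j, so ‖v_k‖ = √λ_k
    eigenvalues : (K,) descending λ_k
    contributions : (K,) λ_k / Σ_all λ, fractions of total variance
    rank : numerical rank of the input; components beyond it carry λ ≈ 0
    """

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    contributions: np.ndarray
    rank: int
    gene_ids: list[str] | None = None
    time_labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_tsv(self, scores_path, loadings_path, eigenvalues_path=None) -> None:
        """Export scores and loadings as TSV with component headers."""
        import pandas as pd

        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        gidx = self.gene_ids or [f"g{i + 1}" for i in range(self.scores.shape[0])]
        tidx = self.time_labels or [str(j + 1) for j in range(self.loadings.shape[0])]
        pd.DataFrame(self.scores, index=gidx, columns=cols).to_csv(
            scores_path, sep="\t", index_label="gene_id"
        )
        pd.DataFrame(self.loadings, index=tidx, columns=cols).to_csv(
            loadings_path, sep="\t", index_label="time"
        )
        if eigenvalues_path is not None:
            pd.DataFrame(
                {"eigenvalue": self.eigenvalues, "contribution": self.contributions},
                index=pd.Index(cols, name="component"),
            ).to_csv(eigenvalues_path, sep="\t")


def embed_genes(
    X: ExpressionMatrix | np.ndarray, K: int | None = None
) -> EmbeddingResult:
    """Embed genes into the top-K principal components.

    Parameters
    ----------
    X : ExpressionMatrix or (N, M) array
        Expression values. Per-sample normalization is the caller's choice;
        a matrix standardized per gene (as a synthetic generator produces)
        may be embedded as-is.
    K : int, optional
        Number of components, 2 ≤ K ≤ min(N, M). Defaults to
        min(N, M) capped at 10.

    The eigenvector sign is arbitrary; for determinism each component is
    flipped so that its largest-magnitude loading entry is positive.
    """
    gene_ids = time_labels = None
    if isinstance(X, ExpressionMatrix):
        gene_ids, time_labels = X.gene_ids, X.time_labels
        values = X.values
    else:
        values = np.asarray(X, dtype=float)
    n, m = values.shape
    if K is None:
        K = min(n, m, 10)
    if K < 2:
        raise ValueError(f"need at least 2 components, got K={K}")
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds min(N, M)={min(n, m)}")

    u, s, _ = np.linalg.svd(values, full_matrices=False)
    lam_all = s**2
    total = lam_all.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero; matrix has no variance")
    rank = int(np.sum(s > s[0] * _RANK_RTOL))

    scores = u[:, :K].copy()
    loadings = values.T @ scores  # v_k = Xᵀ u_k, column norms √λ_k
    for k in range(K):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return EmbeddingResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=lam_all[:K],
        contributions=lam_all[:K] / total,
        rank=rank,
        gene_ids=list(gene_ids) if gene_ids is not None else None,
        time_labels=list(time_labels) if time_labels is not None else None,
    )


def contributions(E: EmbeddingResult) -> np.ndarray:
    """Variance fractions λ_k / Σλ for the embedded components."""
    if E.eigenvalues.size == 0 or not np.any(E.eigenvalues > 0):
        raise ValueError("no positive eigenvalues")
    return E.contributions.copy()
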