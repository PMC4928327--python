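"""Outlier gene selection from PC scores.

Genes whose scores on the selected components Ω are extreme are the ones
driving the periodic components. Assuming the null scores are Gaussian, the
statistic

    s_i = Σ_{k ∈ Ω} (u_ki / σ_k)²

is χ²-distributed with |Ω| degrees of freedom, where σ_k is the population
standard deviation of the k-th score column over all N genes. The upper-tail
probability gives a per-gene P-value, which is Benjamini–Hochberg adjusted;
genes with adjusted P below the chosen level α are selected as outliers.

Selections from several experiments are integrated by counting, per gene,
the number of experiments in which it was selected, and keeping genes at or
above a count threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import GeneList
from .embedding import EmbeddingResult


@dataclass
class SelectionResult:
    """Per-gene outlier statistics and the selected flag."""

    gene_ids: list[str]
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    selected: np.ndarray
    omega: tuple[int, ...]
    alpha: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def selected_genes(self, provenance: str = "") -> GeneList:
        ids = [g for g, s in zip(self.gene_ids, self.selected) if s]
        return GeneList(gene_ids=ids, provenance=provenance)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "statistic": self.statistic,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "selected": self.selected.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class IntegrationResult:
    """Occurrence counts of genes across experiment-level selections."""

    counts: dict[str, int]
    n_experiments: int
    threshold: int
    selected: GeneList

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tcount\tselected\n")
            for g, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{g}\t{c}\t{int(c >= self.threshold)}\n")


def chi2_outlier_pvalues(
    E: EmbeddingResult, omega: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """χ² outlier statistic and raw upper-tail P-value per gene.

    `omega` holds 1-based component indices. The statistic is invariant
    under rescaling any score column, since σ_k rescales identically.
    """
    omega = tuple(omega)
    if not omega:
        raise ValueError("omega must contain at least one component")
    if max(omega) > E.n_components or min(omega) < 1:
        raise ValueError(f"omega {omega} outside available components 1..{E.n_components}")
    cols = E.scores[:, [k - 1 for k in omega]]
    sigma = cols.std(axis=0, ddof=0)
    # zero relative to the column scale: constant columns carry no spread
    scale = np.abs(cols).max(axis=0)
    zero = np.flatnonzero(sigma <= 1e-12 * scale)
    if zero.size:
        raise ValueError(f"zero standard deviation for component {omega[zero[0]]}")
    statistic = ((cols / sigma) ** 2).sum(axis=1)
    p_raw = stats.chi2.sf(statistic, df=len(omega))
    return statistic, p_raw


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values, in the input order."""
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def extract_features(
    E: EmbeddingResult, omega: Sequence[int], alpha: float
) -> SelectionResult:
    """Select outlier genes: χ² statistic on Ω, BH adjustment, adjusted P < α."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    statistic, p_raw = chi2_outlier_pvalues(E, omega)
    p_adj = bh_adjust(p_raw)
    selected = p_adj < alpha
    gene_ids = E.gene_ids or [f"g{i + 1}" for i in range(len(statistic))]
    return SelectionResult(
        gene_ids=list(gene_ids),
        statistic=statistic,
        p_raw=p_raw,
        p_adj=p_adj,
        selected=selected,
        omega=tuple(omega),
        alpha=alpha,
    )


def integrate_counts(
    selections: Sequence[GeneList | Sequence[str]], threshold: int
) -> IntegrationResult:
    """Count per-gene occurrences across selections; keep count ≥ threshold."""
    if not selections:
        raise ValueError("need at least one selection")
    n = len(selections)
    if threshold > n:
        raise ValueError(f"threshold {threshold} exceeds number of selections {n}")
    counter: Counter[str] = Counter()
    for sel in selections:
        ids = sel.gene_ids if isinstance(sel, GeneList) else list(sel)
        counter.update(set(ids))
    kept = sorted(g for g, c in counter.items() if c >= threshold)
    return IntegrationResult(
        counts=dict(counter),
        n_experiments=n,
        threshold=threshold,
        selected=GeneList(gene_ids=kept, provenance=f"count ≥ {threshold} of {n}"),
    )
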