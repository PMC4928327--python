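"""Synthetic periodic-expression generator and method benchmark.

The generator emulates a time course in which a minority of genes follow a
noisy-but-exactly-periodic oscillation while the rest are pure noise:

* two basis signals over M = 100 time points, built from sin and cos of
  period 25 (four complete periods), each disturbed by periodic uniform
  noise of amplitude A — 25 independent draws from U[−A, A], tiled — so the
  disturbed signals remain exactly periodic while becoming less sinusoidal
  as A grows;
* the cos-based signal is orthogonalized against the sin-based one by a
  Gram–Schmidt projection, giving basis columns C and S with Σ C_j S_j = 0;
* 100 signal genes x⁰_ij = C_j cos δ_i + S_j sin δ_i with uniform random
  phases δ_i ∈ [0, 2π);
* 9900 noise genes drawn i.i.d. from U[−1, 1];
* every gene row is divided by its standard deviation over time (population
  divisor M; the mean is not subtracted), so all genes share unit variance
  and a noise gene cannot be dismissed by amplitude alone.

The benchmark scores two feature-extraction routes on this ground truth at
BH-adjusted P < 0.01: projection-based selection (gene embedding, χ² on the
first two PC scores) and sinusoidal regression on the noise-free templates.
Confusion matrices are averaged over seeded ensembles for each A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embedding import embed_genes
from .extraction import bh_adjust, chi2_outlier_pvalues
from .periodic import ols_f_test


@dataclass
class SyntheticDataset:
    """A generated gene × time-point matrix with ground-truth labels.

    `values` follows the generator literally: per-gene scaling divides by the
    row standard deviation but does not subtract the row mean. `labels` is
    True for signal genes (the first `n_signal` rows). `basis` holds the
    realized sequences S⁰, C⁰, S, C.
    """

    values: np.ndarray
    labels: np.ndarray
    A: float
    seed: int
    basis: dict[str, np.ndarray]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class BenchmarkSummary:
    """Mean confusion matrices per (A, method) over seeded ensembles.

    Each confusion matrix is 2×2 with rows (noise, signal) and columns
    (not selected, selected); entries sum to the gene count. A perfect
    selection is [[n_noise, 0], [0, n_signal]].
    """

    confusion: dict[tuple[float, str], np.ndarray]
    ensembles: int
    seeds: list[int]
    n_genes: int

    def accuracy(self, A: float, method: str) -> float:
        cm = self.confusion[(A, method)]
        return float((cm[0, 0] + cm[1, 1]) / cm.sum())

    def sensitivity(self, A: float, method: str) -> float:
        cm = self.confusion[(A, method)]
        return float(cm[1, 1] / cm[1].sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "A\tmethod\tnoise_not_selected\tnoise_selected\t"
                "signal_not_selected\tsignal_selected\taccuracy\n"
            )
            for (A, method), cm in sorted(self.confusion.items()):
                fh.write(
                    f"{A:g}\t{method}\t{cm[0, 0]:.2f}\t{cm[0, 1]:.2f}\t"
                    f"{cm[1, 0]:.2f}\t{cm[1, 1]:.2f}\t{self.accuracy(A, method):.6f}\n"
                )

    def format_table(self) -> str:
        """Text table with one block per method, one row per A."""
        lines = ["method  A   TN       FP     FN     TP     accuracy"]
        for (A, method), cm in sorted(self.confusion.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            lines.append(
                f"{method:<10s}{A:<4g}{cm[0, 0]:<9.2f}{cm[0, 1]:<7.2f}"
                f"{cm[1, 0]:<7.2f}{cm[1, 1]:<7.2f}{self.accuracy(A, method):.4f}"
            )
        return "\n".join(lines)


def generate_synthetic(
    A: float,
    seed: int,
    n_signal: int = 100,
    n_noise: int = 9900,
    M: int = 100,
    period: int = 25,
) -> SyntheticDataset:
    """Generate one synthetic dataset at signal-disturbance amplitude A.

    Random draws come from one `numpy` generator seeded with `seed`, in the
    fixed order: phases δ_i, periodic noise ε^S, periodic noise ε^C, then the
    noise-gene matrix ε_ij — so a seed fully reproduces the dataset.
    """
    if A < 0:
        raise ValueError("amplitude A must be nonnegative")
    if M % period != 0:
        raise ValueError(f"M={M} must cover whole periods of length {period}")
    rng = np.random.default_rng(seed)
    delta = rng.uniform(0, 2 * np.pi, size=n_signal)
    eps_s = rng.uniform(-A, A, size=period)
    eps_c = rng.uniform(-A, A, size=period)
    noise = rng.uniform(-1, 1, size=(n_noise, M))

    j = np.arange(1, M + 1)
    res = j % period
    s0 = np.sin(2 * np.pi * res / period)
    c0 = np.cos(2 * np.pi * res / period)
    s = s0 + eps_s[res]
    c1 = c0 + eps_c[res]
    c = c1 - s * (c1 @ s) / (s @ s)  # Gram–Schmidt: C ⊥ S exactly

    signal = np.outer(np.cos(delta), c) + np.outer(np.sin(delta), s)
    x0 = np.vstack([signal, noise])
    sd = x0.std(axis=1, ddof=0)  # about the row mean, divisor M
    values = x0 / sd[:, None]
    labels = np.zeros(n_signal + n_noise, dtype=bool)
    labels[:n_signal] = True
    return SyntheticDataset(
        values=values,
        labels=labels,
        A=A,
        seed=seed,
        basis={"S0": s0, "C0": c0, "S": s, "C": c},
    )


def confusion_2x2(labels: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Rows (noise, signal) × columns (not selected, selected)."""
    labels = np.asarray(labels, dtype=bool)
    selected = np.asarray(selected, dtype=bool)
    return np.array(
        [
            [np.sum(~labels & ~selected), np.sum(~labels & selected)],
            [np.sum(labels & ~selected), np.sum(labels & selected)],
        ],
        dtype=float,
    )


def score_pca_fe(
    D: SyntheticDataset, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Projection-based selection: embed genes, χ² on PC1–PC2 scores, BH.

    The generated matrix is embedded as-is (it is standardized per gene by
    construction). Returns (adjusted P-values, confusion matrix).
    """
    E = embed_genes(D.values, K=2)
    _, p_raw = chi2_outlier_pvalues(E, omega=(1, 2))
    p_adj = bh_adjust(p_raw)
    return p_adj, confusion_2x2(D.labels, p_adj < alpha)


def score_regression_fe(
    D: SyntheticDataset, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Template-based selection: per-gene OLS on the noise-free sinusoids
    C⁰, S⁰ with intercept, overall-F P-value, BH. Returns (adjusted P,
    confusion matrix)."""
    Z = np.column_stack([D.basis["C0"], D.basis["S0"]])
    _, _, p_raw = ols_f_test(D.values, Z)
    p_adj = bh_adjust(p_raw)
    return p_adj, confusion_2x2(D.labels, p_adj < alpha)


_SCORERS = {"pca": score_pca_fe, "regression": score_regression_fe}


def run_benchmark(
    A_values: Sequence[float],
    ensembles: int,
    base_seed: int,
    methods: Sequence[str] = ("pca", "regression"),
    alpha: float = 0.01,
    **generator_kwargs,
) -> BenchmarkSummary:
    """Average confusion matrices over `ensembles` seeded replicates per A.

    Replicate r uses seed base_seed + r; the same datasets feed every method.
    """
    if ensembles < 1:
        raise ValueError("ensembles must be at least 1")
    unknown = set(methods) - set(_SCORERS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    seeds = [base_seed + r for r in range(ensembles)]
    confusion: dict[tuple[float, str], np.ndarray] = {}
    n_genes = 0
    for A in A_values:
        sums = {m: np.zeros((2, 2)) for m in methods}
        for seed in seeds:
            D = generate_synthetic(A, seed, **generator_kwargs)
            n_genes = D.n_genes
            for m in methods:
                _, cm = _SCORERS[m](D, alpha=alpha)
                sums[m] += cm
        for m in methods:
            confusion[(float(A), m)] = sums[m] / ensembles
    return BenchmarkSummary(
        confusion=confusion, ensembles=ensembles, seeds=seeds, n_genes=n_genes
    )
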