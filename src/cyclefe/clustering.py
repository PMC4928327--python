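"""Phase clustering of extracted genes in the PC-score plane.

Outlier genes of a periodic process spread around a ring in the score plane,
their angular position encoding expression phase. Two clusterings are
offered: K-means with many random restarts (the best solution by
within-cluster sum of squares is kept), and a Gaussian mixture whose cluster
count is chosen by BIC over a small family of covariance structures. A
cross-tabulation compares two assignments gene by gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

COVARIANCE_FAMILY = ("spherical", "diag", "tied", "full")


@dataclass
class ClusterAssignment:
    """Per-gene cluster labels (1-based) with the fitted objective.

    For K-means, `objective` is the total within-cluster sum of squares; for
    the Gaussian mixture it is the BIC trace over all candidate models as a
    list of (k, covariance_type, bic) with BIC in the higher-is-better
    convention 2·loglik − n_params·log n.
    """

    labels: np.ndarray
    method: str
    k: int
    objective: float | list[tuple[int, str, float]]
    gene_ids: list[str] | None = None

    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def to_tsv(self, path) -> None:
        ids = self.gene_ids or [f"g{i + 1}" for i in range(len(self.labels))]
        with open(path, "w") as fh:
            fh.write("gene_id\tcluster\n")
            for g, lab in zip(ids, self.labels):
                fh.write(f"{g}\t{lab}\n")


def _canonicalize(labels: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..k deterministically.

    In 2-D, clusters are ordered by the angle of their centroid (phase
    order); otherwise by first occurrence in the input.
    """
    present = np.unique(labels)
    if points.shape[1] == 2:
        angles = {}
        for lab in present:
            cx, cy = points[labels == lab].mean(axis=0)
            angles[lab] = np.arctan2(cy, cx)
        order = sorted(present, key=lambda lab: angles[lab])
    else:
        first = {lab: int(np.argmax(labels == lab)) for lab in present}
        order = sorted(present, key=lambda lab: first[lab])
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[lab] for lab in labels])


def kmeans_best_of(
    points: np.ndarray,
    k: int,
    restarts: int = 100,
    seed: int | None = None,
    gene_ids: list[str] | None = None,
) -> ClusterAssignment:
    """K-means with `restarts` random initializations; the solution with the
    minimal within-cluster sum of squares wins."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 ≤ k ≤ n, got k={k}, n={n}")
    km = KMeans(n_clusters=k, n_init=restarts, init="random", random_state=seed)
    raw = km.fit_predict(points)
    return ClusterAssignment(
        labels=_canonicalize(raw, points),
        method="kmeans",
        k=k,
        objective=float(km.inertia_),
        gene_ids=gene_ids,
    )


def gmm_bic_select(
    points: np.ndarray,
    k_range: Sequence[int] = range(1, 10),
    seed: int | None = None,
    gene_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Gaussian-mixture clustering with the cluster count chosen by BIC.

    Fits every k in `k_range` under each covariance structure in
    COVARIANCE_FAMILY and keeps the model maximizing 2·loglik − params·log n.
    Candidates that fail to fit are skipped with a warning.
    """
    points = np.asarray(points, dtype=float)
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    trace: list[tuple[int, str, float]] = []
    best = None
    best_bic = -np.inf
    for k in k_range:
        for cov in COVARIANCE_FAMILY:
            try:
                gm = GaussianMixture(
                    n_components=k, covariance_type=cov, random_state=seed, n_init=3
                ).fit(points)
            except Exception as exc:  # singular fit at this candidate
                warnings.warn(f"GMM k={k} cov={cov} skipped: {exc}")
                trace.append((k, cov, -np.inf))
                continue
            bic = -float(gm.bic(points))  # flip to higher-is-better
            trace.append((k, cov, bic))
            if bic > best_bic:
                best, best_bic = gm, bic
    if best is None:
        raise ValueError("no Gaussian-mixture candidate could be fitted")
    raw = best.predict(points)
    labels = _canonicalize(raw, points)
    return ClusterAssignment(
        labels=labels,
        method="gmm",
        k=int(len(np.unique(labels))),
        objective=trace,
        gene_ids=gene_ids,
    )


def crosstab(a: ClusterAssignment, b: ClusterAssignment) -> pd.DataFrame:
    """Contingency table of co-assignments: rows = b's clusters, columns =
    a's clusters."""
    if len(a.labels) != len(b.labels):
        raise ValueError("assignments cover different numbers of genes")
    if a.gene_ids is not None and b.gene_ids is not None and a.gene_ids != b.gene_ids:
        raise ValueError("assignments cover different gene sets")
    return pd.crosstab(
        pd.Series(b.labels, name=b.method),
        pd.Series(a.labels, name=a.method),
    )
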