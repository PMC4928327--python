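"""Winding-number analysis of PC-loading trajectories.

A pair of PC loadings (v_k, v_k′) traces a planar trajectory over the time
points. If the pair carries a periodic signal, the centred trajectory orbits
the origin like a limit cycle, and the cumulative signed rotation — the
winding number — counts how many oscillation periods the series spans. The
winding number is period-free: it detects periodicity without estimating a
period length, and it resolves components that oscillate at different
frequencies (a component at twice the fundamental winds twice as often).

For centred points p_1..p_M the step angle is the signed planar angle

    Δθ_{j,j+1} = atan2(p_j × p_{j+1},  p_j · p_{j+1})  ∈ (−π, π],

and W(M′) = Σ_{j≤M′} Δθ_{j,j+1} / 2π, in turns. W is invariant under
uniform scaling and rotation of the point set and negates under reflection
or time reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingResult


def winding_number(
    trajectory: np.ndarray, center: bool = True
) -> tuple[float, np.ndarray]:
    """Signed winding number of a planar trajectory about the origin.

    Parameters
    ----------
    trajectory : (M, 2) array
        The loading pair over time. When `center` is true, the time-mean of
        each coordinate is subtracted first.

    Returns
    -------
    W : float
        Total winding in turns, W(M−1) = Σ Δθ / 2π.
    step_angles : (M−1,) array
        The signed increments Δθ_{j,j+1} in radians, each in (−π, π].
    """
    pts = np.asarray(trajectory, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("trajectory must be an (M, 2) array")
    m = pts.shape[0]
    if m < 3:
        raise ValueError(f"need at least 3 time points, got {m}")
    if center:
        pts = pts - pts.mean(axis=0)
    norms = np.hypot(pts[:, 0], pts[:, 1])
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"centred point at the origin at time index {bad[0] + 1}; angle undefined"
        )
    a, b = pts[:-1], pts[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    step_angles = np.arctan2(cross, dot)
    return float(step_angles.sum() / (2 * np.pi)), step_angles


def partial_winding(step_angles: np.ndarray) -> np.ndarray:
    """Running winding numbers W(1), …, W(M−1) from the step angles."""
    return np.cumsum(step_angles) / (2 * np.pi)


@dataclass
class WindingMatrix:
    """Winding numbers for all loading pairs (k, k′), k < k′ ≤ k_max.

    `pair_values` stores W for k < k′; the reversed pair is the orientation
    flip, W(k′, k) = −W(k, k′), available through :meth:`w`.
    """

    pair_values: dict[tuple[int, int], float]
    step_angles: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    k_max: int = 4

    def w(self, k: int, kp: int) -> float:
        if k < kp:
            return self.pair_values[(k, kp)]
        return -self.pair_values[(kp, k)]

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pair_values)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tk_prime\tW\n")
            for (k, kp), w in sorted(self.pair_values.items()):
                fh.write(f"{k}\t{kp}\t{w:.6f}\n")

    def plot_grid(self, E: EmbeddingResult, path) -> None:
        """Scatter grid of loading pairs (upper triangle) with W values
        (lower triangle), mirroring the usual limit-cycle overview figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        k_max = self.k_max
        fig, axes = plt.subplots(k_max, k_max, figsize=(2.2 * k_max, 2.2 * k_max))
        v = E.loadings - E.loadings.mean(axis=0)
        for r in range(k_max):
            for c in range(k_max):
                ax = axes[r, c]
                ax.set_xticks([])
                ax.set_yticks([])
                if r == c:
                    ax.text(0.5, 0.5, f"PC{r + 1}", ha="center", va="center")
                elif r < c:
                    ax.plot(v[:, r], v[:, c], "-o", ms=2, lw=0.7)
                    ax.axhline(0, lw=0.3, color="grey")
                    ax.axvline(0, lw=0.3, color="grey")
                else:
                    ax.text(
                        0.5, 0.5, f"W={self.w(c + 1, r + 1):.2f}",
                        ha="center", va="center",
                    )
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def winding_matrix(E: EmbeddingResult, k_max: int = 4) -> WindingMatrix:
    """Winding numbers of every centred loading pair (k, k′), k < k′ ≤ k_max.

    The default cap of 4 reflects that higher components rarely trace clean
    limit cycles even when their |W| is large.
    """
    if E.n_components < k_max:
        raise ValueError(f"embedding has {E.n_components} components, need {k_max}")
    values: dict[tuple[int, int], float] = {}
    angles: dict[tuple[int, int], np.ndarray] = {}
    for k in range(1, k_max + 1):
        for kp in range(k + 1, k_max + 1):
            traj = E.loadings[:, [k - 1, kp - 1]]
            w, dth = winding_number(traj, center=True)
            values[(k, kp)] = w
            angles[(k, kp)] = dth
    return WindingMatrix(pair_values=values, step_angles=angles, k_max=k_max)


def select_pc_set(
    Wm: WindingMatrix, mode: str = "best_pair", w_min: float = 0.75
) -> tuple[int, ...]:
    """Choose the component set Ω for feature extraction.

    mode "best_pair"
        The pair with the largest |W| (ties broken by the lexicographically
        smallest pair).
    mode "threshold"
        All components appearing in any pair with |W| ≥ w_min turns.
    """
    if not Wm.pair_values:
        raise ValueError("empty winding matrix")
    if mode == "best_pair":
        best = min(
            Wm.pair_values, key=lambda p: (-abs(Wm.pair_values[p]), p)
        )
        return tuple(sorted(best))
    if mode == "threshold":
        members: set[int] = set()
        for (k, kp), w in Wm.pair_values.items():
            if abs(w) >= w_min:
                members.update((k, kp))
        if not members:
            raise ValueError(
                f"no pair reaches |W| ≥ {w_min}; specify Ω manually"
            )
        return tuple(sorted(members))
    raise ValueError(f"unknown mode {mode!r}")
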