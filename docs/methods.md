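# Methods

## Overview

`cyclefe` selects genes that drive temporally periodic expression programs
(cell-division or metabolic cycles in synchronized or self-oscillating
cultures) without fitting any periodic template to individual genes. The
procedure has two stages: an unsupervised embedding that concentrates the
shared temporal structure into a few principal components, and an outlier
test that asks which genes project unusually strongly onto those components.
A winding-number diagnostic decides, from the data alone, which components
carry a periodic orbit.

## Gene embedding

Let X be the N×M matrix of N genes over M time points, with each column
(sample) normalized to mean 0 and (1/N) Σᵢ xᵢⱼ² = 1 (population convention,
divisor N; no per-gene normalization follows). In contrast to the usual PCA
orientation, the *genes* are embedded: the k-th PC score vector **u**_k
(one coordinate per gene) solves XXᵀ**u**_k = λ_k**u**_k, and the k-th PC
loading vector **v**_k = Xᵀ**u**_k (one coordinate per time point) is the
matching eigenvector of XᵀX. The loadings are temporal profiles shared
across the transcriptome; a gene's scores measure how much of each profile
it contains.

Implementation: thin SVD of X; scores are left singular vectors, λ_k the
squared singular values, loadings Xᵀ**u**_k (norm √λ_k). The N×N Gram
matrix is never formed, which keeps N = 10⁴ cheap; an eigen-decomposition of
the Gram matrix is retained in the test suite as an independent oracle on
small matrices. Eigenvector signs are arbitrary, so each component is
flipped to make its largest-magnitude loading entry positive — winding
numbers change sign under reflection and the χ² statistic is sign-invariant,
so this is a pure determinism device.

## Winding-number analysis

For a component pair (k, k′), centre each loading sequence by its time mean
and view the M points (v_kj − ⟨v_k⟩, v_k′j − ⟨v_k′⟩) as a planar
trajectory. The winding number

    W(M−1) = Σ_{j=1}^{M−1} Δθ_{j,j+1} / 2π,
    Δθ = atan2(p_j × p_{j+1}, p_j · p_{j+1}) ∈ (−π, π]

counts signed rotations about the origin, in turns. A pair carrying a clean
oscillation traces a limit cycle and |W| ≈ the number of periods the series
spans; the diagnostic is period-free and resolves components oscillating at
multiples of the fundamental (a double-frequency "figure-eight" component
winds twice per fundamental period). `select_pc_set` turns the winding
table into the component set Ω, either as the single pair with the largest
|W| (ties broken lexicographically) or as the union of components in any
pair with |W| ≥ w_min (default 0.75 turns — below one full turn so a series
covering a single period still qualifies, above the typical drift of short
noise trajectories; configurable).

Defaults: pairs up to k_max = 4. One caveat found while validating on
noise-only data and worth stating plainly: for a structureless pair the step
angles are nearly independent, so W performs a random walk with standard
deviation √((M−1)/12) turns — about 1.7 turns at M = 36. |W| alone therefore
cannot certify a limit cycle for long series; it should be read together
with the eigenvalue scree (structured components carry outsized λ_k) and
the smoothness of the orbit, which is how the examples use it. The test
suite asserts the random-walk behaviour of noise pairs rather than a fixed
small bound.

## Outlier gene extraction

Given Ω, each gene receives the statistic s_i = Σ_{k∈Ω} (u_ki / σ_k)²,
where σ_k is the population standard deviation (divisor N) of score column
k over all genes. Treating null scores as Gaussian, s_i is χ² with |Ω|
degrees of freedom; the upper tail gives P_i, which is Benjamini–Hochberg
adjusted (step-up; implemented via `statsmodels`' `fdr_bh`, checked in the
tests against a direct step-up oracle). Genes with adjusted P strictly below
α are selected; α defaults to 0.01, and 0.05 is the conventional choice for
the shorter, noisier synchronized-culture series. Because score columns are
orthonormal and (for column-centred input) mean-zero, σ_k = 1/√N and the
statistic reduces to N·Σ_{k∈Ω} u_ki²; a score column with (relatively) zero
spread is rejected as degenerate rather than divided by.

Selections from multiple experiments are integrated by counting, per gene,
the number of experiments in which it was selected and keeping genes at or
above an integer threshold (≥, inclusive).

## Regression comparator

The comparison target ranks genes by goodness of fit to
x(t) = C₀ + C₁ f(t) + C₂ f(t + T/4), where f has period T and the shifted
copy absorbs phase. Implemented templates: f(t) = sin(2πt/T); the square
wave sign(sin(2πt/T)) with value 0 at the crossings (preserving odd
symmetry); and the triangle wave (2/π)·arcsin(sin(2πt/T)). All satisfy
f(t+T) = f(t), f(t+T/2) = −f(t) and mirror symmetry about T/4 exactly, with
unit amplitude; on grids covering whole periods the two regressors are
orthogonal. Conventional grids: T = 12 on 36 points (three cycles) and
T = 8 on 16 points (two cycles). The regressors may instead be the centred
loadings of selected components.

The per-gene P-value is the overall F-test of the regression against the
intercept-only model. A per-coefficient t-test was rejected because C₁ and
C₂ jointly encode amplitude and phase — either alone can vanish for a
perfectly periodic gene at the wrong phase. The OLS is vectorized across
genes (shared design, one least-squares solve), which the tests check
against `statsmodels.OLS` gene by gene. Degenerate rows: a constant gene
gets F = 0, P = 1; an exact fit gets P = 0. `rank_equal_count` returns the
n best-fitting genes so list sizes can be matched to a projection-based
selection for a fair downstream comparison.

## Synthetic benchmark

The generator builds a 10⁴ × 10² matrix (defaults; all sizes configurable):

* S⁰_j = sin(2π(j mod 25)/25), C⁰_j = cos(2π(j mod 25)/25) on j = 1..100 —
  four complete periods;
* S = S⁰ + ε^S, C¹ = C⁰ + ε^C with ε^S, ε^C each 25 i.i.d. draws from
  U[−A, A] tiled periodically, so the disturbed signals remain exactly
  periodic while growing less sinusoidal with A;
* C = C¹ − S·(ΣC¹S/ΣS²): C is orthogonalized against S (exact by
  construction; at A = 0 the projection term is already zero by discrete
  sin/cos orthogonality over whole periods);
* signal genes i ≤ 100: x⁰ = C cos δᵢ + S sin δᵢ with δᵢ ~ U[0, 2π);
  noise genes: x⁰ᵢⱼ ~ U[−1, 1];
* each row is divided by its standard deviation over time (divisor M, about
  the row mean; the mean itself is deliberately not subtracted), so signal
  and noise genes share unit variance.

Draw order is fixed (δ, ε^S, ε^C, noise matrix) from a single seeded
generator, making every ensemble bit-reproducible. The generated matrix is
embedded as-is — it is standardized per gene by construction and no
per-sample renormalization is applied, matching the generator's definition;
callers may normalize first if they wish.

Scoring: projection-based extraction uses Ω = {1, 2} (the two components
that absorb span{C, S}), χ² with 2 df, BH, adjusted P < 0.01. The
regression route fits every gene to the *noise-free* templates C⁰, S⁰ with
intercept and applies the same BH threshold. Confusion matrices (rows
noise/signal, columns not-selected/selected) are averaged over seeded
ensembles per A.

Observed behaviour, recomputed by the tests and the acceptance script:
projection-based extraction classifies all 10⁴ genes perfectly at every
A ∈ {1..6} — the signal genes form a phase ring in the score plane whose
minimum radius stays well above the 99th percentile of the noise cloud —
while the sinusoidal-regression sensitivity falls monotonically from ≈1.0
at A = 1 to ≈0.1 at A = 6. One footnote: at FDR level 0.01 with ~100 true
discoveries, BH admits on the order of one false positive, so the
regression route's confusion is "near-perfect", not exact, even at A = 0.

What the generator does not emulate: probe-level measurement error
structure, heteroscedastic biological noise, amplitude differences between
signal genes, missing values, or drifting period length. Perfect accuracy
here therefore demonstrates the geometric separation argument under the
stated noise model, not performance on any real platform.

## Clustering

Extracted genes are phase-clustered on selected score columns. K-means runs
with many random initializations (default 100) and keeps the lowest
within-cluster sum of squares — the standard best-of-restarts reading of
"multiple starts"; a vote-over-runs consensus is deliberately not
implemented. The Gaussian mixture fits every k in a range (default 1..9)
under each of scikit-learn's covariance structures (spherical, diagonal,
tied, full) and keeps the model with the highest BIC in the
2·loglik − params·log n convention; exact parity with other mixture
packages' model alphabets is out of scope. Cluster labels are renumbered
deterministically — by centroid angle in 2-D (phase order), otherwise by
first occurrence — so partitions are comparable across runs and methods.

## Numerical choices and problem sizes

* Eigenvalue rank cut: singular values below 10⁻¹² of the largest count as
  zero; contributions are fractions of the *total* variance, so they sum to
  1 only when K reaches the rank.
* Zero-radius trajectory points (a centred loading exactly at the origin)
  raise an error naming the time index rather than producing an undefined
  angle.
* All RNG flows through `numpy.random.default_rng` with explicit seeds; the
  benchmark derives ensemble seeds as base_seed + index.
* The bundled benchmark runs use 10 ensembles per A over A = 1..6 at the
  full 10⁴ × 10² size, which reproduces the averaged confusion matrices to
  well within Monte-Carlo noise; `run_benchmark(..., ensembles=100)` (or
  `cyclefe benchmark --ensembles 100`) gives the production-scale average.

## Limitations

* The winding diagnostic needs several time points per period and at least
  one full period; it cannot separate a true single-period cycle from a
  lucky noise drift on very long structureless series (see above).
* The χ² null treats score columns as independent Gaussians; heavy-tailed
  score distributions inflate the selection, which BH only partially
  absorbs.
* Integration across experiments matches identifiers verbatim; mapping
  probes to gene symbols across platforms is the caller's job (a two-column
  mapping file can be applied as a plain join).
* Series-matrix parsing covers the common tab-separated dialect with
  begin/end table markers; exotic metadata variants are ignored rather than
  interpreted.
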