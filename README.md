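# cyclefe

Unsupervised selection of periodically expressed genes from time-course
transcriptomes — cell-division and metabolic cycles in yeast being the
motivating systems — using PCA with genes as the embedded objects, a
winding-number test for limit cycles among PC loadings, and a χ² outlier
statistic under Benjamini–Hochberg control. No period length, phase or
waveform is assumed anywhere in the selection path, which is what
distinguishes the method from template-regression screening.

## Who it is for

Computational biologists with a gene × time-point expression matrix
(a GEO series-matrix file or a plain TSV) who want a ranked, FDR-controlled
list of cycle-driven genes, a data-driven choice of which principal
components carry the oscillation, phase clustering of the hits, and a
like-for-like comparison against sinusoidal/square/triangle-wave regression.

## Method in brief

With X the N×M matrix of N genes over M time points (each sample normalized
to mean 0, (1/N)Σᵢxᵢⱼ² = 1):

1. **Gene embedding.** Solve XXᵀ**u**_k = λ_k**u**_k (via thin SVD). Scores
   u_ki place genes in component space; loadings **v**_k = Xᵀ**u**_k are the
   shared temporal profiles.
2. **Winding numbers.** For each loading pair (k, k′) ≤ k_max, centre the
   trajectory and accumulate signed step angles,
   W = Σ atan2(p_j×p_{j+1}, p_j·p_{j+1})/2π. Pairs tracing limit cycles
   have |W| ≈ the number of periods spanned; they define the component set Ω.
3. **Extraction.** s_i = Σ_{k∈Ω}(u_ki/σ_k)² is χ²(|Ω|) under a Gaussian
   null; BH-adjust the tail P-values and keep genes with adjusted P < α.
4. Optionally: integrate selections across experiments by occurrence count,
   phase-cluster hits in the score plane (K-means / BIC-selected Gaussian
   mixture), or benchmark against periodic-template regression.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/extract_periodic_genes.py` plants 30 phase-spread periodic genes
(period 12) among 270 noise genes over 24 time points and runs the pipeline:

```
contributions (%): [33.9 27.7  2.7  2.5]
W(PC1, PC2) = -1.93 turns
selected component set Ω: (1, 2)
30 genes selected at BH-adjusted P < 0.01
false picks: []
missed signal genes: 0
```

Reading: the scree drops sharply after two components, so two profiles carry
structure; their loading pair winds ≈2 turns — 24 points cover two periods
of 12 (the sign is orientation only); the χ² selection at adjusted P < 0.01
returns exactly the 30 planted genes. The other scripts in `examples/`
demonstrate winding numbers on constructed orbits, the synthetic benchmark,
template regression, and phase clustering, each printing and explaining its
output.

The same pipeline is scriptable from the shell:

```sh
cyclefe extract --input expr.tsv --mask 1:30 --kmax 4 --alpha 0.01 --out run/
cyclefe benchmark --A 1,2,3,4,5,6 --ensembles 10 --seed 0 --out bench/
cyclefe integrate run1/genes.txt ... run7/genes.txt --threshold 6 --out integ/
```

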