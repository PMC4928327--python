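"""Projection vs template-regression feature extraction on synthetic data.

Generates the standard synthetic design — 100 periodic signal genes at
random phases plus 9900 noise genes over 100 time points, with the periodic
basis disturbed by amplitude-A noise — and scores both selection methods
against the ground truth at several A. Two ensembles per A keep this quick;
pass larger `ensembles` to `run_benchmark` for a production run.
"""

from cyclefe import run_benchmark

summary = run_benchmark([1, 2, 4, 6], ensembles=2, base_seed=0)
print(summary.format_table())
print()
for A in (1.0, 2.0, 4.0, 6.0):
    print(
        f"A={A:g}: projection accuracy {100 * summary.accuracy(A, 'pca'):.1f} %, "
        f"regression sensitivity {100 * summary.sensitivity(A, 'regression'):.1f} %"
    )
print(
    "\nProjection-based extraction stays perfect because the signal genes'\n"
    "score radius separates them from noise regardless of the waveform;\n"
    "the sinusoidal template loses the signals as A pushes them away from\n"
    "a pure sinusoid."
)
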