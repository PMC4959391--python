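"""Replicate study of loading-estimate accuracy at two noise levels.

Simulates 50 datasets from the low-dimensional design at 5% and at 50%
noise, fits each at the true component numbers, sign-corrects the estimated
loadings against the generative truth, and summarizes bias and spread.
"""

import numpy as np

from o2pls import low_dimensional_design, run_study

for alpha in (0.05, 0.5):
    summary = run_study(low_dimensional_design(alpha), replicates=50, base_seed=0)
    print(f"alpha = {alpha}")
    for factor in ("W", "C", "P_Yorth", "P_Xorth"):
        bias = np.abs(summary.bias[factor]).max()
        iqr = np.median(summary.iqr(factor))
        print(f"  {factor:8s} max |bias| = {bias:.4f}   median IQR = {iqr:.4f}")
    print()

print("Joint loadings (W, C) stay nearly unbiased even at 50% noise; the")
print("orthogonal loading estimates — especially the Y-block ones, whose")
print("profile barely overlaps the joint Y-loadings — spread out visibly as")
print("noise grows. That asymmetry is the study's main qualitative finding.")
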