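"""Typical preprocessing: Box-Cox, filtering, alignment, correlation heatmap input.

Builds a small synthetic metabolite-like block (positive, right-skewed) and
an expression-like block, then runs the preparation chain: Box-Cox with
lambda=1/4 on the metabolites, a level x spread filter on the expression
block, sample alignment with missing-value dropping, and the Pearson
correlation matrix of the metabolites.
"""

import numpy as np
import pandas as pd

from o2pls import align_samples, box_cox, correlation_matrix, filter_expression

rng = np.random.default_rng(0)
n = 60
ids = [f"p{i}" for i in range(n)]

# lognormal concentrations: skewed, strictly positive
metab = pd.DataFrame(
    np.exp(rng.normal(0, 1, size=(n, 8))), index=ids,
    columns=[f"m{j}" for j in range(8)],
)
expr = pd.DataFrame(
    rng.normal(8, 1, size=(n, 40)) * rng.uniform(0.2, 2.0, size=40),
    index=ids, columns=[f"g{j}" for j in range(40)],
)
expr.iloc[rng.choice(n, 5, replace=False), 0] = np.nan  # 5 incomplete samples

skew_before = ((metab - metab.mean()) ** 3).mean() / metab.std() ** 3
metab_bc = box_cox(metab, 0.25)
skew_after = ((metab_bc - metab_bc.mean()) ** 3).mean() / metab_bc.std() ** 3
print(f"mean skewness before Box-Cox: {skew_before.mean():.2f}, after: {skew_after.mean():.2f}")

filtered, kept = filter_expression(expr.dropna(), 0.75, 0.75)
print(f"expression filter kept {len(kept)} of {expr.shape[1]} variables (top 25% by level AND by IQR)")

data = align_samples(metab_bc, expr)
print(f"aligned samples: {data.n_samples} of {n} (dropped {n - data.n_samples} with missing values)")

R = correlation_matrix(metab_bc)
print(f"metabolite correlation matrix: {R.shape}, off-diagonal range "
      f"[{R[~np.eye(8, dtype=bool)].min():.2f}, {R[~np.eye(8, dtype=bool)].max():.2f}]")
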