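"""Choose the numbers of joint and orthogonal components on simulated data.

Runs the two-stage selection: for each candidate number of joint components
the orthogonal numbers are picked by maximizing the sum of the two
inner-relation R² values on a grid, then the joint number is picked by
10-fold cross-validated two-way prediction error.
"""

from o2pls import low_dimensional_design, select_components, simulate_dataset

data, _ = simulate_dataset(low_dimensional_design(alpha=0.05), seed=2)
result = select_components(
    data.center(), a_candidates=[1, 2, 3], max_nx=3, max_ny=3, folds=10, seed=0
)

print("a    (n_x, n_y)   criterion   rel. CV MSE (X + Y)")
for rec in result.records:
    crit = rec.criterion_grid[rec.n_x, rec.n_y]
    print(f"{rec.a}    ({rec.n_x}, {rec.n_y})        {crit:.4f}      {rec.combined_mse:.4f}")
print()
print(
    f"chosen: a={result.chosen_a}, n_x={result.chosen_n_x}, n_y={result.chosen_n_y}"
    "  (the generative truth is 1, 1, 1)"
)
print("The grid criterion peaks where removing block-specific variation")
print("tightens the link between the two blocks' joint scores; the CV stage")
print("then rejects spurious extra joint components.  Detection of n_y is")
print("marginal in this design (the Y-orthogonal profile barely overlaps the")
print("joint Y-loadings), so about one replicate in five lands on (1, 1, 0).")
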