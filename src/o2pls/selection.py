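"""Choosing the numbers of O2PLS components.

A full 3-D cross-validation over (a, n_x, n_y) is expensive when one block
has thousands of variables.  The two-stage heuristic implemented here keeps
it tractable:

1. For each candidate number of joint components ``a``, pick (n_x, n_y) on a
   2-D grid by maximizing the sum of the two inner-relation coefficients of
   determination — removing orthogonal variation typically tightens the link
   between the two blocks' joint scores, up to a point.
2. Choose ``a`` by 10-fold cross-validated prediction error, predicting each
   block from the other at the (n_x, n_y) chosen in stage 1.

The grid criterion is evaluated on the full data; cross-validation folds are
re-centered with training means only, so no information leaks from test
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PairedData
from .model import (
    InsufficientRankError,
    InvalidComponentCountError,
    NoOrthogonalVariationError,
    fit_o2pls,
    predict,
)

__all__ = [
    "SelectionResult",
    "inner_r2_criterion",
    "grid_search_orthogonal",
    "cv_mse",
    "select_components",
]


def inner_r2_criterion(data: PairedData, a: int, n_x: int, n_y: int) -> float:
    """Sum of the two inner-relation R² values at fixed components.

    Fits O2PLS at (a, n_x, n_y) and returns
    ``(1 - sum(H_UT^2)/sum(U^2)) + (1 - sum(H_TU^2)/sum(T^2))``, a value in
    [0, 2].  Higher means the two blocks' joint scores predict each other
    better after removing the requested orthogonal variation.
    """
    model = fit_o2pls(data, a, n_x, n_y)
    return model.r2_u_on_t + model.r2_t_on_u


def grid_search_orthogonal(
    data: PairedData, a: int, max_nx: int, max_ny: int
) -> tuple[int, int, np.ndarray]:
    """Maximize the inner-R² criterion over the (n_x, n_y) grid.

    Evaluates every cell of {0..max_nx} x {0..max_ny} and returns the argmax
    together with the full grid (row index n_x, column index n_y).  Cells
    that are infeasible at this ``a`` — more orthogonal components than the
    residual-score cross-product's rank supports, or than the block
    dimensions allow — are recorded as NaN and skipped.  Exact ties go to
    the cell with the smallest n_x + n_y, then the smallest n_x — the most
    parsimonious model among the tied ones.
    """
    grid = np.full((max_nx + 1, max_ny + 1), np.nan)
    for nx in range(max_nx + 1):
        for ny in range(max_ny + 1):
            try:
                grid[nx, ny] = inner_r2_criterion(data, a, nx, ny)
            except (
                InsufficientRankError,
                NoOrthogonalVariationError,
                InvalidComponentCountError,
            ):
                pass
    best = (0, 0)
    best_val = grid[0, 0]
    if np.isnan(best_val):
        raise InvalidComponentCountError(f"no feasible grid cell at a={a}")
    for nx in range(max_nx + 1):
        for ny in range(max_ny + 1):
            v = grid[nx, ny]
            if np.isnan(v):
                continue
            if v > best_val or (
                v == best_val
                and (nx + ny, nx) < (best[0] + best[1], best[0])
            ):
                best_val = v
                best = (nx, ny)
    return best[0], best[1], grid


def cv_mse(
    data: PairedData,
    a: int,
    n_x: int,
    n_y: int,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """K-fold cross-validated two-way prediction error.

    Samples are partitioned by a seeded shuffle into near-equal folds.  Per
    fold, the training blocks are column-centered, the training means are
    applied to the held-out block, the model is fitted and both directions
    predicted; squared errors are pooled over all held-out entries.

    Returns
    -------
    mse_x, mse_y
        Mean squared error per matrix entry for predicting X from Y and Y
        from X respectively.
    """
    N = data.n_samples
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > N:
        raise ValueError(f"folds={folds} exceeds the number of samples N={N}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    fold_assign = np.array_split(order, folds)
    sse_x = 0.0
    sse_y = 0.0
    n_entries_x = 0
    n_entries_y = 0
    for test_idx in fold_assign:
        mask = np.ones(N, dtype=bool)
        mask[test_idx] = False
        train = data.subset_samples(np.flatnonzero(mask)).center()
        model = fit_o2pls(train, a, n_x, n_y)
        X_test = data.X[test_idx]
        Y_test = data.Y[test_idx]
        # training means both center the input and offset the prediction
        Y_hat = predict(model, X_test, "x_to_y")
        X_hat = predict(model, Y_test, "y_to_x")
        sse_y += float(((Y_hat - Y_test) ** 2).sum())
        sse_x += float(((X_hat - X_test) ** 2).sum())
        n_entries_y += Y_test.size
        n_entries_x += X_test.size
    return sse_x / n_entries_x, sse_y / n_entries_y


@dataclass
class PerAComponents:
    """Stage-1 and stage-2 results for one candidate a."""

    a: int
    n_x: int
    n_y: int
    criterion_grid: np.ndarray
    mse_x: float
    mse_y: float
    combined_mse: float


@dataclass
class SelectionResult:
    """Outcome of the two-stage component selection."""

    a_candidates: list[int]
    records: list[PerAComponents]
    chosen_a: int
    chosen_n_x: int
    chosen_n_y: int
    folds: int
    seed: int

    def record_for(self, a: int) -> PerAComponents:
        for rec in self.records:
            if rec.a == a:
                return rec
        raise KeyError(a)

    def to_dict(self) -> dict:
        return {
            "a_candidates": list(self.a_candidates),
            "chosen": {
                "a": self.chosen_a,
                "n_x": self.chosen_n_x,
                "n_y": self.chosen_n_y,
            },
            "folds": self.folds,
            "seed": self.seed,
            "per_a": [
                {
                    "a": r.a,
                    "n_x": r.n_x,
                    "n_y": r.n_y,
                    "criterion_grid": r.criterion_grid.tolist(),
                    "mse_x": r.mse_x,
                    "mse_y": r.mse_y,
                    "combined_mse": r.combined_mse,
                }
                for r in self.records
            ],
        }


def select_components(
    data: PairedData,
    a_candidates: list[int],
    max_nx: int = 10,
    max_ny: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Two-stage selection of (a, n_x, n_y).

    For each candidate ``a``: grid-search (n_x, n_y) by the inner-R²
    criterion, then cross-validate the two-way prediction error at the chosen
    grid cell.  The winning ``a`` minimizes the sum of the total-SS-relative
    MSEs of the two blocks (making a metabolite block and a transcript block
    commensurate); both raw MSEs are reported per candidate.
    """
    if not a_candidates:
        raise ValueError("a_candidates must be non-empty")
    ss_x = float(((data.X - data.X.mean(axis=0)) ** 2).sum())
    ss_y = float(((data.Y - data.Y.mean(axis=0)) ** 2).sum())
    records = []
    for a in a_candidates:
        nx, ny, grid = grid_search_orthogonal(data, a, max_nx, max_ny)
        mse_x, mse_y = cv_mse(data, a, nx, ny, folds=folds, seed=seed)
        combined = mse_x * data.X.size / ss_x + mse_y * data.Y.size / ss_y
        records.append(
            PerAComponents(
                a=a,
                n_x=nx,
                n_y=ny,
                criterion_grid=grid,
                mse_x=mse_x,
                mse_y=mse_y,
                combined_mse=combined,
            )
        )
    best = min(records, key=lambda r: r.combined_mse)
    return SelectionResult(
        a_candidates=list(a_candidates),
        records=records,
        chosen_a=best.a,
        chosen_n_x=best.n_x,
        chosen_n_y=best.n_y,
        folds=folds,
        seed=seed,
    )
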