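"""Preprocessing chain for omics blocks ahead of O2PLS.

Mirrors a typical metabolome/transcriptome preparation: a Box-Cox power
transform to reduce the right skew of concentration-type measurements,
column-mean centering (no unit-variance scaling — scaling would amplify the
contribution of noisy low-signal variables), an expression-level x spread
filter to drop uninformative transcript variables, and a Pearson correlation
matrix for heatmap-style inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessConfig",
    "box_cox",
    "center_columns",
    "filter_expression",
    "correlation_matrix",
]


@dataclass
class PreprocessConfig:
    """Knobs of the default chain.

    ``boxcox_lambda=0.25`` (fourth-root-like transform); ``level_quantile``
    and ``iqr_quantile`` of 0.75 keep variables in the top 25% by mean
    absolute level and by interquartile range respectively.
    """

    boxcox_lambda: float = 0.25
    center: bool = True
    level_quantile: float = 0.75
    iqr_quantile: float = 0.75
    level_statistic: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        for qname in ("level_quantile", "iqr_quantile"):
            q = getattr(self, qname)
            if not 0 < q < 1:
                raise ValueError(f"{qname} must lie in (0, 1)")
        if not np.isfinite(self.boxcox_lambda):
            raise ValueError("boxcox_lambda must be finite")
        if self.level_statistic not in ("mean", "median"):
            raise ValueError("level_statistic must be 'mean' or 'median'")


def box_cox(matrix: np.ndarray | pd.DataFrame, lam: float) -> np.ndarray | pd.DataFrame:
    """Entrywise Box-Cox power transform: (x^lam - 1)/lam, or log(x) at lam=0.

    Strictly increasing in x, so within-variable ranks are preserved.
    All entries must be strictly positive.
    """
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in input")
    if (values <= 0).any():
        bad = np.argwhere(values <= 0)[0]
        if isinstance(matrix, pd.DataFrame):
            name = matrix.columns[bad[1]]
            raise ValueError(
                f"non-positive value in variable {name!r}; Box-Cox requires positive data"
            )
        raise ValueError(
            f"non-positive value at row {bad[0]}, column {bad[1]}; "
            "Box-Cox requires positive data"
        )
    # expm1(lam*log x)/lam is (x^lam - 1)/lam without catastrophic
    # cancellation for small lam, and tends to log x as lam -> 0
    out = np.log(values) if lam == 0 else np.expm1(lam * np.log(values)) / lam
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def center_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove column means; return the centered matrix and the means."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    means = matrix.mean(axis=0)
    return matrix - means, means


def filter_expression(
    frame: pd.DataFrame,
    level_quantile: float = 0.75,
    iqr_quantile: float = 0.75,
    level_statistic: str = "mean",
) -> tuple[pd.DataFrame, list[str]]:
    """Keep variables that are both highly expressed and variable.

    A variable is kept iff its level summary (mean of absolute values across
    samples, or median if requested) reaches the ``level_quantile`` empirical
    quantile of all level summaries AND its interquartile range (Q3 - Q1,
    linear-interpolation quantiles) reaches the ``iqr_quantile`` quantile of
    all IQRs.  Thresholds use >= so exact ties are kept; the original column
    order is preserved.
    """
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute an IQR")
    values = frame.to_numpy(dtype=float)
    absvals = np.abs(values)
    if level_statistic == "mean":
        level = absvals.mean(axis=0)
    elif level_statistic == "median":
        level = np.median(absvals, axis=0)
    else:
        raise ValueError("level_statistic must be 'mean' or 'median'")
    q1 = np.quantile(values, 0.25, axis=0)
    q3 = np.quantile(values, 0.75, axis=0)
    iqr = q3 - q1
    # thresholds are order statistics ("lower") so ties at the cut are kept
    # and a vanishing quantile keeps every variable
    keep = (level >= np.quantile(level, level_quantile, method="lower")) & (
        iqr >= np.quantile(iqr, iqr_quantile, method="lower")
    )
    kept_ids = [str(c) for c, k in zip(frame.columns, keep) if k]
    return frame.loc[:, keep], kept_ids


def correlation_matrix(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Pearson correlations between columns.

    Symmetric with unit diagonal; zero-variance columns are rejected by name
    (their correlation is undefined).
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        names = list(matrix.columns)
    else:
        values = np.asarray(matrix, dtype=float)
        names = list(range(values.shape[1]))
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = names[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance column {bad!r}")
    R = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return R
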