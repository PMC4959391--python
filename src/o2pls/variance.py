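"""Explained-variation statistics for a fitted O2PLS model.

Six R² statistics summarize how the total sum of squares of each block is
split between the model parts:

* ``r2x = 1 - sum(E^2)/sum(X^2)`` — total modeled share of X (joint plus
  orthogonal); symmetrically ``r2y``.
* ``r2x_corr = sum((T W')^2)/sum(X^2)`` — the joint ("correlated") share of
  X; symmetrically ``r2y_corr``.
* ``r2x_hat = sum((U B_U W')^2)/sum(X^2)`` — the share of X predictable from
  Y through the inner relation; symmetrically ``r2y_hat``.

The ratios r2x_hat/r2x_corr and r2y_hat/r2y_corr measure how much of each
joint part is actually predictable from the other block.  Alongside, the raw
sums of squares per model part (scores, residuals, inner-relation residual)
are reported with shares relative to their block's total.

All sums of squares are plain entrywise (Frobenius) sums over the centered
matrices; no degrees-of-freedom corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PairedData
from .model import O2PLSModel

__all__ = ["VarianceDecomposition", "variance_decomposition"]


@dataclass
class VarianceDecomposition:
    r2x: float
    r2y: float
    r2x_corr: float
    r2y_corr: float
    r2x_hat: float
    r2y_hat: float
    ratio_x: float  # r2x_hat / r2x_corr
    ratio_y: float  # r2y_hat / r2y_corr
    #: absolute sums of squares per model part
    ss_parts: dict[str, float]
    #: shares of ss_parts relative to the owning block's total SS
    #: (T, T_Yorth, E relative to X; U, U_Xorth, F relative to Y;
    #:  H_UT relative to U)
    relative_parts: dict[str, float]

    def as_rows(self) -> list[tuple[str, float, float]]:
        """(name, absolute, relative-share) rows for tabular output."""
        out = [
            ("R2X", self.r2x, self.r2x),
            ("R2Y", self.r2y, self.r2y),
            ("R2Xcorr", self.r2x_corr, self.r2x_corr),
            ("R2Ycorr", self.r2y_corr, self.r2y_corr),
            ("R2Xhat", self.r2x_hat, self.r2x_hat),
            ("R2Yhat", self.r2y_hat, self.r2y_hat),
            ("R2Xhat/R2Xcorr", self.ratio_x, self.ratio_x),
            ("R2Yhat/R2Ycorr", self.ratio_y, self.ratio_y),
        ]
        for name, ss in self.ss_parts.items():
            out.append((f"SS_{name}", ss, self.relative_parts[name]))
        return out


def variance_decomposition(
    model: O2PLSModel, data: PairedData
) -> VarianceDecomposition:
    """Compute the R² table and per-part sums of squares for a fit.

    ``data`` must be the centered blocks the model was fitted on; the
    reconstruction pieces are recomputed from the model factors and compared
    against the blocks' total sums of squares.
    """
    ss_x = float((data.X**2).sum())
    ss_y = float((data.Y**2).sum())
    if ss_x == 0 or ss_y == 0:
        raise ValueError("a block has zero total sum of squares")

    ss = {
        "T": float((model.T**2).sum()),
        "T_Yorth": float((model.T_Yorth**2).sum()),
        "E": float((model.E**2).sum()),
        "U": float((model.U**2).sum()),
        "U_Xorth": float((model.U_Xorth**2).sum()),
        "F": float((model.F**2).sum()),
        "H_UT": float((model.H_UT**2).sum()),
    }
    ss_u = ss["U"]
    relative = {
        "T": ss["T"] / ss_x,
        "T_Yorth": ss["T_Yorth"] / ss_x,
        "E": ss["E"] / ss_x,
        "U": ss["U"] / ss_y,
        "U_Xorth": ss["U_Xorth"] / ss_y,
        "F": ss["F"] / ss_y,
        "H_UT": ss["H_UT"] / ss_u if ss_u > 0 else float("nan"),
    }

    r2x = 1.0 - ss["E"] / ss_x
    r2y = 1.0 - ss["F"] / ss_y
    r2x_corr = float(((model.T @ model.W.T) ** 2).sum()) / ss_x
    r2y_corr = float(((model.U @ model.C.T) ** 2).sum()) / ss_y
    r2x_hat = float(((model.U @ model.B_U @ model.W.T) ** 2).sum()) / ss_x
    r2y_hat = float(((model.T @ model.B_T @ model.C.T) ** 2).sum()) / ss_y
    return VarianceDecomposition(
        r2x=r2x,
        r2y=r2y,
        r2x_corr=r2x_corr,
        r2y_corr=r2y_corr,
        r2x_hat=r2x_hat,
        r2y_hat=r2y_hat,
        ratio_x=r2x_hat / r2x_corr if r2x_corr > 0 else float("nan"),
        ratio_y=r2y_hat / r2y_corr if r2y_corr > 0 else float("nan"),
        ss_parts=ss,
        relative_parts=relative,
    )
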