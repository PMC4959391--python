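"""Sample-aligned pairs of omics data matrices.

Two blocks ``X`` (N samples x p variables) and ``Y`` (N x q) measured on the
same samples are the basic input of O2PLS.  :class:`PairedData` keeps the two
numeric matrices together with their sample and variable identifiers, tracks
whether each block has been column-mean centered, and stores the column means
so they can be re-applied to held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["PairedData", "align_samples"]

#: absolute column-mean bound under which a block counts as centered
CENTERED_TOL = 1e-10


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class PairedData:
    """Two sample-aligned numeric blocks with identifiers.

    Parameters
    ----------
    X, Y
        Dense float matrices of shape (N, p) and (N, q).  Missing values are
        rejected: samples with missing measurements must be dropped upstream
        (see :func:`align_samples`).
    sample_ids, x_var_ids, y_var_ids
        Unique string identifiers for rows and for the columns of each block.
    centered_x, centered_y
        Whether each block has been column-mean centered.
    column_means_x, column_means_y
        Column means removed by :meth:`center` (kept for held-out data).
    """

    X: np.ndarray
    Y: np.ndarray
    sample_ids: list[str]
    x_var_ids: list[str]
    y_var_ids: list[str]
    centered_x: bool = False
    centered_y: bool = False
    column_means_x: np.ndarray | None = None
    column_means_y: np.ndarray | None = None
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self._skip_validation:
            return
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-dimensional")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"sample counts differ: X has {self.X.shape[0]}, Y has {self.Y.shape[0]}"
            )
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length does not match the number of rows")
        if len(self.x_var_ids) != self.X.shape[1]:
            raise ValueError("x_var_ids length does not match X's column count")
        if len(self.y_var_ids) != self.Y.shape[1]:
            raise ValueError("y_var_ids length does not match Y's column count")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.x_var_ids, "X variable")
        _check_unique(self.y_var_ids, "Y variable")
        if not np.isfinite(self.X).all() or not np.isfinite(self.Y).all():
            raise ValueError(
                "missing or non-finite values present; drop incomplete samples first"
            )
        if self.centered_x and np.abs(self.X.mean(axis=0)).max() > CENTERED_TOL:
            raise ValueError("X flagged as centered but has nonzero column means")
        if self.centered_y and np.abs(self.Y.mean(axis=0)).max() > CENTERED_TOL:
            raise ValueError("Y flagged as centered but has nonzero column means")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def centered(self) -> bool:
        """True when both blocks are centered."""
        return self.centered_x and self.centered_y

    def center(self) -> "PairedData":
        """Return a copy with both blocks column-mean centered.

        The removed means are stored on the result for later use on new data
        (prediction, cross-validation test folds).
        """
        mx = self.X.mean(axis=0)
        my = self.Y.mean(axis=0)
        return replace(
            self,
            X=self.X - mx,
            Y=self.Y - my,
            centered_x=True,
            centered_y=True,
            column_means_x=mx,
            column_means_y=my,
        )

    def subset_samples(self, indices: np.ndarray) -> "PairedData":
        """Row-subset both blocks; centering flags are reset."""
        idx = np.asarray(indices)
        return PairedData(
            X=self.X[idx],
            Y=self.Y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            x_var_ids=list(self.x_var_ids),
            y_var_ids=list(self.y_var_ids),
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        x = pd.DataFrame(self.X, index=self.sample_ids, columns=self.x_var_ids)
        y = pd.DataFrame(self.Y, index=self.sample_ids, columns=self.y_var_ids)
        return x, y


def align_samples(x_frame: pd.DataFrame, y_frame: pd.DataFrame) -> PairedData:
    """Pair two labeled matrices on their shared samples.

    Samples are matched by row identifier; the intersection is taken in the
    order the identifiers appear in ``x_frame``.  Any sample with a missing
    value in either block is dropped entirely — incomplete samples are never
    imputed.

    Returns an uncentered :class:`PairedData`.

    Raises
    ------
    ValueError
        If either matrix has duplicate sample ids, or the id intersection is
        empty.
    """
    for frame, name in ((x_frame, "X"), (y_frame, "Y")):
        if frame.index.has_duplicates:
            raise ValueError(f"duplicate sample identifiers in {name}")
    shared = [sid for sid in x_frame.index if sid in set(y_frame.index)]
    if not shared:
        raise ValueError("no shared sample identifiers between the two blocks")
    x = x_frame.loc[shared]
    y = y_frame.loc[shared]
    complete = ~(x.isna().any(axis=1).to_numpy() | y.isna().any(axis=1).to_numpy())
    n_dropped = int((~complete).sum())
    kept = [sid for sid, ok in zip(shared, complete) if ok]
    if not kept:
        raise ValueError("all shared samples contain missing values")
    data = PairedData(
        X=x.loc[kept].to_numpy(dtype=float),
        Y=y.loc[kept].to_numpy(dtype=float),
        sample_ids=[str(s) for s in kept],
        x_var_ids=[str(c) for c in x_frame.columns],
        y_var_ids=[str(c) for c in y_frame.columns],
    )
    data.n_dropped_samples = n_dropped  # type: ignore[attr-defined]
    return data
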