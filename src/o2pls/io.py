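"""Delimited-matrix IO, model directories and run manifests.

Matrices travel as TSV/CSV with a header row of variable ids and a first
column of sample ids.  A fitted model is serialized as a directory of TSV
factor matrices plus a JSON metadata file; floats are written at 17
significant digits so round trips are exact.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import O2PLSModel

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_model",
    "load_model",
    "write_manifest",
    "file_digest",
]

_FLOAT_FMT = "%.17g"

#: factor matrices serialized per model, with their label axes
_MODEL_FACTORS = (
    "W",
    "C",
    "P_Yorth",
    "P_Xorth",
    "W_Yorth",
    "C_Xorth",
    "T",
    "U",
    "T_Yorth",
    "U_Xorth",
    "B_T",
    "B_U",
    "E",
    "F",
    "H_UT",
    "H_TU",
)


def read_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a labeled numeric matrix from delimited text.

    The delimiter is inferred from the suffix (.csv -> comma, else tab)
    unless given.  Empty fields and "NA" are read as missing (dropped later
    by sample alignment, never imputed).  Ragged rows, non-numeric cells and
    duplicate identifiers are rejected with coordinates.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=["NA"],
        keep_default_na=True,
        float_precision="round_trip",
    )
    if frame.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    if frame.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate variable identifiers")
    for j, col in enumerate(frame.columns):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric cell at row {i + 1}, column {j + 1} "
                f"(sample {frame.index[i]!r}, variable {col!r})"
            )
        frame[col] = coerced
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    return frame


def write_matrix(
    frame: pd.DataFrame, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a labeled matrix as delimited text at full precision."""
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    frame.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT)


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's contents."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_model(model: O2PLSModel, out_dir: str | Path) -> None:
    """Serialize a fitted model as a directory of TSVs plus metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _MODEL_FACTORS:
        arr = np.atleast_2d(getattr(model, name))
        if arr.size == 0:  # zero-component factor; shape restored from metadata
            (out / f"{name}.tsv").write_text("")
        else:
            np.savetxt(out / f"{name}.tsv", arr, delimiter="\t", fmt=_FLOAT_FMT)
    meta = {
        "a": model.a,
        "n_x": model.n_x,
        "n_y": model.n_y,
        "p": model.p,
        "q": model.q,
        "singular_values": model.singular_values.tolist(),
        "column_means_x": model.column_means_x.tolist(),
        "column_means_y": model.column_means_y.tolist(),
        "r2_u_on_t": model.r2_u_on_t,
        "r2_t_on_u": model.r2_t_on_u,
        "software_version": __version__,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(model_dir: str | Path) -> O2PLSModel:
    """Load a model saved by :func:`save_model`."""
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())

    def read(name: str) -> np.ndarray:
        path = d / f"{name}.tsv"
        if path.stat().st_size == 0:
            return np.zeros((0, 0))
        return np.loadtxt(path, delimiter="\t", ndmin=2)

    factors = {name: read(name) for name in _MODEL_FACTORS}
    # zero-width factors flatten through savetxt; restore their shapes
    n = factors["T"].shape[0]
    p, q, a = meta["p"], meta["q"], meta["a"]
    for name, rows in (
        ("P_Yorth", p),
        ("W_Yorth", p),
        ("P_Xorth", q),
        ("C_Xorth", q),
        ("T_Yorth", n),
        ("U_Xorth", n),
    ):
        if factors[name].size == 0:
            factors[name] = np.zeros((rows, 0))
    return O2PLSModel(
        a=a,
        n_x=meta["n_x"],
        n_y=meta["n_y"],
        singular_values=np.asarray(meta["singular_values"], dtype=float),
        r2_u_on_t=meta["r2_u_on_t"],
        r2_t_on_u=meta["r2_t_on_u"],
        column_means_x=np.asarray(meta["column_means_x"], dtype=float),
        column_means_y=np.asarray(meta["column_means_y"], dtype=float),
        **factors,
    )


def write_manifest(
    out_path: str | Path,
    command: str,
    config: dict,
    input_paths: list[str | Path],
    seed: int | None = None,
    log_path: str | None = None,
) -> dict:
    """Write a JSON run manifest recording inputs, digests, seed and version."""
    manifest = {
        "command": command,
        "config": config,
        "inputs": [
            {"path": str(p), "sha256": file_digest(p)} for p in input_paths
        ],
        "seed": seed,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "log_path": log_path,
    }
    Path(out_path).write_text(json.dumps(manifest, indent=1))
    return manifest
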