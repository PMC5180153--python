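"""On-disk formats: CSV matrices, wide-CSV time series, JSON sidecars.

Matrices are headerless CSV; a file whose entries are all 0/1 loads as a
binary :class:`~phagenet.model.InfectionMatrix`, anything else (non-negative)
as a :class:`~phagenet.model.QuantitativeNetwork`. Time series are wide CSV
with header ``time,h1..hNh,v1..vNv`` (time in days, densities per ml) and an
optional ``<name>.meta.json`` sidecar carrying provenance. Floats are
written at 17 significant digits so write/read round trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .model import InfectionMatrix, QuantitativeNetwork
from .nestedness import MatrixEnsemble, nodf
from .simulate import CommunityTimeSeries

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_ensemble",
    "write_ensemble",
]

_FLOAT_FMT = "%.17g"


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_matrix_csv(matrix: InfectionMatrix | QuantitativeNetwork, path) -> None:
    path = Path(path)
    arr = matrix.entries
    fmt = "%d" if isinstance(matrix, InfectionMatrix) else _FLOAT_FMT
    np.savetxt(path, arr, fmt=fmt, delimiter=",")


def read_matrix_csv(path) -> InfectionMatrix | QuantitativeNetwork:
    """Load a headerless numeric CSV as an infection matrix or rate network."""
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except (ValueError, OSError) as exc:
        if isinstance(exc, OSError) and not path.exists():
            raise FileNotFoundError(path) from exc
        raise FormatError(f"{path}: not a rectangular numeric CSV ({exc})") from exc
    if arr.size == 0:
        raise FormatError(f"{path}: empty matrix file")
    if (arr < 0).any():
        raise FormatError(f"{path}: negative entries are not valid rates")
    if np.isin(arr, (0.0, 1.0)).all():
        try:
            return InfectionMatrix(arr)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return QuantitativeNetwork(arr)


def write_timeseries_csv(ts: CommunityTimeSeries, path) -> None:
    path = Path(path)
    cols = {"time": ts.times}
    for i in range(ts.n_hosts):
        cols[f"h{i + 1}"] = ts.H[i]
    for j in range(ts.n_viruses):
        cols[f"v{j + 1}"] = ts.V[j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if ts.meta:
        with open(_meta_path(path), "w") as fh:
            json.dump(ts.meta, fh, indent=1, default=str)


def read_timeseries_csv(path) -> CommunityTimeSeries:
    """Load a wide-CSV trajectory (header ``time,h1..,v1..``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        # round_trip parser: the default fast path is off by one ulp on some
        # values, breaking write/read bit-exactness
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if "time" not in df.columns:
        raise FormatError(f"{path}: missing 'time' column")
    h_cols = [c for c in df.columns if c.startswith("h") and c[1:].isdigit()]
    v_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    if not h_cols or not v_cols:
        raise FormatError(f"{path}: need h1.. and v1.. density columns")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    h_cols.sort(key=lambda c: int(c[1:]))
    v_cols.sort(key=lambda c: int(c[1:]))
    times = df["time"].to_numpy(dtype=float)
    if len(times) >= 2 and (np.diff(times) <= 0).any():
        raise FormatError(f"{path}: times must be strictly increasing")
    H = df[h_cols].to_numpy(dtype=float).T
    V = df[v_cols].to_numpy(dtype=float).T
    if (H <= 0).any() or (V <= 0).any():
        raise FormatError(f"{path}: densities must be strictly positive")
    meta = {}
    mpath = _meta_path(path)
    if mpath.exists():
        with open(mpath) as fh:
            meta = json.load(fh)
    try:
        return CommunityTimeSeries(times=times, H=H, V=V, meta=meta)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_ensemble(ensemble: MatrixEnsemble, directory) -> None:
    """Directory of ``matrix_XXX.csv`` files plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for k, M in enumerate(ensemble.matrices):
        name = f"matrix_{k:03d}.csv"
        write_matrix_csv(M, directory / name)
        names.append(name)
    index = {
        "matrices": names,
        "nodf": [float(x) for x in ensemble.nodf_values],
        "complete": ensemble.complete,
        "meta": ensemble.meta,
    }
    with open(directory / "index.json", "w") as fh:
        json.dump(index, fh, indent=1, default=str)


def read_ensemble(directory) -> MatrixEnsemble:
    directory = Path(directory)
    index_path = directory / "index.json"
    if not index_path.exists():
        raise FileNotFoundError(index_path)
    with open(index_path) as fh:
        index = json.load(fh)
    matrices = []
    for name in index["matrices"]:
        M = read_matrix_csv(directory / name)
        if not isinstance(M, InfectionMatrix):
            raise FormatError(f"{directory / name}: ensemble members must be binary")
        matrices.append(M)
    nodf_values = index.get("nodf") or [nodf(M) for M in matrices]
    return MatrixEnsemble(
        matrices=matrices,
        nodf_values=np.asarray(nodf_values, dtype=float),
        complete=index.get("complete", True),
        meta=index.get("meta", {}),
    )
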