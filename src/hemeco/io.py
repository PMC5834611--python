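"""CSV/JSON serialization helpers shared across modules.

Conventions: two-column CSV (axis, value) for traces and spectra; matrix CSV
with the wavelength grid as header row and the delay grid as first column for
spectro-temporal data; JSON for fit reports, with a sha256 digest of every
input file consumed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def sha256_digest(data: bytes | str | Path) -> str:
    """sha256 hex digest of raw bytes, or of a file's contents if a path."""
    if isinstance(data, (str, Path)) and Path(data).is_file():
        data = Path(data).read_bytes()
    if isinstance(data, str):
        data = data.encode()
    return hashlib.sha256(data).hexdigest()


def write_xy_csv(path, x, y, x_name: str, y_name: str) -> None:
    pd.DataFrame({x_name: np.asarray(x), y_name: np.asarray(y)}).to_csv(path, index=False)


def read_xy_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_matrix_csv(path, row_grid, col_grid, matrix, row_name: str = "delay_ps") -> None:
    """Matrix CSV: first column = row grid (delays), header = column grid."""
    df = pd.DataFrame(np.asarray(matrix), columns=[f"{c:g}" for c in np.asarray(col_grid)])
    df.insert(0, row_name, np.asarray(row_grid))
    df.to_csv(path, index=False)


def read_matrix_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    rows = df.iloc[:, 0].to_numpy(float)
    cols = np.array([float(c) for c in df.columns[1:]])
    return rows, cols, df.iloc[:, 1:].to_numpy(float)


def write_json_report(path, payload: dict, inputs: dict[str, str] | None = None) -> None:
    """Write a JSON fit report; `inputs` maps input names to their digests."""
    out = dict(payload)
    if inputs:
        out["input_digests"] = inputs
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
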