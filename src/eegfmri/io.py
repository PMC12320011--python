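"""Reading and writing of pipeline signals, tables and sidecar metadata.

Native signal format: tab-separated values, one row per time sample, one
column per channel/region/RSN, with a JSON sidecar next to the file
carrying sampling metadata (``fs`` or ``tr``), labels, units, and the seed
used for synthetic data.  Voxel matrices and spatial maps may also come as
NIfTI volumes (flattened in file order).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "read_nifti_matrix",
    "FormatError",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_timeseries(path: str | Path, values: np.ndarray, labels,
                     sidecar: dict) -> None:
    """Write a ``[n_time, n_col]`` matrix as TSV plus a JSON sidecar.

    Values are stored at full precision (hexadecimal-free ``repr`` floats)
    so a read-back round-trips bitwise.
    """
    path = Path(path)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = list(labels)
    if values.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {values.shape[1]} columns but {len(labels)} labels")
    df = pd.DataFrame(values, columns=labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = dict(sidecar)
    meta["labels"] = labels
    meta["n_time"] = int(values.shape[0])
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_timeseries(path: str | Path, require_keys=()) -> tuple[np.ndarray, list, dict]:
    """Read a TSV + JSON-sidecar time-series file.

    Returns ``(values [n_time, n_col], labels, sidecar)``.  Raises
    :class:`FormatError` naming the file when the sidecar is missing, a
    required metadata key is absent, or labels/shape disagree.
    """
    path = Path(path)
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sc.name}")
    with open(sc) as fh:
        meta = json.load(fh)
    for key in require_keys:
        if key not in meta:
            raise FormatError(f"{path}: sidecar lacks required key {key!r}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = list(df.columns)
    if "labels" in meta and list(meta["labels"]) != labels:
        raise FormatError(f"{path}: sidecar labels disagree with TSV header")
    values = df.to_numpy(dtype=float)
    if "n_time" in meta and values.shape[0] != meta["n_time"]:
        raise FormatError(f"{path}: expected {meta['n_time']} rows, "
                          f"found {values.shape[0]}")
    return values, labels, meta


def read_nifti_matrix(path: str | Path) -> np.ndarray:
    """Load a 4-D NIfTI as a ``[n_vox, n_vol]`` matrix (file voxel order)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 3-D or 4-D image")
    return data.reshape(-1, data.shape[-1], order="F")
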