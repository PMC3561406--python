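"""File I/O: the CSV series dialect, NIfTI volumes, and JSON results.

Series CSV: one row per time point, columns ``time_s, value``, header
required, UTF-8, '.' decimal.  Raw acquisitions travel as one 4-D NIfTI
file per echo plus a JSON metadata sidecar (tr, parity, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .estimator import BCPResult
from .preprocess import RawAcquisition, TimeSeriesPair

__all__ = [
    "read_series",
    "write_series",
    "read_mask",
    "write_bcp_result",
    "write_json",
    "save_acquisition",
    "load_acquisition",
]


def write_series(path, values, tr: float) -> None:
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({"time_s": np.arange(values.size) * tr, "value": values})
    df.to_csv(path, index=False)


def read_series(path) -> tuple[np.ndarray, float]:
    """Read a series CSV; returns ``(values, tr)`` with tr from the time axis."""
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"series CSV {path} lacks columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    tr = float(t[1] - t[0]) if t.size > 1 else 1.0
    if t.size > 1 and (tr <= 0 or not np.allclose(np.diff(t), tr)):
        raise ValueError(f"series CSV {path} is not uniformly sampled")
    return df["value"].to_numpy(dtype=float), tr


def read_mask(path) -> np.ndarray:
    """Nonzero voxels of a 3-D NIfTI mask as a boolean array."""
    return np.asarray(nib.load(str(path)).get_fdata()) != 0


def write_bcp_result(
    prefix,
    pair: TimeSeriesPair,
    result: BCPResult,
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Serialize a fit as CSV (series) plus a JSON sidecar (scalars)."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame(
        {
            "time_s": pair.times,
            "asl_meas": pair.asl,
            "bold_meas": pair.bold,
            "f_hat": result.f_hat,
            "b_hat": result.b_hat,
        }
    ).to_csv(csv_path, index=False)
    s = result.settings
    write_json(
        json_path,
        {
            "k_hat": result.k_hat,
            "cost": result.cost,
            "n_evals": result.n_evals,
            "bracket": list(result.bracket),
            "settings": {
                "bracket_lo": s.bracket_lo,
                "bracket_hi": s.bracket_hi,
                "tolerance": s.tolerance,
                "f_floor": s.f_floor,
                "f_cap": s.f_cap,
            },
            "seed": seed,
        },
    )
    return csv_path, json_path


def write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def save_acquisition(raw: RawAcquisition, out_dir, seed: int | None = None) -> dict[str, Path]:
    """Write a raw acquisition as two 4-D NIfTI files plus JSON metadata.

    A flat voxel list of length V becomes a ``(V, 1, 1, T)`` volume.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, frames in (("echo1", raw.frames_echo1), ("echo2", raw.frames_echo2)):
        arr = np.atleast_2d(frames)
        vol = arr.reshape(arr.shape[0], 1, 1, arr.shape[1])
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float64), affine=np.eye(4)), str(p))
        paths[name] = p
    meta = out_dir / "acquisition.json"
    write_json(meta, {"tr": raw.tr, "parity": raw.parity, "seed": seed})
    paths["meta"] = meta
    return paths


def load_acquisition(echo1_path, echo2_path, meta_path) -> RawAcquisition:
    with open(meta_path, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    e1 = np.asarray(nib.load(str(echo1_path)).get_fdata())
    e2 = np.asarray(nib.load(str(echo2_path)).get_fdata())
    e1 = e1.reshape(-1, e1.shape[-1])
    e2 = e2.reshape(-1, e2.shape[-1])
    if e1.shape[0] == 1:
        e1, e2 = e1[0], e2[0]
    return RawAcquisition(e1, e2, tr=float(meta["tr"]), parity=str(meta["parity"]))
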