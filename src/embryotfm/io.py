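"""Reading and writing of the pipeline's file formats.

Images travel as (multi-frame) grayscale TIFF via tifffile; vector fields,
drift tables, force metrics and trajectories as tidy CSV via pandas.  Every
CSV written by the pipeline carries provenance comment lines (``# key:
value``) holding the config hash and package version.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .fields import DisplacementField, GelProperties, TractionField

PathLike = Union[str, Path]

__all__ = [
    "write_tiff", "read_tiff",
    "displacement_to_frame", "frame_to_displacement",
    "traction_to_frame",
    "write_csv", "read_csv",
    "write_gel_json", "read_gel_json",
]


def write_tiff(path: PathLike, array: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(array))


def read_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path))


def displacement_to_frame(field: DisplacementField) -> pd.DataFrame:
    X, Y = np.meshgrid(field.x, field.y)
    quality = field.quality if field.quality is not None else np.ones_like(field.u)
    return pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "u_um": field.u.ravel(),
            "v_um": field.v.ravel(),
            "valid": field.mask.ravel().astype(int),
            "quality": np.asarray(quality).ravel(),
        }
    )


def frame_to_displacement(df: pd.DataFrame) -> DisplacementField:
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    shape = (y.size, x.size)
    order = np.lexsort((df["x_um"].to_numpy(), df["y_um"].to_numpy()))
    u = df["u_um"].to_numpy()[order].reshape(shape)
    v = df["v_um"].to_numpy()[order].reshape(shape)
    mask = df["valid"].to_numpy()[order].reshape(shape).astype(bool)
    quality = df["quality"].to_numpy()[order].reshape(shape)
    return DisplacementField(x, y, u, v, mask, quality)


def traction_to_frame(traction: TractionField) -> pd.DataFrame:
    X, Y = np.meshgrid(traction.x, traction.y)
    return pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "tx_pa": traction.tx.ravel(),
            "ty_pa": traction.ty.ravel(),
            "t_pa": traction.magnitude.ravel(),
        }
    )


def write_csv(
    path: PathLike, df: pd.DataFrame, provenance: Optional[Dict[str, str]] = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_gel_json(path: PathLike, gel: GelProperties, **extra) -> None:
    payload = {
        "youngs_modulus_pa": gel.youngs_modulus,
        "poisson_ratio": gel.poisson_ratio,
        "thickness_um": gel.thickness,
    }
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_gel_json(path: PathLike) -> GelProperties:
    payload = json.loads(Path(path).read_text())
    return GelProperties(
        youngs_modulus=payload["youngs_modulus_pa"],
        poisson_ratio=payload.get("poisson_ratio", 0.5),
        thickness=payload.get("thickness_um", 150.0),
    )
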