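"""Serialization: TIFF + YAML sidecar volumes, boundary archives, override
and cohort CSV files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import ChoroidBoundaries
from .volume import OCTVolume, Spacing

_SIDE_SUFFIX = ".yaml"


def save_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a multipage 16-bit grayscale TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(volume.intensities, 0.0, 1.0)
    tifffile.imwrite(path, (data * 65535).astype(np.uint16))
    meta = {
        "spacing_um": {"bscan": float(volume.spacing.bscan),
                       "axial": float(volume.spacing.axial),
                       "ascan": float(volume.spacing.ascan)},
        "laterality": volume.laterality,
        "fovea_index": [int(volume.fovea_index[0]), int(volume.fovea_index[1])],
        "id": volume.id,
    }
    sidecar = path.with_suffix(_SIDE_SUFFIX)
    sidecar.write_text(yaml.safe_dump(meta))
    return path


def load_volume(path: str | Path, meta_path: str | Path | None = None) -> OCTVolume:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(_SIDE_SUFFIX)
    meta = yaml.safe_load(Path(meta_path).read_text())
    data = tifffile.imread(path).astype(float) / 65535.0
    sp = meta["spacing_um"]
    return OCTVolume(
        intensities=data,
        spacing=Spacing(sp["bscan"], sp["axial"], sp["ascan"]),
        laterality=meta.get("laterality", "OD"),
        fovea_index=tuple(meta["fovea_index"]) if meta.get("fovea_index") else None,
        id=meta.get("id", ""),
    )


def save_boundaries(boundaries: ChoroidBoundaries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, inner=boundaries.inner, outer=boundaries.outer,
                        corrected=boundaries.corrected,
                        n_axial=boundaries.n_axial)
    return path


def load_boundaries(path: str | Path) -> ChoroidBoundaries:
    with np.load(path) as archive:
        return ChoroidBoundaries(inner=archive["inner"], outer=archive["outer"],
                                 corrected=archive["corrected"],
                                 n_axial=int(archive["n_axial"]))


def load_overrides(path: str | Path) -> pd.DataFrame:
    """Manual boundary corrections: CSV with columns
    ``bscan,ascan,inner_px,outer_px``."""
    df = pd.read_csv(path)
    required = {"bscan", "ascan", "inner_px", "outer_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"override CSV missing columns: {sorted(missing)}")
    return df


def save_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
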