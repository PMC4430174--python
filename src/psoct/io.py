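"""File formats.

Volumes travel as one multi-page float32 TIFF per Stokes channel
(``<prefix>_I.tif`` … ``<prefix>_V.tif``; page = B-scan, page shape
``(n_ascans, n_depth)``) with a JSON sidecar ``<prefix>_geometry.json``
holding the scan geometry.  Masks and maps are single-channel TIFFs, lesion
sets and eye-visit records are CSV, configurations and band overrides are
YAML.  Write->read round-trips are lossless for integer grids and exact to
float32 for volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dopu import RpeMask, StokesVolume
from .ga_quant import AtrophyMap, GaLesionSet, ThicknessMap
from .geometry import ScanGeometry
from .lesion_rules import EyeVisitRecord

__all__ = [
    "write_stokes_volume",
    "read_stokes_volume",
    "write_label_map",
    "read_label_map",
    "write_mask",
    "read_mask",
    "write_thickness_map",
    "read_thickness_map",
    "write_atrophy_map",
    "write_lesion_set",
    "write_records",
    "read_records",
    "write_band_overrides",
    "read_band_overrides",
]

_CHANNELS = ("I", "Q", "U", "V")


def _sidecar(prefix: Path) -> Path:
    return prefix.with_name(prefix.name + "_geometry.json")


def write_stokes_volume(volume: StokesVolume, prefix: str | Path) -> list[Path]:
    """Write the four channel TIFFs plus the geometry sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, arr in zip(_CHANNELS, (volume.i, volume.q, volume.u, volume.v)):
        path = prefix.with_name(f"{prefix.name}_{ch}.tif")
        tifffile.imwrite(path, arr.astype(np.float32))
        paths.append(path)
    side = _sidecar(prefix)
    side.write_text(json.dumps(volume.geometry.to_dict(), indent=2))
    paths.append(side)
    return paths


def read_stokes_volume(prefix: str | Path) -> StokesVolume:
    """Read a volume written by :func:`write_stokes_volume`."""
    prefix = Path(prefix)
    side = _sidecar(prefix)
    if not side.exists():
        raise FileNotFoundError(f"geometry sidecar missing: {side}")
    geometry = ScanGeometry.from_dict(json.loads(side.read_text()))
    arrays = {}
    for ch in _CHANNELS:
        path = prefix.with_name(f"{prefix.name}_{ch}.tif")
        if not path.exists():
            raise FileNotFoundError(f"Stokes channel file missing: {path}")
        arr = tifffile.imread(path)
        if arr.shape != geometry.shape:
            raise ValueError(
                f"{path.name}: shape {arr.shape} does not match geometry "
                f"sidecar {geometry.shape}"
            )
        arrays[ch] = arr
    return StokesVolume(
        i=arrays["I"], q=arrays["Q"], u=arrays["U"], v=arrays["V"], geometry=geometry
    )


def write_label_map(label_map: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, label_map.astype(np.uint8))
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_mask(mask: RpeMask, path: str | Path) -> Path:
    return write_label_map(mask.mask.astype(np.uint8), path)


def read_mask(path: str | Path, geometry: ScanGeometry, **provenance) -> RpeMask:
    arr = tifffile.imread(Path(path)).astype(bool)
    return RpeMask(
        mask=arr,
        dopu_threshold=provenance.pop("dopu_threshold", 0.8),
        window=provenance.pop("window", (9, 9)),
        geometry=geometry,
        provenance=provenance,
    )


def write_thickness_map(tmap: ThicknessMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, tmap.counts.astype(np.int32))
    path.with_suffix(".csv").write_text(
        pd.DataFrame(tmap.counts).to_csv(index=False)
    )
    return path


def read_thickness_map(path: str | Path, geometry: ScanGeometry) -> ThicknessMap:
    return ThicknessMap(
        counts=tifffile.imread(Path(path)).astype(np.int64), geometry=geometry
    )


def write_atrophy_map(amap: AtrophyMap, path: str | Path) -> Path:
    return write_label_map(amap.atrophic.astype(np.uint8), path)


def write_lesion_set(lesions: GaLesionSet, path: str | Path) -> Path:
    """CSV of lesions and sub-threshold components."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for group, entries in (("lesion", lesions.lesions),
                           ("subthreshold", lesions.subthreshold)):
        for entry in entries:
            rows.append(
                {
                    "lesion_id": f"{group}-{entry.lesion_id}",
                    "group": group,
                    "n_pixels": entry.n_pixels,
                    "area_mm2": entry.area_mm2,
                    "centroid_x_mm": entry.centroid_x_mm,
                    "centroid_y_mm": entry.centroid_y_mm,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "lesion_id", "group", "n_pixels", "area_mm2",
            "centroid_x_mm", "centroid_y_mm",
        ],
    ).to_csv(path, index=False)
    return path


_RECORD_COLUMNS = [
    "eye_id", "visit_month", *EyeVisitRecord.LESION_TYPES,
    "ga_area_mm2", "crt_um", "bcva_letters",
]


def write_records(records: list[EyeVisitRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {col: getattr(r, col) for col in _RECORD_COLUMNS} for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)
    return path


def read_records(path: str | Path) -> list[EyeVisitRecord]:
    df = pd.read_csv(Path(path))
    records = []
    for _, row in df.iterrows():
        kwargs = {col: row[col] for col in _RECORD_COLUMNS}
        for t in EyeVisitRecord.LESION_TYPES:
            kwargs[t] = int(kwargs[t])
        kwargs["visit_month"] = int(kwargs["visit_month"])
        for opt in ("crt_um", "bcva_letters"):
            kwargs[opt] = None if pd.isna(kwargs[opt]) else float(kwargs[opt])
        records.append(EyeVisitRecord(**kwargs))
    return records


def write_band_overrides(overrides: dict[int, tuple[int, int]], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        yaml.safe_dump({int(b): [int(u), int(l)] for b, (u, l) in overrides.items()})
    )
    return path


def read_band_overrides(path: str | Path) -> dict[int, tuple[int, int]]:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return {int(b): (int(ul[0]), int(ul[1])) for b, ul in data.items()}
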