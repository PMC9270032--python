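"""Readers and writers for the formats the pipeline travels in.

Point-cloud tables are RFC-4180 CSV with header columns
``animal_id,line,sex,x_um,y_um,z_um`` (one row per nucleus); volumes are
multi-page grayscale TIFF, one page per z-slice, with voxel spacing
supplied via config or a YAML sidecar.  Unknown extra CSV columns are
ignored with a warning.  Parsing is locale-independent (decimal point).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FormatError, ParameterError, PointCloud, Sex, VolumeImage

__all__ = [
    "read_point_cloud_table",
    "write_point_cloud_table",
    "read_volume",
    "write_volume",
    "read_diagram_csv",
    "write_diagram_csv",
    "write_gram_tsv",
    "read_gram_tsv",
]

log = logging.getLogger(__name__)

_COLUMNS = ["animal_id", "line", "sex", "x_um", "y_um", "z_um"]


def read_point_cloud_table(path) -> list[PointCloud]:
    """Read a nuclei-coordinate CSV into one :class:`PointCloud` per animal.

    Row order is preserved within an animal; animals are returned in order
    of first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype={"animal_id": str, "line": str, "sex": str})
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in _COLUMNS]
    if extra:
        log.warning("%s: ignoring unrecognised column(s) %s", path, extra)
    for col in ("x_um", "y_um", "z_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering.
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at line {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise FormatError(f"{path}: missing coordinate in {col!r} at line {row}")
        df[col] = coerced

    clouds = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        lines = sub["line"].unique()
        sexes = sub["sex"].map(Sex.parse).unique()
        if len(lines) > 1 or len(sexes) > 1:
            raise FormatError(
                f"{path}: animal {animal_id!r} has inconsistent line/sex metadata")
        clouds.append(PointCloud(
            animal_id=str(animal_id),
            line=str(lines[0]),
            sex=sexes[0],
            points=sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        ))
    return clouds


def write_point_cloud_table(clouds: Sequence[PointCloud], path) -> Path:
    """Write clouds as a coordinate CSV, ordered by (animal_id, point index)."""
    clouds = list(clouds)
    if not clouds:
        raise ParameterError("refusing to write an empty cloud collection")
    path = Path(path)
    frames = []
    for cloud in sorted(clouds, key=lambda c: c.animal_id):
        frames.append(pd.DataFrame({
            "animal_id": cloud.animal_id,
            "line": cloud.line,
            "sex": cloud.sex.value,
            "x_um": cloud.points[:, 0],
            "y_um": cloud.points[:, 1],
            "z_um": cloud.points[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_volume(path, spacing: tuple[float, float, float] | None = None) -> VolumeImage:
    """Read a multi-page TIFF stack as a :class:`VolumeImage`.

    ``spacing`` is ``(sx, sy, sz)`` in um; if omitted, a YAML sidecar
    ``<path>.yaml`` with a ``spacing_um`` entry is consulted.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a grayscale z-stack, got shape {arr.shape}")
    if spacing is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            spacing = tuple(meta["spacing_um"])
        else:
            raise FormatError(
                f"{path}: voxel spacing not supplied and no sidecar {sidecar.name}")
    return VolumeImage(intensities=arr, spacing=tuple(spacing))


def write_volume(vol: VolumeImage, path, sidecar: bool = True) -> Path:
    """Write a volume as multi-page TIFF (bit-exact for integer dtypes)."""
    path = Path(path)
    tifffile.imwrite(path, vol.intensities)
    if sidecar:
        _sidecar_path(path).write_text(
            yaml.safe_dump({"spacing_um": list(vol.spacing)}))
    return path


def write_diagram_csv(diagrams, path) -> Path:
    """Write persistence diagrams as CSV (item_id,degree,birth,death in um^2)."""
    path = Path(path)
    rows = []
    for item_id, diagram in diagrams:
        for birth, death in diagram.points:
            rows.append((item_id, diagram.degree, birth, death))
    pd.DataFrame(rows, columns=["item_id", "degree", "birth", "death"]).to_csv(
        path, index=False)
    return path


def read_diagram_csv(path):
    """Read diagrams written by :func:`write_diagram_csv`; returns id->diagram."""
    from .core import PersistenceDiagram

    df = pd.read_csv(path)
    missing = {"item_id", "degree", "birth", "death"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out = {}
    for item_id, sub in df.groupby("item_id", sort=False):
        degrees = sub["degree"].unique()
        if len(degrees) != 1:
            raise FormatError(f"{path}: mixed degrees for item {item_id!r}")
        out[str(item_id)] = PersistenceDiagram(
            degree=int(degrees[0]),
            points=sub[["birth", "death"]].to_numpy(dtype=float))
    return out


def write_gram_tsv(gram, path) -> Path:
    """Write a Gram matrix as TSV with item ids in header row/column."""
    from .core import KernelGram

    assert isinstance(gram, KernelGram)
    path = Path(path)
    df = pd.DataFrame(gram.matrix, index=gram.item_ids, columns=gram.item_ids)
    df.insert(0, "group_id", gram.group_ids)
    df.to_csv(path, sep="\t", index_label="item_id")
    return path


def read_gram_tsv(path, kernel_kind: str = "persistence_heat"):
    from .core import KernelGram

    df = pd.read_csv(path, sep="\t", index_col="item_id")
    groups = df.pop("group_id").astype(str).tolist()
    return KernelGram(matrix=df.to_numpy(dtype=float),
                      item_ids=[str(i) for i in df.index],
                      group_ids=groups, kernel_kind=kernel_kind)
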