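"""File formats: SWC skeletons, cell tables, lesion GeoJSON, TIFF volumes.

Conventions: SWC is the standard 7-column whitespace-separated dialect with
'#' comments, soma = type 1, radii in µm. CSV is comma-separated, '.'
decimal, UTF-8, header mandatory. Lesion polygons travel as GeoJSON feature
collections in µm coordinates with a per-feature ``section`` property.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .lesion import DEFAULT_RING_OFFSETS, LesionGeometry
from .raster import RasterVolume
from .skeleton import CellSkeleton


# ----------------------------------------------------------------------
# SWC
# ----------------------------------------------------------------------
def read_swc(path) -> CellSkeleton:
    """Parse an SWC file into a validated skeleton.

    Fails with the offending line number on non-numeric fields, wrong column
    counts, self-parenting, missing parents or cycles.
    """
    path = Path(path)
    ids, types, xs, ys, zs, rs, parents = [], [], [], [], [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, ntype, pid = int(parts[0]), int(parts[1]), int(parts[6])
                x, y, z, r = (float(v) for v in parts[2:6])
            except ValueError as e:
                raise ValueError(f"{path.name}:{lineno}: non-numeric field ({e})") from None
            if pid == nid:
                raise ValueError(f"{path.name}:{lineno}: node {nid} is its own parent")
            ids.append(nid)
            types.append(ntype)
            xs.append(x)
            ys.append(y)
            zs.append(z)
            rs.append(r)
            parents.append(pid)
    if not ids:
        raise ValueError(f"{path.name}: no nodes")
    try:
        return CellSkeleton(
            ids=np.array(ids),
            types=np.array(types),
            xyz=np.column_stack([xs, ys, zs]),
            radius=np.array(rs),
            parent=np.array(parents),
            cell_id=path.stem,
        )
    except ValueError as e:
        raise ValueError(f"{path.name}: {e}") from None


def write_swc(skeleton: CellSkeleton, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(skeleton.n_nodes):
            fh.write(
                f"{skeleton.ids[k]} {skeleton.types[k]} "
                f"{skeleton.xyz[k, 0]:.6f} {skeleton.xyz[k, 1]:.6f} {skeleton.xyz[k, 2]:.6f} "
                f"{skeleton.radius[k]:.6f} {skeleton.parent[k]}\n"
            )


# ----------------------------------------------------------------------
# cell tables
# ----------------------------------------------------------------------
def read_cells_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"code_bits": str, "cell_id": str})
    return df


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


# ----------------------------------------------------------------------
# lesion GeoJSON
# ----------------------------------------------------------------------
def read_lesions_geojson(path) -> list[LesionGeometry]:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("lesion file must be a GeoJSON FeatureCollection")
    lesions = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"lesion feature must be a Polygon, got {geom.geom_type}")
        sec = int(feat.get("properties", {}).get("section", 0))
        offsets = tuple(
            feat.get("properties", {}).get("ring_offsets_um", DEFAULT_RING_OFFSETS)
        )
        lesions.append(LesionGeometry(section=sec, core=geom, ring_offsets=offsets))
    if not lesions:
        raise ValueError("no lesion features found")
    return lesions


def write_lesions_geojson(lesions: list[LesionGeometry], path) -> None:
    feats = []
    for l in lesions:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(l.core),
                "properties": {
                    "section": int(l.section),
                    "ring_offsets_um": list(l.ring_offsets),
                },
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ----------------------------------------------------------------------
# volumes
# ----------------------------------------------------------------------
def write_volume_tiff(volume: RasterVolume, path) -> None:
    """Write a rendered volume as a multi-page TIFF (one page per z slice)."""
    tifffile.imwrite(
        path,
        volume.data,
        metadata={
            "voxel_size_um": volume.voxel_size,
            "origin_um": [float(v) for v in volume.origin],
        },
    )


def read_volume_tiff(path) -> RasterVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return RasterVolume(
        data=data,
        voxel_size=float(meta.get("voxel_size_um", 1.0)),
        origin=np.asarray(meta.get("origin_um", [0.0, 0.0, 0.0]), dtype=float),
    )


# ----------------------------------------------------------------------
# config
# ----------------------------------------------------------------------
def load_config_dict(path) -> dict:
    """Load a TOML or JSON configuration mapping."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    raise ValueError(f"unsupported config format: {path.suffix!r} (use .toml or .json)")
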