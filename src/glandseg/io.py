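"""Image and artifact I/O: tiles, density maps, label maps, result bundles."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Polygon, mapping
from skimage import measure

from .config import BCDConfig
from .errors import InvalidInputError
from .types import DensityMapPair, LabelMap, RGBImage, SegmentationResult, StainModel

__all__ = [
    "read_image",
    "write_image",
    "write_density_maps",
    "write_stain_model",
    "read_stain_model",
    "write_label_map",
    "read_label_map",
    "write_result",
]


def read_image(path: str | Path, bcd_config: BCDConfig | None = None) -> RGBImage:
    """Read an 8/16-bit RGB TIFF or PNG tile.

    The per-channel background intensity I0 is estimated as the
    configured high percentile of the tile (default 99th), a proxy for
    the unstained white level.
    """
    from .bcd import estimate_background

    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise InvalidInputError(f"unreadable image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # drop alpha
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected an RGB image, got shape {arr.shape}")
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    cfg = bcd_config or BCDConfig()
    i0 = estimate_background(arr.astype(float), cfg.i0_percentile)
    i0 = np.maximum(i0, 1.0)
    return RGBImage(pixels=arr.astype(float), background_intensity=i0, bit_depth=bit_depth)


def write_image(image: RGBImage, path: str | Path):
    """Write an RGB tile as 8- or 16-bit TIFF/PNG according to bit depth."""
    path = Path(path)
    dtype = np.uint16 if image.bit_depth > 8 else np.uint8
    arr = np.clip(np.round(image.pixels), 0, 2**image.bit_depth - 1).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        Image.fromarray(arr).save(path)


def write_density_maps(maps: DensityMapPair, out_dir: str | Path, prefix: str = "density") -> dict:
    """Write stromal/epithelial maps as 32-bit float single-channel TIFFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("stromal", maps.stromal), ("epithelial", maps.epithelial)):
        p = out_dir / f"{prefix}_{name}.tif"
        tifffile.imwrite(str(p), arr.astype(np.float32))
        paths[name] = str(p)
    return paths


def write_stain_model(model: StainModel, path: str | Path, config_echo: dict | None = None):
    doc = model.to_dict()
    if config_echo:
        doc["config"] = config_echo
    Path(path).write_text(json.dumps(doc, indent=2))


def read_stain_model(path: str | Path) -> StainModel:
    return StainModel.from_dict(json.loads(Path(path).read_text()))


def write_label_map(labels: LabelMap, path: str | Path):
    """Instance labels as 16-bit single-channel TIFF."""
    arr = labels.labels
    if arr.max() > np.iinfo(np.uint16).max:
        raise InvalidInputError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_label_map(path: str | Path) -> LabelMap:
    return LabelMap(labels=tifffile.imread(str(path)).astype(np.int32))


def _region_polygons(mask: np.ndarray) -> list[Polygon]:
    """Boundary polygons of a binary region, CCW exteriors, pixel coordinates."""
    padded = np.pad(mask.astype(float), 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        # contours are (row, col); shift for padding and swap to (x=col, y=row)
        xy = contour[:, ::-1] - 1.0
        if len(xy) < 4:
            continue
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        polys.append(poly if poly.exterior.is_ccw else Polygon(list(poly.exterior.coords)[::-1]))
    return polys


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_result(result: SegmentationResult, out_dir: str | Path) -> dict:
    """Write the full segmentation bundle and return its manifest.

    Artifacts: 16-bit label TIFF, per-object CSV (id, area, centroid,
    bounding box, accepted flag and rejection reason), GeoJSON boundary
    polygons of the accepted objects, and a JSON manifest listing every
    artifact with a SHA-256 checksum plus the config echo.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    label_path = out_dir / "labels.tif"
    write_label_map(result.labels, label_path)

    rows = []
    rejected_reasons = dict(result.rejected)
    for rid in result.labels.region_ids():
        sel = result.labels.labels == rid
        rr, cc = np.nonzero(sel)
        rows.append(
            {
                "id": int(rid),
                "area_px": int(sel.sum()),
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
                "bbox_min_row": int(rr.min()),
                "bbox_min_col": int(cc.min()),
                "bbox_max_row": int(rr.max()),
                "bbox_max_col": int(cc.max()),
                "accepted": True,
                "reject_reason": "",
            }
        )
    for rid, reason in result.rejected:
        rows.append(
            {
                "id": int(rid),
                "area_px": 0,
                "centroid_row": float("nan"),
                "centroid_col": float("nan"),
                "bbox_min_row": -1,
                "bbox_min_col": -1,
                "bbox_max_row": -1,
                "bbox_max_col": -1,
                "accepted": False,
                "reject_reason": reason,
            }
        )
    table_path = out_dir / "objects.csv"
    columns = [
        "id", "area_px", "centroid_row", "centroid_col",
        "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
        "accepted", "reject_reason",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(table_path, index=False)

    features = []
    for rid in result.labels.region_ids():
        for poly in _region_polygons(result.labels.labels == rid):
            features.append(
                {
                    "type": "Feature",
                    "properties": {"id": int(rid)},
                    "geometry": mapping(poly),
                }
            )
    geojson_path = out_dir / "objects.geojson"
    geojson_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )

    artifacts = {p.name: _sha256(p) for p in (label_path, table_path, geojson_path)}
    manifest = {
        "artifacts": artifacts,
        "n_accepted": int(result.n_accepted),
        "n_rejected": len(result.rejected),
        "rejected": [[int(r), reason] for r, reason in result.rejected],
        "config": result.config,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
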