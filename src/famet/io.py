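"""Scene and result I/O: multi-page TIFF + JSON sidecar, CSV tables.

A scene is stored as one TIFF whose pages are the three channels (red,
green, blue), or ``channels x z_planes`` pages for stacks, plus a JSON
sidecar ``<stem>.json`` carrying the pixel size (µm/px, required — every
downstream metric is unit-bearing), channel order, class label and, when
present, the ground truth (masks as run-length-encoded strings, adhesion
centroids/areas/maturity as lists). Coordinates in all outputs are 0-based
pixel indices converted to µm, origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import AUX_COLUMNS, FEATURE_COLUMNS, CellFeatureVector
from .synthetic import CellScene, GroundTruth

CHANNEL_ORDER = ("red", "green", "blue")
SCHEMA_VERSION = 1


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major, alternating runs
    starting with background)."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    # boundaries between runs
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    if flat[0]:  # prepend a zero-length background run
        starts = np.concatenate([[0], starts])
        lengths = np.concatenate([[0], lengths])
    return {"shape": list(mask.shape), "runs": lengths.tolist()}


def rle_decode(encoded: dict) -> np.ndarray:
    runs = np.asarray(encoded["runs"], dtype=np.int64)
    values = np.zeros(runs.size, dtype=bool)
    values[1::2] = True
    flat = np.repeat(values, runs)
    return flat.reshape(encoded["shape"])


def write_scene(scene: CellScene, path: str | Path) -> Path:
    """Write a scene as TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tif")
    pages = [np.asarray(scene.channels[c]) for c in CHANNEL_ORDER]
    stacked = np.stack(pages)  # (C, H, W) or (C, Z, H, W)
    tifffile.imwrite(path, stacked.astype(np.float32), photometric="minisblack")

    meta: dict = {
        "schema_version": SCHEMA_VERSION,
        "pixel_size_um": scene.pixel_size,
        "channel_order": list(CHANNEL_ORDER),
        "class_label": scene.class_label,
    }
    if scene.ground_truth is not None:
        gt = scene.ground_truth
        meta["ground_truth"] = {
            "cell_mask": rle_encode(gt.cell_mask),
            "nucleus_mask": rle_encode(gt.nucleus_mask),
            "fa_centroids_um": gt.fa_centroids.tolist(),
            "fa_areas_um2": gt.fa_areas.tolist(),
            "fa_maturity": list(gt.fa_maturity),
        }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_scene(path: str | Path, pixel_size: float | None = None) -> CellScene:
    """Read a TIFF scene; pixel size comes from the sidecar or the argument."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if meta and meta.get("schema_version", SCHEMA_VERSION) > SCHEMA_VERSION:
        raise ValueError(
            f"unsupported scene schema version {meta['schema_version']}"
        )
    px = meta.get("pixel_size_um", pixel_size)
    if px is None:
        raise ValueError(
            f"{path.name}: pixel size not in sidecar and not supplied — "
            "metrics are unit-bearing and cannot be computed without it"
        )
    order = meta.get("channel_order", list(CHANNEL_ORDER))
    if data.ndim not in (3, 4) or data.shape[0] != len(order):
        raise ValueError(
            f"{path.name}: expected {len(order)} channel pages, "
            f"got array of shape {data.shape}"
        )
    channels = {name: data[i] for i, name in enumerate(order)}
    truth = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        truth = GroundTruth(
            cell_mask=rle_decode(g["cell_mask"]),
            nucleus_mask=rle_decode(g["nucleus_mask"]),
            fa_centroids=np.asarray(g["fa_centroids_um"]).reshape(-1, 2),
            fa_areas=np.asarray(g["fa_areas_um2"]),
            fa_maturity=list(g["fa_maturity"]),
        )
    return CellScene(
        channels=channels,
        pixel_size=float(px),
        ground_truth=truth,
        class_label=meta.get("class_label"),
    )


FEATURE_CSV_COLUMNS = (
    ["cell_id", "class"] + FEATURE_COLUMNS + AUX_COLUMNS + ["qc_flags"]
)


def write_feature_table(features: list[CellFeatureVector], path: str | Path
                        ) -> pd.DataFrame:
    """Write per-cell features as CSV; returns the assembled DataFrame."""
    table = pd.DataFrame([f.as_dict() for f in features])
    table = table.reindex(columns=FEATURE_CSV_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return table


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(["class"] + FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return table


def write_fa_table(seg, path: str | Path) -> pd.DataFrame:
    """Per-adhesion CSV (id, pixel count, area, centroid, axes, maturity)."""
    rows = [
        {
            "id": fa.label,
            "pixel_count": fa.pixel_count,
            "area_um2": fa.area,
            "centroid_x_um": fa.centroid[0],
            "centroid_y_um": fa.centroid[1],
            "major_um": fa.major_axis,
            "minor_um": fa.minor_axis,
            "maturity": fa.maturity.value,
        }
        for fa in seg.fa_objects
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "id", "pixel_count", "area_um2", "centroid_x_um",
            "centroid_y_um", "major_um", "minor_um", "maturity",
        ],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return table


def dump_json(obj, path: str | Path) -> None:
    """JSON-dump a dataclass/dict, converting numpy scalars and arrays."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=default))
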