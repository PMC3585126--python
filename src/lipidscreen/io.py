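"""File I/O: CSV tables, threshold JSON, TIFF image sets.

All tables are UTF-8 comma-separated files with a header row; genomic
annotation uses 1-based coordinates (column ``pos_1based``) and loading
asserts that convention.  Floats round-trip through ``repr``, so
write-then-read reproduces tables bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from lipidscreen.imaging.types import CHANNELS, ImageSet
from lipidscreen.screen_stats import DeviationTable, ThresholdSet
from lipidscreen.synth.layout import LAYOUT_COLUMNS, PlateLayout

ANNOTATION_COLUMNS = ["gene", "locus", "lead_snp", "chrom", "pos_1based", "distance_bp"]


class DataFormatError(ValueError):
    """Malformed input table."""


def write_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    table = layout.positions.copy()
    table.insert(0, "format", layout.format)
    table.insert(0, "plate_id", layout.plate_id)
    table.to_csv(path, index=False)
    return path


def read_layout(path: str | Path) -> PlateLayout:
    table = pd.read_csv(path)
    missing = {"plate_id", "format", *LAYOUT_COLUMNS} - set(table.columns)
    if missing:
        raise DataFormatError(f"layout file missing columns {sorted(missing)}")
    dup = table["position_id"].duplicated()
    if dup.any():
        lines = (table.index[dup] + 2).tolist()  # header is line 1
        dups = sorted(table.loc[dup, "position_id"].unique())
        raise DataFormatError(f"duplicate position_ids {dups} (lines {lines})")
    plate_id = str(table["plate_id"].iloc[0])
    fmt = str(table["format"].iloc[0])
    positions = table[LAYOUT_COLUMNS].copy()
    positions["gene"] = positions["gene"].where(positions["gene"].notna(), None)
    return PlateLayout(plate_id=plate_id, format=fmt, positions=positions)


def write_cells(cells: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cells.to_csv(path, index=False)
    return path


def read_cells(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    required = {"position_id", "replicate", "image", "cell_id", "assay", "total"}
    missing = required - set(cells.columns)
    if missing:
        raise DataFormatError(f"cell table missing columns {sorted(missing)}")
    return cells


def write_deviations(table: DeviationTable, path: str | Path) -> Path:
    """Persist a deviation table (per-replicate rows; means are derived)."""
    path = Path(path)
    out = table.per_replicate.copy()
    out.insert(0, "assay", table.assay)
    out.to_csv(path, index=False)
    return path


def read_deviations(path: str | Path) -> DeviationTable:
    from lipidscreen.screen_stats import aggregate_deviations

    per_rep = pd.read_csv(path)
    required = {"position_id", "sirna_id", "role", "parameter", "replicate", "deviation"}
    missing = required - set(per_rep.columns)
    if missing:
        raise DataFormatError(f"deviation file missing columns {sorted(missing)}")
    assay = str(per_rep["assay"].iloc[0]) if "assay" in per_rep and len(per_rep) else ""
    per_rep = per_rep.drop(columns=["assay"], errors="ignore")
    return DeviationTable(per_replicate=per_rep, means=aggregate_deviations(per_rep), assay=assay)


def write_thresholds(thresholds: dict[str, ThresholdSet], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        key: {
            "assay": t.assay, "parameter": t.parameter,
            "lower": t.lower, "upper": t.upper, "control_n": t.control_n,
        }
        for key, t in thresholds.items()
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_thresholds(path: str | Path) -> dict[str, ThresholdSet]:
    payload = json.loads(Path(path).read_text())
    return {key: ThresholdSet(**vals) for key, vals in payload.items()}


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Load the gene/locus annotation table (1-based coordinates)."""
    table = pd.read_csv(path)
    if "pos_0based" in table.columns:
        raise DataFormatError(
            "annotation uses 0-based coordinates; this pipeline requires "
            "1-based positions in a 'pos_1based' column"
        )
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise DataFormatError(f"annotation missing columns {sorted(missing)}")
    if (table["pos_1based"] < 1).any():
        bad = (table.index[table["pos_1based"] < 1] + 2).tolist()
        raise DataFormatError(f"pos_1based must be >= 1 (lines {bad})")
    return table


def write_imageset(image_set: ImageSet, directory: str | Path) -> Path:
    """Write one image set as a multi-page TIFF (channel order documented
    in metadata); returns the file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = f"{image_set.position_id}_r{image_set.replicate}_i{image_set.image_index}.tif"
    path = directory / name
    stack = np.stack([image_set.channels[ch] for ch in CHANNELS])
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "channels": list(CHANNELS),
            "assay": image_set.assay,
            "position_id": image_set.position_id,
            "replicate": image_set.replicate,
            "image_index": image_set.image_index,
            "seed": image_set.meta.get("seed"),
        },
    )
    return path


def read_imageset(path: str | Path) -> ImageSet:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    channels = {ch: stack[i] for i, ch in enumerate(CHANNELS)}
    return ImageSet(
        position_id=str(meta.get("position_id", Path(path).stem)),
        replicate=int(meta.get("replicate", 1)),
        channels=channels,
        assay=str(meta.get("assay", "free_cholesterol")),
        image_index=int(meta.get("image_index", 0)),
        meta=dict(meta),
    )
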