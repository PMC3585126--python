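"""Per-cell feature extraction from segmented images.

For every cell the screen's phenotypic parameters are computed from its
structure masks:

* ``total`` — summed signal above local background within masks,
* ``concentration`` — ``total`` divided by the summed mask pixel count,
* ``structures`` — number of masks,
* ``area`` — summed mask area (free-cholesterol assay only),

plus ``cell_area`` and ``nucleus_area``.  A cell with no structures gets
defined zeros, not missing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lipidscreen.imaging.types import ImageSet, SegmentationResult
from lipidscreen.params import Assay

CELL_RECORD_COLUMNS = [
    "position_id", "replicate", "image", "cell_id", "assay",
    "total", "concentration", "structures", "area", "cell_area", "nucleus_area",
]


def extract_cell_features(
    segmentation: SegmentationResult,
    signal_channel: np.ndarray,
    assay: Assay | str,
    position_id: str = "",
    replicate: int = 1,
    image_index: int = 0,
) -> pd.DataFrame:
    """Compute one cell record per segmented cell.

    Per-structure signal is ``sum(intensity - local_background)`` floored
    at zero; ``concentration * mask_pixels == total`` holds by definition.
    """
    assay = Assay(assay)
    img = np.asarray(signal_channel, dtype=float)
    n_cells = segmentation.n_cells

    totals = np.zeros(n_cells + 1)
    areas = np.zeros(n_cells + 1, dtype=int)
    counts = np.zeros(n_cells + 1, dtype=int)
    for s in segmentation.structures:
        yy, xx = s["coords"]
        raw = float(img[yy, xx].sum() - s["local_background"] * len(yy))
        totals[s["cell"]] += max(raw, 0.0)
        areas[s["cell"]] += len(yy)
        counts[s["cell"]] += 1

    cell_area = np.bincount(segmentation.cell_labels.ravel(), minlength=n_cells + 1)
    nuc_area = np.bincount(segmentation.nuclei_labels.ravel(), minlength=n_cells + 1)

    idx = np.arange(1, n_cells + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(areas[idx] > 0, totals[idx] / np.maximum(areas[idx], 1), 0.0)
    return pd.DataFrame(
        {
            "position_id": position_id,
            "replicate": replicate,
            "image": image_index,
            "cell_id": idx,
            "assay": assay.value,
            "total": totals[idx],
            "concentration": conc,
            "structures": counts[idx],
            "area": areas[idx].astype(float) if assay is Assay.FREE_CHOLESTEROL else np.nan,
            "cell_area": cell_area[idx].astype(float),
            "nucleus_area": nuc_area[idx].astype(float),
        },
        columns=CELL_RECORD_COLUMNS,
    )


def quantify_image(
    image_set: ImageSet,
    segment_params=None,
    region_mode: str = "dilate",
    region_radius: float = 18.0,
    structure_params=None,
) -> tuple[SegmentationResult, pd.DataFrame]:
    """Full quantification of one :class:`ImageSet`: segment, detect, extract."""
    from lipidscreen.imaging.segment import approximate_cell_regions, segment_nuclei
    from lipidscreen.imaging.structures import StructureParams, detect_structures

    assay = Assay(image_set.assay)
    nuclei = segment_nuclei(image_set.channels["nuclear"], segment_params)
    aux = image_set.channels["cell_region"] if region_mode == "propagate" else None
    cells = approximate_cell_regions(nuclei, mode=region_mode, aux_channel=aux,
                                     radius=region_radius)
    if structure_params is None:
        structure_params = (
            StructureParams(region="perinuclear_ring")
            if assay is Assay.FREE_CHOLESTEROL
            else StructureParams(region="whole_cell")
        )
    structures = detect_structures(
        image_set.channels["signal"], cells, structure_params, nuclei_labels=nuclei
    )
    seg = SegmentationResult(nuclei_labels=nuclei, cell_labels=cells, structures=structures)
    records = extract_cell_features(
        seg,
        image_set.channels["signal"],
        assay,
        position_id=image_set.position_id,
        replicate=image_set.replicate,
        image_index=image_set.image_index,
    )
    return seg, records
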