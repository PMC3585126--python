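"""Containers shared between image simulation and quantification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lipidscreen.params import Assay

CHANNELS = ("nuclear", "cell_region", "signal")


@dataclass
class ImageSet:
    """One acquired field of view: three aligned channels plus metadata."""

    position_id: str
    replicate: int
    channels: dict[str, np.ndarray]
    assay: str = Assay.FREE_CHOLESTEROL.value
    qc_flag: str = "unreviewed"  # pass | fail | unreviewed
    qc_reason: str | None = None
    image_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.channels)
        if missing:
            raise ValueError(f"missing channels {sorted(missing)}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channel arrays must share one shape")
        for name, arr in self.channels.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative intensities in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SegmentationResult:
    """Labelled nuclei/cells plus detected structures for one image.

    ``structures`` is a list of per-structure records: cell label, boolean
    pixel mask (as index arrays), area, eccentricity and the local
    background estimate in intensity units.
    """

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    structures: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_nuc = int(self.nuclei_labels.max())
        n_cell = int(self.cell_labels.max())
        if n_nuc != n_cell:
            raise ValueError(f"cell count {n_cell} != nucleus count {n_nuc}")

    @property
    def n_cells(self) -> int:
        return int(self.nuclei_labels.max())
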