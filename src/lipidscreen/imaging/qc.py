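"""Automated image quality control.

Stands in for visual curation of screen images: each field of view is
flagged pass/fail on focus (variance of the Laplacian of the normalized
nuclear channel), nucleus count bounds and the fraction of saturated
pixels.  Failed images are excluded from replicate summaries downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from lipidscreen.imaging.segment import SegmentParams, segment_nuclei
from lipidscreen.imaging.types import ImageSet


@dataclass(frozen=True)
class QCCriteria:
    """Pass/fail rules for one image.

    ``min_focus`` applies to the variance of the Laplacian of the nuclear
    channel rescaled to [0, 1]; sharp disc-like nuclei score orders of
    magnitude above a defocused (heavily smoothed) field.
    """

    min_focus: float = 1e-4
    min_nuclei: int = 1
    max_nuclei: int = 200
    max_saturation_fraction: float = 0.05
    saturation_level: float = 65535.0
    segment_params: SegmentParams | None = None


def focus_metric(channel: np.ndarray) -> float:
    """Variance of the Laplacian of the intensity-normalized image."""
    img = np.asarray(channel, dtype=float)
    rng = np.ptp(img)
    if rng == 0:
        return 0.0
    norm = (img - img.min()) / rng
    return float(ndi.laplace(norm).var())


def qc_image(image_set: ImageSet, criteria: QCCriteria | None = None) -> ImageSet:
    """Flag a single image; returns the same object with qc fields set."""
    criteria = criteria or QCCriteria()
    if focus_metric(image_set.channels["nuclear"]) < criteria.min_focus:
        image_set.qc_flag, image_set.qc_reason = "fail", "focus"
        return image_set
    sat = np.mean(
        np.asarray(image_set.channels["signal"], dtype=float) >= criteria.saturation_level
    )
    if sat > criteria.max_saturation_fraction:
        image_set.qc_flag, image_set.qc_reason = "fail", "saturation"
        return image_set
    n_nuclei = int(segment_nuclei(image_set.channels["nuclear"], criteria.segment_params).max())
    if not (criteria.min_nuclei <= n_nuclei <= criteria.max_nuclei):
        image_set.qc_flag, image_set.qc_reason = "fail", "cell_density"
        return image_set
    image_set.qc_flag, image_set.qc_reason = "pass", None
    return image_set


def qc_images(images: list[ImageSet], criteria: QCCriteria | None = None) -> list[ImageSet]:
    """Flag a collection of images (error on an empty collection)."""
    if not images:
        raise ValueError("empty image collection")
    return [qc_image(im, criteria) for im in images]
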