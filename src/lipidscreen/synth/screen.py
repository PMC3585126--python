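"""Whole-screen simulation: layout x effects x replicates.

Two paths share one latent model:

* ``tables_only=True`` (default) draws per-cell phenotypic parameters
  directly — fast enough for hundreds of simulated 384-position screens;
* ``tables_only=False`` additionally renders every field of view into
  three-channel images for the imaging pipeline.

Replicate structure mirrors the screening design: independent biological
replicates, several images per position, and multiplicative intensity
noise at the replicate, position and image level.  The plate-edge
artifact multiplies intensities by the region factor of each well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lipidscreen.imaging.types import ImageSet
from lipidscreen.params import Assay
from lipidscreen.synth.layout import PlateLayout
from lipidscreen.synth.population import (
    EffectSpec,
    GroundTruth,
    SceneSpec,
    draw_cell_table,
    simulate_cell_population,
)
from lipidscreen.synth.render import render_images

CELL_COLUMNS = [
    "position_id", "sirna_id", "replicate", "image", "cell_id", "assay",
    "total", "concentration", "structures", "area", "cell_area", "nucleus_area",
]


@dataclass
class ScreenResult:
    """Output of :func:`simulate_screen`."""

    layout: PlateLayout
    scene: SceneSpec
    assay: str
    n_replicates: int
    effects: dict[str, EffectSpec]
    cells: pd.DataFrame | None = None
    images: list[tuple[ImageSet, GroundTruth]] | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def effect_of(self, sirna_id: str) -> EffectSpec:
        return self.effects.get(sirna_id, EffectSpec.null(sirna_id))


def simulate_screen(
    layout: PlateLayout,
    effects: dict[str, EffectSpec] | None,
    n_replicates: int,
    scene: SceneSpec,
    seed: int = 0,
    images_per_position: int = 4,
    tables_only: bool = True,
    replicate_cv: float = 0.05,
    position_cv: float = 0.04,
    image_cv: float = 0.03,
) -> ScreenResult:
    """Simulate a full screen for one assay.

    ``effects`` maps siRNA ids to :class:`EffectSpec`; any siRNA without an
    entry (all controls in particular) is null.  The same seed always
    reproduces the identical result.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    effects = dict(effects or {})
    assay = Assay(scene.assay)
    positions = layout.positions.reset_index(drop=True)
    n_pos = len(positions)

    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_replicates)

    if not tables_only:
        images: list[tuple[ImageSet, GroundTruth]] = []
        for rep in range(1, n_replicates + 1):
            rep_ss = rep_seeds[rep - 1]
            child = rep_ss.spawn(n_pos * images_per_position + 1)
            rep_factor = float(
                np.exp(np.random.default_rng(child[-1]).normal(0, replicate_cv))
            )
            for p, row in enumerate(positions.itertuples()):
                eff = effects.get(row.sirna_id, EffectSpec.null(row.sirna_id or "empty"))
                for k in range(images_per_position):
                    s = child[p * images_per_position + k]
                    img_rng = np.random.default_rng(s)
                    img_seed = int(img_rng.integers(2**31))
                    amp_factor = rep_factor * float(
                        np.exp(img_rng.normal(0, np.hypot(position_cv, image_cv)))
                    )
                    local = scene.with_(
                        spot_amplitude_mean=scene.spot_amplitude_mean * amp_factor,
                        seed=img_seed,
                    )
                    _, truth = simulate_cell_population(eff, local, geometry=True)
                    img = render_images(
                        truth, local, region=int(row.region),
                        position_id=row.position_id, replicate=rep, image_index=k,
                    )
                    images.append((img, truth))
        return ScreenResult(
            layout=layout, scene=scene, assay=assay.value,
            n_replicates=n_replicates, effects=effects, images=images, seed=seed,
        )

    # ---- fast tables path: vectorized over positions x images x cells ----
    n_cells = scene.n_cells
    edge = np.array([scene.edge_factor(int(r)) for r in positions["region"]])
    # per-position effect shifts on this assay
    amp_shift = np.ones(n_pos)
    cnt_shift = np.ones(n_pos)
    area_shift = np.ones(n_pos)
    pen = np.ones(n_pos)
    for p, sirna in enumerate(positions["sirna_id"]):
        eff = effects.get(sirna)
        if eff is None:
            continue
        amp_shift[p] = eff.shift(assay, "total") * eff.shift(assay, "concentration")
        cnt_shift[p] = eff.shift(assay, "structures")
        if assay is Assay.FREE_CHOLESTEROL:
            area_shift[p] = eff.shift(assay, "area")
        pen[p] = eff.knockdown_penetrance

    frames = []
    n_img = images_per_position
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(rep_seeds[rep - 1])
        rep_factor = np.exp(rng.normal(0, replicate_cv))
        pos_factor = np.exp(rng.normal(0, position_cv, size=n_pos))
        img_factor = np.exp(rng.normal(0, image_cv, size=(n_pos, n_img)))

        # cells per field of view vary as in real acquisitions
        counts = np.maximum(rng.poisson(n_cells, size=n_pos * n_img), 1)
        img_of = np.repeat(np.arange(n_pos * n_img), counts)
        block = int(counts.sum())
        cell_pos = img_of // n_img
        cell_img = img_of % n_img
        cell_idx = np.concatenate([np.arange(c) for c in counts])
        penetrant = rng.random(block) < pen[cell_pos]

        amp_mult = (
            np.where(penetrant, amp_shift[cell_pos], 1.0)
            * edge[cell_pos]
            * rep_factor
            * pos_factor[cell_pos]
            * img_factor[cell_pos, cell_img]
        )
        cnt_mult = np.where(penetrant, cnt_shift[cell_pos], 1.0)
        area_mult = np.where(penetrant, area_shift[cell_pos], 1.0)

        table = draw_cell_table(scene, assay, block, rng, amp_mult, cnt_mult, area_mult)
        table.insert(0, "assay", assay.value)
        table.insert(0, "cell_id", cell_idx)
        table.insert(0, "image", cell_img)
        table.insert(0, "replicate", rep)
        table.insert(0, "sirna_id", positions["sirna_id"].to_numpy()[cell_pos])
        table.insert(0, "position_id", positions["position_id"].to_numpy()[cell_pos])
        frames.append(table)

    cells = pd.concat(frames, ignore_index=True)[CELL_COLUMNS]
    return ScreenResult(
        layout=layout, scene=scene, assay=assay.value,
        n_replicates=n_replicates, effects=effects, cells=cells, seed=seed,
    )
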