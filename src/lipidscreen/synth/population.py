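"""Per-cell populations with planted multiplicative effects.

The generative model is deliberately simple: each cell is a disc with a
nuclear disc inside it, and its signal (endocytosed DiI-LDL or perinuclear
filipin) is carried by a set of small circular "structures" (spots).
A knockdown acts multiplicatively on the latent draws:

* ``*_structures`` shift scales the Poisson mean of the spot count,
* ``*_concentration`` and ``*_total`` shifts scale spot amplitudes,
* ``fc_area`` shift scales spot areas.

Expected per-cell readouts therefore scale exactly with the planted
shifts (linearity of the model), which is what the parameter-recovery
tests exploit.  Shifts apply to the penetrant fraction of cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from lipidscreen.params import ALL_PARAMETERS, Assay

_SHIFT_KEYS = ALL_PARAMETERS


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth multiplicative effect of one siRNA.

    ``shifts`` maps the seven phenotypic parameters to signed multiplicative
    factors (1.0 = no effect); ``knockdown_penetrance`` is the fraction of
    cells in which the knockdown manifests.
    """

    sirna_id: str
    shifts: dict[str, float] = field(default_factory=dict)
    knockdown_penetrance: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.shifts) - set(_SHIFT_KEYS)
        if unknown:
            raise ValueError(f"unknown shift keys {sorted(unknown)}")
        if any(v <= 0 for v in self.shifts.values()):
            raise ValueError("shifts must be > 0")
        if not 0.0 <= self.knockdown_penetrance <= 1.0:
            raise ValueError("knockdown_penetrance must be in [0, 1]")

    @classmethod
    def null(cls, sirna_id: str) -> "EffectSpec":
        return cls(sirna_id=sirna_id)

    @property
    def is_null(self) -> bool:
        return all(v == 1.0 for v in self.shifts.values())

    def shift(self, assay: Assay | str, parameter: str) -> float:
        """Shift for *parameter* measured in *assay* (1.0 if unset)."""
        key = f"{Assay(assay).short}_{parameter}"
        return self.shifts.get(key, 1.0)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, intensity and noise model of one synthetic field of view.

    Cells are placed on a jittered grid with pitch ``grid_pitch`` so that
    neighbouring perinuclear rings never overlap; a scene holds at most
    ``(shape // grid_pitch)**2`` cells.  All noise is off when
    ``noise_sd_frac == 0`` and ``poisson_noise`` is False.
    """

    shape: tuple[int, int] = (320, 320)
    n_cells: int = 18
    cell_radius: tuple[float, float] = (16.0, 22.0)
    nucleus_radius: tuple[float, float] = (6.0, 9.0)
    spots_per_cell_mean: float = 6.0
    spot_radius: tuple[float, float] = (1.5, 2.5)
    spot_amplitude_mean: float = 900.0
    spot_amplitude_cv: float = 0.35
    ring_width: float = 14.0  # FC spots live within this annulus beyond the nucleus
    background: float = 200.0
    gradient_amplitude: float = 20.0
    dynamic_range: float = 4096.0
    noise_sd_frac: float = 0.02  # Gaussian read noise as fraction of dynamic range
    poisson_noise: bool = False
    edge_factors: tuple[float, float, float] = (0.85, 0.95, 1.0)
    grid_pitch: int = 64
    assay: str = Assay.FREE_CHOLESTEROL.value
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius[0] < 1 or self.spot_radius[0] < 1:
            raise ValueError("all radii must be >= 1 px")
        if self.cell_radius[0] <= self.nucleus_radius[1]:
            raise ValueError("cell radius must exceed nucleus radius")
        if self.n_cells > self.max_cells:
            raise ValueError(
                f"n_cells={self.n_cells} exceeds capacity {self.max_cells} "
                f"of a {self.shape} scene at pitch {self.grid_pitch}"
            )

    @property
    def max_cells(self) -> int:
        return (self.shape[0] // self.grid_pitch) * (self.shape[1] // self.grid_pitch)

    @property
    def noise_sd(self) -> float:
        return self.noise_sd_frac * self.dynamic_range

    def edge_factor(self, region: int) -> float:
        return self.edge_factors[region - 1]

    def with_(self, **kwargs) -> "SceneSpec":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """True per-cell (and per-spot) quantities behind a synthetic scene."""

    effect: EffectSpec
    cells: pd.DataFrame  # cy, cx, nucleus_r, cell_r, n_spots, integrated_signal, mask_area
    spots: pd.DataFrame | None = None  # cell_id, y, x, r, amplitude, n_px


def _amplitudes(rng: np.random.Generator, n: int, mean: np.ndarray | float, cv: float):
    """Lognormal amplitudes with the requested mean and coefficient of variation."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))


def draw_cell_table(
    scene: SceneSpec,
    assay: Assay | str,
    n_cells: int,
    rng: np.random.Generator,
    amp_mult: np.ndarray | float = 1.0,
    count_mult: np.ndarray | float = 1.0,
    area_mult: np.ndarray | float = 1.0,
) -> pd.DataFrame:
    """Vectorized draw of per-cell phenotypic parameters (no geometry).

    Multipliers may be scalars or per-cell arrays.  Returns a table with
    columns total, concentration, structures, area, cell_area, nucleus_area;
    ``area`` is NaN for the LDL assay.
    """
    assay = Assay(assay)
    nuc_r = rng.uniform(*scene.nucleus_radius, size=n_cells)
    cell_r = rng.uniform(*scene.cell_radius, size=n_cells)
    lam = scene.spots_per_cell_mean * np.broadcast_to(count_mult, (n_cells,))
    n_spots = rng.poisson(lam)
    total_spots = int(n_spots.sum())
    cell_of_spot = np.repeat(np.arange(n_cells), n_spots)

    r = rng.uniform(*scene.spot_radius, size=total_spots)
    r = r * np.sqrt(np.broadcast_to(area_mult, (n_cells,))[cell_of_spot])
    spot_area = np.pi * r**2
    amp = _amplitudes(
        rng,
        total_spots,
        scene.spot_amplitude_mean * np.broadcast_to(amp_mult, (n_cells,))[cell_of_spot],
        scene.spot_amplitude_cv,
    )

    total = np.bincount(cell_of_spot, weights=amp * spot_area, minlength=n_cells)
    area = np.bincount(cell_of_spot, weights=spot_area, minlength=n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(area > 0, total / np.where(area > 0, area, 1.0), 0.0)

    return pd.DataFrame(
        {
            "total": total,
            "concentration": conc,
            "structures": n_spots.astype(int),
            "area": area if assay is Assay.FREE_CHOLESTEROL else np.nan,
            "cell_area": np.pi * cell_r**2,
            "nucleus_area": np.pi * nuc_r**2,
        }
    )


def effect_multipliers(
    effect: EffectSpec, assay: Assay | str, n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell (amplitude, count, area) multipliers given penetrance."""
    assay = Assay(assay)
    penetrant = rng.random(n_cells) < effect.knockdown_penetrance
    amp = np.where(
        penetrant, effect.shift(assay, "total") * effect.shift(assay, "concentration"), 1.0
    )
    count = np.where(penetrant, effect.shift(assay, "structures"), 1.0)
    area = (
        np.where(penetrant, effect.shift(assay, "area"), 1.0)
        if assay is Assay.FREE_CHOLESTEROL
        else np.ones(n_cells)
    )
    return amp, count, area


def _disc_pixel_count(cy: float, cx: float, r: float) -> int:
    """Exact pixel count of the discretized disc around (cy, cx)."""
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return int(((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2).sum())


def simulate_cell_population(
    effect: EffectSpec,
    scene: SceneSpec,
    seed: int | None = None,
    geometry: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one field of cells under *effect*.

    With ``geometry=True`` the population carries explicit cell centres and
    spot positions (renderable by :func:`lipidscreen.synth.render_images`);
    spot areas are then exact discretized pixel counts.  With
    ``geometry=False`` only the statistical cell table is produced (fast
    path used by screen-level simulation).
    """
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    assay = Assay(scene.assay)
    n = scene.n_cells

    if not geometry:
        amp_m, cnt_m, area_m = effect_multipliers(effect, assay, n, rng)
        table = draw_cell_table(scene, assay, n, rng, amp_m, cnt_m, area_m)
        cells = table.assign(
            cell_id=np.arange(n),
            n_spots=table["structures"],
            integrated_signal=table["total"],
        )
        truth = GroundTruth(effect=effect, cells=cells)
        return table.assign(cell_id=np.arange(n)), truth

    # --- placement: jittered grid keeps perinuclear rings disjoint ---------
    h, w = scene.shape
    ny, nx = h // scene.grid_pitch, w // scene.grid_pitch
    slots = [(iy, ix) for iy in range(ny) for ix in range(nx)]
    chosen = rng.permutation(len(slots))[:n]
    centers = []
    for k in chosen:
        iy, ix = slots[k]
        cy = (iy + 0.5) * scene.grid_pitch + rng.uniform(-6, 6)
        cx = (ix + 0.5) * scene.grid_pitch + rng.uniform(-6, 6)
        centers.append((cy, cx))

    nuc_r = rng.uniform(*scene.nucleus_radius, size=n)
    cell_r = rng.uniform(*scene.cell_radius, size=n)
    amp_m, cnt_m, area_m = effect_multipliers(effect, assay, n, rng)
    n_spots = rng.poisson(scene.spots_per_cell_mean * cnt_m)

    cell_rows, spot_rows = [], []
    for i, (cy, cx) in enumerate(centers):
        placed: list[tuple[float, float, float]] = []
        for _ in range(int(n_spots[i])):
            r_s = rng.uniform(*scene.spot_radius) * np.sqrt(area_m[i])
            if assay is Assay.FREE_CHOLESTEROL:
                d_lo, d_hi = nuc_r[i] + r_s + 1.0, nuc_r[i] + scene.ring_width
            else:
                d_lo, d_hi = nuc_r[i] + r_s + 1.0, cell_r[i] - r_s - 1.0
            d_hi = max(d_hi, d_lo + 0.1)
            ok = False
            for _try in range(200):
                d = np.sqrt(rng.uniform(d_lo**2, d_hi**2))
                theta = rng.uniform(0, 2 * np.pi)
                sy, sx = cy + d * np.sin(theta), cx + d * np.cos(theta)
                if all(
                    np.hypot(sy - py, sx - px) >= r_s + pr + 3.0 for py, px, pr in placed
                ):
                    ok = True
                    break
            if not ok:
                continue  # no room left in this cell; the spot is dropped
            placed.append((sy, sx, r_s))
            amp = float(
                _amplitudes(rng, 1, scene.spot_amplitude_mean * amp_m[i], scene.spot_amplitude_cv)[0]
            )
            n_px = _disc_pixel_count(sy, sx, r_s)
            spot_rows.append(
                {"cell_id": i, "y": sy, "x": sx, "r": r_s, "amplitude": amp, "n_px": n_px}
            )

        mine = [s for s in spot_rows if s["cell_id"] == i]
        mask_area = sum(s["n_px"] for s in mine)
        integrated = sum(s["amplitude"] * s["n_px"] for s in mine)
        cell_rows.append(
            {
                "cell_id": i,
                "cy": cy,
                "cx": cx,
                "nucleus_r": nuc_r[i],
                "cell_r": cell_r[i],
                "n_spots": len(mine),
                "integrated_signal": integrated,
                "mask_area": mask_area,
            }
        )

    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "cy", "cx", "nucleus_r", "cell_r", "n_spots",
                 "integrated_signal", "mask_area"],
    )
    spots = pd.DataFrame(
        spot_rows, columns=["cell_id", "y", "x", "r", "amplitude", "n_px"]
    )
    truth = GroundTruth(effect=effect, cells=cells, spots=spots)

    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(
            cells["mask_area"] > 0,
            cells["integrated_signal"] / cells["mask_area"].replace(0, 1),
            0.0,
        )
    table = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "total": cells["integrated_signal"],
            "concentration": conc,
            "structures": cells["n_spots"],
            "area": cells["mask_area"] if assay is Assay.FREE_CHOLESTEROL else np.nan,
            "cell_area": np.pi * cells["cell_r"] ** 2,
            "nucleus_area": np.pi * cells["nucleus_r"] ** 2,
        }
    )
    return table, truth
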