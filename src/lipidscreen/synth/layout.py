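"""Plate layouts: grids, control placement and edge regions.

A screening plate (384-well plate, 96-well plate, or a spotted 384-position
cell array) carries candidate siRNAs plus a fixed complement of controls:
16 non-silencing negative-control positions, mock transfections (reagent
without siRNA), positive controls for LDL uptake (LDLR siRNA) and free
cholesterol (NPC1 siRNA), and transfection-efficiency controls (INCENP).

Wells are assigned to three concentric regions used for plate-effect
normalization: the outermost ring of wells is region 1, their inward
neighbours region 2 and the plate interior region 3.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lipidscreen.params import Role

#: rows x cols per supported format
FORMATS = {
    "plate_384": (16, 24),
    "array_384": (16, 24),
    "plate_96": (8, 12),
}

#: default control siRNA identities (non-silencing, LDLR, NPC1, INCENP)
CONTROL_SIRNAS = {
    Role.NEGATIVE_CONTROL: ("s229174", None),
    Role.MOCK: ("mock", None),
    Role.POSITIVE_LDL: ("s224006", "LDLR"),
    Role.POSITIVE_FC: ("s237198", "NPC1"),
    Role.TRANSFECTION_CONTROL: ("sINCENP", "INCENP"),
}

LAYOUT_COLUMNS = ["row", "col", "position_id", "sirna_id", "gene", "role", "region"]


class LayoutCapacityError(ValueError):
    """More siRNAs than the plate format can hold."""


@dataclass(frozen=True)
class ControlSpec:
    """Number of control positions per role.

    Defaults follow the screening plate design: 16 non-silencing controls,
    8 mock, 8 LDLR, 8 NPC1 and 4 INCENP positions.
    """

    negative_control: int = 16
    mock: int = 8
    positive_ldl: int = 8
    positive_fc: int = 8
    transfection_control: int = 4

    def counts(self) -> dict[Role, int]:
        return {
            Role.NEGATIVE_CONTROL: self.negative_control,
            Role.MOCK: self.mock,
            Role.POSITIVE_LDL: self.positive_ldl,
            Role.POSITIVE_FC: self.positive_fc,
            Role.TRANSFECTION_CONTROL: self.transfection_control,
        }

    @property
    def total(self) -> int:
        return sum(self.counts().values())


def region_of(row: int, col: int, n_rows: int, n_cols: int) -> int:
    """Region of well (row, col): 1 = plate edge, 2 = its neighbours, 3 = rest.

    Pure function of the coordinates; 0-based row/col.
    """
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise ValueError(f"well ({row}, {col}) outside a {n_rows}x{n_cols} grid")
    ring = min(row, col, n_rows - 1 - row, n_cols - 1 - col)
    return 1 if ring == 0 else 2 if ring == 1 else 3


def position_name(row: int, col: int) -> str:
    """Well name such as 'A01' (rows lettered, columns 1-based)."""
    letters = string.ascii_uppercase
    prefix = letters[row] if row < 26 else letters[row // 26 - 1] + letters[row % 26]
    return f"{prefix}{col + 1:02d}"


@dataclass
class PlateLayout:
    """Mapping of plate positions to siRNAs, control roles and regions."""

    plate_id: str
    format: str
    positions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ValueError(f"unknown format {self.format!r}")
        missing = set(LAYOUT_COLUMNS) - set(self.positions.columns)
        if missing:
            raise ValueError(f"layout table missing columns {sorted(missing)}")
        dup = self.positions["position_id"].duplicated()
        if dup.any():
            dups = sorted(self.positions.loc[dup, "position_id"].unique())
            raise ValueError(f"duplicate position_ids: {dups}")

    @property
    def shape(self) -> tuple[int, int]:
        return FORMATS[self.format]

    def by_role(self, *roles: Role | str) -> pd.DataFrame:
        wanted = {Role(r).value for r in roles}
        return self.positions[self.positions["role"].isin(wanted)]

    @property
    def sirna_gene_map(self) -> dict[str, str | None]:
        sub = self.positions.dropna(subset=["sirna_id"])
        return dict(zip(sub["sirna_id"], sub["gene"]))


def make_plate_layout(
    format: str,
    candidate_sirnas: list[tuple[str, str | None]] | list[str],
    control_spec: ControlSpec | None = None,
    seed: int = 0,
    plate_id: str = "plate01",
) -> PlateLayout:
    """Build a layout with seeded pseudo-random control placement.

    Parameters
    ----------
    candidate_sirnas:
        ``(sirna_id, gene)`` pairs (or bare siRNA ids) for candidate wells.
    control_spec:
        counts of control positions per role; defaults to the standard
        16 negative / 8 mock / 8+8 positive / 4 transfection complement.
    seed:
        determines control positions; identical seeds give identical layouts.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(FORMATS)}")
    control_spec = control_spec or ControlSpec()
    candidates = [
        (c, None) if isinstance(c, str) else (str(c[0]), c[1]) for c in candidate_sirnas
    ]
    n_rows, n_cols = FORMATS[format]
    capacity = n_rows * n_cols
    needed = len(candidates) + control_spec.total
    if needed > capacity:
        raise LayoutCapacityError(
            f"{len(candidates)} candidates + {control_spec.total} controls "
            f"exceed {capacity} positions of {format}"
        )

    rng = np.random.default_rng(seed)
    all_wells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    order = rng.permutation(len(all_wells))

    rows: list[dict] = []
    cursor = 0
    for role, count in control_spec.counts().items():
        sirna_id, gene = CONTROL_SIRNAS[role]
        for _ in range(count):
            r, c = all_wells[order[cursor]]
            cursor += 1
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "position_id": position_name(r, c),
                    "sirna_id": sirna_id,
                    "gene": gene,
                    "role": role.value,
                    "region": region_of(r, c, n_rows, n_cols),
                }
            )
    # candidates fill the remaining wells in plate order (row-major)
    used = {(row["row"], row["col"]) for row in rows}
    free = [w for w in all_wells if w not in used]
    for (sirna_id, gene), (r, c) in zip(candidates, free):
        rows.append(
            {
                "row": r,
                "col": c,
                "position_id": position_name(r, c),
                "sirna_id": sirna_id,
                "gene": gene,
                "role": Role.CANDIDATE.value,
                "region": region_of(r, c, n_rows, n_cols),
            }
        )

    table = (
        pd.DataFrame(rows, columns=LAYOUT_COLUMNS)
        .sort_values(["row", "col"])
        .reset_index(drop=True)
    )
    return PlateLayout(plate_id=plate_id, format=format, positions=table)
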