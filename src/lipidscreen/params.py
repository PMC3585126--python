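"""Shared vocabulary: assays, phenotypic parameters, plate roles.

The screen measures two assays per gene. From every segmented cell the
LDL-uptake assay yields three parameters and the free-cholesterol (FC)
assay four, giving the seven-parameter phenotypic space used throughout:

==============  =========================================================
parameter       meaning
==============  =========================================================
total           summed signal above local background within structure
                masks per cell (intensity * px)
concentration   mean signal above local background per mask pixel
structures      number of structure masks per cell
area            total mask area per cell (px^2; FC assay only)
==============  =========================================================
"""

from __future__ import annotations

import enum


class Assay(str, enum.Enum):
    """Screening readout."""

    LDL_UPTAKE = "ldl_uptake"
    FREE_CHOLESTEROL = "free_cholesterol"

    @property
    def short(self) -> str:
        return "ldl" if self is Assay.LDL_UPTAKE else "fc"


class Role(str, enum.Enum):
    """Function of a plate position."""

    CANDIDATE = "candidate"
    NEGATIVE_CONTROL = "negative_control"
    MOCK = "mock"
    POSITIVE_LDL = "positive_ldl"
    POSITIVE_FC = "positive_fc"
    TRANSFECTION_CONTROL = "transfection_control"


#: roles whose positions carry no gene-level perturbation of interest
CONTROL_ROLES = frozenset(
    {
        Role.NEGATIVE_CONTROL,
        Role.MOCK,
        Role.POSITIVE_LDL,
        Role.POSITIVE_FC,
        Role.TRANSFECTION_CONTROL,
    }
)

#: roles entering threshold derivation (non-silencing + mock)
NULL_CONTROL_ROLES = frozenset({Role.NEGATIVE_CONTROL, Role.MOCK})

#: per-assay cell-level signal parameters
LDL_PARAMETERS = ("total", "concentration", "structures")
FC_PARAMETERS = ("total", "concentration", "area", "structures")

#: the canonical seven-parameter fingerprint columns, LDL block then FC block
ALL_PARAMETERS = (
    "ldl_total",
    "ldl_concentration",
    "ldl_structures",
    "fc_total",
    "fc_concentration",
    "fc_area",
    "fc_structures",
)

#: extra per-assay parameters used only for correlation QC
EXTRA_PARAMETERS = ("n_cells", "cell_area")


def assay_parameters(assay: Assay | str) -> tuple[str, ...]:
    """Signal parameters quantified for *assay*."""
    assay = Assay(assay)
    return LDL_PARAMETERS if assay is Assay.LDL_UPTAKE else FC_PARAMETERS


def fingerprint_column(assay: Assay | str, parameter: str) -> str:
    """Map (assay, parameter) to its seven-parameter fingerprint column."""
    col = f"{Assay(assay).short}_{parameter}"
    if col not in ALL_PARAMETERS:
        raise ValueError(f"{parameter!r} is not a {Assay(assay).value} parameter")
    return col
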