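"""The factorial space of hypothetical drugs and obesity scenarios.

The study has no external data by construction: its input is a full
factorial grid over three drug parameters — unbound plasma fraction in the
normal-weight subject (fu), blood-cell partition coefficient (Kp), and
intrinsic active-secretion clearance (CL_int_ATS) — crossed with the
relative transporter activity (rTA) of the obese subject.  With the default
axes this yields 6 × 10 × 32 × 6 = 11,520 combinations, evaluated once per
binding protein (HSA, AAG) and BMI category.

Enumeration order is fixed (first axis slowest, last axis fastest) so that
output tables are reproducible byte for byte.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BindingProtein",
    "DrugSpec",
    "Scenario",
    "default_grid_values",
    "clint_ats_values",
    "enumerate_combinations",
    "grid_table",
    "DRUG_AXES",
]


class BindingProtein(str, enum.Enum):
    HSA = "HSA"
    AAG = "AAG"


@dataclass(frozen=True)
class DrugSpec:
    """One hypothetical drug.

    fu_normal_weight — unbound plasma fraction in the normal-weight subject, (0, 1]
    kp               — blood-cell partition coefficient, > 0
    clint_ats        — intrinsic active-secretion clearance, µl·min⁻¹·(mg protein)⁻¹
    binding_protein  — the single plasma protein the drug binds (HSA or AAG)
    """

    fu_normal_weight: float
    kp: float
    clint_ats: float
    binding_protein: BindingProtein = BindingProtein.HSA

    def __post_init__(self) -> None:
        if not 0 < self.fu_normal_weight <= 1:
            raise ValueError(f"fu_normal_weight must lie in (0, 1], got {self.fu_normal_weight}")
        if self.kp <= 0:
            raise ValueError(f"kp must be positive, got {self.kp}")
        if self.clint_ats <= 0:
            raise ValueError(f"clint_ats must be positive, got {self.clint_ats}")
        object.__setattr__(self, "binding_protein", BindingProtein(self.binding_protein))


@dataclass(frozen=True)
class Scenario:
    """A (BMI category, relative transporter activity) pairing.

    rta is a fraction of normal-weight transporter activity (1.0 = unchanged).
    """

    bmi: float
    rta: float

    def __post_init__(self) -> None:
        if self.rta <= 0:
            raise ValueError(f"rta must be positive, got {self.rta}")


def clint_ats_values(start: float = 2.0, stop: float = 500.0, count: int = 32) -> list[float]:
    """Equidistant CL_int_ATS grid with inclusive endpoints (default 2…500, n=32)."""
    if count < 2:
        raise ValueError("count must be at least 2")
    return [float(v) for v in np.linspace(start, stop, count)]


#: axes that define a drug (binding protein is run as two parallel grids)
DRUG_AXES = ("fu", "kp", "clint_ats")


def default_grid_values() -> dict[str, list]:
    """The study's default axis values, in their documented order.

    Returned axes: fu (fraction), kp, clint_ats (µl·min⁻¹·mg⁻¹, 32
    equidistant values 2…500), rta (fraction of normal-weight activity),
    bmi (kg/m² categories) and binding_protein.
    """
    return {
        "fu": [0.05, 0.25, 0.50, 0.75, 0.95, 1.00],
        "kp": [0.35, 1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 20.0, 30.0, 40.0],
        "clint_ats": clint_ats_values(),
        "rta": [0.2, 0.5, 1.0, 1.5, 2.0, 2.5],
        "bmi": [20.0, 25.0, 30.0, 40.0, 50.0, 60.0],
        "binding_protein": [BindingProtein.HSA.value, BindingProtein.AAG.value],
    }


def enumerate_combinations(
    grid: dict[str, list] | None = None,
    axes: tuple[str, ...] = ("fu", "kp", "clint_ats", "rta"),
) -> pd.DataFrame:
    """Full Cartesian product over the named axes, one combination per row.

    Rows are in lexicographic order: the first named axis varies slowest,
    the last fastest.  The default axes reproduce the study's 11,520
    drug × rTA combinations (binding protein handled as two parallel runs).
    """
    grid = default_grid_values() if grid is None else grid
    values = []
    for axis in axes:
        if axis not in grid:
            raise KeyError(f"axis {axis!r} missing from grid (have {sorted(grid)})")
        if len(grid[axis]) == 0:
            raise ValueError(f"axis {axis!r} is empty")
        values.append(list(grid[axis]))
    rows = list(itertools.product(*values))
    return pd.DataFrame(rows, columns=list(axes))


#: stable export column names
GRID_COLUMNS = ("fu_normal_weight", "kp", "clint_ats", "binding_protein", "bmi", "rta")


def grid_table(grid: dict[str, list] | None = None) -> pd.DataFrame:
    """Full study grid (drug axes × protein × BMI × rTA) with stable column names."""
    df = enumerate_combinations(grid, axes=("binding_protein", "fu", "kp", "clint_ats", "bmi", "rta"))
    df = df.rename(columns={"fu": "fu_normal_weight"})
    return df[list(GRID_COLUMNS)]
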