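"""Stem-census / soil-grid overlay and per-species median soil associations.

A species' "trait" here is measured on the environment, not the organism:
the median value of a gridded soil variable over the cells occupied by the
species' stems.  Cells are ``cell_size`` x ``cell_size`` metre quadrats
(default 20 m, the scale of the kriged soil layers); coordinates are metres
from the plot corner, cells are half-open intervals and the far plot
boundary is clamped inward so every in-bounds stem lands in exactly one
cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treeio import COUNT_COLUMN, validate_trait_table

__all__ = [
    "SoilGrid",
    "read_census",
    "write_census",
    "assign_quadrat",
    "stem_values",
    "species_medians",
    "OutOfBoundsError",
    "UnknownVariableError",
]


class OutOfBoundsError(ValueError):
    """Stem coordinate outside the plot."""


class UnknownVariableError(KeyError):
    """Requested layer is not in the grid."""


@dataclass
class SoilGrid:
    """A stack of gridded environmental layers on one regular lattice.

    ``data`` maps variable name to an ``(nx, ny)`` array indexed ``[i, j]``
    with ``i`` along x.  Missing cells are NaN.  The origin (0, 0) is the
    plot corner.
    """

    cell_size: float
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        shapes = {name: arr.shape for name, arr in self.data.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"layers disagree on grid shape: {shapes}")
        for name, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            self.data[name] = arr
            if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
                raise ValueError(f"layer {name!r} must be a 2-D array")
            vals = arr[~np.isnan(arr)]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"layer {name!r} has non-finite values")

    @property
    def nx(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def ny(self) -> int:
        return next(iter(self.data.values())).shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.data)

    @property
    def width(self) -> float:
        return self.nx * self.cell_size

    @property
    def height(self) -> float:
        return self.ny * self.cell_size

    def copy(self) -> "SoilGrid":
        return SoilGrid(self.cell_size, {k: v.copy() for k, v in self.data.items()})

    # -- I/O ----------------------------------------------------------
    def to_wide_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        cols = {"cell_i": ii.ravel(), "cell_j": jj.ravel()}
        for name, arr in self.data.items():
            cols[name] = arr.ravel()
        return pd.DataFrame(cols)

    def to_wide_csv(self, path, cell_size_comment: bool = True) -> None:
        with open(path, "w") as fh:
            if cell_size_comment:
                fh.write(f"# cell_size={self.cell_size}\n")
            self.to_wide_frame().to_csv(fh, index=False)

    @classmethod
    def from_wide_frame(cls, df: pd.DataFrame, cell_size: float) -> "SoilGrid":
        nx = int(df["cell_i"].max()) + 1
        ny = int(df["cell_j"].max()) + 1
        data = {}
        i = df["cell_i"].to_numpy(int)
        j = df["cell_j"].to_numpy(int)
        for name in df.columns:
            if name in ("cell_i", "cell_j"):
                continue
            arr = np.full((nx, ny), np.nan)
            arr[i, j] = df[name].to_numpy(float)
            data[name] = arr
        return cls(cell_size, data)

    @classmethod
    def from_wide_csv(cls, path, cell_size: float | None = None) -> "SoilGrid":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                if cell_size is None and "cell_size=" in first:
                    cell_size = float(first.split("cell_size=")[1].strip())
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        if cell_size is None:
            raise ValueError("cell_size not given and not recorded in the file")
        return cls.from_wide_frame(df, cell_size)

    def to_long_frame(self) -> pd.DataFrame:
        wide = self.to_wide_frame()
        return wide.melt(
            id_vars=["cell_i", "cell_j"], var_name="variable", value_name="value"
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, cell_size: float) -> "SoilGrid":
        wide = df.pivot_table(
            index=["cell_i", "cell_j"], columns="variable", values="value"
        ).reset_index()
        wide.columns.name = None
        return cls.from_wide_frame(wide, cell_size)


# ---------------------------------------------------------------------------
# Census I/O
# ---------------------------------------------------------------------------

def read_census(path) -> pd.DataFrame:
    """Read a stem census TSV with columns species, x, y, dbh."""
    df = pd.read_csv(path, sep="\t")
    missing = {"species", "x", "y", "dbh"} - set(df.columns)
    if missing:
        raise ValueError(f"census is missing columns: {sorted(missing)}")
    if (df["dbh"] <= 0).any():
        raise ValueError("census contains non-positive dbh values")
    return df


def write_census(census: pd.DataFrame, path) -> None:
    census.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

def assign_quadrat(x, y, cell_size: float, nx: int, ny: int):
    """Map plot coordinates (metres) to 0-based cell indices.

    Cells are half-open ``[i*s, (i+1)*s)``; points exactly on the far plot
    boundary are clamped into the last cell.  Accepts scalars or arrays.
    Out-of-bounds coordinates raise :class:`OutOfBoundsError` naming the
    offending record positions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bad = (x < 0) | (x > nx * cell_size) | (y < 0) | (y > ny * cell_size)
    if np.any(bad):
        idx = np.nonzero(np.atleast_1d(bad))[0][:10].tolist()
        raise OutOfBoundsError(
            f"coordinates outside the {nx * cell_size:g}x{ny * cell_size:g} m plot "
            f"at record positions {idx}"
        )
    i = np.minimum(np.floor(x / cell_size).astype(int), nx - 1)
    j = np.minimum(np.floor(y / cell_size).astype(int), ny - 1)
    if i.ndim == 0:
        return int(i), int(j)
    return i, j


def stem_values(census: pd.DataFrame, grid: SoilGrid, variable: str):
    """Per-stem values of one grid variable.

    Returns ``(values, n_excluded)``: one value per stem whose cell is not
    missing, plus the count of stems excluded because they fell in missing
    cells.
    """
    if variable not in grid.data:
        raise UnknownVariableError(
            f"unknown variable {variable!r}; available: {grid.variables}"
        )
    i, j = assign_quadrat(
        census["x"].to_numpy(), census["y"].to_numpy(),
        grid.cell_size, grid.nx, grid.ny,
    )
    vals = grid.data[variable][i, j]
    keep = ~np.isnan(vals)
    return vals[keep], int((~keep).sum())


def species_medians(
    census: pd.DataFrame,
    grid: SoilGrid,
    variables: list[str] | None = None,
    min_dbh: float = 1.0,
) -> pd.DataFrame:
    """Per-species median soil values — the trait-file construction.

    Stems below ``min_dbh`` (cm, inclusive threshold: kept if dbh >= min_dbh)
    are dropped first.  Each remaining stem contributes the value of its
    cell; stems in cells where *any* requested variable is missing are
    excluded listwise so that one individual count describes every trait
    column.  Even-count medians are the mean of the two middle order
    statistics.  Species with no included stems are omitted.

    Returns a trait table: species index, one column per variable, plus an
    ``n_individuals`` count column.
    """
    if variables is None:
        variables = grid.variables
    for v in variables:
        if v not in grid.data:
            raise UnknownVariableError(
                f"unknown variable {v!r}; available: {grid.variables}"
            )
    kept = census[census["dbh"] >= min_dbh]
    if kept.empty:
        raise ValueError(f"no stems with dbh >= {min_dbh} cm")
    i, j = assign_quadrat(
        kept["x"].to_numpy(), kept["y"].to_numpy(),
        grid.cell_size, grid.nx, grid.ny,
    )
    value_matrix = np.column_stack([grid.data[v][i, j] for v in variables])
    complete = ~np.isnan(value_matrix).any(axis=1)
    frame = pd.DataFrame(value_matrix[complete], columns=variables)
    frame["species"] = kept["species"].to_numpy()[complete]
    if frame.empty:
        raise ValueError("every stem fell in a missing cell")
    grouped = frame.groupby("species", sort=True)
    table = grouped[variables].median()
    table[COUNT_COLUMN] = grouped.size()
    validate_trait_table(table)
    return table
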