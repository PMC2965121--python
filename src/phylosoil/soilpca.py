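"""Composite soil-fertility axes by PCA on gridded soil variables.

Strongly skewed nutrient concentrations (the Mehlich-3 extractable
cations, phosphorus, zinc) and elevation are natural-log transformed,
every variable is standardized to zero mean and unit variance across
non-missing grid cells, and the correlation matrix of the resulting cell
x variable matrix is eigendecomposed.  The leading axes (default: three)
are appended to the grid as new layers so that downstream stages can
treat an axis score exactly like a measured soil variable.

Sign convention: each axis is oriented so that the variable with the
largest absolute loading has a positive loading.  Orientation is
arbitrary in PCA; fixing it makes runs reproducible and comparisons to
published loading tables a matter of flipping signs per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import SoilGrid

__all__ = [
    "DEFAULT_LOG_VARS",
    "PCAResult",
    "transform_variables",
    "run_pca",
    "scores_to_grid",
    "write_loadings_tsv",
]

#: Variables log-transformed by default before standardization.  Nitrogen
#: mineralization is never log-transformed: its range includes negative rates.
DEFAULT_LOG_VARS = ("B", "Ca", "Cu", "Fe", "K", "Mg", "P", "Zn", "elevation")


@dataclass
class PCAResult:
    """Eigendecomposition of the standardized soil data's correlation matrix.

    ``loadings`` is (p x p) with orthonormal columns (axes ordered by
    decreasing eigenvalue); ``scores`` is (n_complete_cells x p);
    ``cell_index`` holds the flat ``i * ny + j`` index of each complete cell;
    ``variance_fraction[k] = eigenvalues[k] / p``.
    """

    variables: list[str]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    scores: np.ndarray
    cell_index: np.ndarray
    grid_shape: tuple[int, int]

    @property
    def p(self) -> int:
        return len(self.variables)

    def loadings_frame(self, k: int | None = None) -> pd.DataFrame:
        k = self.p if k is None else k
        cols = [f"Axis {a + 1}" for a in range(k)]
        return pd.DataFrame(self.loadings[:, :k], index=self.variables, columns=cols)


def transform_variables(grid: SoilGrid, log_vars=DEFAULT_LOG_VARS) -> SoilGrid:
    """Log-transform the designated layers, then z-score every layer.

    Only layers present in the grid are taken from ``log_vars`` (so the
    default list can be used with grids carrying a subset of variables).
    A non-positive value in a log variable, or a constant layer, is an
    error naming the variable.
    """
    log_set = {v for v in log_vars if v in grid.data}
    out = {}
    for name, arr in grid.data.items():
        arr = arr.copy()
        mask = ~np.isnan(arr)
        if name in log_set:
            if np.any(arr[mask] <= 0):
                i, j = np.argwhere(mask & (arr <= 0))[0]
                raise ValueError(
                    f"cannot log-transform {name!r}: non-positive value "
                    f"{arr[i, j]!r} at cell ({i}, {j})"
                )
            arr[mask] = np.log(arr[mask])
        mu = arr[mask].mean()
        sd = arr[mask].std(ddof=0)  # population SD; irrelevant to correlation PCA
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable {name!r} is constant; cannot standardize")
        arr[mask] = (arr[mask] - mu) / sd
        out[name] = arr
    return SoilGrid(grid.cell_size, out)


def run_pca(grid: SoilGrid, variables: list[str] | None = None) -> PCAResult:
    """PCA of the correlation matrix over complete grid cells.

    Cells missing any requested variable are dropped listwise.  All p axes
    are computed; eigenvalues sum to p (the correlation-matrix trace).
    """
    if variables is None:
        variables = grid.variables
    if len(variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    stack = np.stack([grid.data[v].ravel() for v in variables], axis=1)
    complete = ~np.isnan(stack).any(axis=1)
    X = stack[complete]
    n = X.shape[0]
    p = len(variables)
    if n < 3:
        raise ValueError(f"only {n} complete cells; need at least 3")
    if n < p:
        warnings.warn(
            f"fewer complete cells ({n}) than variables ({p}): "
            "the correlation matrix is rank deficient",
            stacklevel=2,
        )
    # standardize over the complete-cell set so scores are exactly centred
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    # eigenvalues of a correlation matrix lie in [0, p]; enforce against
    # eigh round-off so variance fractions are exact in degenerate cases
    eigval = np.clip(eigval[order], 0.0, float(p))
    eigval[np.abs(eigval - p) < 1e-12 * p] = float(p)  # degenerate: all mass on one axis
    eigvec = eigvec[:, order]
    # orient each axis: largest-|loading| variable gets a positive loading
    for k in range(p):
        lead = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[lead, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = Z @ eigvec
    return PCAResult(
        variables=list(variables),
        loadings=eigvec,
        eigenvalues=eigval,
        variance_fraction=eigval / p,
        scores=scores,
        cell_index=np.nonzero(complete)[0],
        grid_shape=(grid.nx, grid.ny),
    )


def scores_to_grid(grid: SoilGrid, result: PCAResult, k: int = 3) -> SoilGrid:
    """Append the first ``k`` axis-score layers (PCA1..PCAk) to the grid.

    Cells that were incomplete during the PCA get missing scores.
    """
    if not 1 <= k <= result.p:
        raise ValueError(f"k must be in [1, {result.p}], got {k}")
    if (grid.nx, grid.ny) != result.grid_shape:
        raise ValueError("grid shape differs from the PCA input grid")
    out = grid.copy()
    for a in range(k):
        layer = np.full(grid.nx * grid.ny, np.nan)
        layer[result.cell_index] = result.scores[:, a]
        out.data[f"PCA{a + 1}"] = layer.reshape(grid.nx, grid.ny)
    return out


def write_loadings_tsv(result: PCAResult, path, k: int = 3) -> None:
    """Loadings table with a trailing '% variance' row per axis."""
    frame = result.loadings_frame(k).round(3)
    with open(path, "w") as fh:
        fh.write("Soil variable\t" + "\t".join(frame.columns) + "\n")
        for name, row in frame.iterrows():
            fh.write(name + "\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")
        pct = [f"{100 * result.variance_fraction[a]:.0f}%" for a in range(k)]
        fh.write("% variance\t" + "\t".join(pct) + "\n")
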