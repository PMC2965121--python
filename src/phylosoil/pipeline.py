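"""End-to-end orchestration: extract -> PCA -> signal -> node tests.

``run_pipeline`` reads a tree, a stem census and a soil grid, builds the
composite PCA layers, computes per-species median "traits" for the
selected soil variables and axis scores, fits the evolutionary-signal
model, and writes the full report set into the output directory.  With a
fixed seed the output directory is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import soilpca
from .landscape import SoilGrid, read_census, species_medians
from .model import PhyloSignalModel
from .treeio import read_newick, write_trait_table

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("phylosoil")

#: soil variables tested by default, alongside the first three PCA axes
DEFAULT_TEST_VARS = ("Al", "Mn", "P", "pH", "slope")


@dataclass
class RunConfig:
    tree: str = ""
    census: str = ""
    grid: str = ""
    outdir: str = "phylosoil_out"
    variables: tuple[str, ...] = DEFAULT_TEST_VARS
    log_vars: tuple[str, ...] = soilpca.DEFAULT_LOG_VARS
    n_axes: int = 3
    min_dbh: float = 1.0
    cell_size: float = 20.0
    R: int = 999
    alpha: float = 0.05
    min_individuals: int = 5
    require_both: bool = True
    pca_high_only: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must be in (0, 0.5]")
        if self.n_axes < 0:
            raise ValueError("n_axes must be >= 0")
        if self.min_dbh < 0 or self.cell_size <= 0:
            raise ValueError("min_dbh must be >= 0 and cell_size > 0")


def validate_config(doc: dict) -> RunConfig:
    """Normalize a parsed config mapping: fill defaults, reject unknown
    keys, check invariants (errors name the offending key)."""
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    doc = dict(doc)
    for key in ("variables", "log_vars"):
        if key in doc and not isinstance(doc[key], (list, tuple)):
            raise ValueError(f"config key {key!r} must be a list")
        if key in doc:
            doc[key] = tuple(doc[key])
    try:
        return RunConfig(**doc)
    except ValueError as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def run_pipeline(config: RunConfig):
    """Run the whole analysis; returns the fitted results object.

    Outputs written to ``config.outdir``: traits.tsv, pca_loadings.tsv,
    pca_scores.csv, k_table.tsv, phylogeny_wide.tsv, node_tests_low.tsv,
    node_tests_high.tsv, node_tests_long.tsv, run_metadata.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("reading tree %s", config.tree)
    tree = read_newick(Path(config.tree).read_text())
    log.info("tree: %d tips", tree.n_tips)

    log.info("reading census %s", config.census)
    census = read_census(config.census)
    log.info("census: %d stems, %d species", len(census), census["species"].nunique())

    log.info("reading grid %s", config.grid)
    grid = SoilGrid.from_wide_csv(config.grid, cell_size=config.cell_size)
    log.info("grid: %dx%d cells of %g m, %d variables",
             grid.nx, grid.ny, grid.cell_size, len(grid.variables))

    pca_axis_names: tuple[str, ...] = ()
    if config.n_axes > 0:
        transformed = soilpca.transform_variables(grid, config.log_vars)
        pca = soilpca.run_pca(transformed)
        grid = soilpca.scores_to_grid(grid, pca, k=config.n_axes)
        pca_axis_names = tuple(f"PCA{a + 1}" for a in range(config.n_axes))
        soilpca.write_loadings_tsv(pca, outdir / "pca_loadings.tsv", k=config.n_axes)
        score_grid = SoilGrid(
            grid.cell_size, {a: grid.data[a] for a in pca_axis_names}
        )
        score_grid.to_wide_csv(outdir / "pca_scores.csv")
        log.info("PCA: first %d axes hold %.0f%% of the variance",
                 config.n_axes, 100 * pca.variance_fraction[: config.n_axes].sum())

    test_vars = [v for v in config.variables if v in grid.variables]
    missing = [v for v in config.variables if v not in grid.variables]
    if missing:
        raise ValueError(f"requested variables absent from the grid: {missing}")
    all_traits = list(test_vars) + list(pca_axis_names)

    log.info("extracting species medians for %s (min dbh %.2g cm)",
             all_traits, config.min_dbh)
    traits = species_medians(census, grid, all_traits, min_dbh=config.min_dbh)
    write_trait_table(traits.round(6), outdir / "traits.tsv")
    log.info("trait table: %d species", len(traits))

    model = PhyloSignalModel(tree, traits, trait_names=all_traits,
                             pca_axes=pca_axis_names)
    if model.match_report["dropped_tips"] or model.match_report["dropped_trait_rows"]:
        log.info("taxon matching dropped %d tips, %d trait rows",
                 len(model.match_report["dropped_tips"]),
                 len(model.match_report["dropped_trait_rows"]))
    log.info("fitting signal model (R=%d, alpha=%g, seed=%s)",
             config.R, config.alpha, config.seed)
    results = model.fit(
        R=config.R, alpha=config.alpha, seed=config.seed,
        min_individuals=config.min_individuals,
        require_both=config.require_both,
        pca_high_only=config.pca_high_only,
    )
    results.write(outdir)

    meta_path = outdir / "run_metadata.json"
    meta = json.loads(meta_path.read_text())
    meta["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
        if k != "outdir"  # run-specific, kept out so identical analyses
                          # produce byte-identical output directories
    }
    meta["n_stems"] = int(len(census))
    meta["n_census_species"] = int(census["species"].nunique())
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote results to %s", outdir)
    return results
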