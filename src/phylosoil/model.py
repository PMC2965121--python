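"""Model/Results front end for the evolutionary-signal analysis.

:class:`PhyloSignalModel` binds a phylogeny to a species trait table
(typically per-species median soil values plus PCA-axis scores) and
``fit()`` runs the full statistical stage: Blomberg's K with a two-tailed
permutation test per trait, phylogeny-wide contrast signal, and the
node-specific tip/ancestral permutation tests with the conservatism
filters.  The returned :class:`PhyloSignalResults` carries the estimates,
their permutation p values, diagnostics and a ``summary()`` table, and
can write the full set of report files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrasts as _contrasts
from . import nodetests as _nodetests
from .treeio import COUNT_COLUMN, Phylogeny, match_taxa, read_newick, read_trait_table

__all__ = ["PhyloSignalModel", "PhyloSignalResults"]


class PhyloSignalModel:
    """Evolutionary signal of species-level (soil) traits on a phylogeny.

    Parameters
    ----------
    tree
        Rooted phylogeny with branch lengths; tips are species codes.
    traits
        Trait table: species index, one column per trait, optionally an
        ``n_individuals`` column used by the rare-species filter.
    trait_names
        Traits to analyse (default: every non-count column).
    pca_axes
        Names of traits that are PCA-axis scores; for these only the
        high tail is reported in node tables.

    The tree and table are reconciled on construction (shared species
    kept, unary nodes suppressed); the reconciliation report is available
    as ``model.match_report``.
    """

    def __init__(self, tree: Phylogeny, traits: pd.DataFrame,
                 trait_names: list[str] | None = None,
                 pca_axes: tuple[str, ...] = ()):
        self.tree, self.traits, self.match_report = match_taxa(tree, traits)
        if trait_names is None:
            trait_names = [c for c in self.traits.columns if c != COUNT_COLUMN]
        unknown = [t for t in trait_names if t not in self.traits.columns]
        if unknown:
            raise ValueError(f"traits not in table: {unknown}")
        self.trait_names = list(trait_names)
        self.pca_axes = tuple(pca_axes)

    @classmethod
    def from_files(cls, tree_path, traits_path, **kwargs) -> "PhyloSignalModel":
        tree = read_newick(Path(tree_path).read_text())
        traits = read_trait_table(traits_path)
        return cls(tree, traits, **kwargs)

    def fit(self, R: int = 999, alpha: float = 0.05, seed: int | None = None,
            min_individuals: int = 5, require_both: bool = True,
            pca_high_only: bool = True) -> "PhyloSignalResults":
        """Run every signal statistic for every trait.

        ``seed`` drives one master stream; each trait gets its own derived
        sub-seeds (recorded in the results) so traits can be re-run
        individually yet deterministically.
        """
        master = np.random.default_rng(seed)
        sub = {t: master.integers(0, 2**31 - 1, size=3) for t in self.trait_names}
        k_rows, wide_rows = [], []
        node_results: dict[str, list[_nodetests.NodeTestResult]] = {}
        filtered: dict[str, _nodetests.FilteredNodeTests] = {}
        for trait in self.trait_names:
            s_k, s_w, s_n = (int(v) for v in sub[trait])
            kres = _contrasts.k_significance(self.tree, self.traits, trait, R=R, seed=s_k)
            k_rows.append({"trait": trait, "K": kres.K, "p_two_tailed": kres.p_two_tailed})
            sig = _contrasts.phylogeny_wide_signal(self.tree, self.traits, trait, R=R, seed=s_w)
            wide_rows.append({
                "trait": trait,
                "mean_abs_contrast": sig.observed,
                "p_low": sig.p_low,
                "p_high": sig.p_high,
            })
            res = _nodetests.node_permutation_test(
                self.tree, self.traits, trait, R=R, seed=s_n, alpha=alpha
            )
            node_results[trait] = res
            filtered[trait] = _nodetests.filter_and_flag(
                res, self.tree, self.traits, trait,
                alpha=alpha, min_individuals=min_individuals,
                require_both=require_both,
                is_pca_axis=trait in self.pca_axes,
                pca_high_only=pca_high_only,
            )
        return PhyloSignalResults(
            model=self,
            k_table=pd.DataFrame(k_rows).set_index("trait"),
            phylowide=pd.DataFrame(wide_rows).set_index("trait"),
            node_results=node_results,
            filtered=filtered,
            R=R, alpha=alpha, seed=seed,
            min_individuals=min_individuals,
            require_both=require_both,
            pca_high_only=pca_high_only,
        )


@dataclass
class PhyloSignalResults:
    """Fitted evolutionary-signal results for one tree + trait table."""

    model: PhyloSignalModel
    k_table: pd.DataFrame
    phylowide: pd.DataFrame
    node_results: dict[str, list]
    filtered: dict[str, "_nodetests.FilteredNodeTests"]
    R: int
    alpha: float
    seed: int | None
    min_individuals: int
    require_both: bool
    pca_high_only: bool
    _long_cache: pd.DataFrame | None = field(default=None, repr=False)

    # -- views --------------------------------------------------------
    @property
    def n_tests(self) -> int:
        """Number of node x trait x tail x method p values computed."""
        return sum(4 * len(v) for v in self.node_results.values())

    def significant_nodes(self, tail: str) -> pd.DataFrame:
        recs = [f for f in self.filtered.values()]
        return _nodetests.write_node_tables(recs, tail, _DevNull())

    def node_long_frame(self) -> pd.DataFrame:
        """Every node x trait p value in long format."""
        if self._long_cache is None:
            rows = []
            for trait, results in self.node_results.items():
                for r in results:
                    for method in ("tip", "anc"):
                        for tail in ("low", "high"):
                            rows.append({
                                "trait": trait,
                                "node_id": r.node_id,
                                "n_species": len(r.species),
                                "method": method,
                                "tail": tail,
                                "mean": r.tip_mean if method == "tip" else r.ancestral_mean,
                                "p": getattr(r, f"p_{tail}_{method}"),
                                "is_root": r.is_root,
                            })
            self._long_cache = pd.DataFrame(rows)
        return self._long_cache

    def summary(self) -> str:
        """Human-readable run summary in the spirit of a fit report."""
        lines = [
            "Evolutionary signal in species-environment associations",
            "=" * 56,
            f"Species (tips): {self.model.tree.n_tips}    "
            f"Traits: {len(self.model.trait_names)}    "
            f"Permutations: {self.R}    alpha per tail: {self.alpha}",
            "",
            "Blomberg's K (two-tailed tip-shuffle test)",
            "-" * 44,
            f"{'trait':<14}{'K':>8}{'p':>10}",
        ]
        for trait, row in self.k_table.iterrows():
            lines.append(f"{trait:<14}{row['K']:>8.2f}{row['p_two_tailed']:>10.3f}")
        lines += [
            "",
            "Phylogeny-wide signal (mean |contrast|; low tail = conservatism)",
            "-" * 64,
            f"{'trait':<14}{'mean|c|':>10}{'p_low':>8}{'p_high':>8}",
        ]
        for trait, row in self.phylowide.iterrows():
            lines.append(
                f"{trait:<14}{row['mean_abs_contrast']:>10.4f}"
                f"{row['p_low']:>8.3f}{row['p_high']:>8.3f}"
            )
        n_low = sum(len(f.low) for f in self.filtered.values())
        n_high = sum(len(f.high) for f in self.filtered.values())
        lines += [
            "",
            "Node-specific tests (significant under both averagings, filtered)",
            "-" * 66,
            f"low-tail nodes reported: {n_low}    high-tail nodes reported: {n_high}",
            f"total p values computed: {self.n_tests} "
            "(no multiple-testing correction applied)",
        ]
        return "\n".join(lines)

    # -- output -------------------------------------------------------
    def write(self, outdir) -> None:
        """Write k_table, phylogeny-wide, node tables (both tails), the
        long-format p-value file and a metadata sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _contrasts.write_k_table(
            {
                t: _contrasts.KResult(
                    K=row["K"], MSE0=np.nan, MSE=np.nan,
                    observed_ratio=np.nan, expected_ratio=np.nan,
                    p_two_tailed=row["p_two_tailed"],
                )
                for t, row in self.k_table.iterrows()
            },
            outdir / "k_table.tsv",
        )
        self.phylowide.round(6).to_csv(outdir / "phylogeny_wide.tsv", sep="\t")
        recs = list(self.filtered.values())
        _nodetests.write_node_tables(recs, "low", outdir / "node_tests_low.tsv")
        _nodetests.write_node_tables(recs, "high", outdir / "node_tests_high.tsv")
        self.node_long_frame().to_csv(outdir / "node_tests_long.tsv", sep="\t", index=False)
        meta = {
            "R": self.R,
            "alpha": self.alpha,
            "seed": self.seed,
            "min_individuals": self.min_individuals,
            "require_both": self.require_both,
            "pca_high_only": self.pca_high_only,
            "n_species": self.model.tree.n_tips,
            "traits": self.model.trait_names,
            "pca_axes": list(self.model.pca_axes),
            "n_tests": self.n_tests,
            "match_report": self.model.match_report,
        }
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def plot_k(self, ax=None):  # pragma: no cover - thin plotting helper
        """Bar chart of K per trait (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.k_table["K"].plot.bar(ax=ax)
        ax.axhline(1.0, color="grey", ls="--", lw=1)
        ax.set_ylabel("Blomberg's K")
        return ax


class _DevNull:
    """File-like sink for building report frames without touching disk."""

    def write(self, *_args):
        return None
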