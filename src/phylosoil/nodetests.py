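"""Node-specific evolutionary-signal tests.

For every internal node the observed mean trait value of its subtended
species is compared to a null distribution built by permuting trait
values across the tips of the phylogeny (default 999 shuffles, one shared
shuffle stream for all nodes of a run so results are comparable within
it).  Two averaging schemes are computed:

* **tip averaging** — the unweighted mean over all subtended species;
* **ancestral averaging** — a recursive equal-weight mean over immediate
  daughters (each daughter counts once regardless of its subtree size),
  the classic nodes-as-units correction for uneven clade sizes.  Branch
  lengths are ignored.

A node "has signal" in a tail when its observed mean lands in that tail
of the null (p <= alpha per tail, (r+1)/(R+1) rule, ties extreme);
reporting conservatively focuses on nodes significant under *both*
averaging schemes.  Nodes whose significance hinges on a species with
fewer than ``min_individuals`` stems are probed by a leave-one-out
re-test and excluded when the signal does not survive removal of the
rare species.  For PCA-axis traits only the high tail is reported (low
composite-fertility scores are not interpretable as tolerance), though
both tails are always computed and retained.

Both node statistics are linear in the tip values, so the whole
permutation test reduces to two matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contrasts import _trait_vector
from .treeio import COUNT_COLUMN, Phylogeny, match_taxa

__all__ = [
    "NodeTestResult",
    "FilteredNodeTests",
    "tip_means",
    "ancestral_means",
    "node_permutation_test",
    "filter_and_flag",
    "write_node_tables",
]

#: relative tolerance for counting a null value as tied with the observed
_TIE_RTOL = 1e-9


@dataclass
class NodeTestResult:
    """Permutation-test outcome for one internal node and one trait."""

    node_id: int
    species: tuple[str, ...]            # subtended tips, tree order
    individuals: tuple[int, ...] | None  # per species, same order
    tip_mean: float
    ancestral_mean: float
    p_low_tip: float
    p_high_tip: float
    p_low_anc: float
    p_high_anc: float
    R: int
    seed: int | None
    is_root: bool = False
    significant_both_low: bool = False
    significant_both_high: bool = False
    min_count_flag: bool = False
    dependent_on_rare: bool = False


@dataclass
class FilteredNodeTests:
    """Reportable records after the conservatism filters, plus everything."""

    trait: str
    is_pca_axis: bool
    low: list[NodeTestResult]
    high: list[NodeTestResult]
    all_results: list[NodeTestResult] = field(repr=False, default_factory=list)


class _NodeMaps:
    """Indicator/weight matrices mapping tip values to node means.

    ``T`` (m x n): row k averages the subtended tips of internal node k.
    ``A`` (m x n): row k gives ancestral-averaging weights (recursive
    equal-weight mean over daughters).  Internal nodes are numbered in
    postorder; the root is last.
    """

    def __init__(self, tree: Phylogeny):
        tips = tree.tips()
        self.tip_labels = [t.label for t in tips]
        n = len(tips)
        slot = {id(t): k for k, t in enumerate(tips)}
        tip_rows: list[np.ndarray] = []
        anc_rows: list[np.ndarray] = []
        species: list[tuple[str, ...]] = []
        tipsets: dict[int, list[int]] = {}
        anc_w: dict[int, np.ndarray] = {}
        node_no = 0
        self.root_index = None
        for node in tree.postorder():
            if node.is_leaf:
                tipsets[id(node)] = [slot[id(node)]]
                w = np.zeros(n)
                w[slot[id(node)]] = 1.0
                anc_w[id(node)] = w
                continue
            members: list[int] = []
            for c in node.children:
                members.extend(tipsets.pop(id(c)))
            tipsets[id(node)] = members
            row = np.zeros(n)
            row[members] = 1.0 / len(members)
            tip_rows.append(row)
            w = np.mean([anc_w.pop(id(c)) for c in node.children], axis=0)
            anc_w[id(node)] = w
            anc_rows.append(w)
            species.append(tuple(self.tip_labels[i] for i in sorted(members)))
            if node is tree.root:
                self.root_index = node_no
            node_no += 1
        self.T = np.array(tip_rows)
        self.A = np.array(anc_rows)
        self.species = species
        self.n_nodes = node_no


def tip_means(tree: Phylogeny, traits, trait: str | None = None) -> dict[int, float]:
    """Unweighted mean trait value of the species subtended by each
    internal node (postorder node numbering; root last)."""
    maps = _NodeMaps(tree)
    x = _trait_vector(traits, trait, maps.tip_labels)
    vals = maps.T @ x
    return {k: float(v) for k, v in enumerate(vals)}


def ancestral_means(tree: Phylogeny, traits, trait: str | None = None) -> dict[int, float]:
    """Recursive equal-weight daughter means per internal node (branch
    lengths ignored; each immediate daughter counts once)."""
    maps = _NodeMaps(tree)
    x = _trait_vector(traits, trait, maps.tip_labels)
    vals = maps.A @ x
    return {k: float(v) for k, v in enumerate(vals)}


def _tail_counts(null: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r+1)/(R+1) per-node tail p values, ties counted as extreme."""
    R = null.shape[1]
    tol = _TIE_RTOL * np.maximum(1.0, np.abs(obs))
    le = (null <= (obs + tol)[:, None]).sum(axis=1)
    ge = (null >= (obs - tol)[:, None]).sum(axis=1)
    return (le + 1) / (R + 1), (ge + 1) / (R + 1)


def node_permutation_test(
    tree: Phylogeny,
    traits,
    trait: str | None = None,
    R: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[NodeTestResult]:
    """Tip-shuffle permutation test of every internal node's mean.

    One shared stream of R shuffles feeds all nodes and both averaging
    methods.  Returns one :class:`NodeTestResult` per internal node, in
    postorder (root last).  The root's tip average is permutation
    invariant, so its p values are 1 by construction and it is never
    flagged significant.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    maps = _NodeMaps(tree)
    if len(maps.tip_labels) < 3:
        raise ValueError("node tests need at least 3 tips")
    x = _trait_vector(traits, trait, maps.tip_labels)
    counts = None
    if isinstance(traits, pd.DataFrame) and COUNT_COLUMN in traits.columns:
        counts = traits[COUNT_COLUMN]
    rng = np.random.default_rng(seed)
    perms = np.empty((len(x), R))
    for r in range(R):
        perms[:, r] = rng.permutation(x)
    obs_tip = maps.T @ x
    obs_anc = maps.A @ x
    null_tip = maps.T @ perms
    null_anc = maps.A @ perms
    p_low_tip, p_high_tip = _tail_counts(null_tip, obs_tip)
    p_low_anc, p_high_anc = _tail_counts(null_anc, obs_anc)
    out: list[NodeTestResult] = []
    for k in range(maps.n_nodes):
        is_root = k == maps.root_index
        sig_low = (not is_root) and p_low_tip[k] <= alpha and p_low_anc[k] <= alpha
        sig_high = (not is_root) and p_high_tip[k] <= alpha and p_high_anc[k] <= alpha
        sp = maps.species[k]
        ind = None
        if counts is not None:
            ind = tuple(int(counts.loc[s]) for s in sp)
        out.append(
            NodeTestResult(
                node_id=k,
                species=sp,
                individuals=ind,
                tip_mean=float(obs_tip[k]),
                ancestral_mean=float(obs_anc[k]),
                p_low_tip=float(p_low_tip[k]),
                p_high_tip=float(p_high_tip[k]),
                p_low_anc=float(p_low_anc[k]),
                p_high_anc=float(p_high_anc[k]),
                R=R,
                seed=seed,
                is_root=is_root,
            )
        )
    return out


def _significant(res: NodeTestResult, tail: str, alpha: float, require_both: bool) -> bool:
    if res.is_root:
        return False
    if tail == "low":
        p_t, p_a = res.p_low_tip, res.p_low_anc
    else:
        p_t, p_a = res.p_high_tip, res.p_high_anc
    if require_both:
        return p_t <= alpha and p_a <= alpha
    return p_t <= alpha


def filter_and_flag(
    results: list[NodeTestResult],
    tree: Phylogeny,
    traits: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    min_individuals: int = 5,
    require_both: bool = True,
    is_pca_axis: bool = False,
    pca_high_only: bool = True,
) -> FilteredNodeTests:
    """Apply the reporting filters to raw node-test results.

    1. Keep only nodes significant in a tail (under both averaging methods
       when ``require_both``).
    2. Flag nodes containing a species with fewer than ``min_individuals``
       stems; for each such rare species, re-test with that species removed
       (re-pruned tree, same R and seed) and mark the node *dependent* —
       and exclude it — if significance does not survive any removal.
    3. For PCA-axis traits, suppress the low tail from the report (the
       full result list is retained unfiltered in ``all_results``).
    """
    if not results:
        return FilteredNodeTests(trait, is_pca_axis, [], [], [])
    R = results[0].R
    seed = results[0].seed
    counts = traits[COUNT_COLUMN] if COUNT_COLUMN in traits.columns else None

    loo_cache: dict[str, list[NodeTestResult] | None] = {}

    def _loo_results(species: str):
        if species not in loo_cache:
            reduced = traits.drop(index=species)
            try:
                sub_tree, sub_traits, _ = match_taxa(tree, reduced)
                loo_cache[species] = node_permutation_test(
                    sub_tree, sub_traits, trait, R=R, seed=seed, alpha=alpha
                )
            except ValueError:
                loo_cache[species] = None
        return loo_cache[species]

    def _survives_removal(res: NodeTestResult, rare: str, tail: str) -> bool:
        target = frozenset(res.species) - {rare}
        sub = _loo_results(rare)
        if sub is None:
            return False
        for cand in sub:
            if frozenset(cand.species) == target:
                return _significant(cand, tail, alpha, require_both)
        return False  # node vanished with the species

    kept = {"low": [], "high": []}
    for res in results:
        for tail in ("low", "high"):
            if not _significant(res, tail, alpha, require_both):
                continue
            rec = res
            if counts is not None:
                rare = [s for s in res.species if counts.loc[s] < min_individuals]
                if rare:
                    dependent = any(
                        not _survives_removal(res, s, tail) for s in rare
                    )
                    rec = replace(res, min_count_flag=True, dependent_on_rare=dependent)
                    if dependent:
                        continue
            if tail == "low":
                rec = replace(rec, significant_both_low=True)
            else:
                rec = replace(rec, significant_both_high=True)
            kept[tail].append(rec)

    low = [] if (is_pca_axis and pca_high_only) else kept["low"]
    return FilteredNodeTests(
        trait=trait,
        is_pca_axis=is_pca_axis,
        low=low,
        high=kept["high"],
        all_results=list(results),
    )


def write_node_tables(
    filtered: list[FilteredNodeTests], tail: str, path
) -> pd.DataFrame:
    """Write the reportable node records for one tail as a TSV.

    Columns mirror the published layout: trait, the species sharing the
    node, per-species individual counts (same order as the species list),
    the tip-averaged mean, and its tail p value.  Rows sort by trait then
    p.  Returns the frame that was written.
    """
    if tail not in ("low", "high"):
        raise ValueError("tail must be 'low' or 'high'")
    rows = []
    for f in filtered:
        for rec in getattr(f, tail):
            p = rec.p_low_tip if tail == "low" else rec.p_high_tip
            rows.append(
                {
                    "trait": f.trait,
                    "node_species": ",".join(rec.species),
                    "individuals_per_species": ",".join(
                        str(c) for c in (rec.individuals or ())
                    ),
                    "T_mean": rec.tip_mean,
                    "T_p_value": p,
                    "min_count_flag": rec.min_count_flag,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "trait", "node_species", "individuals_per_species",
            "T_mean", "T_p_value", "min_count_flag",
        ],
    )
    if not frame.empty:
        frame = frame.sort_values(["trait", "T_p_value"], kind="stable")
    frame.to_csv(path, sep="\t", index=False)
    return frame
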