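"""Phylogeny I/O, validation, and tree-trait alignment.

The tree container is deliberately small: a rooted node structure with
parent links, branch lengths and (preserved) polytomies.  Newick parsing
and writing go through dendropy; everything downstream (contrasts, node
tests, Brownian simulation) consumes this container directly.

Conventions
-----------
* Tip labels are species codes and are compared by exact, case-sensitive
  string equality.
* Branch lengths are taken in the units of the input tree (time or
  substitutions); the signal statistics are invariant to a global
  rescaling.  A Newick branch without a stated length gets length 1.
* Zero-length terminal branches are rejected (they would break contrast
  standardization); zero-length internal branches are allowed and flagged,
  since collapsing them is how polytomies arise.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "Phylogeny",
    "TreeError",
    "NewickParseError",
    "TreeValidationError",
    "TaxonMismatchError",
    "read_newick",
    "write_newick",
    "match_taxa",
    "phylo_vcv",
    "read_trait_table",
    "write_trait_table",
    "validate_trait_table",
]

COUNT_COLUMN = "n_individuals"


class TreeError(ValueError):
    """Base class for phylogeny errors."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class TreeValidationError(TreeError):
    """Structurally valid tree violating a phylosoil invariant."""


class TaxonMismatchError(TreeError):
    """Tree tips and trait rows share fewer than two species."""


class Node:
    """A node of a rooted phylogeny.

    ``length`` is the branch length to the parent (``None`` for the root).
    """

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class Phylogeny:
    """A rooted phylogeny with branch lengths; polytomies preserved."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- traversal ----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def has_zero_internal_branch(self) -> bool:
        return any(
            (not n.is_leaf) and n.parent is not None and n.length == 0.0
            for n in self.postorder()
        )

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if len(labels) < 2:
            raise TreeValidationError("phylogeny must have at least 2 tips")
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        seen: set[str] = set()
        dups: list[str] = []
        for lbl in labels:
            if lbl in seen and lbl not in dups:
                dups.append(lbl)
            seen.add(lbl)
        if dups:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dups)}")
        for node in self.postorder():
            if node is self.root:
                continue
            if node.length is None or not math.isfinite(node.length):
                raise TreeValidationError(
                    f"non-finite branch length at node {node.label!r}"
                )
            if node.length < 0:
                raise TreeValidationError(
                    f"negative branch length at node {node.label!r}"
                )
            if node.is_leaf and node.length == 0.0:
                raise TreeValidationError(
                    f"zero-length terminal branch at tip {node.label!r}"
                )

    # -- utilities ----------------------------------------------------
    def copy(self) -> "Phylogeny":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return Phylogeny(_copy(self.root), validate=False)

    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + node.length
        return out

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict to the given tip labels, suppressing unary nodes.

        Branch lengths of suppressed unary nodes are summed onto their
        single child so root-to-tip distances are preserved.
        """
        keep_set = set(keep)

        def _prune(node: Node) -> Node | None:
            if node.is_leaf:
                if node.label in keep_set:
                    return Node(node.label, node.length)
                return None
            kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                only = kept[0]
                if node.length is not None and only.length is not None:
                    only.length = only.length + node.length
                elif node.length is None:
                    only.length = None  # promoted to root
                return only
            new = Node(node.label, node.length)
            for c in kept:
                new.add_child(c)
            return new

        new_root = _prune(self.root)
        if new_root is None or new_root.is_leaf:
            raise TreeValidationError("pruning left fewer than 2 tips")
        new_root.length = None
        new_root.parent = None
        return Phylogeny(new_root)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Polytomies are preserved as written.  Parse failures raise
    :class:`NewickParseError` carrying dendropy's character-position
    diagnostics; duplicate tip labels raise :class:`TreeValidationError`
    listing the duplicates.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        msg = str(exc)
        if "duplicate" in msg.lower():
            # dendropy rejects duplicate taxon labels itself; re-raise as the
            # validation error our invariants promise
            raise TreeValidationError(f"duplicate tip labels: {msg}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def _convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        node = Node(label, float(length) if length is not None else None)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        if not node.is_leaf and node.length is None and dnode.parent_node is not None:
            node.length = 1.0
        if node.is_leaf and node.length is None:
            node.length = 1.0
        return node

    root = _convert(dtree.seed_node)
    root.length = None
    return Phylogeny(root)


def _fmt_len(x: float) -> str:
    return repr(float(x))


def write_newick(tree: Phylogeny) -> str:
    def _write(node: Node) -> str:
        if node.is_leaf:
            body = node.label
        else:
            inner = ",".join(_write(c) for c in node.children)
            body = f"({inner})" + (node.label or "")
        if node.length is not None:
            body += f":{_fmt_len(node.length)}"
        return body

    return _write(tree.root) + ";"


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

def validate_trait_table(traits: pd.DataFrame) -> None:
    """Check the trait-table invariants: unique species index, finite
    values, positive integer individual counts."""
    if traits.index.has_duplicates:
        dups = sorted(traits.index[traits.index.duplicated()].unique())
        raise ValueError(f"duplicate species rows: {dups}")
    value_cols = [c for c in traits.columns if c != COUNT_COLUMN]
    vals = traits[value_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = traits.index[~np.isfinite(vals).all(axis=1)].tolist()
        raise ValueError(f"non-finite trait values for species: {bad}")
    if COUNT_COLUMN in traits.columns:
        counts = traits[COUNT_COLUMN]
        if (counts < 1).any():
            bad = traits.index[counts < 1].tolist()
            raise ValueError(f"individual_count < 1 for species: {bad}")


def read_trait_table(path) -> pd.DataFrame:
    """Read a TSV trait table (columns: species, <traits...>, n_individuals)."""
    df = pd.read_csv(path, sep="\t", index_col="species")
    validate_trait_table(df)
    return df


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="species")


# ---------------------------------------------------------------------------
# Tree-trait alignment
# ---------------------------------------------------------------------------

def match_taxa(tree: Phylogeny, traits: pd.DataFrame):
    """Reconcile a phylogeny with a trait table.

    Returns ``(pruned_tree, aligned_traits, report)`` where the pruned tree
    contains exactly the shared species, the trait table is reordered to the
    pruned tree's tip order, and the report lists what was dropped on each
    side.  Fewer than two shared species is a fatal mismatch.  The operation
    is idempotent.
    """
    tip_set = set(tree.tip_labels)
    trait_set = set(traits.index.astype(str))
    shared = tip_set & trait_set
    if len(shared) < 2:
        raise TaxonMismatchError(
            f"only {len(shared)} species shared between tree ({len(tip_set)} tips) "
            f"and trait table ({len(trait_set)} rows); need at least 2"
        )
    dropped_tips = sorted(tip_set - shared)
    dropped_rows = sorted(trait_set - shared)
    pruned = tree.prune_to(shared) if dropped_tips else tree.copy()
    aligned = traits.loc[pruned.tip_labels].copy()
    report = {
        "n_shared": len(shared),
        "dropped_tips": dropped_tips,
        "dropped_trait_rows": dropped_rows,
    }
    return pruned, aligned, report


# ---------------------------------------------------------------------------
# Brownian-motion tip covariance
# ---------------------------------------------------------------------------

def phylo_vcv(tree: Phylogeny, order: list[str] | None = None) -> np.ndarray:
    """Phylogenetic variance-covariance matrix V.

    ``V[i, j]`` is the branch length shared by the root paths of tips *i*
    and *j* (the depth of their most recent common ancestor); the diagonal
    holds root-to-tip distances.  Under Brownian motion with rate sigma^2 the
    tip values have covariance sigma^2 * V.
    """
    tips = tree.tips()
    labels = [t.label for t in tips]
    if order is None:
        order = labels
    index = {lbl: k for k, lbl in enumerate(order)}
    n = len(order)
    V = np.zeros((n, n))
    depths = tree.depths()
    # tip sets per node, assembled in postorder; each tip pair is assigned
    # exactly once, at its MRCA
    tipsets: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            tipsets[node] = [index[node.label]]
            V[index[node.label], index[node.label]] = depths[node]
            continue
        d = depths[node]
        child_sets = [tipsets.pop(c) for c in node.children]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = d
                        V[j, i] = d
        merged: list[int] = []
        for s in child_sets:
            merged.extend(s)
        tipsets[node] = merged
    return V
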