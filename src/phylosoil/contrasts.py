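"""Independent contrasts, phylogeny-wide signal, and Blomberg's K.

Phylogenetic signal — the tendency of related species to resemble each
other more than species drawn at random from the tree — is measured here
with two contrast-based statistics:

* **Phylogeny-wide signal**: the mean absolute standardized contrast over
  all internal nodes, tested against a null built by permuting trait
  values across the tips.  Low observed values (small contrasts between
  relatives) indicate trait conservatism.

* **Blomberg's K**: a ratio-of-ratios comparing the observed
  (MSE0 / MSE) — the trait's variance around the phylogenetic mean over
  its variance under the tree's Brownian covariance — with the value
  expected under Brownian motion.  K = 1 under Brownian evolution, K > 1
  means stronger-than-Brownian conservatism; K is unitless and invariant
  to affine trait transforms and to global branch-length rescaling.

Contrasts follow the standard branch-length standardization: at a
bifurcation with child values x1, x2 on adjusted branches b1, b2 the
contrast is (x1 - x2) / sqrt(b1 + b2), the node's value estimate is the
precision-weighted mean, and the node's own parent branch is lengthened
by b1*b2/(b1+b2).  Polytomies contribute one contrast per node via a
rank-based two-group split (see :func:`_split_polytomy`); the split rule
is isolated so an alternative (e.g. sequential pairwise contrasts) can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .treeio import Phylogeny, phylo_vcv

__all__ = [
    "Contrast",
    "ContrastSet",
    "SignalResult",
    "KResult",
    "independent_contrasts",
    "phylogeny_wide_signal",
    "blomberg_k",
    "k_significance",
    "write_k_table",
]


def _trait_vector(traits, trait: str | None, tip_labels: list[str]) -> np.ndarray:
    """Pull trait values in tip order from a DataFrame / Series / dict."""
    if isinstance(traits, pd.DataFrame):
        if trait is None:
            raise ValueError("trait name required with a trait table")
        series = traits[trait]
    elif isinstance(traits, pd.Series):
        series = traits
    else:
        series = pd.Series(traits)
    missing = [lbl for lbl in tip_labels if lbl not in series.index]
    if missing:
        raise ValueError(f"missing trait value for tips: {missing}")
    x = series.loc[tip_labels].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        bad = [lbl for lbl, v in zip(tip_labels, x) if not np.isfinite(v)]
        raise ValueError(f"non-finite trait value for tips: {bad}")
    return x


# ---------------------------------------------------------------------------
# Contrast engine
# ---------------------------------------------------------------------------

@dataclass
class Contrast:
    node_id: int
    value: float           # standardized contrast
    estimate: float        # node trait estimate passed up the tree
    adjusted_branch: float | None  # node's parent branch after lengthening
    polytomy: bool


@dataclass
class ContrastSet:
    contrasts: list[Contrast]

    @property
    def values(self) -> np.ndarray:
        return np.array([c.value for c in self.contrasts])

    @property
    def n_polytomies(self) -> int:
        return sum(c.polytomy for c in self.contrasts)

    def mean_abs(self) -> float:
        return float(np.mean(np.abs(self.values)))


class _Schedule:
    """Precompiled postorder traversal of a tree for fast repeated passes.

    ``steps`` lists internal nodes in postorder as
    ``(slot, child_slots, child_lengths, is_root)``; tip slots are
    0..n_tips-1 in tip order, internal slots follow.
    """

    def __init__(self, tree: Phylogeny):
        tips = tree.tips()
        self.tip_labels = [t.label for t in tips]
        slot = {id(t): k for k, t in enumerate(tips)}
        self.steps = []
        next_slot = len(tips)
        for node in tree.postorder():
            if node.is_leaf:
                continue
            slot[id(node)] = next_slot
            self.steps.append(
                (
                    next_slot,
                    [slot[id(c)] for c in node.children],
                    [float(c.length) for c in node.children],
                    node is tree.root,
                )
            )
            next_slot += 1
        self.n_slots = next_slot
        self.n_tips = len(tips)


def _split_polytomy(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group split of a polytomy's children by trait rank.

    Children are ordered by value (stable sort, so input order breaks
    ties); the lower half of the ranks — the floor(k/2) smallest — form
    group 1 and the rest group 2, i.e. the split sits at the median of the
    child values.  Returns the two index arrays.
    """
    order = np.argsort(values, kind="stable")
    half = len(values) // 2
    return order[:half], order[half:]


def _contrast_pass(sched: _Schedule, x: np.ndarray):
    """One postorder contrast pass over a precompiled schedule.

    Returns (contrasts, estimates, adjustments, polytomy flags) as plain
    lists, in schedule (postorder-internal) order.  Kept free of pandas
    so permutation nulls can call it in a tight loop.
    """
    values = np.empty(sched.n_slots)
    values[: sched.n_tips] = x
    lengths = np.empty(sched.n_slots)  # contrast adjustment per slot
    contrasts, estimates, adjustments, polys = [], [], [], []
    for slot, child_slots, child_lengths, is_root in sched.steps:
        b = np.array([
            child_lengths[k] + lengths[c] if c >= sched.n_tips else child_lengths[k]
            for k, c in enumerate(child_slots)
        ])
        v = values[list(child_slots)]
        if np.any(b <= 0):
            raise ValueError("non-positive adjusted branch length at an internal node")
        w = 1.0 / b
        if len(child_slots) == 2:
            contrast = (v[0] - v[1]) / np.sqrt(b[0] + b[1])
            poly = False
            g1w, g2w = w[0], w[1]
        else:
            i1, i2 = _split_polytomy(v)
            g1w = w[i1].sum()
            g2w = w[i2].sum()
            m1 = (w[i1] @ v[i1]) / g1w
            m2 = (w[i2] @ v[i2]) / g2w
            contrast = (m1 - m2) / np.sqrt(1.0 / g1w + 1.0 / g2w)
            poly = True
        B1, B2 = 1.0 / g1w, 1.0 / g2w
        estimate = float(w @ v / w.sum())
        values[slot] = estimate
        adjustment = B1 * B2 / (B1 + B2)
        lengths[slot] = adjustment  # added to this node's own branch by parent
        contrasts.append(float(contrast))
        estimates.append(estimate)
        adjustments.append(None if is_root else adjustment)
        polys.append(poly)
    return contrasts, estimates, adjustments, polys


def independent_contrasts(
    tree: Phylogeny, traits, trait: str | None = None
) -> ContrastSet:
    """Standardized independent contrasts, one per internal node.

    Polytomies yield a single contrast between the branch-length-weighted
    means of a rank-based two-group split of the children; group branch
    lengths combine harmonically (group precision = sum of child
    precisions), so the node estimate and the parent-branch lengthening
    reduce to the usual formulas at bifurcations.
    """
    sched = _Schedule(tree)
    x = _trait_vector(traits, trait, sched.tip_labels)
    contrasts, estimates, adjustments, polys = _contrast_pass(sched, x)
    out = [
        Contrast(
            node_id=sched.n_tips + k,
            value=c,
            estimate=e,
            adjusted_branch=a,
            polytomy=p,
        )
        for k, (c, e, a, p) in enumerate(zip(contrasts, estimates, adjustments, polys))
    ]
    return ContrastSet(out)


# ---------------------------------------------------------------------------
# Phylogeny-wide signal
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    """Mean-|contrast| signal with a tip-shuffle permutation null.

    ``p_low`` is the conservatism tail (observed mean contrast unusually
    small); p values use the (r + 1) / (R + 1) rule with ties counted as
    extreme.
    """

    observed: float
    null: np.ndarray
    p_low: float
    p_high: float
    R: int
    seed: int | None


def _perm_p(null: np.ndarray, observed: float) -> tuple[float, float]:
    R = len(null)
    tol = 1e-9 * max(1.0, abs(observed))
    p_low = (np.count_nonzero(null <= observed + tol) + 1) / (R + 1)
    p_high = (np.count_nonzero(null >= observed - tol) + 1) / (R + 1)
    return float(p_low), float(p_high)


def phylogeny_wide_signal(
    tree: Phylogeny, traits, trait: str | None = None,
    R: int = 999, seed: int | None = None,
) -> SignalResult:
    """Phylogeny-wide signal: mean |contrast| against R tip shuffles."""
    if R < 1:
        raise ValueError("R must be >= 1")
    sched = _Schedule(tree)
    x = _trait_vector(traits, trait, sched.tip_labels)
    observed = float(np.mean(np.abs(_contrast_pass(sched, x)[0])))
    rng = np.random.default_rng(seed)
    null = np.empty(R)
    for r in range(R):
        null[r] = np.mean(np.abs(_contrast_pass(sched, rng.permutation(x))[0]))
    p_low, p_high = _perm_p(null, observed)
    return SignalResult(observed, null, p_low, p_high, R, seed)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

@dataclass
class KResult:
    K: float
    MSE0: float
    MSE: float
    observed_ratio: float
    expected_ratio: float
    p_two_tailed: float | None = None
    R: int | None = None
    seed: int | None = None
    ridged: bool = False
    null: np.ndarray | None = field(default=None, repr=False)


class _KEngine:
    """Precomputed V-dependent pieces so K is cheap per trait vector."""

    def __init__(self, tree: Phylogeny):
        self.tip_labels = tree.tip_labels
        V = phylo_vcv(tree)
        self.ridged = False
        if tree.has_zero_internal_branch:
            V = V + 1e-8 * np.mean(np.diag(V)) * np.eye(len(V))
            self.ridged = True
        n = V.shape[0]
        try:
            self._cho = cho_factor(V)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"phylogenetic covariance matrix is singular: {exc}")
        ones = np.ones(n)
        self._Vinv_1 = cho_solve(self._cho, ones)
        self._sum_Vinv = float(ones @ self._Vinv_1)
        self.n = n
        self.expected_ratio = (np.trace(V) - n / self._sum_Vinv) / (n - 1)

    def k_many(self, X: np.ndarray) -> np.ndarray:
        """K for each column of the (n x m) trait matrix X."""
        a_hat = (self._Vinv_1 @ X) / self._sum_Vinv
        D = X - a_hat[np.newaxis, :]
        MSE0 = np.sum(D * D, axis=0) / (self.n - 1)
        Y = cho_solve(self._cho, D)
        MSE = np.sum(D * Y, axis=0) / (self.n - 1)
        return (MSE0 / MSE) / self.expected_ratio

    def k_one(self, x: np.ndarray) -> tuple[float, float, float]:
        a_hat = float(self._Vinv_1 @ x) / self._sum_Vinv
        d = x - a_hat
        MSE0 = float(d @ d) / (self.n - 1)
        MSE = float(d @ cho_solve(self._cho, d)) / (self.n - 1)
        return MSE0, MSE, a_hat


def blomberg_k(tree: Phylogeny, traits, trait: str | None = None) -> KResult:
    """Blomberg's K (no significance test).

    K = (MSE0/MSE) / E[MSE0/MSE | Brownian motion], with MSE0 the trait
    variance around the phylogenetic (GLS) mean and MSE the
    V-standardized variance.  Requires a non-constant trait; a zero
    internal branch triggers a tiny diagonal ridge on V (flagged).
    """
    engine = _KEngine(tree)
    x = _trait_vector(traits, trait, engine.tip_labels)
    if np.allclose(x, x[0]):
        raise ValueError("trait is constant across tips; K is undefined")
    MSE0, MSE, _ = engine.k_one(x)
    ratio = MSE0 / MSE
    return KResult(
        K=float(ratio / engine.expected_ratio),
        MSE0=MSE0,
        MSE=MSE,
        observed_ratio=float(ratio),
        expected_ratio=float(engine.expected_ratio),
        ridged=engine.ridged,
    )


def k_significance(
    tree: Phylogeny, traits, trait: str | None = None,
    R: int = 999, seed: int | None = None, keep_null: bool = False,
) -> KResult:
    """Blomberg's K with a two-tailed tip-shuffle permutation p value.

    The null distribution is K recomputed on R random reassignments of
    trait values to tips; p doubles the smaller tail ((r+1)/(R+1) per
    tail, ties extreme) and is capped at 1.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    engine = _KEngine(tree)
    x = _trait_vector(traits, trait, engine.tip_labels)
    if np.allclose(x, x[0]):
        raise ValueError("trait is constant across tips; K is undefined")
    MSE0, MSE, _ = engine.k_one(x)
    K_obs = float((MSE0 / MSE) / engine.expected_ratio)
    rng = np.random.default_rng(seed)
    perms = np.empty((engine.n, R))
    for r in range(R):
        perms[:, r] = rng.permutation(x)
    null = engine.k_many(perms)
    p_low, p_high = _perm_p(null, K_obs)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return KResult(
        K=K_obs,
        MSE0=MSE0,
        MSE=MSE,
        observed_ratio=float(MSE0 / MSE),
        expected_ratio=float(engine.expected_ratio),
        p_two_tailed=p,
        R=R,
        seed=seed,
        ridged=engine.ridged,
        null=null if keep_null else None,
    )


def write_k_table(results: dict[str, KResult], path) -> None:
    """TSV of K and two-tailed p per trait (one row per trait)."""
    with open(path, "w") as fh:
        fh.write("Trait\tK\tP value\n")
        for trait, res in results.items():
            p = "" if res.p_two_tailed is None else f"{res.p_two_tailed:.3f}"
            fh.write(f"{trait}\t{res.K:.2f}\t{p}\n")
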