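import subprocess

import numpy as np
import pandas as pd
import pytest

import phylosoil as ps
from phylosoil.contrasts import _perm_p

from conftest import random_tree


# ---------------------------------------------------------------------------
# Independent brute-force oracle: a from-scratch recursive implementation of
# the contrast rules (bifurcation formulas; polytomies split into the
# floor(k/2) lowest-ranked children vs the rest, groups combined by
# precision weighting).  Shares no code with the engine under test.
# ---------------------------------------------------------------------------

def oracle_contrasts(tree, trait_map):
    contrasts = []

    def visit(node):
        """Returns (value, total_branch) where total_branch includes the
        node's own branch plus any contrast adjustment."""
        if node.is_leaf:
            return trait_map[node.label], node.length
        pairs = [visit(c) for c in node.children]
        vals = [p[0] for p in pairs]
        brs = [p[1] for p in pairs]
        if len(pairs) == 2:
            (x1, b1), (x2, b2) = pairs
            contrasts.append((x1 - x2) / (b1 + b2) ** 0.5)
        else:
            ranked = sorted(range(len(vals)), key=lambda i: (vals[i], i))
            half = len(vals) // 2
            g1, g2 = ranked[:half], ranked[half:]
            p1 = sum(1.0 / brs[i] for i in g1)
            p2 = sum(1.0 / brs[i] for i in g2)
            m1 = sum(vals[i] / brs[i] for i in g1) / p1
            m2 = sum(vals[i] / brs[i] for i in g2) / p2
            b1, b2 = 1.0 / p1, 1.0 / p2
            contrasts.append((m1 - m2) / (b1 + b2) ** 0.5)
            x1, x2 = m1, m2
        prec = sum(1.0 / b for b in brs)
        est = sum(v / b for v, b in zip(vals, brs)) / prec
        b1b2 = b1 * b2 / (b1 + b2)
        own = node.length if node.length is not None else 0.0
        return est, own + b1b2

    visit(tree.root)
    return contrasts


class TestIndependentContrasts:
    def test_two_tip_hand_value(self):
        tree = ps.read_newick("(A:1,B:1);")
        cs = ps.independent_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert cs.values[0] == pytest.approx(2 / np.sqrt(2))

    def test_equal_traits_zero_contrasts(self):
        tree = random_tree(np.random.default_rng(0), 9)
        cs = ps.independent_contrasts(tree, {t: 4.2 for t in tree.tip_labels})
        np.testing.assert_allclose(cs.values, 0.0, atol=1e-12)

    def test_four_tip_adjusted_branches(self, cherry_pair_tree, cherry_pair_traits):
        cs = ps.independent_contrasts(cherry_pair_tree, cherry_pair_traits)
        vals = sorted(np.round(cs.values, 5))
        assert vals == [-5.7735, 0.0, 0.0]
        # root-child branches adjusted from 1 to 1.5 => root contrast 10/sqrt(3)
        assert cs.mean_abs() == pytest.approx(1.9245, abs=1e-4)

    def test_missing_trait_named(self):
        tree = ps.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            ps.independent_contrasts(tree, {"A": 1.0})

    def test_matches_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(2, 9))
            tree = random_tree(rng, n)
            traits = {t: float(rng.normal()) for t in tree.tip_labels}
            got = np.sort(ps.independent_contrasts(tree, traits).values)
            want = np.sort(oracle_contrasts(tree, traits))
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_polytomy_flagged(self):
        tree = ps.read_newick("(A:1,B:1,C:1);")
        cs = ps.independent_contrasts(tree, {"A": 0.0, "B": 1.0, "C": 5.0})
        assert cs.n_polytomies == 1


def test_brownian_contrasts_have_rate_variance():
    """Under Brownian motion, standardized contrasts are ~N(0, sigma^2):
    the pooled contrast variance matches the simulation rate."""
    sigma2 = 2.0
    tree = ps.simulate_tree(20, seed=31)
    vals = []
    for k in range(300):
        x = ps.simulate_bm(tree, sigma2, seed=4000 + k)
        vals.extend(ps.independent_contrasts(tree, x).values)
    vals = np.asarray(vals)
    assert abs(vals.mean()) < 0.05
    assert abs(vals.var(ddof=1) / sigma2 - 1.0) < 0.1


class TestPhylogenyWideSignal:
    def test_equal_traits_all_ties(self, cherry_pair_tree):
        sig = ps.phylogeny_wide_signal(
            cherry_pair_tree, {t: 1.0 for t in "ABCD"}, R=99, seed=0
        )
        assert sig.observed == 0.0
        assert sig.p_low == 1.0

    def test_worked_example_exact_vs_mc(self, cherry_pair_tree, cherry_pair_traits):
        sig = ps.phylogeny_wide_signal(
            cherry_pair_tree, cherry_pair_traits, R=999, seed=1
        )
        assert sig.observed == pytest.approx(1.9245, abs=1e-4)
        se = np.sqrt((1 / 3) * (2 / 3) / 999)
        assert abs(sig.p_low - 1 / 3) < 3 * se

    def test_extremes_of_p_rule(self):
        # direct check of the (r+1)/(R+1) arithmetic with ties extreme
        null = np.linspace(1.0, 2.0, 999)
        p_low, p_high = _perm_p(null, 0.5)   # observed below every draw
        assert p_low == pytest.approx(1 / 1000)
        assert p_high == 1.0
        p_low, _ = _perm_p(null, null[4])     # ties count as extreme
        assert p_low == pytest.approx(6 / 1000)

    def test_invalid_R(self, cherry_pair_tree, cherry_pair_traits):
        with pytest.raises(ValueError):
            ps.phylogeny_wide_signal(cherry_pair_tree, cherry_pair_traits, R=0)

    def test_p_uniform_under_exchangeable_traits(self):
        """Tip-exchangeable traits give uniform permutation p values
        (KS test over 500 replicates at alpha = 0.01)."""
        from scipy.stats import kstest
        tree = ps.simulate_tree(8, seed=55)
        rng = np.random.default_rng(3)
        p_low = []
        for _ in range(500):
            x = pd.Series(rng.normal(size=8), index=tree.tip_labels)
            sig = ps.phylogeny_wide_signal(tree, x, R=199,
                                           seed=int(rng.integers(1 << 30)))
            p_low.append(sig.p_low)
        _, ks_p = kstest(p_low, "uniform")
        assert ks_p > 0.01

    def test_seed_reproducible(self, cherry_pair_tree, cherry_pair_traits):
        a = ps.phylogeny_wide_signal(cherry_pair_tree, cherry_pair_traits, R=99, seed=7)
        b = ps.phylogeny_wide_signal(cherry_pair_tree, cherry_pair_traits, R=99, seed=7)
        np.testing.assert_array_equal(a.null, b.null)


class TestBlombergK:
    def test_star_tree_identity(self):
        tree = ps.read_newick("(A:2,B:2,C:2,D:2,E:2);")
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=5), index=list("ABCDE"))
        assert ps.blomberg_k(tree, x).K == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self):
        tree = random_tree(np.random.default_rng(1), 12, polytomy_prob=0.0)
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=12), index=tree.tip_labels)
        k1 = ps.blomberg_k(tree, x).K
        k2 = ps.blomberg_k(tree, -3.5 * x + 11.0).K
        assert k1 == pytest.approx(k2, rel=1e-10)

    def test_branch_rescale_invariance(self):
        tree = random_tree(np.random.default_rng(3), 10, polytomy_prob=0.0)
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=10), index=tree.tip_labels)
        k1 = ps.blomberg_k(tree, x).K
        scaled = tree.copy()
        for node in scaled.postorder():
            if node.length is not None:
                node.length *= 7.25
        assert ps.blomberg_k(scaled, x).K == pytest.approx(k1, rel=1e-9)

    def test_constant_trait_rejected(self):
        tree = ps.read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="constant"):
            ps.blomberg_k(tree, {"A": 2.0, "B": 2.0, "C": 2.0})

    def test_zero_internal_branch_ridged(self):
        tree = ps.read_newick("((A:1,B:1):0,C:2);")
        res = ps.blomberg_k(tree, {"A": 1.0, "B": 2.0, "C": 5.0})
        assert res.ridged and np.isfinite(res.K)

    def test_matches_picante(self, tmp_path):
        """Independent oracle: Kcalc from the R package picante."""
        tree = ps.simulate_tree(12, seed=99)
        x = ps.simulate_bm(tree, 1.0, seed=100)
        (tmp_path / "tree.nwk").write_text(tree.to_newick() + "\n")
        x.rename("x").to_csv(tmp_path / "traits.csv")
        script = """
        suppressMessages(library(picante))
        tree <- read.tree(commandArgs(TRUE)[1])
        tab <- read.csv(commandArgs(TRUE)[2], row.names=1)
        x <- setNames(tab$x, rownames(tab))[tree$tip.label]
        cat(sprintf("%.10f", Kcalc(x, tree)))
        """
        out = subprocess.run(
            ["Rscript", "-e", script, str(tmp_path / "tree.nwk"),
             str(tmp_path / "traits.csv")],
            capture_output=True, text=True, check=True,
        )
        k_picante = float(out.stdout.strip())
        assert ps.blomberg_k(tree, x).K == pytest.approx(k_picante, abs=1e-6)


class TestKSignificance:
    def test_two_tailed_doubling_rule(self):
        tree = ps.simulate_tree(20, seed=5)
        x = ps.simulate_bm(tree, 1.0, seed=6)
        res = ps.k_significance(tree, x, R=199, seed=7, keep_null=True)
        tol = 1e-9 * max(1.0, abs(res.K))
        lo = (np.count_nonzero(res.null <= res.K + tol) + 1) / 200
        hi = (np.count_nonzero(res.null >= res.K - tol) + 1) / 200
        assert res.p_two_tailed == pytest.approx(min(1.0, 2 * min(lo, hi)))

    def test_conserved_trait_significant_high(self):
        # deep two-clade tree with strongly separated values: K large, p small
        labels = [f"t{i}" for i in range(16)]
        left = ",".join(f"{t}:1" for t in labels[:8])
        right = ",".join(f"{t}:1" for t in labels[8:])
        tree = ps.read_newick(f"(({left}):9,({right}):9);")
        rng = np.random.default_rng(8)
        x = pd.Series(np.r_[rng.normal(0, 0.1, 8), rng.normal(10, 0.1, 8)],
                      index=labels)
        res = ps.k_significance(tree, x, R=999, seed=8)
        assert res.K > 1.0
        assert res.p_two_tailed <= 0.01

    def test_seeded_determinism(self):
        tree = ps.simulate_tree(15, seed=9)
        x = ps.simulate_bm(tree, 1.0, seed=10)
        r1 = ps.k_significance(tree, x, R=99, seed=11)
        r2 = ps.k_significance(tree, x, R=99, seed=11)
        assert r1.p_two_tailed == r2.p_two_tailed


def test_k_table_writer(tmp_path):
    tree = ps.simulate_tree(10, seed=12)
    traits = pd.DataFrame(
        {"P": ps.simulate_bm(tree, 1.0, seed=13),
         "Al": ps.simulate_bm(tree, 1.0, seed=14)}
    )
    results = {t: ps.k_significance(tree, traits, t, R=99, seed=15) for t in traits}
    from phylosoil.contrasts import write_k_table
    path = tmp_path / "k.tsv"
    write_k_table(results, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0] == "Trait\tK\tP value"
    assert len(lines) == 3
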