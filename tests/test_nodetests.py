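import numpy as np
import pandas as pd
import pytest

import phylosoil as ps
from phylosoil.nodetests import write_node_tables

from conftest import random_tree


def _table(values: dict, counts: dict | None = None) -> pd.DataFrame:
    df = pd.DataFrame({"P": pd.Series(values, dtype=float)})
    df.index.name = "species"
    df["n_individuals"] = pd.Series(counts) if counts else 10
    return df


class TestMeans:
    def test_cherry_mean(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        tips = ps.tip_means(tree, {"A": 2.0, "B": 4.0, "C": 9.0})
        assert tips[0] == 3.0        # cherry node first in postorder
        assert tips[1] == 5.0        # root = grand mean

    def test_ancestral_differs_on_imbalance(self):
        tree = ps.read_newick("((A:1,B:1):1,C:1);")
        traits = {"A": 0.0, "B": 0.0, "C": 6.0}
        tips = ps.tip_means(tree, traits)
        anc = ps.ancestral_means(tree, traits)
        assert tips[0] == 0.0 and anc[0] == 0.0
        assert tips[1] == 2.0            # root tip average
        assert anc[1] == 3.0             # root daughter average

    def test_balanced_tree_methods_agree(self):
        tree = ps.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rng = np.random.default_rng(0)
        traits = {t: float(rng.normal()) for t in "ABCD"}
        tips = ps.tip_means(tree, traits)
        anc = ps.ancestral_means(tree, traits)
        for k in tips:
            assert tips[k] == pytest.approx(anc[k], abs=1e-12)

    def test_root_equals_grand_mean(self):
        tree = random_tree(np.random.default_rng(1), 11)
        traits = {t: float(np.random.default_rng(2).normal()) for t in tree.tip_labels}
        traits = {t: float(v) for t, v in zip(tree.tip_labels,
                                              np.random.default_rng(2).normal(size=11))}
        tips = ps.tip_means(tree, traits)
        root_mean = tips[max(tips)]  # root is last in postorder numbering
        assert root_mean == pytest.approx(np.mean(list(traits.values())), abs=1e-12)


class TestNodePermutationTest:
    def test_root_p_is_one(self, cherry_pair_tree, cherry_pair_traits):
        res = ps.node_permutation_test(
            cherry_pair_tree, cherry_pair_traits, R=999, seed=0
        )
        root = [r for r in res if r.is_root][0]
        assert root.p_low_tip == 1.0 and root.p_high_tip == 1.0

    def test_worked_example_node_p(self, cherry_pair_tree, cherry_pair_traits):
        res = ps.node_permutation_test(
            cherry_pair_tree, cherry_pair_traits, R=999, seed=1
        )
        cd = [r for r in res if set(r.species) == {"C", "D"}][0]
        assert cd.tip_mean == 10.0
        se = np.sqrt((1 / 6) * (5 / 6) / 999)
        assert abs(cd.p_high_tip - 1 / 6) < 3 * se

    def test_shared_stream_and_determinism(self, cherry_pair_tree, cherry_pair_traits):
        r1 = ps.node_permutation_test(cherry_pair_tree, cherry_pair_traits, R=99, seed=3)
        r2 = ps.node_permutation_test(cherry_pair_tree, cherry_pair_traits, R=99, seed=3)
        for a, b in zip(r1, r2):
            assert (a.p_low_tip, a.p_high_anc) == (b.p_low_tip, b.p_high_anc)

    def test_species_lists_partition(self):
        tree = random_tree(np.random.default_rng(4), 10)
        traits = _table({t: v for t, v in zip(
            tree.tip_labels, np.random.default_rng(5).normal(size=10))})
        res = ps.node_permutation_test(tree, traits, "P", R=49, seed=6)
        root = [r for r in res if r.is_root][0]
        assert sorted(root.species) == sorted(tree.tip_labels)
        # each non-root node's species are a subset of the root's
        for r in res:
            assert set(r.species) <= set(root.species)

    def test_individual_counts_attached_in_species_order(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        tbl = _table({"A": 1.0, "B": 2.0, "C": 3.0}, {"A": 4, "B": 9, "C": 2})
        res = ps.node_permutation_test(tree, tbl, "P", R=49, seed=7)
        cherry = [r for r in res if set(r.species) == {"A", "B"}][0]
        assert dict(zip(cherry.species, cherry.individuals)) == {"A": 4, "B": 9}

    def test_bad_parameters(self, cherry_pair_tree, cherry_pair_traits):
        with pytest.raises(ValueError):
            ps.node_permutation_test(cherry_pair_tree, cherry_pair_traits, R=0)
        with pytest.raises(ValueError):
            ps.node_permutation_test(cherry_pair_tree, cherry_pair_traits,
                                     R=9, alpha=0.6)

    def test_require_both_never_less_conservative(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            tree = random_tree(rng, 12)
            tbl = _table(dict(zip(tree.tip_labels, rng.normal(size=12))))
            res = ps.node_permutation_test(tree, tbl, "P", R=199,
                                           seed=int(rng.integers(1 << 30)))
            for tail in ("low", "high"):
                both = sum(
                    getattr(r, f"p_{tail}_tip") <= 0.05
                    and getattr(r, f"p_{tail}_anc") <= 0.05
                    for r in res if not r.is_root
                )
                tip_only = sum(
                    getattr(r, f"p_{tail}_tip") <= 0.05
                    for r in res if not r.is_root
                )
                assert both <= tip_only


class TestFilterAndFlag:
    """Fixtures around an 8-tip tree where clade (A,B,C) = ((A,B),C)."""

    NEWICK = ("(((A:1,B:1):1,C:2):3,"
              "(D:1,E:1,F:1,G:1,H:1):3);")

    def _run(self, values, counts, **kwargs):
        tree = ps.read_newick(self.NEWICK)
        tbl = _table(values, counts)
        res = ps.node_permutation_test(tree, tbl, "P", R=999, seed=11)
        return ps.filter_and_flag(res, tree, tbl, "P", **kwargs), res

    def test_all_counts_high_no_flag(self):
        values = {"A": 8.0, "B": 9.0, "C": 10.0,
                  "D": 0.0, "E": 0.3, "F": -0.2, "G": 0.1, "H": -0.1}
        counts = {s: 100 for s in values}
        filtered, _ = self._run(values, counts)
        abc = [r for r in filtered.high if set(r.species) == {"A", "B", "C"}]
        assert abc and not abc[0].min_count_flag

    def test_rare_species_removal_destroys_significance(self):
        # clade (((A,B),C),R): R is a 1-individual species carrying a huge
        # value amid 120 mild tips, so any node containing R is significant
        # while (A,B,C) alone is unremarkable
        rng = np.random.default_rng(13)
        others = [f"o{k}" for k in range(120)]
        star = ",".join(f"{t}:3" for t in others)
        tree = ps.read_newick(f"((((A:1,B:1):1,C:2):1,R:3):1,{star});")
        values = {t: float(v) for t, v in zip(others, rng.normal(size=120))}
        values.update({"A": 0.1, "B": -0.1, "C": 0.05, "R": 1000.0})
        counts = {s: 100 for s in values}
        counts["R"] = 1
        tbl = _table(values, counts)
        res = ps.node_permutation_test(tree, tbl, "P", R=999, seed=11)
        raw = [r for r in res if set(r.species) == {"A", "B", "C", "R"}][0]
        assert raw.p_high_tip <= 0.05 and raw.p_high_anc <= 0.05
        filtered = ps.filter_and_flag(res, tree, tbl, "P")
        assert all("R" not in r.species for r in filtered.high)

    def test_rare_species_removal_preserves_significance(self):
        values = {"A": 28.0, "B": 29.0, "C": 30.0,
                  "D": 0.0, "E": 0.3, "F": -0.2, "G": 0.1, "H": -0.1}
        counts = {s: 100 for s in values}
        counts["C"] = 1
        filtered, _ = self._run(values, counts)
        abc = [r for r in filtered.high if set(r.species) == {"A", "B", "C"}]
        assert abc
        assert abc[0].min_count_flag and not abc[0].dependent_on_rare

    def test_require_both_drops_tip_only_nodes(self):
        rng = np.random.default_rng(12)
        found = False
        for trial in range(40):
            tree = random_tree(rng, 14)
            tbl = _table(dict(zip(tree.tip_labels, rng.normal(size=14))))
            res = ps.node_permutation_test(tree, tbl, "P", R=199, seed=trial)
            tip_only = [
                r for r in res if not r.is_root
                and r.p_high_tip <= 0.05 < r.p_high_anc
            ]
            if not tip_only:
                continue
            found = True
            filtered = ps.filter_and_flag(res, tree, tbl, "P", require_both=True)
            highs = {frozenset(r.species) for r in filtered.high}
            for r in tip_only:
                assert frozenset(r.species) not in highs
        assert found, "no tip-only-significant node arose in 40 trials"

    def test_pca_low_tail_suppressed_but_retained(self):
        values = {"A": -8.0, "B": -9.0, "C": -10.0,
                  "D": 0.0, "E": 0.3, "F": -0.2, "G": 0.1, "H": -0.1}
        counts = {s: 100 for s in values}
        filtered, _ = self._run(values, counts, is_pca_axis=True)
        assert filtered.low == []
        assert any(
            r.p_low_tip <= 0.05 for r in filtered.all_results if not r.is_root
        )
        as_soil, _ = self._run(values, counts, is_pca_axis=False)
        assert any(set(r.species) == {"A", "B", "C"} for r in as_soil.low)


class TestWriters:
    def test_table_layout_and_sorting(self, tmp_path):
        tree = ps.read_newick("(((A:1,B:1):1,C:2):3,(D:1,E:1,F:1,G:1,H:1):3);")
        values = {"A": 8.0, "B": 9.0, "C": 10.0,
                  "D": 0.0, "E": 0.3, "F": -0.2, "G": 0.1, "H": -0.1}
        tbl = _table(values, {s: 50 for s in values})
        res = ps.node_permutation_test(tree, tbl, "P", R=999, seed=13)
        filtered = ps.filter_and_flag(res, tree, tbl, "P")
        path = tmp_path / "high.tsv"
        frame = write_node_tables([filtered], "high", path)
        assert list(frame.columns)[:5] == [
            "trait", "node_species", "individuals_per_species", "T_mean", "T_p_value"
        ]
        assert (frame["T_p_value"].diff().dropna() >= 0).all()
        for _, row in frame.iterrows():
            assert len(row["node_species"].split(",")) == \
                len(row["individuals_per_species"].split(","))

    def test_empty_report_is_header_only(self, tmp_path):
        from phylosoil.nodetests import FilteredNodeTests
        path = tmp_path / "empty.tsv"
        write_node_tables([FilteredNodeTests("P", False, [], [], [])], "low", path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1 and lines[0].startswith("trait")
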