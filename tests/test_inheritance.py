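import itertools

import numpy as np
import pandas as pd
import pytest

from m6akit.errors import ParameterError, StructureError
from m6akit.inheritance import (InheritanceTable, aggregate_group_fraction,
                                classify_inheritance, stage_fractions)
from m6akit.io import HierarchyTree
from m6akit.landscape import M6ALandscape


def landscape_from_targets(target_sets: dict[str, set[str]],
                           universe: list[str]) -> M6ALandscape:
    """Landscape where every gene is scored everywhere; z values arbitrary."""
    pops = list(target_sets)
    z = pd.DataFrame(0.0, index=pd.Index(universe, name="gene_id"), columns=pops)
    is_target = pd.DataFrame(False, index=z.index, columns=pops, dtype="boolean")
    for pop, genes in target_sets.items():
        is_target.loc[sorted(genes), pop] = True
    return M6ALandscape(z, is_target)


def brute_force_origin(target_sets, tree: HierarchyTree, pop: str, gene: str,
                       mode: str) -> str:
    """Independent oracle: enumerate the root path explicitly."""
    if pop == tree.root:
        return "root_set"
    path = []
    cur = pop
    while cur != tree.root:
        cur = tree.parent[cur]
        path.append(cur)
    if mode == "parent":
        path = path[:1]
    for anc in path:
        if anc in target_sets and gene in target_sets[anc]:
            return "inherited"
    return "de_novo"


class TestClassify:
    def test_chain_inherited(self):
        tree = HierarchyTree(["SSC", "pBCSP"], [("SSC", "pBCSP")])
        ls = landscape_from_targets({"SSC": {"G1"}, "pBCSP": {"G1"}}, ["G1"])
        table = classify_inheritance(ls, tree).table.set_index(["population", "gene_id"])
        assert table.loc[("pBCSP", "G1"), "origin"] == "inherited"
        assert table.loc[("pBCSP", "G1"), "evidence"] == "SSC"
        assert table.loc[("SSC", "G1"), "origin"] == "root_set"

    def test_leaf_only_de_novo(self, chain_tree):
        ls = landscape_from_targets(
            {p: set() for p in ["SSC", "pBCSP", "BCSP"]} | {"Thy": {"G2"}},
            ["G2"])
        table = classify_inheritance(ls, chain_tree).table
        assert table["origin"].tolist() == ["de_novo"]

    def test_mode_contrast_skipped_generation(self):
        tree = HierarchyTree(["SSC", "pBCSP", "BCSP"],
                             [("SSC", "pBCSP"), ("pBCSP", "BCSP")])
        ls = landscape_from_targets(
            {"SSC": {"G3"}, "pBCSP": set(), "BCSP": {"G3"}}, ["G3"])
        any_anc = classify_inheritance(ls, tree, mode="any_ancestor").table
        parent = classify_inheritance(ls, tree, mode="parent").table
        row_a = any_anc[any_anc["population"] == "BCSP"].iloc[0]
        row_p = parent[parent["population"] == "BCSP"].iloc[0]
        assert row_a["origin"] == "inherited" and row_a["evidence"] == "SSC"
        assert row_p["origin"] == "de_novo"

    def test_unknown_population_errors(self, chain_tree):
        ls = landscape_from_targets({"XXX": {"G1"}}, ["G1"])
        with pytest.raises(StructureError):
            classify_inheritance(ls, chain_tree)

    def test_bad_mode(self, chain_tree):
        ls = landscape_from_targets({"SSC": set()}, ["G1"])
        with pytest.raises(ParameterError):
            classify_inheritance(ls, chain_tree, mode="sideways")

    def test_missing_cell_counts_as_absent(self):
        # G1 unscored (NaN) in the parent: inheritance needs positive evidence
        tree = HierarchyTree(["A", "B"], [("A", "B")])
        z = pd.DataFrame({"A": [np.nan], "B": [1.0]},
                         index=pd.Index(["G1"], name="gene_id"))
        is_target = pd.DataFrame({"A": [pd.NA], "B": [True]}, index=z.index,
                                 dtype="boolean")
        table = classify_inheritance(M6ALandscape(z, is_target), tree).table
        assert table.iloc[0]["origin"] == "de_novo"


def random_trees_upto_5_nodes():
    """All rooted trees on 2..5 labeled nodes via parent-assignment vectors."""
    trees = []
    for n in range(2, 6):
        names = [f"N{i}" for i in range(n)]
        # node 0 is the root; node i>0 picks any lower-indexed node as parent
        for parents in itertools.product(*[range(i) for i in range(1, n)]):
            edges = [(names[p], names[i + 1]) for i, p in enumerate(parents)]
            trees.append(HierarchyTree(names, edges))
    return trees


class TestExhaustiveOracle:
    @pytest.mark.parametrize("mode", ["parent", "any_ancestor"])
    def test_all_small_trees(self, mode):
        rng = np.random.default_rng(17)
        genes = [f"G{i}" for i in range(20)]
        for tree in random_trees_upto_5_nodes():
            target_sets = {
                pop: {g for g in genes if rng.random() < 0.4}
                for pop in tree.nodes
            }
            ls = landscape_from_targets(target_sets, genes)
            table = classify_inheritance(ls, tree, mode=mode).table
            for _, row in table.iterrows():
                expected = brute_force_origin(target_sets, tree,
                                              row["population"],
                                              row["gene_id"], mode)
                assert row["origin"] == expected

    def test_partition_invariant(self, chain_tree):
        rng = np.random.default_rng(23)
        genes = [f"G{i}" for i in range(30)]
        target_sets = {pop: {g for g in genes if rng.random() < 0.5}
                       for pop in chain_tree.nodes}
        ls = landscape_from_targets(target_sets, genes)
        table = classify_inheritance(ls, chain_tree)
        fr = stage_fractions(table).set_index("population")
        for pop in chain_tree.nodes:
            if pop == chain_tree.root or fr.loc[pop, "n_targets"] == 0:
                continue
            assert fr.loc[pop, "frac_inherited"] + fr.loc[pop, "frac_de_novo"] \
                == pytest.approx(1.0)

    def test_any_ancestor_never_less_inherited(self):
        rng = np.random.default_rng(29)
        genes = [f"G{i}" for i in range(20)]
        for tree in random_trees_upto_5_nodes()[::7]:
            target_sets = {pop: {g for g in genes if rng.random() < 0.4}
                           for pop in tree.nodes}
            ls = landscape_from_targets(target_sets, genes)
            t_parent = classify_inheritance(ls, tree, mode="parent").table
            t_any = classify_inheritance(ls, tree, mode="any_ancestor").table
            n_p = (t_parent["origin"] == "inherited").sum()
            n_a = (t_any["origin"] == "inherited").sum()
            assert n_a >= n_p


class TestFractions:
    def test_stage_fraction_arithmetic(self):
        table = InheritanceTable(pd.DataFrame({
            "population": ["B"] * 4,
            "gene_id": ["G1", "G2", "G3", "G4"],
            "origin": ["inherited"] * 3 + ["de_novo"],
            "evidence": ["A"] * 3 + [""],
        }), mode="any_ancestor")
        fr = stage_fractions(table).iloc[0]
        assert fr["frac_inherited"] == pytest.approx(0.75)
        assert fr["frac_de_novo"] == pytest.approx(0.25)

    def test_root_all_root_set(self):
        table = InheritanceTable(pd.DataFrame({
            "population": ["SSC"] * 2, "gene_id": ["G1", "G2"],
            "origin": ["root_set"] * 2, "evidence": ["", ""],
        }), mode="any_ancestor")
        assert stage_fractions(table).iloc[0]["frac_root_set"] == 1.0

    def test_aggregate_weighted_mean(self):
        rows = ([("P1", f"a{i}", "de_novo") for i in range(6)]
                + [("P1", f"b{i}", "inherited") for i in range(4)]
                + [("P2", f"c{i}", "de_novo") for i in range(21)]
                + [("P2", f"d{i}", "inherited") for i in range(9)])
        table = InheritanceTable(pd.DataFrame(
            [{"population": p, "gene_id": g, "origin": o, "evidence": ""}
             for p, g, o in rows]), mode="any_ancestor")
        agg = aggregate_group_fraction(table, ["P1", "P2"], "de_novo")
        assert agg["fraction"] == pytest.approx(0.675)
        assert agg["n_targets"] == 40
        single = aggregate_group_fraction(table, ["P1"], "de_novo")
        assert single["fraction"] == pytest.approx(0.6)

    def test_empty_origin_class(self):
        table = InheritanceTable(pd.DataFrame({
            "population": ["B"], "gene_id": ["G1"],
            "origin": ["inherited"], "evidence": ["A"],
        }), mode="any_ancestor")
        assert aggregate_group_fraction(table, ["B"], "de_novo")["fraction"] == 0.0

    def test_empty_subset_rejected(self):
        table = InheritanceTable(pd.DataFrame(
            columns=["population", "gene_id", "origin", "evidence"]),
            mode="any_ancestor")
        with pytest.raises(ParameterError):
            aggregate_group_fraction(table, [], "de_novo")
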