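"""Newick conventions, distances, NJ, bootstrap and support bookkeeping."""

import math

import numpy as np
import pytest

from _oracles import best_additive_topology, random_additive_matrix
from loopinv.msa import Msa
from loopinv.resample import duplicate_interleaved
from loopinv.treekit import (CladeSupportTable, SupportConfig, TreeError,
                             bootstrap_support, clade_partition_frequencies,
                             clade_sets, count_supported_nodes, has_split,
                             incompatible, jc_distance_matrix, leaf_labels,
                             nj_tree, parse_newick, read_tree_list,
                             replicate_support_summary, root_on_outgroup,
                             splits, write_newick)

DOWNWEIGHTED = ("((foliosa1,concreta2):1,((concreta3,concreta4):1,"
                "(foliosa2,concreta1):0.76):1)")
ENTIRE_LOOPS = ("((concreta3,concreta4):1,((foliosa1,foliosa2):0.98,"
                "(concreta1,concreta2):0.98):0.97)")


class TestNewick:
    def test_post_colon_supports(self):
        tree = parse_newick(DOWNWEIGHTED, "post_colon_support")
        assert len(leaf_labels(tree)) == 6
        sups = sorted(n.support for n in tree
                      if not n.is_leaf() and n is not tree.seed_node)
        assert sups == [0.76, 1.0, 1.0, 1.0]

    def test_two_leaves_no_support(self):
        tree = parse_newick("(A,B)")
        assert leaf_labels(tree) == {"A", "B"}
        assert all(n.support is None for n in tree)

    def test_node_label_supports(self):
        tree = parse_newick("((A,B)0.9,(C,D)0.8)", "node_label_support")
        sups = {n.support for n in tree if not n.is_leaf()}
        assert sups == {0.9, 0.8, None}

    def test_round_trip(self):
        for conv in ("branch_lengths", "post_colon_support"):
            src = DOWNWEIGHTED if conv == "post_colon_support" \
                else "((A:1,B:2):0.5,(C:1,D:1):0.5,E:3)"
            t1 = parse_newick(src, conv)
            t2 = parse_newick(write_newick(t1, conv), conv)
            assert splits(t1) == splits(t2)
            if conv == "post_colon_support":
                assert sorted(n.support for n in t2 if n.support is not None) \
                    == sorted(n.support for n in t1 if n.support is not None)

    def test_malformed(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B)")

    def test_tree_list_reader(self, tmp_path):
        f = tmp_path / "trees.nwk"
        f.write_text("(A,(B,C));\n(B,(A,C));\n")
        trees = read_tree_list(f)
        assert len(trees) == 2


class TestSplits:
    def test_label_order_invariance(self):
        a = parse_newick("((A,B),(C,D),E)")
        b = parse_newick("(E,(D,C),(B,A))")
        assert splits(a) == splits(b)

    def test_has_split_both_orientations(self):
        t = parse_newick("((A,B),(C,D),E)")
        assert has_split(t, {"A", "B"})
        assert has_split(t, {"C", "D", "E"})
        assert not has_split(t, {"A", "C"})

    def test_incompatibility(self):
        assert incompatible(frozenset("AB"), frozenset("BC"))
        assert not incompatible(frozenset("AB"), frozenset("ABC"))
        assert not incompatible(frozenset("AB"), frozenset("CD"))


class TestJCDistance:
    def test_identical_rows(self):
        msa = Msa([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert jc_distance_matrix(msa).loc["a", "b"] == 0.0

    def test_closed_form_p_01(self):
        # 1 mismatch in 10 -> d = -(3/4) ln(1 - 4*0.1/3)
        msa = Msa([("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC")])
        d = jc_distance_matrix(msa).loc["a", "b"]
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert d == pytest.approx(0.10732, abs=1e-5)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), size=60)
        rows = []
        for i in range(4):
            r = base.copy()
            hit = rng.random(60) < 0.1
            r[hit] = rng.choice(list("ACGT"), size=int(hit.sum()))
            rows.append((f"t{i}", "".join(r)))
        D = jc_distance_matrix(Msa(rows))
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_saturation_flag(self):
        msa = Msa([("a", "AAAA"), ("b", "CCCC")])
        assert math.isnan(jc_distance_matrix(msa).loc["a", "b"])


class TestNJ:
    def test_additive_four_taxon_exact(self):
        D = np.array([[0, 3, 7, 8], [3, 0, 6, 7],
                      [7, 6, 0, 5], [8, 7, 5, 0]], float)
        tree = nj_tree(D, labels=list("abcd"))
        assert splits(tree) == {frozenset("cd")}
        lengths = {n.taxon.label: n.edge.length for n in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 2, "b": 1, "c": 2, "d": 3})

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = nj_tree(D, labels=list("abc"))
        assert len(tree.seed_node.child_nodes()) == 3

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (6, 2), (7, 3)])
    def test_additive_recovery_vs_exhaustive_oracle(self, n, seed):
        D, true_splits = random_additive_matrix(n, seed)
        labels = [str(i) for i in range(n)]
        nj_splits = {frozenset(int(x) for x in s)
                     for s in splits(nj_tree(D, labels=labels))}
        oracle_splits, resid = best_additive_topology(D)
        assert resid < 1e-18
        assert nj_splits == oracle_splits == true_splits

    def test_matches_dendropy_nj(self):
        import io

        import dendropy
        rng = np.random.default_rng(11)
        base = rng.choice(list("ACGT"), size=300)
        rows = []
        for i in range(6):
            r = base.copy()
            hit = rng.random(300) < 0.05 * (i + 1)
            r[hit] = rng.choice(list("ACGT"), size=int(hit.sum()))
            rows.append((f"t{i}", "".join(r)))
        D = jc_distance_matrix(Msa(rows))
        mine = splits(nj_tree(D))
        header = "," + ",".join(D.columns)
        lines = [header] + [f"{t}," + ",".join(f"{v:.10f}" for v in D.loc[t])
                            for t in D.index]
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO("\n".join(lines)), delimiter=",")
        theirs = splits(pdm.nj_tree())
        assert mine == theirs

    def test_nan_matrix_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(TreeError, match="saturated"):
            nj_tree(D)


class TestBootstrap:
    def _clean_msa(self, L=400, seed=5):
        rng = np.random.default_rng(seed)
        base = rng.choice(list("ACGT"), size=L)
        rows = {t: base.copy() for t in "ABCD"}
        # many sites cleanly partition AB | CD
        for c in range(0, L, 4):
            alt = "A" if rows["A"][c] != "A" else "C"
            rows["A"][c] = rows["B"][c] = alt
        return Msa((t, "".join(r)) for t, r in rows.items())

    def test_clean_partition_converges(self):
        msa = self._clean_msa()
        tree = bootstrap_support(msa, B=50, seed=1)
        node = clade_sets(tree).get(frozenset("AB")) or \
            clade_sets(tree).get(frozenset("CD"))
        assert node is not None and node.support == 1.0

    def test_single_replicate_supports_are_binary(self):
        msa = self._clean_msa(seed=6)
        tree = bootstrap_support(msa, B=1, seed=2)
        sups = {n.support for n in tree if not n.is_leaf()
                and n is not tree.seed_node and n.support is not None}
        assert sups <= {0.0, 1.0}

    def test_duplication_sharpens_support(self):
        from loopinv.experiments import bootstrap_split_frequency
        rng = np.random.default_rng(9)
        base = rng.choice(list("ACGT"), size=200)
        rows = {t: base.copy() for t in "ABCD"}
        rows["A"][0] = rows["B"][0] = "A" if base[0] != "A" else "C"
        msa = Msa((t, "".join(r)) for t, r in rows.items())
        f1 = bootstrap_split_frequency(msa, frozenset("AB"), B=60, seed=3)
        f8 = bootstrap_split_frequency(duplicate_interleaved(msa, 8),
                                       frozenset("AB"), B=60, seed=3)
        assert f8 >= f1  # one supporting pattern: duplication consolidates it


class TestCountSupportedNodes:
    def test_printed_downweighted_topology(self):
        tree = parse_newick(DOWNWEIGHTED, "post_colon_support")
        assert count_supported_nodes(tree, 0.95) == 3

    def test_threshold_zero_counts_all(self):
        tree = parse_newick(DOWNWEIGHTED, "post_colon_support")
        assert count_supported_nodes(tree, 0.0) == 4

    def test_threshold_above_one(self):
        tree = parse_newick(DOWNWEIGHTED, "post_colon_support")
        assert count_supported_nodes(tree, 1.01) == 0

    def test_no_supports_error(self):
        with pytest.raises(TreeError):
            count_supported_nodes(parse_newick("((A,B),(C,D))"), 0.5)


def annotated(newick, support_map):
    """Rooted tree with supports set on the named clades."""
    tree = parse_newick(newick)
    for node in tree:
        node.support = None
    for clade, node in clade_sets(tree, include_root=True).items():
        if clade in support_map:
            node.support = support_map[clade]
    return tree


class TestReplicateSummary:
    TAXA = "(((A,B),(C,D)),E)"

    def _replicate(self, ab_support, contradict=False):
        if contradict:
            tree = parse_newick("(((A,C),(B,D)),E)")
            cl = frozenset("AC")
        else:
            tree = parse_newick(self.TAXA)
            cl = frozenset("AB")
        for node in tree:
            node.support = None
        for clade, node in clade_sets(tree, include_root=True).items():
            node.support = ab_support if clade == cl else 0.5
        return tree

    def test_all_high_is_category_i(self):
        reps = [self._replicate(1.0) for _ in range(20)]
        table = replicate_support_summary(reps, [frozenset("AB")])
        entry = table.entries[frozenset("AB")]
        assert entry.mean == 1.0 and entry.category == "most_high"

    def test_rarely_high_with_poor_rest_is_category_iii(self):
        reps = [self._replicate(0.95) for _ in range(4)] + \
               [self._replicate(0.0) for _ in range(16)]
        table = replicate_support_summary(reps, [frozenset("AB")])
        assert table.entries[frozenset("AB")].category == "generally_poor"

    def test_rarely_high_rarely_contradicted_is_category_ii(self):
        # few high replicates, the rest middling, at most one contradiction
        reps = [self._replicate(0.96) for _ in range(4)] + \
               [self._replicate(0.5) for _ in range(15)] + \
               [self._replicate(0.99, contradict=True)]
        table = replicate_support_summary(reps, [frozenset("AB")])
        entry = table.entries[frozenset("AB")]
        assert entry.category == "rarely_high_rarely_contradicted"
        assert sum(entry.contradicted) == 1

    def test_mutually_exclusive_clades_tallied_independently(self):
        # AB high in some replicates, AC high in others
        reps = [self._replicate(0.96) for _ in range(4)] + \
               [self._replicate(0.96, contradict=True) for _ in range(2)] + \
               [self._replicate(0.3) for _ in range(14)]
        table = replicate_support_summary(
            reps, [frozenset("AB"), frozenset("AC")])
        ab = table.entries[frozenset("AB")].values
        ac = table.entries[frozenset("AC")].values
        assert sum(v >= 0.90 for v in ab) == 4
        assert sum(v >= 0.90 for v in ac) == 2

    def test_summary_recomputable(self):
        reps = [self._replicate(s) for s in (0.2, 0.9, 1.0)]
        table = replicate_support_summary(reps, [frozenset("AB")])
        e = table.entries[frozenset("AB")]
        assert e.mean == pytest.approx(np.mean(e.values))
        assert (e.min, e.max) == (min(e.values), max(e.values))
        df = table.to_dataframe()
        assert list(df.columns[:5]) == ["clade", "mean", "min", "max",
                                        "category"]

    def test_posterior_sample_mode_and_partition(self):
        sample = [parse_newick(self.TAXA) for _ in range(8)] + \
                 [parse_newick("(((A,C),(B,D)),E)") for _ in range(2)]
        f_clade, f_contra, f_other = clade_partition_frequencies(
            sample, frozenset("AB"))
        assert f_clade == pytest.approx(0.8)
        assert f_clade + f_contra + f_other == pytest.approx(1.0, abs=1e-9)
        table = replicate_support_summary(
            [sample], [frozenset("AB")],
            SupportConfig(burn_in_fraction=0.0))
        assert table.entries[frozenset("AB")].values[0] == pytest.approx(0.8)

    def test_empty_replicate_error(self):
        with pytest.raises(TreeError, match="replicate 0"):
            replicate_support_summary([[]], [frozenset("AB")])


class TestRooting:
    def test_outgroup_child_of_root(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,(D:1,out:1):1):1)")
        root_on_outgroup(tree, "out")
        children = tree.seed_node.child_nodes()
        labels = [c.taxon.label if c.taxon else None for c in children]
        assert "out" in labels

    def test_missing_outgroup(self):
        with pytest.raises(TreeError):
            root_on_outgroup(parse_newick("(A,B,C)"), "zz")
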