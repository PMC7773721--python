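"""MPD/MNTD, randomization null models, cophenetic distances, FCA tables."""

from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
import pytest

import beehex as bh
from beehex.assembly import DistanceMatrix
from conftest import random_loci


def toy_matrix(pts, ids=None):
    pts = np.asarray(pts, float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, values=(d + d.T) / 2)


class TestMpdMntd:
    def test_single_pair(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert bh.mpd(dm, ["a", "b"]) == pytest.approx(0.4)
        assert bh.mntd(dm, ["a", "b"]) == pytest.approx(0.4)

    def test_right_triangle_closed_forms(self):
        dm = toy_matrix([[0, 0], [1, 0], [0, 1]])
        assert bh.mpd(dm, dm.ids) == pytest.approx((1 + 1 + np.sqrt(2)) / 3)
        assert bh.mntd(dm, dm.ids) == pytest.approx(1.0)

    def test_six_species_match_brute_force(self):
        rng = np.random.default_rng(1)
        dm = toy_matrix(rng.uniform(0, 1, size=(6, 2)))
        pairs = list(combinations(range(6), 2))
        mpd_bf = np.mean([dm.values[i, j] for i, j in pairs])
        mntd_bf = np.mean(
            [min(dm.values[i, j] for j in range(6) if j != i) for i in range(6)]
        )
        assert bh.mpd(dm, dm.ids) == pytest.approx(mpd_bf)
        assert bh.mntd(dm, dm.ids) == pytest.approx(mntd_bf)

    def test_unknown_label_errors(self):
        dm = toy_matrix([[0, 0], [1, 0]])
        with pytest.raises(KeyError, match="nope"):
            bh.mpd(dm, ["s0", "nope"])

    def test_too_small_subset_errors(self):
        dm = toy_matrix([[0, 0], [1, 0]])
        with pytest.raises(ValueError):
            bh.mpd(dm, ["s0"])


class TestNullTest:
    def test_group_equals_pool_is_degenerate(self):
        dm = toy_matrix(np.random.default_rng(2).uniform(0, 1, (5, 2)))
        res = bh.null_test(dm, dm.ids, reps=50, seed=0)
        assert res.null_sd == 0.0
        assert res.p == 1.0

    def test_null_mean_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        dm = toy_matrix(rng.uniform(0, 1, (4, 2)))
        exact = np.array(
            [bh.mpd(dm, [dm.ids[i], dm.ids[j]]) for i, j in combinations(range(4), 2)]
        )
        res = bh.null_test(dm, dm.ids[:2], reps=10_000, seed=4)
        se = exact.std(ddof=1) / np.sqrt(res.reps)
        assert abs(res.null_mean - exact.mean()) < 3 * se

    def test_actual_below_all_nulls_gives_minimal_p(self):
        # three coincident species inside a large spread-out pool: drawing
        # that exact triple back is the only way to tie the observed MPD
        rng = np.random.default_rng(5)
        pts = np.vstack([np.zeros((3, 2)), rng.uniform(1, 2, (17, 2))])
        dm = toy_matrix(pts)
        res = bh.null_test(dm, ["s0", "s1", "s2"], reps=199, seed=1)
        assert res.actual == 0.0
        assert res.p == pytest.approx(1 / 200)
        assert res.ses < 0

    def test_oversized_group_errors(self):
        dm = toy_matrix([[0, 0], [1, 0]])
        with pytest.raises(ValueError):
            bh.null_test(dm, dm.ids, pool=["s0"], reps=10)

    def test_seeded_reproducibility_bit_identical(self):
        dm = toy_matrix(np.random.default_rng(6).uniform(0, 1, (10, 2)))
        a = bh.null_test(dm, dm.ids[:4], reps=200, seed=7)
        b = bh.null_test(dm, dm.ids[:4], reps=200, seed=7)
        assert a == b

    def test_null_mean_equals_pool_mpd_on_small_pools(self):
        # under uniform resampling E[MPD_null] equals the pool MPD exactly;
        # verify by exhaustive enumeration of subsets for pools up to 8
        rng = np.random.default_rng(8)
        for n_pool, n_sub in ((5, 3), (8, 4)):
            dm = toy_matrix(rng.uniform(0, 1, (n_pool, 2)))
            pool_mpd = bh.mpd(dm, dm.ids)
            subset_mpds = [
                bh.mpd(dm, [dm.ids[i] for i in c])
                for c in combinations(range(n_pool), n_sub)
            ]
            assert np.mean(subset_mpds) == pytest.approx(pool_mpd, rel=1e-12)


class TestCopheneticMatrix:
    def test_two_tip_path_sum(self):
        tree = dendropy.Tree.get(data="(a:1,b:2);", schema="newick")
        dm = bh.cophenetic_matrix(tree)
        assert dm.values[0, 1] == pytest.approx(3.0)

    def test_balanced_ultrametric_cross_cherry_distance(self, balanced_four_tip_tree):
        dm = bh.cophenetic_matrix(balanced_four_tip_tree)
        i, j = dm.ids.index("a"), dm.ids.index("c")
        assert dm.values[i, j] == pytest.approx(6.0)  # 2 * depth

    def test_yule_tree_matches_brute_force_lca_path_sums(self):
        tree = bh.gen_yule_tree(20, seed=9)
        dm = bh.cophenetic_matrix(tree)
        # independent recomputation from node depths and ancestor sets
        depth = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            d = depth[parent] if parent else 0.0
            depth[node] = d + (node.edge.length or 0.0)
        leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i >= j:
                    continue
                anc_a = set()
                node = leaves[a]
                while node:
                    anc_a.add(id(node))
                    node = node.parent_node
                node = leaves[b]
                while id(node) not in anc_a:
                    node = node.parent_node
                expected = depth[leaves[a]] + depth[leaves[b]] - 2 * depth[node]
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_missing_branch_length_errors(self):
        tree = dendropy.Tree.get(data="(a:1,(b,c:1):1);", schema="newick")
        with pytest.raises(ValueError, match="branch length"):
            bh.cophenetic_matrix(tree)

    def test_duplicate_tip_labels_error(self):
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        for label in ("a", "a", "c"):
            child = tree.seed_node.new_child(edge_length=1.0)
            child.taxon = tns.new_taxon(label)
        with pytest.raises(ValueError, match="duplicate"):
            bh.cophenetic_matrix(tree)


def _groups_frame(mapping):
    return pd.DataFrame(
        [{"species_id": s, "group": g} for g, members in mapping.items() for s in members]
    )


class TestFcaTable:
    def test_single_group_equal_to_pool_is_degenerate(self):
        loci = random_loci(6, seed=10)
        groups = _groups_frame({"only": [l.species_id for l in loci]})
        table = bh.fca_table(loci, groups, reps=50, seed=0)
        assert table.loc[0, "p"] == 1.0

    def test_member_without_locus_errors(self):
        loci = random_loci(4, seed=11)
        groups = _groups_frame({"g": [l.species_id for l in loci] + ["ghost"]})
        with pytest.raises(ValueError, match="ghost"):
            bh.fca_table(loci, groups, reps=10, seed=0)

    @pytest.mark.parametrize("structure,check", [("clustered", "low"), ("overdispersed", "high")])
    def test_structured_communities_detected(self, structure, check):
        hits = 0
        for seed in range(10):
            loci = random_loci(120, seed=1000 + seed)
            members = bh.gen_community(loci, structure, n=25, seed=seed)
            rest = [l.species_id for l in loci if l.species_id not in set(members)]
            groups = _groups_frame({"focal": members, "rest": rest})
            table = bh.fca_table(loci, groups, reps=199, seed=seed)
            p = float(table.loc[table.group == "focal", "p"].iloc[0])
            hits += (p <= 0.05) if check == "low" else (p >= 0.95)
        assert hits >= 8

    def test_pollinator_class_rows_use_full_pool(self):
        loci = random_loci(30, seed=12)
        ids = [l.species_id for l in loci]
        groups = _groups_frame({"g1": ids[:15], "g2": ids[15:]})
        groups["pollinator_class"] = ["bee", "insect"] * 15
        table = bh.fca_table(loci, groups, reps=99, seed=1)
        assert set(table.group) == {"g1", "g2", "g1:bee", "g1:insect", "g2:bee", "g2:insect"}
        # same pool -> null means of subset rows estimate the same quantity
        base = table.loc[table.group == "g1", "null_mean"].iloc[0]
        sub = table.loc[table.group == "g1:bee", ["null_mean", "null_sd"]].iloc[0]
        assert abs(sub.null_mean - base) < 5 * sub.null_sd


class TestPhyloStructureTable:
    def test_group_equal_to_pool_degenerate_rows(self):
        tree = bh.gen_yule_tree(8, seed=13)
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        table = bh.phylo_structure_table(tree, _groups_frame({"all": tips}), reps=30, seed=0)
        assert set(table.statistic) == {"MPD", "MNTD"}
        assert (table.p == 1.0).all()

    def test_member_absent_from_tree_errors(self):
        tree = bh.gen_yule_tree(8, seed=14)
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        with pytest.raises(ValueError, match="absent"):
            bh.phylo_structure_table(tree, _groups_frame({"g": tips[:3] + ["zzz"]}), reps=10)

    def test_single_clade_community_is_clustered(self):
        hits = 0
        for seed in range(10):
            tree = bh.gen_yule_tree(40, seed=2000 + seed)
            tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
            # the clade under one child of the root
            root_child = tree.seed_node.child_nodes()[0]
            clade = sorted(l.taxon.label for l in root_child.leaf_iter())
            if not 5 <= len(clade) <= 35:
                clade = tips[:10]
            rest = [t for t in tips if t not in set(clade)]
            table = bh.phylo_structure_table(
                tree, _groups_frame({"clade": clade, "rest": rest}), reps=199, seed=seed
            )
            row = table[(table.group == "clade") & (table.statistic == "MPD")]
            hits += float(row.p.iloc[0]) <= 0.05
        assert hits >= 8

    def test_uniform_communities_have_calibrated_type_one_error(self):
        tree = bh.gen_yule_tree(60, seed=15)
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        dm = bh.cophenetic_matrix(tree)
        rng = np.random.default_rng(16)
        rejections = 0
        runs = 200
        for k in range(runs):
            members = list(rng.choice(tips, size=15, replace=False))
            res = bh.null_test(dm, members, statistic="MPD", reps=199, seed=k)
            rejections += res.p <= 0.05
        assert 0.01 <= rejections / runs <= 0.10
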