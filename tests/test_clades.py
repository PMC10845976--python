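import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from famsurvey.clades import (
    ClanPartitionError,
    DegenerateResolutionError,
    TrivialTreeError,
    ZeroOverlapError,
    assign_clades,
    bootstrap_support,
    clan_partition,
    name_clade,
    nj_tree,
    pairwise_distance,
)
from famsurvey.synthetic import default_template, evolve_with_mask, make_root_domain_with_mask
from oracles import least_squares_topology, random_additive_matrix, tree_bipartitions


# ---- distances ----

def test_p_distance_values():
    dm = pairwise_distance(["AAAA", "AAAC"], ["a", "b"], correction="p")
    assert dm["a", "b"] == pytest.approx(0.25)
    assert dm["a", "a"] == 0.0


def test_poisson_correction():
    dm = pairwise_distance(["AAAA", "AACC"], ["a", "b"], correction="poisson")
    assert dm["a", "b"] == pytest.approx(-np.log(1 - 0.5))


def test_distance_ignores_gapped_columns():
    # only co-occupied columns count: 2 shared, 1 mismatch
    dm = pairwise_distance(["AA-C", "AAC-"], ["a", "b"], correction="p")
    assert dm["a", "b"] == pytest.approx(0.0)
    dm = pairwise_distance(["AC-C", "AAC-"], ["a", "b"], correction="p")
    assert dm["a", "b"] == pytest.approx(0.5)


def test_poisson_cap():
    dm = pairwise_distance(["AAAA", "CCCC"], ["a", "b"], correction="poisson",
                           max_distance=5.0)
    assert dm["a", "b"] == 5.0


def test_zero_overlap_error_names_pair():
    with pytest.raises(ZeroOverlapError, match="a.*b|b.*a"):
        pairwise_distance(["AA--", "--CC"], ["a", "b"])


def test_low_overlap_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="famsurvey.clades"):
        pairwise_distance(["AAAA", "AAAA"], ["a", "b"], min_shared=20)
    assert any("fewer than" in r.message for r in caplog.records)


# ---- neighbor joining ----

def test_nj_needs_three_taxa():
    with pytest.raises(TrivialTreeError):
        nj_tree(DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"]))


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(DistanceMatrix(d, ids=["a", "b", "c"]))
    lens = {t.name: t.length for t in tree.tips()}
    assert lens["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lens["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lens["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_recovers_four_taxon_topology():
    labels = ["a", "b", "c", "d"]
    D, splits = random_additive_matrix(labels, seed=5)
    tree = nj_tree(DistanceMatrix(D, ids=labels))
    assert tree_bipartitions(tree, labels[0]) == splits


def test_nj_matches_least_squares_oracle_20_matrices():
    recovered = 0
    for seed in range(20):
        n = 4 + seed % 3  # 4, 5, 6 taxa
        labels = [f"t{i}" for i in range(n)]
        D, splits = random_additive_matrix(labels, seed=100 + seed)
        tree = nj_tree(DistanceMatrix(D, ids=labels))
        got = tree_bipartitions(tree, labels[0])
        oracle = least_squares_topology(D, labels)
        assert got == oracle == splits, seed
        recovered += 1
    assert recovered == 20


def test_nj_additive_branch_lengths_recovered():
    labels = ["a", "b", "c", "d", "e"]
    D, _ = random_additive_matrix(labels, seed=7)
    tree = nj_tree(DistanceMatrix(D, ids=labels))
    # patristic distances on the NJ tree reproduce the additive matrix
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            got = tree.find(x).distance(tree.find(y))
            assert got == pytest.approx(D[labels.index(x), labels.index(y)], abs=1e-9)


def test_nj_deterministic_under_ties():
    d = np.ones((4, 4)) - np.eye(4)
    ids = ["a", "b", "c", "d"]
    t1 = nj_tree(DistanceMatrix(d, ids=ids))
    t2 = nj_tree(DistanceMatrix(d, ids=ids))
    assert t1.compare_rfd(t2) == 0.0
    assert str(t1) == str(t2)


# ---- bootstrap ----

def _two_clade_strings(seed=0, between=0.4, within=0.02, members=4):
    tpl = default_template(seed)
    root, mask = make_root_domain_with_mask(tpl)
    out_ids, out_rows = [], []
    for ci in range(2):
        anc, amask = evolve_with_mask(root, between, seed * 100 + ci, mask, indel_rate=0.0)
        for m in range(members):
            row, _ = evolve_with_mask(anc, within, seed * 100 + 10 + ci * members + m,
                                      amask, indel_rate=0.0)
            out_ids.append(f"c{ci}_m{m}")
            out_rows.append(row)
    return out_ids, out_rows


def test_bootstrap_separating_edge_support():
    ids, rows = _two_clade_strings(seed=1)
    tree = bootstrap_support(rows, ids, n_replicates=100, seed=3)
    clade0 = frozenset(i for i in ids if i.startswith("c0"))
    found = False
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side in (clade0, frozenset(ids) - clade0):
            assert node.support >= 95.0
            found = True
    assert found


def test_bootstrap_single_replicate_support_binary():
    ids, rows = _two_clade_strings(seed=2)
    tree = bootstrap_support(rows, ids, n_replicates=1, seed=0)
    sups = [node.support for node in tree.non_tips(include_self=False)
            if hasattr(node, "support")]
    assert sups and all(s in (0.0, 100.0) for s in sups)


def test_bootstrap_deterministic():
    ids, rows = _two_clade_strings(seed=3)
    t1 = bootstrap_support(rows, ids, n_replicates=25, seed=9)
    t2 = bootstrap_support(rows, ids, n_replicates=25, seed=9)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False) if hasattr(n, "support"))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False) if hasattr(n, "support"))
    assert s1 == s2


# ---- clade naming and assignment ----

def test_name_clade_paper_convention():
    assert name_clade(["Pezizomycotina"], "VosA") == "Pez-VosA"
    assert name_clade(["Saccharomycotina", "Taphrinomycotina"], "VelB") == "Sac-Tap-VelB"
    assert name_clade(["Blastocladiomycota", "Cryptomycota"], "Velvet1") == "Bla-Cry-Velvet1"
    with pytest.raises(ValueError):
        name_clade([], "VeA")


def test_assign_clades_on_known_tree():
    nwk = "((((m1:0.1,m2:0.1):0.1,refA:0.1):0.3,((m3:0.1,m4:0.1):0.1,refB:0.1):0.3):0.5,outgroup:1.0);"
    tree = TreeNode.read([nwk])
    clades = assign_clades(tree, {"refA": "VeA", "refB": "VelB"})
    by_anchor = {c.anchor: set(c.member_ids) for c in clades}
    assert by_anchor["VeA"] == {"m1", "m2", "refA"}
    assert by_anchor["VelB"] == {"m3", "m4", "refB"}


def test_assign_clades_numbered_leftovers():
    # the x-leaves sit outside both anchored clades: any subtree containing
    # them and a reference contains both references, so the walk-up cannot
    # absorb them and they become a numbered VelvetN clade
    nwk = ("((((m1:0.1,refA:0.1):0.2,(m2:0.1,refB:0.1):0.2):0.2,"
           "((x1:0.05,x2:0.05):0.05,x3:0.1):0.4):0.3,outgroup:1.0);")
    tree = TreeNode.read([nwk])
    clades = assign_clades(tree, {"refA": "VeA", "refB": "VelB"})
    anchors = {c.anchor: set(c.member_ids) for c in clades}
    assert anchors["VeA"] == {"m1", "refA"}
    assert anchors["VelB"] == {"m2", "refB"}
    assert anchors["Velvet1"] == {"x1", "x2", "x3"}


def test_assign_clades_missing_outgroup():
    tree = TreeNode.read(["((a:1,b:1):1,(c:1,refA:1):1);"])
    with pytest.raises(ValueError):
        assign_clades(tree, {"refA": "VeA"}, outgroup_id="outgroup")


def test_assign_clades_degenerate_pair():
    # two references that are each other's closest relatives cannot be
    # resolved into disjoint anchored subtrees
    nwk = "(((refA:0.1,refB:0.1):0.2,(m1:0.1,m2:0.1):0.2):0.3,outgroup:1.0);"
    tree = TreeNode.read([nwk])
    clades = assign_clades(tree, {"refA": "VeA", "refB": "VelB"})
    by_anchor = {c.anchor: set(c.member_ids) for c in clades}
    # each reference falls back to a singleton clade rather than erroring,
    # because the maximal exclusive subtree is the reference leaf itself
    assert by_anchor["VeA"] == {"refA"}
    assert by_anchor["VelB"] == {"refB"}


def test_assign_clades_groups_drive_names():
    nwk = ("(((m1:0.1,refA:0.1):0.3,((m2:0.1,m3:0.1):0.2,refB:0.1):0.3):0.2,"
           "outgroup:1.0);")
    tree = TreeNode.read([nwk])
    groups = {"m1": "Pezizomycotina", "m2": "Saccharomycotina", "m3": "Taphrinomycotina"}
    clades = assign_clades(tree, {"refA": "VosA", "refB": "VelB"}, groups=groups)
    names = {c.clade_name for c in clades}
    assert "Pez-VosA" in names
    assert "Sac-Tap-VelB" in names


# ---- clans ----

def test_clan_partition_two_sides():
    nwk = "((A:0.1,B:0.1):1.0,(C:0.1,D:0.1):1.0);"
    tree = TreeNode.read([nwk])
    clans = clan_partition(tree, velb_anchor="A", vosa_anchor="C")
    assert clans["VelB"] == frozenset({"A", "B"})
    assert clans["VosA"] == frozenset({"C", "D"})


def test_clan_partition_same_side_raises():
    nwk = "((A:0.1,C:0.1):1.0,(B:0.1,D:0.1):1.0);"
    tree = TreeNode.read([nwk])
    with pytest.raises(ClanPartitionError):
        clan_partition(tree, velb_anchor="A", vosa_anchor="C")


def test_clan_partition_unknown_anchor():
    tree = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])
    with pytest.raises(ValueError):
        clan_partition(tree, "A", "Z")
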