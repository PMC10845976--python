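"""Distance phylogenies of match-state domain strings and clade assignment.

Match strings from the profile scan form an implicit alignment, so pairwise
distances are computed directly: p = mismatches over co-occupied columns,
optionally Poisson-corrected as -ln(1 - p). Trees are built by canonical
neighbor-joining (Saitou-Nei Q criterion) with deterministic tie-breaking;
branch support comes from column-resampling bootstrap. Clades are anchored
to reference sequences (VeA / VelB / VelC / VosA): a reference's clade is
the largest rooted subtree containing it and no other reference after
rooting on the outgroup; leftover leaves form numbered VelvetN clades.
Clade names follow the taxonomic-prefix convention (e.g. "Pez-VosA",
"Sac-Tap-VelB"), and the deepest split of the clade-consensus tree defines
the two clans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from ._alphabet import AA_INDEX, GAP

__all__ = [
    "CladeAssignment",
    "TrivialTreeError",
    "ZeroOverlapError",
    "DegenerateResolutionError",
    "ClanPartitionError",
    "pairwise_distance",
    "nj_tree",
    "bootstrap_support",
    "assign_clades",
    "name_clade",
    "clan_partition",
]

logger = logging.getLogger(__name__)


class TrivialTreeError(ValueError):
    """Fewer than 3 taxa: no informative tree exists."""


class ZeroOverlapError(ValueError):
    """A pair of match strings shares no occupied column."""


class DegenerateResolutionError(ValueError):
    """Reference clades cannot be resolved as disjoint subtrees."""


class ClanPartitionError(ValueError):
    """Both clan anchors fall on the same side of the root split."""


@dataclass(frozen=True)
class CladeAssignment:
    clade_name: str
    member_ids: tuple[str, ...]
    anchor: str  # "VeA" / "VelB" / "VelC" / "VosA" / "VelvetN"
    groups_spanned: tuple[str, ...] = ()
    singleton: bool = False


def _encode_rows(match_strings: Sequence[str]) -> np.ndarray:
    L = len(match_strings[0])
    if any(len(s) != L for s in match_strings):
        raise ValueError("all match strings must have equal length")
    return np.array(
        [[AA_INDEX.get(c, -1) if c != GAP else -1 for c in s] for s in match_strings],
        dtype=np.int16,
    )


def _distance_array(
    arr: np.ndarray,
    ids: Sequence[str],
    correction: str,
    max_distance: float,
    min_shared: int,
    strict: bool = True,
) -> np.ndarray:
    occ = arr >= 0
    shared = occ[:, None, :] & occ[None, :, :]
    n_shared = shared.sum(axis=2)
    mism = (shared & (arr[:, None, :] != arr[None, :, :])).sum(axis=2)
    n = arr.shape[0]
    zero = (n_shared == 0) & ~np.eye(n, dtype=bool)
    if zero.any():
        i, j = map(int, np.argwhere(zero)[0])
        if strict:
            raise ZeroOverlapError(
                f"no shared occupied columns between {ids[i]!r} and {ids[j]!r}"
            )
        logger.warning("pair (%s, %s) shares no columns; distance capped", ids[i], ids[j])
    low = (n_shared < min_shared) & (n_shared > 0) & ~np.eye(n, dtype=bool)
    if low.any():
        logger.warning("%d pairs share fewer than %d columns", int(low.sum()) // 2, min_shared)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_shared > 0, mism / np.maximum(n_shared, 1), 1.0)
    if correction == "p":
        d = p
    elif correction == "poisson":
        cap_p = 1.0 - np.exp(-max_distance)
        with np.errstate(divide="ignore"):
            d = np.where(p >= cap_p, max_distance, -np.log(np.maximum(1.0 - p, 1e-300)))
    else:
        raise ValueError(f"unknown correction {correction!r} (use 'p' or 'poisson')")
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # exact symmetry against float noise


def pairwise_distance(
    match_strings: Sequence[str],
    ids: Sequence[str],
    correction: str = "poisson",
    max_distance: float = 5.0,
    min_shared: int = 20,
) -> DistanceMatrix:
    """Pairwise distances over co-occupied match columns.

    p-distance = mismatches / shared columns; the Poisson correction
    -ln(1 - p) is capped at `max_distance` as p approaches 1. Pairs sharing
    fewer than `min_shared` columns are flagged via a warning; a pair with
    zero shared columns is an error naming the pair.
    """
    if len(match_strings) != len(ids):
        raise ValueError("ids and match_strings must correspond")
    arr = _encode_rows(match_strings)
    d = _distance_array(arr, ids, correction, max_distance, min_shared, strict=True)
    return DistanceMatrix(d, ids=list(ids))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining.

    Q(i,j) = (n-2) d(i,j) - r_i - r_j; the minimal pair joins, with ties
    broken toward the smallest (i, j) index pair for determinism. Branch
    lengths use the standard formulas; a negative length is clamped to zero
    and its deficit moved to the sister edge. The final three nodes join at
    an unrooted trifurcation via the three-point formulas.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise TrivialTreeError(f"neighbor-joining needs >= 3 taxa, got {n}")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qvals = Q[iu]
        best = qvals.min()
        # ties -> smallest (i, j): triu_indices is already in lexicographic order
        k = int(np.flatnonzero(np.isclose(qvals, best, rtol=0, atol=1e-12))[0])
        i, j = int(iu[0][k]), int(iu[1][k])
        dij = D[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [parent]
        D = D2

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, ln in zip(nodes, lens):
        node.length = max(float(ln), 0.0)
    return TreeNode(children=list(nodes))


def _bipartitions(tree: TreeNode, all_tips: frozenset[str], anchor_tip: str) -> dict[TreeNode, frozenset[str]]:
    """Non-trivial bipartitions, canonicalized as the side without `anchor_tip`."""
    out: dict[TreeNode, frozenset[str]] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        if anchor_tip in side:
            side = all_tips - side
        out[node] = side
    return out


def bootstrap_support(
    match_strings: Sequence[str],
    ids: Sequence[str],
    n_replicates: int = 100,
    seed: int = 0,
    correction: str = "poisson",
    max_distance: float = 5.0,
) -> TreeNode:
    """Point-estimate NJ tree with bootstrap support on internal edges.

    Match columns are resampled with replacement per replicate; support of
    an internal edge is the percentage of replicate trees containing the
    same bipartition (stored on each internal node as `.support`, 0-100).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    arr = _encode_rows(match_strings)
    L = arr.shape[1]
    d = _distance_array(arr, ids, correction, max_distance, min_shared=1, strict=True)
    tree = nj_tree(DistanceMatrix(d, ids=list(ids)))
    all_tips = frozenset(ids)
    anchor = sorted(ids)[0]
    point = _bipartitions(tree, all_tips, anchor)
    counts = {bp: 0 for bp in point.values()}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rd = _distance_array(arr[:, cols], ids, correction, max_distance, min_shared=1, strict=False)
        rtree = nj_tree(DistanceMatrix(rd, ids=list(ids)))
        seen = set(_bipartitions(rtree, all_tips, anchor).values())
        for bp in counts:
            if bp in seen:
                counts[bp] += 1
    for node, bp in point.items():
        node.support = 100.0 * counts[bp] / n_replicates
    return tree


def _node_support(node: TreeNode) -> float:
    """Support of a node's parent edge; unsupported trees count as 100."""
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.name is not None:
        try:
            return float(node.name)
        except ValueError:
            pass
    return 100.0


def assign_clades(
    tree: TreeNode,
    references: Mapping[str, str],
    outgroup_id: str = "outgroup",
    support_threshold: float = 50.0,
    groups: Mapping[str, str] | None = None,
) -> list[CladeAssignment]:
    """Partition leaves into reference-anchored and numbered clades.

    The tree is rooted on the outgroup. Each reference's clade is the
    largest rooted subtree containing it, no other reference, and not the
    outgroup. Remaining leaves form maximal reference-free subtrees whose
    parent edge support reaches `support_threshold`, named Velvet1,
    Velvet2, ... in decreasing member count (ties by first member id).

    `references` maps leaf id -> anchor name; `groups` optionally maps leaf
    id -> taxonomic group, enabling full taxonomic clade names.
    """
    tip_names = {t.name for t in tree.tips()}
    if outgroup_id not in tip_names:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
    missing = [r for r in references if r not in tip_names]
    if missing:
        raise ValueError(f"reference leaves not in tree: {missing}")
    rooted = tree.root_by_outgroup([outgroup_id], branch_attrs=["support"])

    ref_ids = set(references)
    chosen: dict[str, TreeNode] = {}
    for rid in sorted(ref_ids):
        leaf = rooted.find(rid)
        node = leaf
        anc = leaf.parent
        while anc is not None and not anc.is_root():
            tips = {t.name for t in anc.tips()}
            if (tips & ref_ids) != {rid} or outgroup_id in tips:
                break
            node = anc
            anc = anc.parent
        chosen[rid] = node
    seen_nodes: dict[int, str] = {}
    for rid, node in chosen.items():
        if id(node) in seen_nodes:
            raise DegenerateResolutionError(
                f"references {seen_nodes[id(node)]!r} and {rid!r} resolve to the same subtree"
            )
        seen_nodes[id(node)] = rid

    def make_assignment(members: set[str], anchor: str) -> CladeAssignment:
        gspan: tuple[str, ...] = ()
        if groups:
            gspan = tuple(sorted({groups[m] for m in members if m in groups}))
        name = name_clade(gspan, anchor) if gspan else anchor
        return CladeAssignment(
            clade_name=name,
            member_ids=tuple(sorted(members)),
            anchor=anchor,
            groups_spanned=gspan,
            singleton=len(members) == 1,
        )

    assignments: list[CladeAssignment] = []
    assigned: set[str] = set()
    for rid in sorted(ref_ids):
        node = chosen[rid]
        members = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if members == {rid}:
            logger.warning("reference %r forms a singleton clade", rid)
        assignments.append(make_assignment(members, references[rid]))
        assigned |= members

    remaining = tip_names - assigned - {outgroup_id}
    new_clades: list[set[str]] = []

    def collect(node: TreeNode) -> None:
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if not tips & remaining:
            return
        if tips <= remaining and (node.is_tip() or _node_support(node) >= support_threshold):
            new_clades.append(tips)
            return
        for child in node.children:
            collect(child)

    collect(rooted)
    new_clades.sort(key=lambda m: (-len(m), min(m)))
    for k, members in enumerate(new_clades, start=1):
        assignments.append(make_assignment(members, f"Velvet{k}"))
    return assignments


def name_clade(groups_spanned: Sequence[str], anchor: str) -> str:
    """Taxonomic clade name: three-letter group prefixes, then the anchor.

    Each group contributes its first three letters with a capitalized first
    letter, hyphen-joined in input order, e.g. ("Pezizomycotina", "VosA")
    -> "Pez-VosA"; ("Saccharomycotina", "Taphrinomycotina") with VelB ->
    "Sac-Tap-VelB".
    """
    if not groups_spanned:
        raise ValueError("at least one group is required")
    parts = [g[:3][0].upper() + g[1:3].lower() for g in groups_spanned]
    return "-".join(parts) + "-" + anchor


def clan_partition(
    clade_consensus_tree: TreeNode,
    velb_anchor: str,
    vosa_anchor: str,
) -> dict[str, frozenset[str]]:
    """Two clans from the midpoint-rooted clade-consensus tree.

    The two child subtrees of the midpoint root are the clans, labeled by
    which anchor leaf each contains; if both anchors fall in one subtree,
    the partition is refused rather than guessed.
    """
    tips = {t.name for t in clade_consensus_tree.tips()}
    for a in (velb_anchor, vosa_anchor):
        if a not in tips:
            raise ValueError(f"anchor {a!r} is not a leaf of the tree")
    rooted = clade_consensus_tree.root_at_midpoint()
    sides: list[frozenset[str]] = []
    for child in rooted.children:
        if child.is_tip():
            sides.append(frozenset({child.name}))
        else:
            sides.append(frozenset(t.name for t in child.tips()))
    velb_side = [s for s in sides if velb_anchor in s]
    vosa_side = [s for s in sides if vosa_anchor in s]
    if not velb_side or not vosa_side or velb_side[0] == vosa_side[0]:
        raise ClanPartitionError(
            f"anchors {velb_anchor!r} and {vosa_anchor!r} fall in the same root subtree"
        )
    return {"VelB": velb_side[0], "VosA": vosa_side[0]}
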