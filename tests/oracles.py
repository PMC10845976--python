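"""Independent reference implementations used to check the library.

These are deliberately written with different algorithms from the package:
exhaustive enumeration instead of dynamic programming, least-squares
topology search instead of neighbor-joining, and pair counting for the
Rand index. Slow but transparently correct on small inputs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_local_alignment(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best local profile/sequence alignment score by exhaustive enumeration.

    Enumerates every set of matched (column, position) pairs with strictly
    increasing columns and positions. Between consecutive matches, skipped
    columns form a deletion run and skipped residues an insertion run; a
    run costs gap_open for its first site plus gap_extend per additional
    site, and the two kinds of run may not both occur between the same two
    matches. Terminal unmatched columns/residues are free (local
    alignment). Returns 0.0 when no positive alignment exists.
    """
    L, n = S.shape
    best = 0.0
    cols = range(1, L + 1)
    poss = range(1, n + 1)
    for k in range(1, min(L, n) + 1):
        for cset in combinations(cols, k):
            for pset in combinations(poss, k):
                score = 0.0
                ok = True
                for idx, (c, p) in enumerate(zip(cset, pset)):
                    score += S[c - 1, p - 1]
                    if idx > 0:
                        dc = c - cset[idx - 1] - 1
                        dp = p - pset[idx - 1] - 1
                        if dc > 0 and dp > 0:
                            ok = False
                            break
                        if dc > 0:
                            score += gap_open + (dc - 1) * gap_extend
                        if dp > 0:
                            score += gap_open + (dp - 1) * gap_extend
                if ok and score > best:
                    best = score
    return best


def enumerate_unrooted_topologies(labels: list[str]) -> list[list[tuple[frozenset, frozenset]]]:
    """All unrooted binary topologies as edge lists of (side, side) label splits.

    Built by stepwise insertion: each topology is represented by its list of
    edges, where an edge is the bipartition of labels it induces. For n
    taxa this yields 1, 3, 15, 105 ... topologies.
    """
    # represent a topology as a list of edges; an edge is a frozenset pair
    # grow trees as adjacency structures over node ids
    def insert_all(adj: dict[int, set[int]], leaf_of: dict[int, str], next_id: int, label: str):
        out = []
        edges = {(a, b) for a in adj for b in adj[a] if a < b}
        for a, b in edges:
            adj2 = {k: set(v) for k, v in adj.items()}
            mid, leaf = next_id, next_id + 1
            adj2[a].discard(b)
            adj2[b].discard(a)
            adj2[mid] = {a, b, leaf}
            adj2[a].add(mid)
            adj2[b].add(mid)
            adj2[leaf] = {mid}
            lo2 = dict(leaf_of)
            lo2[leaf] = label
            out.append((adj2, lo2, next_id + 2))
        return out

    # start: 3-taxon star
    adj0 = {0: {1, 2, 3}, 1: {0}, 2: {0}, 3: {0}}
    lo0 = {1: labels[0], 2: labels[1], 3: labels[2]}
    states = [(adj0, lo0, 4)]
    for label in labels[3:]:
        states = [s for st in states for s in insert_all(st[0], st[1], st[2], label)]

    all_labels = frozenset(labels)
    topologies = []
    for adj, leaf_of, _ in states:
        edges = []
        for a in adj:
            for b in adj[a]:
                if a < b:
                    side = _side_labels(adj, leaf_of, a, b)
                    edges.append((side, all_labels - side))
        topologies.append(edges)
    return topologies


def _side_labels(adj: dict[int, set[int]], leaf_of: dict[int, str], root: int, block: int) -> frozenset:
    """Labels reachable from `root` without crossing the edge to `block`."""
    seen = {root}
    stack = [root]
    labels = set()
    while stack:
        node = stack.pop()
        if node in leaf_of:
            labels.add(leaf_of[node])
        for nxt in adj[node]:
            if nxt not in seen and not (node == root and nxt == block):
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(labels)


def least_squares_topology(D: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Best-fit topology for distance matrix D by exhaustive least squares.

    Fits branch lengths per topology with ordinary least squares on the
    path-incidence system and returns the internal bipartitions (each as
    the side not containing labels[0]) of the minimum-residual topology.
    """
    n = len(labels)
    lab_idx = {l: i for i, l in enumerate(labels)}
    pairs = list(combinations(range(n), 2))
    best_res, best_split = np.inf, None
    for edges in enumerate_unrooted_topologies(labels):
        A = np.zeros((len(pairs), len(edges)))
        for r, (i, j) in enumerate(pairs):
            for c, (side_a, _) in enumerate(edges):
                ai = labels[i] in side_a
                aj = labels[j] in side_a
                if ai != aj:
                    A[r, c] = 1.0
        d = np.array([D[i, j] for i, j in pairs])
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        res = float(((A @ x - d) ** 2).sum())
        if res < best_res - 1e-12:
            best_res = res
            best_split = {
                side_b if labels[0] in side_a else side_a
                for side_a, side_b in edges
                if min(len(side_a), len(side_b)) >= 2
            }
    assert best_split is not None
    return best_split


def tree_bipartitions(tree, anchor: str) -> set[frozenset]:
    """Internal bipartitions of an skbio tree, sides not containing `anchor`."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        if anchor in side:
            side = tips - side
        out.add(side)
    return out


def random_additive_matrix(labels: list[str], seed: int) -> tuple[np.ndarray, set[frozenset]]:
    """Additive distances from a random binary tree with positive lengths.

    Returns (distance matrix, internal bipartitions of the generating tree,
    canonicalized as the side not containing labels[0]).
    """
    rng = np.random.default_rng(seed)
    topologies = enumerate_unrooted_topologies(labels)
    edges = topologies[int(rng.integers(len(topologies)))]
    lengths = rng.uniform(0.2, 1.5, size=len(edges))
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = 0.0
        for (side_a, _), ln in zip(edges, lengths):
            if (labels[i] in side_a) != (labels[j] in side_a):
                d += ln
        D[i, j] = D[j, i] = d
    splits = {
        side_b if labels[0] in side_a else side_a
        for side_a, side_b in edges
        if min(len(side_a), len(side_b)) >= 2
    }
    return D, splits


def rand_index(labels_a: dict[str, object], labels_b: dict[str, object]) -> float:
    """Rand index between two labelings of the same item set (pair counting)."""
    items = sorted(labels_a)
    assert set(items) == set(labels_b)
    agree = total = 0
    for x, y in combinations(items, 2):
        same_a = labels_a[x] == labels_a[y]
        same_b = labels_b[x] == labels_b[y]
        agree += same_a == same_b
        total += 1
    return agree / total if total else 1.0
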