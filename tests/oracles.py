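"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for tiny inputs and enumerates the full search
space rather than sharing any code path with the package.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_align_score(
    a: str,
    b: str,
    substitution,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best global alignment score by exhaustive path enumeration.

    Affine gaps: a gap of length L costs gap_open + gap_extend * (L - 1).
    ``substitution`` is "BLOSUM62" or a (match, mismatch) pair.
    """

    def sub(x: str, y: str) -> float:
        if substitution == "BLOSUM62":
            return float(_BLOSUM62[x, y])
        match, mismatch = substitution
        return match if x == y else mismatch

    best = -math.inf

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + sub(a[i], b[j]))
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "A" else gap_open
            rec(i + 1, j, "A", score + cost)
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "B" else gap_open
            rec(i, j + 1, "B", score + cost)

    rec(0, 0, "", 0.0)
    return best


def brute_force_jc69_lnl(tree: dendropy.Tree, sequences: dict[str, str]) -> float:
    """Log-likelihood by summing over every internal-node state assignment."""
    bases = {"A": 0, "C": 1, "G": 2, "T": 3}

    def p(t: float, i: int, j: int) -> float:
        e = math.exp(-4.0 * t / 3.0)
        return 0.25 + 0.75 * e if i == j else 0.25 - 0.25 * e

    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    n_sites = len(next(iter(sequences.values())))
    lnl = 0.0
    for site in range(n_sites):
        total = 0.0
        leaf_states = {}
        for lf in leaves:
            ch = sequences[lf.taxon.label][site]
            leaf_states[id(lf)] = [bases[ch]] if ch in bases else [0, 1, 2, 3]
        for assign in itertools.product(range(4), repeat=len(internals)):
            states = {id(nd): s for nd, s in zip(internals, assign)}
            for combo in itertools.product(*(leaf_states[id(lf)] for lf in leaves)):
                full = dict(states)
                for lf, s in zip(leaves, combo):
                    full[id(lf)] = s
                prob = 0.25  # root prior
                for nd in tree.preorder_node_iter():
                    if nd.parent_node is None:
                        continue
                    prob *= p(
                        nd.edge.length or 0.0, full[id(nd.parent_node)], full[id(nd)]
                    )
                total += prob
        lnl += math.log(total)
    return lnl


def brute_force_parsimony(
    tree: dendropy.Tree, leaf_states: dict[str, object]
) -> tuple[int, set[int]]:
    """(min changes, optimal root states) by enumerating internal states.

    ``leaf_states`` maps leaf label to 0, 1 or '?'.
    """
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    best = math.inf
    root_states: set[int] = set()
    leaf_choices = [
        [0, 1] if leaf_states[lf.taxon.label] == "?" else [int(leaf_states[lf.taxon.label])]
        for lf in leaves
    ]
    for assign in itertools.product((0, 1), repeat=len(internals)):
        states = {id(nd): s for nd, s in zip(internals, assign)}
        for combo in itertools.product(*leaf_choices):
            full = dict(states)
            for lf, s in zip(leaves, combo):
                full[id(lf)] = s
            changes = sum(
                full[id(nd)] != full[id(nd.parent_node)]
                for nd in tree.preorder_node_iter()
                if nd.parent_node is not None
            )
            if changes < best:
                best = changes
                root_states = {full[id(tree.seed_node)]}
            elif changes == best:
                root_states.add(full[id(tree.seed_node)])
    return int(best), root_states


def random_binary_tree(
    labels: list[str], rng: np.random.Generator, min_len: float = 0.1, max_len: float = 1.0
) -> dendropy.Tree:
    """Random unrooted binary topology with uniform branch lengths."""

    def leaf(lb):
        nd = dendropy.Node()
        nd.taxon = dendropy.Taxon(label=lb)
        nd.edge.length = float(rng.uniform(min_len, max_len))
        return nd

    order = list(rng.permutation(labels))
    root = dendropy.Node()
    for lb in order[:3]:
        root.add_child(leaf(lb))
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = False
    for lb in order[3:]:
        edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent_node
        mid = dendropy.Node()
        mid.edge.length = float(rng.uniform(min_len, max_len))
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        mid.add_child(leaf(lb))
    tree.update_taxon_namespace()
    return tree


def path_distance_matrix(tree: dendropy.Tree):
    """Leaf-to-leaf path-length matrix (pandas DataFrame) from edge lengths."""
    import pandas as pd

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]

    def depth_map(leaf):
        d = {}
        node, acc = leaf, 0.0
        while node is not None:
            d[id(node)] = acc
            acc += node.edge.length or 0.0
            node = node.parent_node
        return d

    maps = {lf.taxon.label: depth_map(lf) for lf in leaves}
    n = len(leaves)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            da, db = maps[labels[i]], maps[labels[j]]
            # find lowest common ancestor: deepest shared node
            node = leaves[j]
            dist = None
            acc = 0.0
            while node is not None:
                if id(node) in da:
                    dist = da[id(node)] + acc
                    break
                acc += node.edge.length or 0.0
                node = node.parent_node
            out[i, j] = out[j, i] = dist
    return pd.DataFrame(out, index=labels, columns=labels)


def splits_with_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each edge's unrooted bipartition to its branch length.

    The key is a frozenset of the two leaf-label frozensets. Trivial root
    edges are skipped; for the edge pair adjacent to a 2-child seed node the
    two lengths are merged.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: dict[frozenset, float] = {}

    def below(node) -> frozenset:
        if node.is_leaf():
            return frozenset([node.taxon.label])
        return frozenset().union(*(below(c) for c in node.child_nodes()))

    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = below(nd)
        if not side or side == all_leaves:
            continue
        key = frozenset([side, all_leaves - side])
        splits[key] = splits.get(key, 0.0) + (nd.edge.length or 0.0)
    return splits
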