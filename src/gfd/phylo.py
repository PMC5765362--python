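"""Distance and likelihood phylogenetics for gene families.

Neighbor-joining tree construction, Jukes–Cantor (JC69) distances, the
Felsenstein pruning log-likelihood under JC69, unrooted monophyly ("clan")
queries, a constrained-vs-unconstrained monophyly likelihood comparison for
genomic clusters, and Fitch parsimony for intron presence/absence characters.

Trees are dendropy objects treated as unrooted; the node holding the
seed-node position is an arbitrary basal trifurcation. Branch lengths are in
expected substitutions per site.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cluster_synteny import ClusterAssignment
from .core_io import SequenceSet, SpeciesTree

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}

# lnL values closer than this are treated as ties (the branch-length
# optimizer's own convergence tolerance)
LNL_TIE_TOL = 1e-6


# ---------------------------------------------------------------------------
# distances


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing sites over gap-free, unambiguous columns."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    diffs = valid = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        valid += 1
        if x != y:
            diffs += 1
    if valid == 0:
        raise ValueError("no comparable columns")
    return diffs / valid, valid


def jc69_distance(a: str, b: str, aligned: bool = True) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3) from two nucleotide sequences.

    Sequences are assumed aligned unless ``aligned=False``, in which case a
    global alignment is computed first. Undefined (raises) for p >= 0.75.
    """
    if not aligned:
        from .divergence import align_global, default_policy

        aln = align_global(a, b, default_policy("nt"))
        a, b = aln.aligned_a, aln.aligned_b
    p, _ = p_distance(a, b)
    if p >= 0.75:
        raise ValueError(f"JC69 distance undefined for p = {p:.4f} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc69_matrix(seqs: SequenceSet | dict[str, str], cap: float | None = None) -> pd.DataFrame:
    """All-pairs JC69 distance matrix from an aligned nucleotide set.

    With ``cap`` set, saturated pairs (p >= 0.75) are assigned ``cap``
    instead of raising — useful inside heuristic tree searches.
    """
    data = seqs.as_dict() if isinstance(seqs, SequenceSet) else dict(seqs)
    ids = list(data)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = jc69_distance(data[ids[i]], data[ids[j]])
            except ValueError:
                if cap is None:
                    raise
                dij = cap
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(distances: pd.DataFrame) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    ``distances`` must be a symmetric non-negative matrix over >= 3 taxa.
    Q-criterion ties are broken by the lexicographically smallest pair of
    cluster keys (a cluster's key is its smallest leaf label). Negative
    branch lengths are clamped to zero with a warning.
    """
    d = distances.to_numpy(dtype=float)
    ids = [str(i) for i in distances.index]
    if d.shape[0] != d.shape[1] or list(distances.columns.astype(str)) != ids:
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative branch length {x:.3g} clamped to 0")
            return 0.0
        return x

    nodes: dict[str, dendropy.Node] = {}
    for label in ids:
        leaf = dendropy.Node()
        leaf.taxon = dendropy.Taxon(label=label)
        nodes[label] = leaf
    active = list(ids)  # cluster keys, each the min leaf label of its cluster
    dist = {frozenset((a, b)): d[i, j] for i, a in enumerate(ids) for j, b in enumerate(ids) if i < j}

    def dd(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dd(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * dd(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    pair = (a, b)
        a, b = pair
        la = 0.5 * dd(a, b) + (r[a] - r[b]) / (2 * (len(active) - 2))
        lb = dd(a, b) - la
        new = dendropy.Node()
        ca, cb = nodes[a], nodes[b]
        new.add_child(ca)
        new.add_child(cb)
        ca.edge.length = clamp(la)
        cb.edge.length = clamp(lb)
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((min(a, b), c))] = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
        key = min(a, b)
        nodes[key] = new
        active = [c for c in active if c not in (a, b)] + [key]
        active.sort()

    a, b, c = sorted(active)
    root = dendropy.Node()
    la = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
    lb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
    lc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
    for key, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[key])
        nodes[key].edge.length = clamp(length)
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def tree_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()


# ---------------------------------------------------------------------------
# pruning likelihood


@dataclass
class TreeLikelihood:
    tree: dendropy.Tree
    model: str
    log_likelihood: float
    per_site: np.ndarray | None = None


def _jc69_p(t: float) -> np.ndarray:
    e = math.exp(-4.0 * max(t, 0.0) / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


class _PruningEngine:
    """Cached site-pattern pruning for one alignment.

    Gaps and ambiguity codes are missing data (partial likelihood one for
    every state).
    """

    def __init__(self, sequences: dict[str, str]):
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        self.n_sites = lengths.pop()
        ids = list(sequences)
        coded = np.array(
            [[_BASES.get(ch, 4) for ch in sequences[i].upper()] for i in ids]
        )
        patterns, inverse, counts = np.unique(
            coded.T, axis=0, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(float)
        self._inverse = inverse
        self.leaf_partials: dict[str, np.ndarray] = {}
        eye5 = np.vstack([np.eye(4), np.ones(4)])
        for row, i in enumerate(ids):
            self.leaf_partials[i] = eye5[patterns[:, row]]

    def log_likelihood(self, tree: dendropy.Tree, per_site: bool = False):
        missing = set(leaf_labels(tree)) ^ set(self.leaf_partials)
        if missing:
            raise ValueError(f"tree/alignment leaf mismatch: {sorted(missing)}")

        def partial(node: dendropy.Node) -> np.ndarray:
            if node.is_leaf():
                return self.leaf_partials[node.taxon.label]
            out = None
            for child in node.child_nodes():
                p = _jc69_p(child.edge.length or 0.0)
                term = partial(child) @ p  # P symmetric
                out = term if out is None else out * term
            return out

        site_l = 0.25 * partial(tree.seed_node).sum(axis=1)
        logs = np.log(site_l)
        lnl = float(np.dot(self.weights, logs))
        if per_site:
            return lnl, logs[self._inverse]
        return lnl


def pruning_log_likelihood(
    tree: dendropy.Tree,
    alignment: SequenceSet | dict[str, str],
    model: str = "JC69",
    per_site: bool = False,
) -> TreeLikelihood:
    """Felsenstein pruning log-likelihood of an aligned nucleotide set under
    JC69 with uniform root frequencies."""
    if model != "JC69":
        raise ValueError("only the JC69 model is implemented")
    seqs = alignment.as_dict() if isinstance(alignment, SequenceSet) else dict(alignment)
    engine = _PruningEngine(seqs)
    if per_site:
        lnl, sites = engine.log_likelihood(tree, per_site=True)
        return TreeLikelihood(tree, model, lnl, sites)
    return TreeLikelihood(tree, model, engine.log_likelihood(tree))


def optimize_branch_lengths(
    tree: dendropy.Tree,
    engine_or_alignment,
    tol: float = 1e-6,
    max_cycles: int = 10,
    edges: Sequence[dendropy.Node] | None = None,
) -> float:
    """Cycle bounded univariate optimization over branch lengths until the
    lnL gain per cycle drops below ``tol``; returns the final lnL.

    ``edges`` (given as the child nodes owning each edge) restricts the sweep
    to a subset — used for cheap local rescoring during topology search.
    """
    if isinstance(engine_or_alignment, _PruningEngine):
        engine = engine_or_alignment
    else:
        seqs = (
            engine_or_alignment.as_dict()
            if isinstance(engine_or_alignment, SequenceSet)
            else dict(engine_or_alignment)
        )
        engine = _PruningEngine(seqs)
    targets = list(edges) if edges is not None else [
        nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
    ]
    current = engine.log_likelihood(tree)
    for _ in range(max_cycles):
        start = current
        for node in targets:
            def neg(t: float, node=node) -> float:
                node.edge.length = t
                return -engine.log_likelihood(tree)

            res = minimize_scalar(
                neg, bounds=(1e-9, 20.0), method="bounded", options={"xatol": 1e-7}
            )
            node.edge.length = float(res.x)
            current = -float(res.fun)
        if current - start < tol:
            break
    return current


# ---------------------------------------------------------------------------
# monophyly


def is_monophyletic(tree: dendropy.Tree, tips: set[str]) -> bool:
    """True iff some edge of the unrooted tree separates exactly ``tips``
    from the remaining leaves (clan membership)."""
    leaves = set(leaf_labels(tree))
    tips = set(tips)
    if not tips or tips == leaves:
        raise ValueError("tips must be a non-empty proper subset of the leaf set")
    if not tips <= leaves:
        raise ValueError(f"tips not in tree: {sorted(tips - leaves)}")

    found = False

    def walk(node: dendropy.Node) -> set[str]:
        nonlocal found
        if node.is_leaf():
            below = {node.taxon.label}
        else:
            below = set()
            for c in node.child_nodes():
                below |= walk(c)
        if below == tips or leaves - below == tips:
            found = True
        return below

    walk(tree.seed_node)
    return found


def random_topology(labels: Sequence[str], rng: np.random.Generator) -> dendropy.Tree:
    """Uniform-ish random unrooted binary topology by random sequential
    addition, with branch lengths initialised to 0.05."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    order = list(rng.permutation(labels))

    def leaf(lb: str) -> dendropy.Node:
        nd = dendropy.Node()
        nd.taxon = dendropy.Taxon(label=lb)
        nd.edge.length = 0.05
        return nd

    root = dendropy.Node()
    for lb in order[:3]:
        root.add_child(leaf(lb))
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = False
    for lb in order[3:]:
        candidates = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
        target = candidates[int(rng.integers(len(candidates)))]
        parent = target.parent_node
        mid = dendropy.Node()
        mid.edge.length = 0.05
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        mid.add_child(leaf(lb))
    tree.update_taxon_namespace()
    return tree


def _nni_neighbors(tree: dendropy.Tree):
    """Yield (description, apply, undo) for every NNI move around each
    internal edge of the rooted representation."""
    moves = []
    for v in tree.preorder_node_iter():
        u = v.parent_node
        if u is None or v.is_leaf():
            continue
        siblings = [s for s in u.child_nodes() if s is not v]
        for s in siblings:
            for c in v.child_nodes():
                moves.append((u, v, s, c))

    def swap(u, v, s, c):
        u.remove_child(s)
        v.remove_child(c)
        u.add_child(c)
        v.add_child(s)

    for u, v, s, c in moves:
        yield (u, v, s, c), (lambda u=u, v=v, s=s, c=c: swap(u, v, s, c)), (
            lambda u=u, v=v, s=s, c=c: swap(u, v, c, s)
        )


@dataclass
class MonophylyComparison:
    constrained_lnL: float
    unconstrained_lnL: float
    delta: float
    n_random_starts: int
    clades_tested: list[str]
    per_clade_monophyletic: dict[str, bool]
    best_tree: dendropy.Tree | None = None
    constrained_tree: dendropy.Tree | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "constrained_lnL": self.constrained_lnL,
            "unconstrained_lnL": self.unconstrained_lnL,
            "delta": self.delta,
            "n_random_starts": self.n_random_starts,
            "clades_tested": self.clades_tested,
            "per_clade_monophyletic": self.per_clade_monophyletic,
            "best_tree": tree_newick(self.best_tree) if self.best_tree else None,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _graft_constrained_tree(
    dmat: pd.DataFrame, cluster_members: dict[str, list[str]]
) -> dendropy.Tree:
    """NJ among clusters (mean inter-cluster distance), then NJ within each
    cluster, grafted at the cluster's tip."""
    cids = sorted(cluster_members)
    k = len(cids)
    cd = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = dmat.loc[cluster_members[cids[i]], cluster_members[cids[j]]]
            cd[i, j] = cd[j, i] = float(sub.to_numpy().mean())
    if k >= 3:
        cluster_tree = neighbor_joining(pd.DataFrame(cd, index=cids, columns=cids))
    else:  # two clusters: a single edge; realised as a 2-child seed
        root = dendropy.Node()
        for cid in cids:
            nd = dendropy.Node()
            nd.taxon = dendropy.Taxon(label=cid)
            nd.edge.length = cd[0, 1] / 2.0
            root.add_child(nd)
        cluster_tree = dendropy.Tree(seed_node=root)
        cluster_tree.is_rooted = False

    def subtree_for(members: list[str]) -> dendropy.Node:
        if len(members) == 1:
            nd = dendropy.Node()
            nd.taxon = dendropy.Taxon(label=members[0])
            return nd
        if len(members) == 2:
            nd = dendropy.Node()
            half = float(dmat.loc[members[0], members[1]]) / 2.0
            for m in members:
                c = dendropy.Node()
                c.taxon = dendropy.Taxon(label=m)
                c.edge.length = half
                nd.add_child(c)
            return nd
        sub = neighbor_joining(dmat.loc[members, members])
        return sub.seed_node

    for lf in list(cluster_tree.leaf_node_iter()):
        cid = lf.taxon.label
        sub_root = subtree_for(cluster_members[cid])
        length = lf.edge.length
        parent = lf.parent_node
        parent.remove_child(lf)
        parent.add_child(sub_root)
        sub_root.edge.length = length
    cluster_tree.update_taxon_namespace()
    return cluster_tree


def monophyly_comparison(
    alignment: SequenceSet | dict[str, str],
    clusters: Sequence[ClusterAssignment],
    n_random_starts: int = 5,
    seed: int | None = None,
    max_nni_iter: int = 15,
) -> MonophylyComparison:
    """Compare the best tree in which every genomic cluster is monophyletic
    against the best tree found allowing non-monophyletic clusters.

    The constrained candidate is a grafted NJ tree (clusters, then members
    within clusters); unconstrained candidates are the plain NJ tree plus
    ``n_random_starts`` NNI hill-climbs from random topologies, restricted to
    topologies in which at least one cluster is non-monophyletic. All
    candidates get full branch-length optimization; ``delta`` is best overall
    lnL minus constrained lnL (>= 0; zero when the constrained tree wins or
    ties within the optimizer tolerance).
    """
    if n_random_starts < 1:
        raise ValueError("n_random_starts must be >= 1")
    seqs = alignment.as_dict() if isinstance(alignment, SequenceSet) else dict(alignment)
    cluster_members: dict[str, list[str]] = {}
    for c in clusters:
        members = [m for m in c.member_ids if m in seqs]
        if len(members) < 2:
            warnings.warn(f"cluster {c.cluster_id} has <2 aligned members; skipped")
            continue
        cluster_members[c.cluster_id] = members
    if len(cluster_members) < 2:
        raise ValueError("need >=2 clusters with >=2 members each")
    clade_sets = {cid: set(m) for cid, m in cluster_members.items()}
    all_leaves = list(seqs)

    engine = _PruningEngine(seqs)
    dmat = jc69_matrix(seqs, cap=3.0)

    def n_non_monophyletic(tree: dendropy.Tree) -> int:
        return sum(not is_monophyletic(tree, s) for s in clade_sets.values())

    # genes outside any usable cluster still belong in the tree: they enter
    # the constrained construction as free-floating singletons
    in_cluster = {m for ms in cluster_members.values() for m in ms}
    tree_members = dict(cluster_members)
    for g in sorted(set(seqs) - in_cluster):
        tree_members[f"singleton:{g}"] = [g]
    constrained = _graft_constrained_tree(dmat, tree_members)
    constrained_lnl = optimize_branch_lengths(constrained, engine)

    rng = np.random.default_rng(seed)
    candidates: list[tuple[float, dendropy.Tree, str]] = []

    nj = neighbor_joining(dmat)
    nj_lnl = optimize_branch_lengths(nj, engine)
    candidates.append((nj_lnl, nj, "nj"))

    for start in range(n_random_starts):
        tree = None
        for _ in range(20):  # re-draw until the start is non-monophyletic
            cand = random_topology(all_leaves, rng)
            if n_non_monophyletic(cand) >= 1:
                tree = cand
                break
        if tree is None:
            continue
        lnl = optimize_branch_lengths(tree, engine, max_cycles=2)
        for _ in range(max_nni_iter):
            best_gain = 0.0
            best_move = None
            for move, apply_, undo in _nni_neighbors(tree):
                u, v, s, c = move
                saved = (v.edge.length, s.edge.length, c.edge.length)
                apply_()
                trial = -np.inf
                if n_non_monophyletic(tree) >= 1:
                    trial = optimize_branch_lengths(
                        tree, engine, max_cycles=1, edges=[v, s, c]
                    )
                if trial - lnl > best_gain + LNL_TIE_TOL:
                    best_gain = trial - lnl
                    best_move = (apply_, undo)
                undo()
                v.edge.length, s.edge.length, c.edge.length = saved
            if best_move is None:
                break
            best_move[0]()
            lnl = optimize_branch_lengths(tree, engine, max_cycles=2)
        lnl = optimize_branch_lengths(tree, engine)
        candidates.append((lnl, tree, f"restart{start}"))

    # classes: the constrained class is every candidate in which all clusters
    # are monophyletic (the grafted tree by construction, but e.g. the NJ
    # tree often lands there too); delta is best-overall minus best-constrained
    best_lnl, best_tree = constrained_lnl, constrained
    for lnl, tree, _name in candidates:
        if lnl > best_lnl + LNL_TIE_TOL:
            best_lnl, best_tree = lnl, tree
        if n_non_monophyletic(tree) == 0 and lnl > constrained_lnl:
            constrained_lnl = lnl
    best_lnl = max(best_lnl, constrained_lnl)  # constrained class is in the search space
    per_clade = {cid: is_monophyletic(best_tree, s) for cid, s in clade_sets.items()}
    delta = max(0.0, best_lnl - constrained_lnl)
    if delta <= LNL_TIE_TOL:
        delta = 0.0
    return MonophylyComparison(
        constrained_lnL=float(constrained_lnl),
        unconstrained_lnL=float(best_lnl),
        delta=float(delta),
        n_random_starts=n_random_starts,
        clades_tested=sorted(clade_sets),
        per_clade_monophyletic=per_clade,
        best_tree=best_tree,
        constrained_tree=constrained,
    )


# ---------------------------------------------------------------------------
# Fitch parsimony


@dataclass
class IntronStateReconstruction:
    species_tree: SpeciesTree
    characters: pd.DataFrame
    ancestral_states: dict[str, list[set[int]]]
    root_states: list[set[int]]
    min_changes: int


def fitch_parsimony(
    species_tree: SpeciesTree, characters: pd.DataFrame
) -> IntronStateReconstruction:
    """Minimum-change (Fitch) parsimony for binary characters (intron
    presence/absence) on a rooted species tree.

    ``characters`` is species x characters with entries 0, 1 or '?'
    (missing; either state allowed at the leaf). Species in the tree but
    absent from the table are all-missing. Implemented as an exact
    unit-cost dynamic programme (valid for polytomies too); a node's
    ancestral state set contains every state attained by that node in at
    least one most-parsimonious reconstruction, so ``root_states`` is the
    exact set of optimal ancestral gene states.
    """
    tree = species_tree.tree
    leaves = set(species_tree.leaf_labels)
    extra = set(map(str, characters.index)) - leaves
    if extra:
        raise ValueError(f"species absent from tree: {sorted(extra)}")

    INF = float("inf")

    def leaf_costs(sp: str, col) -> list[float]:
        if sp not in characters.index:
            return [0.0, 0.0]
        v = characters.loc[sp, col]
        if v == "?" or v is None or (isinstance(v, float) and math.isnan(v)):
            return [0.0, 0.0]
        v = int(v)
        return [0.0 if s == v else INF for s in (0, 1)]

    nodes = list(tree.preorder_node_iter())
    n_chars = characters.shape[1]
    ancestral: dict[str, list[set[int]]] = {}
    labels = {}
    for idx, node in enumerate(nodes):
        label = node.taxon.label if node.is_leaf() else (node.label or f"node{idx}")
        labels[id(node)] = str(label)
        ancestral[str(label)] = [set() for _ in range(n_chars)]

    total_changes = 0
    for ci, col in enumerate(characters.columns):
        down: dict[int, list[float]] = {}
        contrib: dict[int, list[float]] = {}  # per child: min over child states
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                down[id(node)] = leaf_costs(node.taxon.label, col)
            else:
                d = [0.0, 0.0]
                for c in node.child_nodes():
                    dc = down[id(c)]
                    contrib[id(c)] = [
                        min(dc[0] + (0 != s), dc[1] + (1 != s)) for s in (0, 1)
                    ]
                    d = [d[s] + contrib[id(c)][s] for s in (0, 1)]
                down[id(node)] = d
        root = tree.seed_node
        best = min(down[id(root)])
        total_changes += int(best)
        up: dict[int, list[float]] = {id(root): [0.0, 0.0]}
        for node in tree.preorder_node_iter():
            children = node.child_nodes()
            for c in children:
                # cost outside c's subtree, for each state s' at node, minus
                # c's own contribution; then step across the edge to c
                outside = [
                    up[id(node)][s] + down[id(node)][s] - contrib[id(c)][s]
                    for s in (0, 1)
                ]
                up[id(c)] = [
                    min(outside[0] + (s != 0), outside[1] + (s != 1)) for s in (0, 1)
                ]
        for node in nodes:
            total = [down[id(node)][s] + up[id(node)][s] for s in (0, 1)]
            ancestral[labels[id(node)]][ci] = {s for s in (0, 1) if total[s] == best}
    root_label = labels[id(tree.seed_node)]
    return IntronStateReconstruction(
        species_tree=species_tree,
        characters=characters,
        ancestral_states=ancestral,
        root_states=ancestral[root_label],
        min_changes=total_changes,
    )


def intron_presence_matrix(models_by_species: dict[str, Sequence]) -> pd.DataFrame:
    """Species x intron-position presence/absence matrix: a position is
    present (1) in a species when any gene copy of that species carries it."""
    positions = sorted(
        {p for models in models_by_species.values() for m in models for p in m.intron_positions_aa}
    )
    rows = {}
    for sp, models in models_by_species.items():
        present = {p for m in models for p in m.intron_positions_aa}
        rows[sp] = [1 if p in present else 0 for p in positions]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"intron_after_aa{p}" for p in positions]
    )
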