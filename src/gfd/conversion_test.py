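"""Permutation test for gene conversion.

Tests whether nucleotide sequence identity is higher within genomic clusters
of gene-family members than between clusters. Genomic positions — and hence
the observed cluster sizes and memberships-by-position — are held fixed while
gene labels are shuffled uniformly over positions genome-wide. The test
statistic is

    D = mean identity over within-cluster pairs - mean identity over
        between-cluster pairs,

with pairs pooled across clusters, and the test is one-sided (within >
between). When the number of distinct labelled assignments is small the null
is enumerated exactly; otherwise a Monte-Carlo null with the plus-one
estimator p = (1 + #{D_perm >= D_obs}) / (1 + N) is used, which can never
return zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .cluster_synteny import ClusterAssignment
from .divergence import IdentityMatrix


@dataclass
class PermutationResult:
    statistic_observed: float
    null_samples: np.ndarray
    n_permutations: int
    p_value: float
    seed: int | None
    cluster_sizes: list[int]
    mode: Literal["monte_carlo", "exhaustive"]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "statistic_observed": self.statistic_observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "cluster_sizes": self.cluster_sizes,
            "mode": self.mode,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _membership(
    matrix: IdentityMatrix, clusters: Sequence[ClusterAssignment]
) -> np.ndarray:
    """Cluster index per matrix position; genes not in any cluster become
    singleton clusters of their own (they still shuffle and contribute
    between-cluster pairs)."""
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    labels = np.full(len(matrix.gene_ids), -1, dtype=int)
    for ci, c in enumerate(clusters):
        for gid in c.member_ids:
            if gid not in index:
                raise ValueError(f"cluster member {gid!r} not in matrix")
            if labels[index[gid]] != -1:
                raise ValueError(f"gene {gid!r} assigned to more than one cluster")
            labels[index[gid]] = ci
    next_label = len(clusters)
    for i in range(labels.size):
        if labels[i] == -1:
            labels[i] = next_label
            next_label += 1
    return labels


def _pair_sums(m: np.ndarray, groups: list[np.ndarray], perm: np.ndarray):
    """(within-pair sum, within-pair count) for gene order ``perm`` laid onto
    the fixed position groups."""
    w_sum = 0.0
    w_n = 0
    for pos in groups:
        genes = perm[pos]
        sub = m[np.ix_(genes, genes)]
        k = genes.size
        w_sum += (sub.sum() - np.trace(sub)) / 2.0
        w_n += k * (k - 1) // 2
    return w_sum, w_n


def within_between_statistic(
    matrix: IdentityMatrix, clusters: Sequence[ClusterAssignment]
) -> float:
    """Observed D: pooled mean within-cluster identity minus pooled mean
    between-cluster identity (percentage points)."""
    labels = _membership(matrix, clusters)
    return _statistic_from_labels(matrix.values, labels)


def _groups(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == c) for c in np.unique(labels)]


def _statistic_from_labels(m: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    groups = [g for g in _groups(labels)]
    identity = np.arange(n)
    w_sum, w_n = _pair_sums(m, groups, identity)
    total_pairs = n * (n - 1) // 2
    b_n = total_pairs - w_n
    if w_n == 0:
        raise ValueError("no within-cluster pairs (all clusters are singletons)")
    if b_n == 0:
        raise ValueError("no between-cluster pairs (a single cluster)")
    total_sum = (m.sum() - np.trace(m)) / 2.0
    return w_sum / w_n - (total_sum - w_sum) / b_n


def permutation_test(
    matrix: IdentityMatrix,
    clusters: Sequence[ClusterAssignment],
    n_permutations: int = 100_000,
    seed: int | None = None,
    exhaustive_threshold: int = 20_000,
) -> PermutationResult:
    """One-sided permutation test of within- vs between-cluster identity.

    The number of distinct labelled assignments of genes to the fixed
    position groups is the multinomial n! / prod(size_c!); when it does not
    exceed ``exhaustive_threshold`` every assignment is enumerated and the
    exact p (proportion of assignments with D >= D_obs, including the
    observed one) is returned.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = _membership(matrix, clusters)
    m = matrix.values
    n = labels.size
    groups = _groups(labels)
    d_obs = _statistic_from_labels(m, labels)
    sizes = sorted((g.size for g in groups), reverse=True)

    n_assignments = math.factorial(n)
    for s in sizes:
        n_assignments //= math.factorial(s)

    total_sum = (m.sum() - np.trace(m)) / 2.0
    total_pairs = n * (n - 1) // 2
    w_n = sum(s * (s - 1) // 2 for s in sizes)
    b_n = total_pairs - w_n

    def stat_for(perm: np.ndarray) -> float:
        w_sum, _ = _pair_sums(m, groups, perm)
        return w_sum / w_n - (total_sum - w_sum) / b_n

    if n_assignments <= exhaustive_threshold:
        # enumerate distinct assignments of genes to position groups: each
        # multiset permutation of the label vector is one labelled assignment
        null = []
        for lab in multiset_permutations([int(c) for c in labels]):
            lab = np.asarray(lab)
            w_sum = 0.0
            for c in np.unique(lab):
                genes = np.flatnonzero(lab == c)
                sub = m[np.ix_(genes, genes)]
                w_sum += (sub.sum() - np.trace(sub)) / 2.0
            null.append(w_sum / w_n - (total_sum - w_sum) / b_n)
        null = np.asarray(null)
        p = float(np.mean(null >= d_obs - 1e-12))
        return PermutationResult(
            float(d_obs), null, len(null), p, seed, sizes, "exhaustive"
        )

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stat_for(rng.permutation(n))
    exceed = int(np.sum(null >= d_obs - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationResult(
        float(d_obs), null, n_permutations, float(p), seed, sizes, "monte_carlo"
    )
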