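"""Pairwise divergence analysis of a gene family.

Global (Needleman–Wunsch, affine-gap) pairwise alignment, percent-identity /
residue-change matrices, within-species and reference-relative divergence
summaries, exact-protein ("isopeptide") subfamily grouping, and per-residue
change maps against a reference sequence.

A gap of length L is charged ``gap_open + gap_extend * (L - 1)`` in score
space. Identity is computed, by default, over aligned columns in which
neither row is a gap; ambiguity symbols (N for nucleotide, X for protein)
never count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import GeneModel, GfdIOError, SequenceSet, detect_alphabet

AMBIGUOUS = {"nt": "N", "aa": "X"}


@dataclass(frozen=True)
class AlignmentPolicy:
    """Scoring scheme for global pairwise alignment.

    ``substitution`` is either a named matrix (e.g. ``"BLOSUM62"``) or a
    ``(match, mismatch)`` pair. ``identity_denominator`` selects what percent
    identity is normalised by.
    """

    alphabet: Literal["nt", "aa"]
    substitution: object = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    identity_denominator: Literal[
        "aligned_columns_excluding_gaps", "alignment_length", "shorter_sequence_length"
    ] = "aligned_columns_excluding_gaps"

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0 in score space")


def default_policy(alphabet: str) -> AlignmentPolicy:
    if alphabet == "aa":
        return AlignmentPolicy("aa", "BLOSUM62", -10.0, -0.5)
    return AlignmentPolicy("nt", (2.0, -3.0), -5.0, -2.0)


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    policy: AlignmentPolicy

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


def _make_aligner(policy: AlignmentPolicy) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(policy.substitution, str):
        aligner.substitution_matrix = substitution_matrices.load(policy.substitution)
    else:
        match, mismatch = policy.substitution
        aligner.match_score = float(match)
        aligner.mismatch_score = float(mismatch)
    aligner.open_gap_score = policy.gap_open
    aligner.extend_gap_score = policy.gap_extend
    return aligner


def align_global(
    a: str, b: str, policy: AlignmentPolicy | None = None, id_a: str = "a", id_b: str = "b"
) -> PairwiseAlignment:
    """Optimal global alignment of two same-alphabet sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alpha_a, alpha_b = detect_alphabet(a), detect_alphabet(b)
    if policy is None:
        policy = default_policy("aa" if "aa" in (alpha_a, alpha_b) else "nt")
    if policy.alphabet == "nt" and "aa" in (alpha_a, alpha_b):
        raise ValueError("mixed alphabets: amino-acid sequence under an nt policy")
    aligner = _make_aligner(policy)
    aln = aligner.align(a.upper(), b.upper())[0]
    return PairwiseAlignment(id_a, id_b, str(aln[0]), str(aln[1]), float(aln.score), policy)


def _column_counts(aln: PairwiseAlignment) -> tuple[int, int, int]:
    """(matches, gap-free columns, differing gap-free columns)."""
    amb = AMBIGUOUS[aln.policy.alphabet]
    matches = gapfree = diffs = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            continue
        gapfree += 1
        if x == y and x != amb:
            matches += 1
        else:
            diffs += 1
    return matches, gapfree, diffs


def percent_identity(aln: PairwiseAlignment) -> float:
    """Percent identity under the alignment's denominator policy."""
    matches, gapfree, _ = _column_counts(aln)
    denom_kind = aln.policy.identity_denominator
    if denom_kind == "aligned_columns_excluding_gaps":
        denom = gapfree
    elif denom_kind == "alignment_length":
        denom = len(aln.aligned_a)
    else:
        denom = min(
            len(aln.aligned_a.replace("-", "")), len(aln.aligned_b.replace("-", ""))
        )
    if denom == 0:
        raise ValueError("identity denominator is zero (no comparable columns)")
    return 100.0 * matches / denom


def residue_changes(aln: PairwiseAlignment) -> int:
    """Count of aligned, gap-free columns whose residues differ."""
    _, _, diffs = _column_counts(aln)
    return diffs


@dataclass
class IdentityMatrix:
    """Symmetric pairwise matrix over a gene set.

    ``values`` is percent scale: percent identity for identity metrics
    (diagonal 100) or percent of compared columns that differ for
    ``aa_divergence`` (diagonal 0). For ``aa_divergence`` the residue-change
    counts are stored in ``counts`` and are the primary readout.
    """

    gene_ids: list[str]
    values: np.ndarray
    metric: Literal["nt_identity", "aa_identity", "aa_divergence"]
    policy: AlignmentPolicy
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match gene_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
            raise ValueError("values outside [0, 100]")

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.values[iu]

    def offdiag_counts(self) -> np.ndarray:
        if self.counts is None:
            raise ValueError("no counts stored for this metric")
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.counts[iu]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)
        df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")

    @staticmethod
    def from_tsv(path: str | Path, metric: str = "nt_identity") -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return IdentityMatrix(
            list(df.index), df.to_numpy(dtype=float), metric, default_policy("nt")
        )


def _sequences_for(genes: Sequence[GeneModel | tuple[str, str]], metric: str):
    out = []
    for g in genes:
        if isinstance(g, GeneModel):
            seq = g.cds_seq if metric == "nt_identity" else g.protein_seq
            if not seq:
                raise ValueError(f"{g.gene_id}: missing sequence for metric {metric}")
            out.append((g.gene_id, seq))
        else:
            out.append(g)
    return out


def pairwise_matrix(
    genes: Sequence[GeneModel | tuple[str, str]],
    metric: Literal["nt_identity", "aa_identity", "aa_divergence"] = "aa_divergence",
    policy: AlignmentPolicy | None = None,
    precomputed: SequenceSet | None = None,
) -> IdentityMatrix:
    """All-pairs identity/divergence matrix.

    ``precomputed`` may carry an externally produced multiple alignment
    (equal-length gapped rows keyed by gene id), in which case each pair is
    scored column-wise from those rows instead of being re-aligned.
    """
    pairs = _sequences_for(genes, metric)
    if len(pairs) < 2:
        raise ValueError("need at least two genes for a pairwise matrix")
    if policy is None:
        policy = default_policy("nt" if metric == "nt_identity" else "aa")
    n = len(pairs)
    values = np.full((n, n), 0.0 if metric == "aa_divergence" else 100.0)
    counts = np.zeros((n, n), dtype=int) if metric == "aa_divergence" else None
    aligned = precomputed.as_dict() if precomputed is not None else None
    for i in range(n):
        for j in range(i + 1, n):
            ida, a = pairs[i]
            idb, b = pairs[j]
            if aligned is not None:
                aln = PairwiseAlignment(ida, idb, aligned[ida], aligned[idb], 0.0, policy)
            else:
                aln = align_global(a, b, policy, ida, idb)
            if metric == "aa_divergence":
                d = residue_changes(aln)
                counts[i, j] = counts[j, i] = d
                _, gapfree, _ = _column_counts(aln)
                pct = 100.0 * d / gapfree if gapfree else 0.0
                values[i, j] = values[j, i] = pct
            else:
                pct = percent_identity(aln)
                values[i, j] = values[j, i] = pct
    return IdentityMatrix(
        [p[0] for p in pairs], values, metric, policy, counts=counts
    )


@dataclass(frozen=True)
class DivergenceSummary:
    species: str
    median: float
    lower_quartile: float
    upper_quartile: float
    comparison: Literal["within_species", "vs_reference"]
    n_pairs: int


def summarize_divergence(
    values: Iterable[float],
    species: str = "",
    comparison: Literal["within_species", "vs_reference"] = "within_species",
) -> DivergenceSummary:
    """Median and quartiles (linear interpolation between order statistics)
    of pooled pairwise divergence values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no pairwise values to summarise")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return DivergenceSummary(species, float(med), float(q1), float(q3), comparison, arr.size)


def vs_reference_values(
    genes: Sequence[GeneModel | tuple[str, str]],
    references: Sequence[GeneModel | tuple[str, str]],
    metric: str = "aa_divergence",
    policy: AlignmentPolicy | None = None,
    as_counts: bool = True,
) -> np.ndarray:
    """All |genes| x |references| pairwise divergences against a reference set."""
    gs = _sequences_for(genes, metric)
    rs = _sequences_for(references, metric)
    if not gs or not rs:
        raise ValueError("empty comparison set")
    if policy is None:
        policy = default_policy("nt" if metric == "nt_identity" else "aa")
    out = np.empty((len(gs), len(rs)))
    for i, (ida, a) in enumerate(gs):
        for j, (idb, b) in enumerate(rs):
            aln = align_global(a, b, policy, ida, idb)
            if metric == "aa_divergence":
                out[i, j] = residue_changes(aln) if as_counts else 100 - percent_identity(aln)
            else:
                out[i, j] = percent_identity(aln)
    return out.ravel()


@dataclass
class Subfamily:
    """Genes of one species with exactly identical protein sequence."""

    species: str
    representative_protein: str
    member_ids: list[str]
    n_diff_vs_reference: int | None = None


def group_subfamilies(
    genes: Sequence[GeneModel],
    reference_proteins: Sequence[str] | None = None,
    policy: AlignmentPolicy | None = None,
) -> list[Subfamily]:
    """Partition one species' genes into exact-protein subfamilies; if a
    reference protein set is given, attach the minimum aligned residue-change
    count against it."""
    by_protein: dict[str, list[str]] = {}
    species = genes[0].species if genes else ""
    for g in genes:
        if not g.protein_seq:
            raise ValueError(f"{g.gene_id}: missing protein sequence")
        by_protein.setdefault(g.protein_seq, []).append(g.gene_id)
    if policy is None:
        policy = default_policy("aa")
    subfamilies = []
    for prot, members in sorted(by_protein.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        ndiff = None
        if reference_proteins:
            ndiff = min(
                residue_changes(align_global(prot, ref, policy))
                for ref in reference_proteins
            )
        subfamilies.append(Subfamily(species, prot, sorted(members), ndiff))
    return subfamilies


@dataclass(frozen=True)
class ResidueChangeMap:
    reference: str
    counts: np.ndarray  # per reference residue (1-based positions = index + 1)
    flagged_positions: list[int]
    min_subfamilies: int


def residue_change_map(
    subfamilies: Sequence[Subfamily],
    reference: str,
    min_subfamilies: int = 3,
    policy: AlignmentPolicy | None = None,
) -> ResidueChangeMap:
    """Per-reference-residue count of subfamilies whose aligned residue
    differs from the reference (a gap against the reference counts as a
    difference); positions hit by >= ``min_subfamilies`` subfamilies are
    flagged."""
    if not subfamilies:
        raise ValueError("no subfamilies given")
    if policy is None:
        policy = default_policy("aa")
    counts = np.zeros(len(reference), dtype=int)
    for sf in subfamilies:
        aln = align_global(sf.representative_protein, reference, policy)
        ref_pos = 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if y == "-":
                continue
            if x != y:
                counts[ref_pos] += 1
            ref_pos += 1
    flagged = [i + 1 for i, c in enumerate(counts) if c >= min_subfamilies]
    return ResidueChangeMap(reference, counts, flagged, min_subfamilies)
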