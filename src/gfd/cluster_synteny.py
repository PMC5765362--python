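"""Genomic clustering of gene-family members and anchor-based synteny maps.

Clusters are called by single-linkage chaining along a chromosome: two
consecutive family members whose intergenic gap (next start minus previous
end) is at most ``max_gap`` join one cluster. Synteny is assessed on
relative coordinates obtained by fixing one conserved anchor gene as the
origin in every species; a species whose shared anchors appear in reversed
rank order relative to the reference is reported as inverted.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from scipy.stats import spearmanr

from .core_io import GeneModel


@dataclass
class ClusterAssignment:
    """A genomic cluster of gene copies, ordered by position."""

    cluster_id: str
    species: str
    chromosome: str
    member_ids: list[str]
    span: tuple[int, int]  # 0-based half-open


def _cluster_labels() -> Iterable[str]:
    letters = string.ascii_lowercase
    yield from letters
    for a, b in itertools.product(letters, letters):
        yield a + b


def call_clusters(
    genes: Sequence[GeneModel], max_gap: int
) -> list[ClusterAssignment]:
    """Chain family members into clusters per chromosome.

    The gap between consecutive genes is ``next.start - prev.end``; a gap of
    exactly ``max_gap`` still joins (inclusive rule). Singleton clusters are
    allowed. Cluster ids are ``<chromosome>-<letter>`` assigned by chromosome
    name then position.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    for g in genes:
        if g.start is None or g.end is None:
            raise ValueError(f"{g.gene_id}: gene lacks coordinates")
    clusters: list[ClusterAssignment] = []
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault((g.species, g.chromosome), []).append(g)
    for (species, chrom), members in sorted(by_chrom.items()):
        members = sorted(members, key=lambda m: (m.start, m.end, m.gene_id))
        labels = _cluster_labels()
        run: list[GeneModel] = []
        runs: list[list[GeneModel]] = []
        for g in members:
            if run and g.start - run[-1].end > max_gap:
                runs.append(run)
                run = []
            run.append(g)
        if run:
            runs.append(run)
        for label, rgenes in zip(labels, runs):
            clusters.append(
                ClusterAssignment(
                    cluster_id=f"{chrom}-{label}",
                    species=species,
                    chromosome=chrom,
                    member_ids=[g.gene_id for g in rgenes],
                    span=(rgenes[0].start, max(g.end for g in rgenes)),
                )
            )
    return clusters


def clusters_to_bed(clusters: Sequence[ClusterAssignment], path: str | Path) -> None:
    """BED6-like output: chrom, start, end, cluster_id, size, strand('.')
    plus a 7th column with comma-joined member ids."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chromosome}\t{c.span[0]}\t{c.span[1]}\t{c.cluster_id}\t"
                f"{len(c.member_ids)}\t.\t{','.join(c.member_ids)}\n"
            )


def clusters_from_bed(path: str | Path, species: str = "unknown") -> list[ClusterAssignment]:
    clusters = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        chrom, start, end, cid = parts[0], int(parts[1]), int(parts[2]), parts[3]
        members = parts[6].split(",") if len(parts) > 6 and parts[6] else []
        clusters.append(ClusterAssignment(cid, species, chrom, members, (start, end)))
    return clusters


@dataclass
class AnchorMap:
    """Anchor-relative coordinate system across species.

    ``relative_positions[species][gene_id]`` is the signed nucleotide offset
    of a gene's start from the origin anchor's start in that species.
    """

    anchor_ids: list[str]
    origin_anchor: str
    reference_species: str
    relative_positions: dict[str, dict[str, int]]
    orientation: dict[str, Literal["same", "inverted"]]

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for sp, positions in sorted(self.relative_positions.items()):
            for gid, pos in sorted(positions.items(), key=lambda kv: kv[1]):
                rows.append((sp, gid, pos, self.orientation[sp]))
        pd.DataFrame(
            rows, columns=["species", "anchor_id", "relative_position", "orientation"]
        ).to_csv(path, sep="\t", index=False)


def build_anchor_map(
    anchors_by_species: dict[str, Sequence[GeneModel]],
    origin_anchor: str,
    reference_species: str | None = None,
) -> AnchorMap:
    """Anchor-relative offsets per species, with inversion detection.

    Orientation is 'inverted' when the Spearman rank correlation between a
    species' shared-anchor order and the reference species' order is
    negative; at least two shared anchors are required.
    """
    if reference_species is None:
        reference_species = sorted(anchors_by_species)[0]
    rel: dict[str, dict[str, int]] = {}
    orientation: dict[str, str] = {}
    ref_positions: dict[str, int] = {}
    for sp, anchors in anchors_by_species.items():
        starts = {a.gene_id: a.start for a in anchors}
        if origin_anchor not in starts:
            raise ValueError(f"origin anchor {origin_anchor!r} missing in {sp}")
        origin = starts[origin_anchor]
        rel[sp] = {gid: s - origin for gid, s in starts.items()}
    ref_positions = rel[reference_species]
    for sp, positions in rel.items():
        shared = sorted(set(positions) & set(ref_positions))
        if len(shared) < 2:
            raise ValueError(
                f"{sp}: need >=2 anchors shared with {reference_species} to orient"
            )
        rho = spearmanr(
            [ref_positions[g] for g in shared], [positions[g] for g in shared]
        ).statistic
        orientation[sp] = "inverted" if rho < 0 else "same"
    anchor_ids = sorted(
        set().union(*(set(p) for p in rel.values())),
        key=lambda g: ref_positions.get(g, 0),
    )
    return AnchorMap(anchor_ids, origin_anchor, reference_species, rel, orientation)


def cluster_anchor_overlap(
    clusters: Sequence[ClusterAssignment],
    anchors: Sequence[GeneModel],
) -> dict[str, str]:
    """Classify each cluster span against the anchor span of its chromosome.

    Returns cluster_id -> 'within_anchor_span' | 'outside' | 'partial';
    clusters on chromosomes carrying no anchors are 'outside'.
    """
    spans: dict[str, tuple[int, int]] = {}
    for a in anchors:
        lo, hi = spans.get(a.chromosome, (a.start, a.end))
        spans[a.chromosome] = (min(lo, a.start), max(hi, a.end))
    report = {}
    for c in clusters:
        if c.chromosome not in spans:
            report[c.cluster_id] = "outside"
            continue
        alo, ahi = spans[c.chromosome]
        clo, chi = c.span
        if clo >= alo and chi <= ahi:
            report[c.cluster_id] = "within_anchor_span"
        elif chi <= alo or clo >= ahi:
            report[c.cluster_id] = "outside"
        else:
            report[c.cluster_id] = "partial"
    return report
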