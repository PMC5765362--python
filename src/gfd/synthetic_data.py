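"""Forward simulator of lineage-specific gene-family evolution.

A single ancestral gene evolves along a species tree under a Gillespie
process with per-gene duplication, translocation and loss, per-ordered-pair
within-cluster gene conversion, per-site nucleotide mutation filtered by a
nonsynonymous acceptance probability (purifying selection as a single knob),
and per-gene intron gain/loss. Tandem duplication grows physical clusters;
translocation seeds new clusters far away, so the emitted coordinates
reproduce the cluster structure the analysis modules assume. Conversion
overwrites the acceptor's entire CDS with the donor's, homogenising clusters
the way concerted evolution does.

Mutations that would destroy the start codon, the terminal stop, or create
an in-frame internal stop are always rejected (treated as lethal), so every
emitted gene remains a valid ORF. Output is deterministic given the config
(including its seed).
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .cluster_synteny import ClusterAssignment, clusters_to_bed, _cluster_labels
from .core_io import (
    STOP_CODONS,
    GeneModel,
    SpeciesTree,
    read_newick,
    translate_cds,
    write_fasta,
    write_gff3,
)

DEFAULT_SPECIES_TREE = (
    "((((elegans:0.3,sp34:0.3):0.2,briggsae:0.5):0.2,remanei:0.7):0.3,angaria:1.0);"
)

_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


@dataclass
class SimulationConfig:
    """Rates are events per gene (or per ordered within-cluster gene pair,
    for conversion) per unit branch length; mutation_rate is substitutions
    per site per unit branch length. ``ancestral_cds_length`` is in codons,
    stop included (the default 128 codons = 384 nt)."""

    species_tree: str = DEFAULT_SPECIES_TREE
    seed: int = 0
    rate_duplication: float = 1.2
    rate_translocation: float = 0.2
    rate_loss: float = 0.3
    rate_conversion: float = 3.0
    mutation_rate: float = 0.3
    nonsyn_acceptance: float = 0.05
    intron_gain_rate: float = 0.03
    intron_loss_rate: float = 0.15
    ancestral_cds_length: int = 128
    ancestral_intron_positions: tuple[int, ...] = (10,)
    tandem_spacing: int = 500
    translocation_min_distance: int = 100_000
    intron_length: int = 60
    root_stem_length: float = 0.5

    def __post_init__(self) -> None:
        rates = [
            self.rate_duplication,
            self.rate_translocation,
            self.rate_loss,
            self.rate_conversion,
            self.mutation_rate,
            self.intron_gain_rate,
            self.intron_loss_rate,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if not 0 <= self.nonsyn_acceptance <= 1:
            raise ValueError("nonsyn_acceptance must be in [0, 1]")
        if self.ancestral_cds_length < 2:
            raise ValueError("ancestral CDS must be at least 2 codons")

    @staticmethod
    def from_yaml(path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "ancestral_intron_positions" in data:
            data["ancestral_intron_positions"] = tuple(data["ancestral_intron_positions"])
        return SimulationConfig(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ancestral_intron_positions"] = list(self.ancestral_intron_positions)
        return d


@dataclass
class SimEvent:
    time: float
    branch: str
    type: str
    gene_ids: list[str]
    details: dict = field(default_factory=dict)


@dataclass
class SimEventLog:
    events: list[SimEvent] = field(default_factory=list)

    def add(self, *args, **kwargs) -> None:
        self.events.append(SimEvent(*args, **kwargs))

    def by_type(self, event_type: str) -> list[SimEvent]:
        return [e for e in self.events if e.type == event_type]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps([asdict(e) for e in self.events], indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class _SimGene:
    gene_id: str
    cds: str
    introns: list[int]


@dataclass
class SimOutput:
    config: SimulationConfig
    models_by_species: dict[str, list[GeneModel]]
    true_clusters: dict[str, list[ClusterAssignment]]
    event_log: SimEventLog
    ancestral_cds: str
    ancestral_protein: str

    def all_models(self) -> list[GeneModel]:
        return [m for models in self.models_by_species.values() for m in models]


class _Simulator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.log = SimEventLog()
        self.counter = itertools.count(1)

    def _new_id(self) -> str:
        return f"g{next(self.counter)}"

    def ancestral_gene(self) -> _SimGene:
        codons = ["ATG"]
        codons += [
            _SENSE_CODONS[int(i)]
            for i in self.rng.integers(len(_SENSE_CODONS), size=self.cfg.ancestral_cds_length - 2)
        ]
        codons.append(sorted(STOP_CODONS)[int(self.rng.integers(len(STOP_CODONS)))])
        introns = sorted(
            p for p in self.cfg.ancestral_intron_positions
            if 1 <= p <= self.cfg.ancestral_cds_length - 1
        )
        return _SimGene(self._new_id(), "".join(codons), list(introns))

    # -- event execution ---------------------------------------------------

    def _pick_gene(self, state: list[list[_SimGene]]) -> tuple[int, int]:
        flat = [(ci, gi) for ci, cl in enumerate(state) for gi in range(len(cl))]
        return flat[int(self.rng.integers(len(flat)))]

    def _substitute(self, state, t, branch) -> None:
        ci, gi = self._pick_gene(state)
        gene = state[ci][gi]
        cds = gene.cds
        site = int(self.rng.integers(len(cds)))
        old = cds[site]
        choices = [b for b in "ACGT" if b != old]
        new = choices[int(self.rng.integers(3))]
        codon_idx = site // 3
        cstart = codon_idx * 3
        old_codon = cds[cstart : cstart + 3]
        new_codon = (
            old_codon[: site - cstart] + new + old_codon[site - cstart + 1 :]
        )
        last_idx = len(cds) // 3 - 1
        if codon_idx == 0:
            return  # start codon is invariant (lethal otherwise)
        if codon_idx == last_idx:
            if new_codon not in STOP_CODONS:
                return  # losing the terminal stop is lethal
            kind = "substitution_syn"  # stop-to-stop: protein unchanged
        elif new_codon in STOP_CODONS:
            return  # premature stop is lethal
        else:
            old_aa = translate_cds(old_codon, include_stop=True)
            new_aa = translate_cds(new_codon, include_stop=True)
            if old_aa == new_aa:
                kind = "substitution_syn"
            else:
                kind = "substitution_nonsyn"
                if self.rng.random() >= self.cfg.nonsyn_acceptance:
                    return  # purged by purifying selection
        gene.cds = cds[:site] + new + cds[site + 1 :]
        self.log.add(t, branch, kind, [gene.gene_id], {"site": site, "from": old, "to": new})

    def _duplicate(self, state, t, branch) -> None:
        ci, gi = self._pick_gene(state)
        parent = state[ci][gi]
        child = _SimGene(self._new_id(), parent.cds, list(parent.introns))
        state[ci].insert(gi + 1, child)
        self.log.add(t, branch, "dup", [parent.gene_id, child.gene_id])

    def _translocate(self, state, t, branch) -> None:
        ci, gi = self._pick_gene(state)
        gene = state[ci].pop(gi)
        if not state[ci]:
            state.pop(ci)
        state.append([gene])
        self.log.add(t, branch, "trans", [gene.gene_id])

    def _lose(self, state, t, branch) -> None:
        ci, gi = self._pick_gene(state)
        gene = state[ci].pop(gi)
        if not state[ci]:
            state.pop(ci)
        self.log.add(t, branch, "loss", [gene.gene_id])
        if not state:
            self.log.add(t, branch, "extinction", [])

    def _convert(self, state, t, branch) -> None:
        weights = np.array([len(c) * (len(c) - 1) for c in state], dtype=float)
        total = weights.sum()
        if total == 0:
            return
        ci = int(self.rng.choice(len(state), p=weights / total))
        cluster = state[ci]
        di, ai = self.rng.choice(len(cluster), size=2, replace=False)
        donor, acceptor = cluster[int(di)], cluster[int(ai)]
        acceptor.cds = donor.cds
        self.log.add(t, branch, "conversion", [donor.gene_id, acceptor.gene_id])

    def _intron_gain(self, state, t, branch) -> None:
        ci, gi = self._pick_gene(state)
        gene = state[ci][gi]
        prot_len = len(gene.cds) // 3 - 1
        available = sorted(set(range(1, prot_len + 1)) - set(gene.introns))
        if not available:
            return
        pos = available[int(self.rng.integers(len(available)))]
        gene.introns = sorted(gene.introns + [pos])
        self.log.add(t, branch, "intron_gain", [gene.gene_id], {"position": pos})

    def _intron_loss(self, state, t, branch) -> None:
        ci, gi = self._pick_gene(state)
        gene = state[ci][gi]
        if not gene.introns:
            return
        pos = gene.introns[int(self.rng.integers(len(gene.introns)))]
        gene.introns = [p for p in gene.introns if p != pos]
        self.log.add(t, branch, "intron_loss", [gene.gene_id], {"position": pos})

    # -- branch evolution --------------------------------------------------

    def evolve_branch(self, state: list[list[_SimGene]], length: float, branch: str) -> None:
        cfg = self.cfg
        cds_len = cfg.ancestral_cds_length * 3
        t = 0.0
        while True:
            n = sum(len(c) for c in state)
            if n == 0:
                return
            pair_count = sum(len(c) * (len(c) - 1) for c in state)
            rates = np.array(
                [
                    cfg.rate_duplication * n,
                    cfg.rate_translocation * n,
                    cfg.rate_loss * n,
                    cfg.rate_conversion * pair_count,
                    cfg.mutation_rate * n * cds_len,
                    cfg.intron_gain_rate * n,
                    cfg.intron_loss_rate * n,
                ]
            )
            total = rates.sum()
            if total == 0:
                return
            t += self.rng.exponential(1.0 / total)
            if t > length:
                return
            kind = int(self.rng.choice(7, p=rates / total))
            handler = (
                self._duplicate,
                self._translocate,
                self._lose,
                self._convert,
                self._substitute,
                self._intron_gain,
                self._intron_loss,
            )[kind]
            handler(state, t, branch)

    def run(self) -> SimOutput:
        cfg = self.cfg
        tree = read_newick(cfg.species_tree).tree
        root_state = [[self.ancestral_gene()]]
        ancestral = root_state[0][0]
        anc_cds = ancestral.cds
        if cfg.root_stem_length > 0:
            self.evolve_branch(root_state, cfg.root_stem_length, "stem")
        leaf_states: dict[str, list[list[_SimGene]]] = {}

        internal_idx = itertools.count(1)

        def recurse(node, state):
            for child in node.child_nodes():
                child_state = copy.deepcopy(state)
                # renumber duplicated lineage copies so ids stay unique per leaf?
                branch = (
                    child.taxon.label
                    if child.is_leaf()
                    else f"internal{next(internal_idx)}"
                )
                self.evolve_branch(child_state, child.edge.length or 0.0, branch)
                if child.is_leaf():
                    leaf_states[child.taxon.label] = child_state
                else:
                    recurse(child, child_state)

        recurse(tree.seed_node, root_state)

        models_by_species: dict[str, list[GeneModel]] = {}
        clusters_by_species: dict[str, list[ClusterAssignment]] = {}
        for species in sorted(leaf_states):
            models, clusters = self._lay_out(species, leaf_states[species])
            models_by_species[species] = models
            clusters_by_species[species] = clusters
        return SimOutput(
            config=cfg,
            models_by_species=models_by_species,
            true_clusters=clusters_by_species,
            event_log=self.log,
            ancestral_cds=anc_cds,
            ancestral_protein=translate_cds(anc_cds),
        )

    def _lay_out(self, species: str, state: list[list[_SimGene]]):
        """Assign genomic coordinates: tandem spacing within clusters, at
        least ``translocation_min_distance`` between clusters."""
        cfg = self.cfg
        chrom = "chr1"
        cursor = 10_000
        models: list[GeneModel] = []
        clusters: list[ClusterAssignment] = []
        labels = _cluster_labels()
        for cluster_genes in state:
            label = next(labels)
            member_ids = []
            span_start = cursor
            for gene in cluster_genes:
                exon_lens = _exon_lengths(len(gene.cds), gene.introns)
                exons = []
                pos = cursor
                for k, ln in enumerate(exon_lens):
                    exons.append((pos, pos + ln))
                    pos += ln
                    if k < len(exon_lens) - 1:
                        pos += cfg.intron_length
                gid = f"{species}_{gene.gene_id}"
                models.append(
                    GeneModel(
                        gene_id=gid,
                        species=species,
                        chromosome=chrom,
                        start=cursor,
                        end=pos,
                        strand="+",
                        exons=exons,
                        cds_seq=gene.cds,
                        intron_positions_aa=list(gene.introns),
                    )
                )
                member_ids.append(gid)
                cursor = pos + cfg.tandem_spacing
            if member_ids:
                span_end = models[-1].end
                clusters.append(
                    ClusterAssignment(
                        cluster_id=f"{chrom}-{label}",
                        species=species,
                        chromosome=chrom,
                        member_ids=member_ids,
                        span=(span_start, span_end),
                    )
                )
                cursor = span_end + cfg.translocation_min_distance
        return models, clusters


def _exon_lengths(cds_len: int, introns: Sequence[int]) -> list[int]:
    """Split a CDS at codon boundaries: an intron after residue k falls
    after nucleotide 3k."""
    boundaries = [3 * k for k in introns]
    edges = [0] + boundaries + [cds_len]
    return [b - a for a, b in zip(edges, edges[1:])]


def simulate(config: SimulationConfig | None = None, **overrides) -> SimOutput:
    """Run the forward simulation; keyword overrides patch the default
    config (e.g. ``simulate(seed=3, rate_conversion=10.0)``)."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        d = config.to_dict()
        d.update(overrides)
        d["ancestral_intron_positions"] = tuple(d["ancestral_intron_positions"])
        config = SimulationConfig(**d)
    return _Simulator(config).run()


def emit(output: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write per-species genome FASTA, CDS FASTA, GFF3 and true-cluster BED,
    plus the event log and config. Re-reading the GFF3 + genome FASTA with
    core_io reproduces the gene models exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for species, models in sorted(output.models_by_species.items()):
        chrom_len = max((m.end for m in models), default=0) + 10_000
        genome = bytearray(b"N" * chrom_len)
        for m in models:
            offset = 0
            for s, e in m.exons:
                genome[s:e] = m.cds_seq[offset : offset + (e - s)].encode()
                offset += e - s
        gpath = outdir / f"{species}.genome.fasta"
        write_fasta({"chr1": genome.decode()}, gpath)
        cpath = outdir / f"{species}.cds.fasta"
        write_fasta({m.gene_id: m.cds_seq for m in models}, cpath)
        gffpath = outdir / f"{species}.gff3"
        write_gff3(models, gffpath)
        bedpath = outdir / f"{species}.clusters.bed"
        clusters_to_bed(output.true_clusters[species], bedpath)
        written.update(
            {
                f"{species}.genome": gpath,
                f"{species}.cds": cpath,
                f"{species}.gff3": gffpath,
                f"{species}.clusters": bedpath,
            }
        )
    events = outdir / "events.json"
    output.event_log.to_json(events)
    written["events"] = events
    cfgpath = outdir / "config.json"
    cfgpath.write_text(json.dumps(output.config.to_dict(), indent=1, sort_keys=True) + "\n")
    written["config"] = cfgpath
    return written
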