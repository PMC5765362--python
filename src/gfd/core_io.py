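"""Input/output and shared data model.

All genomic intervals are stored 0-based, half-open; on-disk GFF3 is 1-based,
inclusive (the GFF3 standard). CDS sequences are spliced, stranded (5'->3')
and include the terminal stop codon; protein sequences exclude it. Intron
placement is encoded as "intron after residue k" (1-based residue numbering):
a splice junction falling inside codon k is assigned to residue k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_CHARS = set("ACGTN")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_STANDARD.forward_table)
STOP_CODONS = set(_STANDARD.stop_codons)
START_CODON = "ATG"


class GfdIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# sequence sets


@dataclass(frozen=True)
class SeqRecordGfd:
    id: str
    seq: str
    alphabet: Literal["nt", "aa"]


@dataclass
class SequenceSet:
    """An ordered set of uniquely named sequences sharing one alphabet."""

    records: list[SeqRecordGfd]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GfdIOError(f"duplicate sequence ids: {', '.join(dupes)}")
        alphabets = {r.alphabet for r in self.records}
        if len(alphabets) > 1:
            raise GfdIOError("mixed alphabets within one sequence set")
        for r in self.records:
            if not r.seq:
                raise GfdIOError(f"empty sequence for id {r.id!r}")

    @property
    def alphabet(self) -> str:
        return self.records[0].alphabet if self.records else "nt"

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.seq
        raise KeyError(seq_id)

    def as_dict(self) -> dict[str, str]:
        return {r.id: r.seq for r in self.records}


def detect_alphabet(seq: str) -> str:
    """'nt' iff every character is in {A,C,G,T,N}; otherwise 'aa'."""
    return "nt" if set(seq.upper()) <= NT_CHARS else "aa"


def read_fasta(path: str | Path, alphabet: str | None = None) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased. The alphabet is auto-detected per file (any
    residue outside {A,C,G,T,N} in any record makes the whole set amino
    acid); pass ``alphabet`` to override.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise GfdIOError(f"no FASTA records in {path}")
    if alphabet is None:
        alphabet = "nt" if all(detect_alphabet(s) == "nt" for _, s in records) else "aa"
    return SequenceSet([SeqRecordGfd(i, s, alphabet) for i, s in records])


def write_fasta(seqs: SequenceSet | dict[str, str], path: str | Path) -> None:
    if isinstance(seqs, SequenceSet):
        items = [(r.id, r.seq) for r in seqs.records]
    else:
        items = list(seqs.items())
    SeqIO.write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in items], str(path), "fasta"
    )


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """One annotated gene copy.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order regardless of strand; ``cds_seq`` is the spliced, strand-corrected
    coding sequence including the stop codon.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    cds_seq: str
    protein_seq: str = ""
    intron_positions_aa: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GfdIOError(f"{self.gene_id}: end must exceed start")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise GfdIOError(f"{self.gene_id}: overlapping exons")
        self.exons = exons
        if self.exons and sum(e - s for s, e in self.exons) != len(self.cds_seq):
            raise GfdIOError(f"{self.gene_id}: exon lengths do not sum to CDS length")
        if not self.protein_seq and len(self.cds_seq) % 3 == 0:
            self.protein_seq = translate_cds(self.cds_seq)
        pos = self.intron_positions_aa
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise GfdIOError(f"{self.gene_id}: intron positions not strictly increasing")
        if self.protein_seq and pos:
            if pos[0] < 1 or pos[-1] > len(self.protein_seq):
                raise GfdIOError(f"{self.gene_id}: intron position outside protein")

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def n_exons(self) -> int:
        return max(1, len(self.exons))


def translate_cds(cds: str, include_stop: bool = False) -> str:
    """Translate a spliced CDS with the standard code.

    Codons containing N (or any non-ACGT character) yield ``X``. The terminal
    stop codon is dropped unless ``include_stop``; stops are rendered ``*``.
    """
    cds = cds.upper()
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in _FORWARD:
            aas.append(_FORWARD[codon])
        elif codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append("X")
    prot = "".join(aas)
    if not include_stop and prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass(frozen=True)
class OrfReport:
    gene_id: str
    has_start: bool
    has_terminal_stop: bool
    length_multiple_of_3: bool
    no_internal_stop: bool

    @property
    def passed(self) -> bool:
        return (
            self.has_start
            and self.has_terminal_stop
            and self.length_multiple_of_3
            and self.no_internal_stop
        )


def validate_orf(model: GeneModel) -> OrfReport:
    """Report-only ORF sanity check (start codon, in-frame terminal stop,
    length divisible by three, no in-frame internal stop)."""
    cds = model.cds_seq.upper()
    if not cds:
        raise GfdIOError(f"{model.gene_id}: empty CDS")
    mult3 = len(cds) % 3 == 0
    has_start = cds.startswith(START_CODON)
    has_stop = mult3 and cds[-3:] in STOP_CODONS
    last_full = len(cds) - len(cds) % 3
    end = last_full - 3 if mult3 else last_full  # terminal codon slot is not internal
    internal = any(cds[i : i + 3] in STOP_CODONS for i in range(0, end, 3))
    return OrfReport(model.gene_id, has_start, has_stop, mult3, not internal)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def intron_positions_from_exons(exon_lengths: Sequence[int]) -> list[int]:
    """Residue indices (1-based, 'intron after residue k') from spliced exon
    lengths in CDS order; a junction inside codon k maps to residue k."""
    positions = []
    offset = 0
    for length in exon_lengths[:-1]:
        offset += length
        positions.append((offset + 2) // 3)
    return positions


def read_gff3_gene_models(
    gff_path: str | Path, fasta: SequenceSet, species: str = "unknown"
) -> list[GeneModel]:
    """Assemble :class:`GeneModel` objects from a GFF3 file plus the genome
    FASTA providing chromosome sequences.

    CDS features are preferred; exon features are used for genes without CDS
    rows. Minus-strand genes are spliced in transcription order and
    reverse-complemented.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    chrom_seqs = fasta.as_dict()
    models: list[GeneModel] = []
    genes = list(db.features_of_type("gene"))
    if not genes:  # headerless minimal files: treat every mRNA as a gene
        genes = list(db.features_of_type("mRNA"))
    for gene in genes:
        parts = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not parts:
            parts = list(db.children(gene, featuretype="exon", order_by="start"))
        if not parts:
            raise GfdIOError(f"{gene.id}: no CDS or exon children")
        chrom = gene.seqid
        if chrom not in chrom_seqs:
            raise GfdIOError(f"{gene.id}: chromosome {chrom!r} not in FASTA")
        chrom_seq = chrom_seqs[chrom]
        exons = [(f.start - 1, f.end) for f in parts]  # GFF3 1-based inclusive
        for s, e in exons:
            if s < 0 or e > len(chrom_seq):
                raise GfdIOError(f"{gene.id}: exon outside chromosome bounds")
        exons.sort()
        pieces = [chrom_seq[s:e] for s, e in exons]
        strand = gene.strand if gene.strand in "+-" else "+"
        if strand == "-":
            cds = _revcomp("".join(pieces))
            exon_lengths = [e - s for s, e in reversed(exons)]
        else:
            cds = "".join(pieces)
            exon_lengths = [e - s for s, e in exons]
        if set(cds) - NT_CHARS:
            bad = sorted(set(cds) - NT_CHARS)
            raise GfdIOError(f"{gene.id}: non-ACGTN characters in CDS: {bad}")
        models.append(
            GeneModel(
                gene_id=gene.id,
                species=species,
                chromosome=chrom,
                start=min(s for s, _ in exons),
                end=max(e for _, e in exons),
                strand=strand,
                exons=exons,
                cds_seq=cds,
                intron_positions_aa=intron_positions_from_exons(exon_lengths),
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.start, m.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/exon/CDS rows (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.chromosome}\tgfd\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(
                f"{base}gene\t{m.start + 1}\t{m.end}{tail}.\tID={m.gene_id}\n"
            )
            mrna = f"{m.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{m.start + 1}\t{m.end}{tail}.\tID={mrna};Parent={m.gene_id}\n"
            )
            phase = 0
            exon_iter = m.exons if m.strand == "+" else list(reversed(m.exons))
            for k, (s, e) in enumerate(exon_iter, 1):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}{tail}.\t"
                    f"ID={mrna}.exon{k};Parent={mrna}\n"
                )
                fh.write(
                    f"{base}CDS\t{s + 1}\t{e}{tail}{phase}\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3


# ---------------------------------------------------------------------------
# species trees


@dataclass
class SpeciesTree:
    """A rooted species tree with optional non-negative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise GfdIOError("duplicate leaf labels in species tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise GfdIOError("negative branch length in species tree")

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()


def read_newick(source: str | Path) -> SpeciesTree:
    """Read a Newick tree from a path or a literal Newick string."""
    text = str(source)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    return SpeciesTree(tree)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")
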