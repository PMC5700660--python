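"""Genome feature model: replicons, genes, intergenic regions.

Loads annotated prokaryotic genomes (GenBank flat files, or GFF3 plus a
FASTA of the replicon sequences) into a small in-memory model with exact
1-based inclusive coordinates, strands, replicon topology and the
organism taxonomy, and provides sequence access for genes and for the
gaps between consecutive genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Strand",
    "Topology",
    "GeneRecord",
    "Replicon",
    "IntergenicRegion",
    "GenomeSet",
    "GenomeError",
    "load_genome",
    "load_genbank",
    "load_gff3",
    "gene_sequence",
    "intergenic",
    "reverse_complement_replicon",
    "write_gene_table",
]


class GenomeError(ValueError):
    """Raised for inconsistent genome input."""


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"

    @property
    def flipped(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


@dataclass(frozen=True)
class GeneRecord:
    """One gene feature with 1-based inclusive nucleotide coordinates.

    A gene spanning the origin of a circular replicon is stored with
    ``wraps_origin=True`` and ``start > end``; its length is
    ``(replicon_length - start + 1) + end``.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: Strand
    protein_id: str | None = None
    product: str = ""
    protein_seq: str | None = None
    xrefs: tuple[str, ...] = ()
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise GenomeError(
                f"gene {self.gene_id}: coordinates must be >= 1"
            )
        if not self.wraps_origin and self.start > self.end:
            raise GenomeError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    def length(self, replicon_length: int | None = None) -> int:
        if self.wraps_origin:
            if replicon_length is None:
                raise GenomeError(
                    f"gene {self.gene_id} wraps the origin; replicon length required"
                )
            return (replicon_length - self.start + 1) + self.end
        return self.end - self.start + 1


@dataclass
class Replicon:
    """A chromosome or plasmid with its sorted gene list.

    ``taxonomy`` is the source lineage, highest rank first; the first
    two entries are the high-level taxonomy units shown next to each
    neighborhood row.
    """

    replicon_id: str
    organism: str
    taxonomy: tuple[str, ...]
    topology: Topology
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        for g in self.genes:
            if max(g.start, g.end) > self.length:
                raise GenomeError(
                    f"gene {g.gene_id} ends at {max(g.start, g.end)} beyond "
                    f"replicon length {self.length}"
                )
        self.genes.sort(key=lambda g: (g.start, g.end))

    @property
    def high_level_taxa(self) -> tuple[str, ...]:
        return self.taxonomy[:2]

    def gene_index(self, gene: GeneRecord) -> int:
        for i, g in enumerate(self.genes):
            if g is gene or g.gene_id == gene.gene_id:
                return i
        raise GenomeError(f"gene {gene.gene_id} not on replicon {self.replicon_id}")


@dataclass(frozen=True)
class IntergenicRegion:
    """The gap between two consecutive genes (may be empty).

    Between gene i ending at ``e`` and gene i+1 starting at ``s`` a gap
    exists iff ``s > e + 1``, with coordinates ``[e+1, s-1]``. Abutting
    or overlapping genes yield an empty region without sequence.
    """

    replicon_id: str
    start: int
    end: int
    left_gene: str
    right_gene: str
    empty: bool = False
    sequence: str | None = None
    reverse_complement: str | None = None
    span_length: int | None = None  # set for origin-wrapping gaps

    @property
    def gap_length(self) -> int:
        if self.empty:
            return 0
        if self.span_length is not None:
            return self.span_length
        return self.end - self.start + 1


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gene_sequence(replicon: Replicon, gene: GeneRecord) -> str:
    """Nucleotide sequence of a gene, reverse-complemented on ``-``.

    Requires the replicon to carry its sequence.
    """
    if replicon.sequence is None:
        raise GenomeError(f"replicon {replicon.replicon_id} has no sequence")
    if max(gene.start, gene.end) > len(replicon.sequence):
        raise GenomeError(
            f"gene {gene.gene_id} extends beyond the sequence "
            f"({len(replicon.sequence)} nt)"
        )
    if gene.wraps_origin:
        raw = replicon.sequence[gene.start - 1 :] + replicon.sequence[: gene.end]
    else:
        raw = replicon.sequence[gene.start - 1 : gene.end]
    return _revcomp(raw) if gene.strand is Strand.REVERSE else raw


def intergenic(
    replicon: Replicon, left_gene: GeneRecord, right_gene: GeneRecord
) -> IntergenicRegion:
    """Intergenic region between two genes adjacent in sorted order.

    Returns both strands of the gap when the replicon carries sequence.
    Overlapping or abutting genes give an empty, flagged region.
    """
    li = replicon.gene_index(left_gene)
    ri = replicon.gene_index(right_gene)
    n = len(replicon.genes)
    wraps = replicon.topology is Topology.CIRCULAR and li == n - 1 and ri == 0
    if ri != li + 1 and not wraps:
        raise GenomeError(
            f"genes {left_gene.gene_id} and {right_gene.gene_id} are not adjacent"
        )
    if wraps:
        gap_start = left_gene.end + 1
        gap_end = replicon.length + right_gene.start - 1  # virtual, unwrapped
        if gap_end < gap_start:
            return IntergenicRegion(
                replicon.replicon_id, 0, 0, left_gene.gene_id,
                right_gene.gene_id, empty=True,
            )
        seq = rc = None
        if replicon.sequence is not None:
            raw = (
                replicon.sequence[left_gene.end :]
                + replicon.sequence[: right_gene.start - 1]
            )
            seq, rc = raw, _revcomp(raw)
        return IntergenicRegion(
            replicon.replicon_id,
            gap_start if gap_start <= replicon.length else gap_start - replicon.length,
            right_gene.start - 1 if right_gene.start > 1 else replicon.length,
            left_gene.gene_id,
            right_gene.gene_id,
            empty=False,
            sequence=seq,
            reverse_complement=rc,
            span_length=gap_end - gap_start + 1,
        )
    e, s = left_gene.end, right_gene.start
    if s <= e + 1:
        return IntergenicRegion(
            replicon.replicon_id, 0, 0, left_gene.gene_id, right_gene.gene_id,
            empty=True,
        )
    seq = rc = None
    if replicon.sequence is not None:
        raw = replicon.sequence[e : s - 1]
        seq, rc = raw, _revcomp(raw)
    return IntergenicRegion(
        replicon.replicon_id, e + 1, s - 1, left_gene.gene_id,
        right_gene.gene_id, empty=False, sequence=seq, reverse_complement=rc,
    )


_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "ncRNA", "tmRNA", "misc_RNA"}


def load_genbank(path: str | Path) -> list[Replicon]:
    """Load one GenBank flat file (possibly multi-record) into Replicons.

    Coding and RNA features become :class:`GeneRecord` instances; a
    feature lacking both a protein id and a product is skipped. Topology
    is read from the record header (default linear). A compound
    location whose parts touch both ends of a circular record is
    normalized to the wrapped representation.
    """
    replicons: list[Replicon] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        topology = Topology(
            rec.annotations.get("topology", "linear")
            if rec.annotations.get("topology") in ("linear", "circular")
            else "linear"
        )
        length = len(rec.seq)
        genes: list[GeneRecord] = []
        seen = 0
        for feat in rec.features:
            if feat.type not in _FEATURE_TYPES:
                continue
            q = feat.qualifiers
            protein_id = (q.get("protein_id") or [None])[0]
            product = (q.get("product") or [""])[0]
            if protein_id is None and not product:
                continue
            seen += 1
            gene_id = (q.get("locus_tag") or q.get("gene") or [f"feat{seen}"])[0]
            strand = Strand.REVERSE if feat.location.strand == -1 else Strand.FORWARD
            parts = sorted(feat.location.parts, key=lambda p: int(p.start))
            wraps = (
                topology is Topology.CIRCULAR
                and len(parts) == 2
                and int(parts[0].start) == 0
                and int(parts[-1].end) == length
            )
            if wraps:
                start, end = int(parts[-1].start) + 1, int(parts[0].end)
            else:
                start, end = int(feat.location.start) + 1, int(feat.location.end)
            if max(start, end) > length:
                raise GenomeError(
                    f"{rec.id}: feature {gene_id} ends beyond the sequence"
                )
            xrefs = tuple(
                ref.split(":", 1)[1]
                for ref in q.get("db_xref", [])
                if ref.startswith("UniProt")
            )
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    replicon_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein_id=protein_id,
                    product=product,
                    protein_seq=(q.get("translation") or [None])[0],
                    xrefs=xrefs,
                    wraps_origin=wraps,
                )
            )
        replicons.append(
            Replicon(
                replicon_id=rec.id,
                organism=rec.annotations.get("organism", ""),
                taxonomy=tuple(rec.annotations.get("taxonomy", [])),
                topology=topology,
                length=length,
                genes=genes,
                sequence=str(rec.seq) if len(rec.seq) else None,
            )
        )
    if not replicons:
        raise GenomeError(f"no GenBank records in {path}")
    return replicons


def load_gff3(gff_path: str | Path, fasta_path: str | Path) -> list[Replicon]:
    """Load a GFF3 + FASTA pair into Replicons.

    One Replicon per FASTA sequence (GFF3 landmark); CDS features become
    genes. Topology comes from an ``Is_circular=true`` attribute on the
    landmark's ``region`` feature when present, else linear.
    """
    import gffutils

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise GenomeError(f"no sequences in {fasta_path}")
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    circular: set[str] = set()
    organism: dict[str, str] = {}
    for feat in db.features_of_type("region"):
        if feat.attributes.get("Is_circular", ["false"])[0].lower() == "true":
            circular.add(feat.seqid)
        if "organism" in feat.attributes:
            organism[feat.seqid] = feat.attributes["organism"][0]
    genes_by_seq: dict[str, list[GeneRecord]] = {sid: [] for sid in seqs}
    for i, feat in enumerate(db.features_of_type("CDS"), 1):
        if feat.seqid not in seqs:
            raise GenomeError(f"GFF3 landmark {feat.seqid} missing from FASTA")
        if feat.end > len(seqs[feat.seqid]):
            raise GenomeError(
                f"CDS {feat.id or i} ends beyond sequence {feat.seqid}"
            )
        attrs = feat.attributes
        genes_by_seq[feat.seqid].append(
            GeneRecord(
                gene_id=(attrs.get("ID") or attrs.get("Name") or [f"cds{i}"])[0],
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=Strand.REVERSE if feat.strand == "-" else Strand.FORWARD,
                protein_id=(attrs.get("protein_id") or [None])[0],
                product=(attrs.get("product") or [""])[0],
            )
        )
    return [
        Replicon(
            replicon_id=sid,
            organism=organism.get(sid, ""),
            taxonomy=(),
            topology=Topology.CIRCULAR if sid in circular else Topology.LINEAR,
            length=len(seq),
            genes=genes_by_seq[sid],
            sequence=seq,
        )
        for sid, seq in seqs.items()
    ]


def load_genome(
    path: str | Path, fasta: str | Path | None = None
) -> list[Replicon]:
    """Load a genome from GenBank, or from GFF3 when ``fasta`` is given."""
    path = Path(path)
    if fasta is not None or path.suffix.lower() in {".gff", ".gff3"}:
        if fasta is None:
            raise GenomeError("GFF3 input requires a FASTA companion file")
        return load_gff3(path, fasta)
    return load_genbank(path)


def reverse_complement_replicon(replicon: Replicon) -> Replicon:
    """Mirror a replicon: flip coordinates, strands, and the sequence.

    A gene at [s, e] maps to [L - e + 1, L - s + 1] with its strand
    swapped; rendered neighborhoods are invariant under this transform.
    """
    L = replicon.length
    genes = [
        replace(g, start=L - g.end + 1, end=L - g.start + 1, strand=g.strand.flipped)
        for g in replicon.genes
    ]
    return Replicon(
        replicon_id=replicon.replicon_id,
        organism=replicon.organism,
        taxonomy=replicon.taxonomy,
        topology=replicon.topology,
        length=L,
        genes=genes,
        sequence=_revcomp(replicon.sequence) if replicon.sequence else None,
    )


class GenomeSet:
    """A collection of replicons with a protein-id index."""

    def __init__(self, replicons: Iterable[Replicon]) -> None:
        self.replicons: list[Replicon] = list(replicons)
        self._by_protein: dict[str, tuple[Replicon, GeneRecord]] = {}
        for rep in self.replicons:
            for g in rep.genes:
                if g.protein_id is not None:
                    if g.protein_id in self._by_protein:
                        raise GenomeError(
                            f"duplicate protein_id {g.protein_id}"
                        )
                    self._by_protein[g.protein_id] = (rep, g)

    def __iter__(self) -> Iterator[Replicon]:
        return iter(self.replicons)

    def __len__(self) -> int:
        return len(self.replicons)

    def by_protein(self, protein_id: str) -> tuple[Replicon, GeneRecord]:
        """Replicon and gene encoding the given protein."""
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise GenomeError(f"unknown protein_id {protein_id}") from None

    def replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.replicon_id == replicon_id:
                return rep
        raise GenomeError(f"unknown replicon {replicon_id}")


def write_gene_table(path: str | Path, replicons: Iterable[Replicon]) -> None:
    """Write all genes as TSV (gene_id, replicon, coordinates, strand ...)."""
    with open(path, "w") as fh:
        fh.write("gene_id\treplicon\tstart\tend\tstrand\tprotein_id\tproduct\n")
        for rep in replicons:
            for g in rep.genes:
                fh.write(
                    f"{g.gene_id}\t{rep.replicon_id}\t{g.start}\t{g.end}\t"
                    f"{g.strand.value}\t{g.protein_id or ''}\t{g.product}\n"
                )
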