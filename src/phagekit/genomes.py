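"""Annotated genome handling: ordered gene calls and their I/O.

A :class:`Proteome` is one genome's ordered list of protein-coding gene
calls.  Genomes are treated as linear (assemblies are linearized before
annotation); coordinates are 0-based half-open internally and 1-based
inclusive on GFF3 I/O.  Two input routes are supported and yield identical
proteomes: GFF3 gene calls plus a protein FASTA, or a GenBank record with
CDS translations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "GeneCall",
    "Proteome",
    "read_proteome_gff",
    "read_proteome_genbank",
    "read_annotated_genomes",
    "write_protein_fasta",
    "write_proteome_gff",
]


@dataclass(frozen=True)
class GeneCall:
    """One protein-coding gene: position in gene order plus its product."""

    genome_id: str
    gene_id: str
    rank: int  # 0-based position in gene order
    strand: str  # '+' or '-'
    start: int  # 0-based half-open nucleotide coordinates
    end: int
    protein: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.genome_id}/{self.gene_id}: invalid coordinates [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.genome_id}/{self.gene_id}: strand must be '+' or '-'")
        if not self.protein:
            raise ValueError(f"{self.genome_id}/{self.gene_id}: empty protein sequence")

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


@dataclass
class Proteome:
    """Ordered gene calls of one genome."""

    genome_id: str
    genes: list[GeneCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.genome_id}: duplicate gene ids")
        for expected, g in enumerate(self.genes):
            if g.rank != expected:
                raise ValueError(
                    f"{self.genome_id}: ranks must be consecutive from 0 "
                    f"(found {g.rank} at position {expected})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def protein(self, gene_id: str) -> str:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g.protein
        raise KeyError(gene_id)


def _clean_protein(seq: str, where: str) -> str:
    seq = seq.rstrip("*").upper()
    if not seq:
        raise ValueError(f"{where}: CDS without an obtainable protein")
    return seq


def read_proteome_gff(
    gff_path: str | Path,
    protein_fasta: str | Path,
    genome_id: str | None = None,
) -> Proteome:
    """Proteome from GFF3 CDS features plus a protein FASTA keyed by CDS ID.

    Gene order is assigned by ascending start coordinate.  GFF3 1-based
    inclusive coordinates are converted to the internal 0-based half-open
    convention.
    """
    gff_path = Path(gff_path)
    genome_id = genome_id or gff_path.stem
    with open(protein_fasta) as fh:
        proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}

    raw: list[tuple[int, int, str, str]] = []
    seen: set[str] = set()
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 tab-separated fields")
            _, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            gene_id = attr.get("ID")
            if gene_id is None:
                raise ValueError(f"{gff_path}:{lineno}: CDS without an ID attribute")
            if gene_id in seen:
                raise ValueError(f"{gff_path}:{lineno}: duplicate CDS ID {gene_id!r}")
            seen.add(gene_id)
            start_i, end_i = int(start) - 1, int(end)  # GFF3 -> half-open
            if end_i <= start_i:
                raise ValueError(f"{gff_path}:{lineno}: CDS with end <= start")
            if gene_id not in proteins:
                raise ValueError(
                    f"{gff_path}:{lineno}: no protein for CDS {gene_id!r} in {protein_fasta}"
                )
            raw.append((start_i, end_i, strand, gene_id))

    raw.sort(key=lambda r: (r[0], r[1], r[3]))
    genes = [
        GeneCall(
            genome_id=genome_id,
            gene_id=gene_id,
            rank=rank,
            strand=strand,
            start=start,
            end=end,
            protein=_clean_protein(proteins[gene_id], f"{gff_path}:{gene_id}"),
        )
        for rank, (start, end, strand, gene_id) in enumerate(raw)
    ]
    return Proteome(genome_id=genome_id, genes=genes)


def read_proteome_genbank(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Proteome from a single-record GenBank file.

    CDS translations are taken from the ``translation`` qualifier when
    present and otherwise translated from the coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "genbank"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    record = records[0]
    genome_id = genome_id or record.id

    raw = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        gene_id = (
            feat.qualifiers.get("locus_tag", feat.qualifiers.get("protein_id", [None]))[0]
        )
        if gene_id is None:
            raise ValueError(f"{path}: CDS at {feat.location} without locus_tag/protein_id")
        start, end = int(feat.location.start), int(feat.location.end)
        if end <= start:
            raise ValueError(f"{path}: CDS {gene_id} with end <= start")
        strand = "-" if feat.location.strand == -1 else "+"
        if "translation" in feat.qualifiers:
            protein = feat.qualifiers["translation"][0]
        else:
            protein = str(feat.extract(record.seq).translate(to_stop=True))
        raw.append((start, end, strand, gene_id, _clean_protein(protein, f"{path}:{gene_id}")))

    raw.sort(key=lambda r: (r[0], r[1], r[3]))
    seen: set[str] = set()
    for _, _, _, gene_id, _ in raw:
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate CDS id {gene_id!r}")
        seen.add(gene_id)
    genes = [
        GeneCall(genome_id, gene_id, rank, strand, start, end, protein)
        for rank, (start, end, strand, gene_id, protein) in enumerate(raw)
    ]
    return Proteome(genome_id=genome_id, genes=genes)


def read_annotated_genomes(
    specs: Iterable[tuple[str | Path, str | Path] | str | Path],
) -> list[Proteome]:
    """Read several genomes; each spec is ``(gff3, protein_fasta)`` or a GenBank path."""
    proteomes = []
    for spec in specs:
        if isinstance(spec, (tuple, list)):
            proteomes.append(read_proteome_gff(spec[0], spec[1]))
        else:
            proteomes.append(read_proteome_genbank(spec))
    ids = [p.genome_id for p in proteomes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate genome ids: {ids}")
    return proteomes


def write_protein_fasta(proteome: Proteome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in proteome:
            fh.write(f">{gene.gene_id}\n{gene.protein}\n")


def write_proteome_gff(proteome: Proteome, path: str | Path, source: str = "phagekit") -> None:
    """Emit CDS features in GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in proteome:
            fh.write(
                "\t".join(
                    [
                        proteome.genome_id,
                        source,
                        "CDS",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        "0",
                        f"ID={gene.gene_id}",
                    ]
                )
                + "\n"
            )
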