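"""Annotated-genome readers and the ordered per-scaffold gene index.

Internal coordinates are 0-based half-open throughout the package; GFF3
and GenBank use 1-based inclusive coordinates, and the conversion happens
only here, at the file boundary.  Genes (not mRNAs) are the unit of
analysis: when a gene has several transcripts the longest CDS set wins,
because cluster detection operates per locus.

Translation uses the standard code (table 1); a trailing stop is removed
and a gene whose CDS contains an internal stop is skipped with a warning.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Scaffold",
    "Genome",
    "read_genome",
    "read_genbank",
    "extract_proteome",
    "write_db",
    "load_db",
]


@dataclass
class GeneModel:
    """A located, stranded, protein-coding gene on a scaffold."""

    id: str
    scaffold_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'
    protein: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Scaffold:
    id: str
    length: int
    genes: list[GeneModel] = field(default_factory=list)

    def sort(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.id))


@dataclass
class Genome:
    """A set of scaffolds carrying uniquely-identified gene models."""

    id: str
    scaffolds: dict[str, Scaffold] = field(default_factory=dict)

    def genes(self):
        """All genes, ordered by (scaffold id, start)."""
        for sid in sorted(self.scaffolds):
            yield from self.scaffolds[sid].genes

    def gene(self, gene_id: str) -> GeneModel:
        g = self._index().get(gene_id)
        if g is None:
            raise KeyError(f"unknown gene id: {gene_id!r}")
        return g

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index()

    def n_genes(self) -> int:
        return sum(len(s.genes) for s in self.scaffolds.values())

    def _index(self) -> dict[str, GeneModel]:
        # rebuilt lazily; genomes are effectively immutable after reading
        idx = getattr(self, "_gene_index", None)
        if idx is None or len(idx) != self.n_genes():
            idx = {g.id: g for g in self.genes()}
            object.__setattr__(self, "_gene_index", idx)
        return idx


def _translate_cds(dna: str, gene_id: str) -> str | None:
    protein = str(Seq(dna).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        warnings.warn(f"gene {gene_id}: internal stop codon, gene skipped")
        return None
    if not protein:
        warnings.warn(f"gene {gene_id}: empty translation, gene skipped")
        return None
    return protein


def read_genome(sequence_path, annotation_path, genome_id: str | None = None) -> Genome:
    """Read a genome from FASTA + GFF3.

    Multi-exon CDS are joined in transcription order; minus-strand genes are
    translated from the reverse complement.  An annotation line referring to
    a scaffold absent from the FASTA is a hard error; a gene with no CDS is
    skipped with a warning.
    """
    sequence_path = Path(sequence_path)
    annotation_path = Path(annotation_path)
    if genome_id is None:
        genome_id = sequence_path.stem

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequence_path), "fasta")}
    genome = Genome(id=genome_id)
    for sid, seq in seqs.items():
        genome.scaffolds[sid] = Scaffold(id=sid, length=len(seq))

    try:
        db = gffutils.create_db(
            str(annotation_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return genome  # annotation with no features: scaffolds, zero genes

    seen_ids: set[str] = set()
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in seqs:
            raise ValueError(
                f"annotation references unknown scaffold id {gene.seqid!r} "
                f"(gene {gene.id})"
            )
        cds_set = _best_cds_set(db, gene)
        if not cds_set:
            warnings.warn(f"gene {gene.id}: no CDS features, gene skipped")
            continue

        strand = gene.strand if gene.strand in ("+", "-") else "+"
        parts = sorted(cds_set, key=lambda c: c.start)
        dna = "".join(
            seqs[c.seqid][c.start - 1 : c.end] for c in parts
        )
        if strand == "-":
            dna = str(Seq(dna).reverse_complement())
        protein = _translate_cds(dna, gene.id)
        if protein is None:
            continue
        if gene.id in seen_ids:
            raise ValueError(f"duplicate gene id in annotation: {gene.id!r}")
        seen_ids.add(gene.id)

        product = ";".join(gene.attributes.get("product", [])) or ";".join(
            gene.attributes.get("Name", [])
        )
        genome.scaffolds[gene.seqid].genes.append(
            GeneModel(
                id=gene.id,
                scaffold_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=strand,
                protein=protein,
                product=product,
            )
        )

    for scaffold in genome.scaffolds.values():
        scaffold.sort()
    return genome


def _best_cds_set(db, gene):
    """CDS features of the longest transcript of a gene (or direct children)."""
    mrnas = list(db.children(gene, featuretype="mRNA"))
    if not mrnas:
        return list(db.children(gene, featuretype="CDS"))
    best, best_len = [], -1
    for mrna in mrnas:
        cds = list(db.children(mrna, featuretype="CDS"))
        total = sum(c.end - c.start + 1 for c in cds)
        if total > best_len:
            best, best_len = cds, total
    return best


def read_genbank(path, genome_id: str | None = None) -> Genome:
    """Read a genome from a GenBank flat file (one scaffold per record).

    CDS ``/translation`` qualifiers are used verbatim when present,
    otherwise the protein is translated from the (possibly joined)
    feature location.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    genome = Genome(id=genome_id)
    seen_ids: set[str] = set()
    n_records = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        n_records += 1
        if len(rec.seq) == 0:
            raise ValueError(f"GenBank record {rec.id} has no sequence")
        scaffold = Scaffold(id=rec.id, length=len(rec.seq))
        genome.scaffolds[rec.id] = scaffold
        counter = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            quals = feat.qualifiers
            gid = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"{rec.id}_cds{counter}"
            )
            if gid in seen_ids:
                raise ValueError(f"duplicate gene id in GenBank file: {gid!r}")
            if "translation" in quals:
                protein = quals["translation"][0]
            else:
                dna = str(feat.extract(rec.seq))
                protein = _translate_cds(dna, gid)
                if protein is None:
                    continue
            seen_ids.add(gid)
            scaffold.genes.append(
                GeneModel(
                    id=gid,
                    scaffold_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    protein=protein,
                    product=quals.get("product", [""])[0],
                )
            )
        scaffold.sort()
    if n_records == 0:
        raise ValueError(f"no LOCUS records found in {path}")
    return genome


def extract_proteome(genome: Genome) -> str:
    """Protein FASTA text, one record per gene, in (scaffold, start) order."""
    buf = io.StringIO()
    for gene in genome.genes():
        buf.write(f">{gene.id}\n")
        seq = gene.protein
        for i in range(0, len(seq), 60):
            buf.write(seq[i : i + 60] + "\n")
    return buf.getvalue()


# -- on-disk database (a plain-text directory consumed by search/detect) -----

def write_db(genome: Genome, out_dir) -> None:
    """Persist a genome index as proteome FASTA + gene/scaffold TSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "proteome.faa").write_text(extract_proteome(genome))
    with open(out_dir / "genes.tsv", "w") as fh:
        fh.write("gene_id\tscaffold_id\tstart\tend\tstrand\tproduct\n")
        for g in genome.genes():
            fh.write(f"{g.id}\t{g.scaffold_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.product}\n")
    with open(out_dir / "scaffolds.tsv", "w") as fh:
        fh.write("scaffold_id\tlength\n")
        for sid in sorted(genome.scaffolds):
            fh.write(f"{sid}\t{genome.scaffolds[sid].length}\n")
    (out_dir / "genome_id.txt").write_text(genome.id + "\n")


def load_db(db_dir) -> Genome:
    """Reload a genome index written by :func:`write_db`."""
    db_dir = Path(db_dir)
    genome_id = (db_dir / "genome_id.txt").read_text().strip()
    genome = Genome(id=genome_id)
    with open(db_dir / "scaffolds.tsv") as fh:
        next(fh)
        for line in fh:
            sid, length = line.rstrip("\n").split("\t")
            genome.scaffolds[sid] = Scaffold(id=sid, length=int(length))
    proteins = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(db_dir / "proteome.faa"), "fasta")
    }
    with open(db_dir / "genes.tsv") as fh:
        next(fh)
        for line in fh:
            gid, sid, start, end, strand, product = line.rstrip("\n").split("\t")
            genome.scaffolds[sid].genes.append(
                GeneModel(
                    id=gid,
                    scaffold_id=sid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    protein=proteins[gid],
                    product=product,
                )
            )
    for scaffold in genome.scaffolds.values():
        scaffold.sort()
    return genome
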