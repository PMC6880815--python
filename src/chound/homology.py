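"""Query-protein -> subject-gene homology hits.

Hits come from either the built-in optimal local aligner (Smith-Waterman
with affine gaps, run over every query x gene pair) or from an external
12-column tabular search output ("outfmt 6" dialect).  Significance is by
identity and query-coverage thresholds rather than E-values: the full-DP
search has no score calibration, and at desk scale (clusters of <=10
queries against annotated proteomes) explicit thresholds are both
transparent and deterministic.  E-values are honoured only when parsed
from external files.

Gap costs follow the BLAST convention: a gap of length k costs
open + k * extend (defaults 11/1 with BLOSUM62).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import Genome

__all__ = ["Hit", "SearchParams", "AlignmentResult", "local_align", "search",
           "parse_tabular_hits", "read_query_fasta"]


@dataclass(frozen=True)
class SearchParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_identity: float = 30.0
    min_coverage: float = 50.0
    max_evalue: float | None = None  # applies to external hits only

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class Hit:
    """One query-protein-to-subject-gene homology record."""

    query_id: str
    subject_gene_id: str
    identity: float        # percent of alignment columns identical
    coverage_query: float  # percent of query residues aligned
    score: float           # raw alignment score (matrix units) or bitscore
    evalue: float | None = None


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float
    coverage_query: float
    query_span: tuple[int, int] | None  # 0-based half-open on the query
    subject_span: tuple[int, int] | None


def _make_aligner(params: SearchParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # first gap residue costs open+extend => gap of length k costs open + k*extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_alphabet(seq: str, alphabet: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    for ch in seq:
        if ch not in alphabet:
            raise ValueError(f"{label} contains residue {ch!r} not in the substitution matrix alphabet")


def local_align(a: str, b: str, params: SearchParams | None = None) -> AlignmentResult:
    """Optimal local alignment of query ``a`` against subject ``b``.

    identity = identical columns / total alignment columns (gap columns
    count); coverage_query = aligned query residues / len(a) * 100.
    An empty local alignment (all pair scores negative) is returned as a
    zero-score result, not an error.

    When several alignments are co-optimal the reported identity depends
    on which is chosen; to keep identity(a, b) == identity(b, a) exactly,
    the pair is always aligned in lexicographic order and the spans are
    swapped back afterwards.
    """
    params = params or SearchParams()
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    _check_alphabet(a, alphabet, "query")
    _check_alphabet(b, alphabet, "subject")

    swapped = a > b
    first, second = (b, a) if swapped else (a, b)
    alignments = aligner.align(first, second)
    if alignments.score <= 0:
        return AlignmentResult(0.0, 0.0, 0.0, None, None)
    aln = alignments[0]
    blocks_first, blocks_second = aln.aligned
    blocks_a, blocks_b = (
        (blocks_second, blocks_first) if swapped else (blocks_first, blocks_second)
    )
    matches = 0
    columns = 0
    aligned_query = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            columns += (a0 - prev_a_end) + (b0 - prev_b_end)  # gap columns
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += a1 - a0
        aligned_query += a1 - a0
        prev_a_end, prev_b_end = a1, b1
    q_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    s_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return AlignmentResult(
        score=float(alignments.score),
        identity=100.0 * matches / columns,
        coverage_query=100.0 * aligned_query / len(a),
        query_span=q_span,
        subject_span=s_span,
    )


def read_query_fasta(path) -> dict[str, str]:
    """Ordered id -> protein map from a query FASTA file."""
    queries = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not queries:
        raise ValueError(f"no query sequences found in {path}")
    return queries


def search(
    queries: dict[str, str],
    genomes: Genome | list[Genome],
    params: SearchParams | None = None,
) -> list[Hit]:
    """Align every query against every gene; keep hits passing the thresholds.

    Output order is deterministic: query order as given, then genome id,
    scaffold id, gene start.
    """
    params = params or SearchParams()
    if not queries:
        raise ValueError("empty query set")
    if isinstance(genomes, Genome):
        genomes = [genomes]

    hits: list[Hit] = []
    for query_id, qseq in queries.items():
        for genome in genomes:
            for gene in genome.genes():
                result = local_align(qseq, gene.protein, params)
                if result.score <= 0:
                    continue
                if result.identity < params.min_identity:
                    continue
                if result.coverage_query < params.min_coverage:
                    continue
                hits.append(
                    Hit(
                        query_id=query_id,
                        subject_gene_id=gene.id,
                        identity=result.identity,
                        coverage_query=result.coverage_query,
                        score=result.score,
                    )
                )
    return hits


_OUTFMT6_COLUMNS = 12


def parse_tabular_hits(
    path,
    genome: Genome | None = None,
    query_lengths: dict[str, int] | None = None,
    params: SearchParams | None = None,
) -> list[Hit]:
    """Parse 12-column tab-separated search output.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Query coverage is computed from
    qstart/qend when query lengths are supplied, else reported as 100.
    Hits above ``params.max_evalue`` (when set) are dropped; a subject id
    absent from ``genome`` (when given) is an error.
    """
    params = params or SearchParams()
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_OUTFMT6_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            qseqid, sseqid, pident = fields[0], fields[1], float(fields[2])
            qstart, qend = int(fields[6]), int(fields[7])
            evalue, bitscore = float(fields[10]), float(fields[11])
            if genome is not None and sseqid not in genome:
                raise ValueError(
                    f"{path}:{lineno}: subject id {sseqid!r} not present in "
                    f"genome {genome.id!r}"
                )
            if params.max_evalue is not None and evalue > params.max_evalue:
                continue
            if query_lengths is not None and qseqid in query_lengths:
                coverage = 100.0 * (qend - qstart + 1) / query_lengths[qseqid]
            else:
                coverage = 100.0
            if pident < params.min_identity or coverage < params.min_coverage:
                continue
            hits.append(
                Hit(
                    query_id=qseqid,
                    subject_gene_id=sseqid,
                    identity=pident,
                    coverage_query=coverage,
                    score=bitscore,
                    evalue=evalue,
                )
            )
    return hits
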