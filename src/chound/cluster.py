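"""Co-localization chaining: group homology hits into candidate gene clusters.

Hit-bearing genes on a scaffold are chained left to right while BOTH
conditions hold between consecutive hit-bearing genes: the intergenic
distance is at most ``max_gap_bp`` AND at most ``max_intervening_genes``
non-hit genes lie between them.  The dual criterion tolerates the long
intergenic stretches of fungal genomes while rejecting scaffold-wide
smearing of isolated hits.  A chain covering at least
``min_unique_queries`` distinct query proteins becomes a candidate locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import GeneModel, Genome
from .homology import Hit

__all__ = [
    "DetectionParams",
    "ClusterCandidate",
    "detect_clusters",
    "conserved_queries",
    "write_candidates",
]


@dataclass(frozen=True)
class DetectionParams:
    min_unique_queries: int = 3
    max_gap_bp: int = 10_000
    max_intervening_genes: int = 5
    require: str | None = None  # query id a candidate must cover

    def __post_init__(self) -> None:
        if self.min_unique_queries < 1:
            raise ValueError("min_unique_queries must be >= 1")
        if self.max_gap_bp < 0 or self.max_intervening_genes < 0:
            raise ValueError("gap limits must be non-negative")


@dataclass
class ClusterCandidate:
    """A contiguous locus covering hits to several distinct query proteins."""

    genome_id: str
    scaffold_id: str
    gene_span: list[str]            # hit-bearing gene ids, left to right
    start: int                      # locus bounds in bp (0-based half-open)
    end: int
    queries_covered: frozenset[str]
    score: float                    # sum of best hit score per covered query
    best_hits: dict[str, Hit]       # query id -> best hit in this locus
    partial: bool = False           # locus touches a scaffold end

    @property
    def n_queries(self) -> int:
        return len(self.queries_covered)


def detect_clusters(
    hits: list[Hit],
    genome: Genome,
    params: DetectionParams | None = None,
) -> list[ClusterCandidate]:
    """Chain co-localized hits into candidates, best first.

    Within a chain, each query's best hit is chosen by descending score,
    then descending identity, then leftmost subject-gene start.  Output is
    sorted by descending score.  A hit naming a gene absent from the
    genome is an error.
    """
    params = params or DetectionParams()

    hits_by_gene: dict[str, list[Hit]] = {}
    for hit in hits:
        if hit.subject_gene_id not in genome:
            raise ValueError(
                f"hit references unknown gene {hit.subject_gene_id!r} "
                f"in genome {genome.id!r}"
            )
        hits_by_gene.setdefault(hit.subject_gene_id, []).append(hit)

    candidates: list[ClusterCandidate] = []
    for sid in sorted(genome.scaffolds):
        scaffold = genome.scaffolds[sid]
        genes = scaffold.genes  # sorted by start
        marked = [(pos, g) for pos, g in enumerate(genes) if g.id in hits_by_gene]
        for chain in _chain(marked, params):
            cand = _make_candidate(chain, hits_by_gene, genome.id, scaffold, params)
            if cand is not None:
                candidates.append(cand)

    candidates = _merge_overlapping(candidates, hits_by_gene, params)
    if params.require is not None:
        candidates = [c for c in candidates if params.require in c.queries_covered]
    candidates.sort(key=lambda c: (-c.score, c.scaffold_id, c.start))
    return candidates


def _chain(
    marked: list[tuple[int, GeneModel]], params: DetectionParams
) -> list[list[tuple[int, GeneModel]]]:
    """Split the ordered hit-bearing genes at broken adjacency links."""
    chains: list[list[tuple[int, GeneModel]]] = []
    current: list[tuple[int, GeneModel]] = []
    for pos, gene in marked:
        if current:
            prev_pos, prev_gene = current[-1]
            gap_bp = gene.start - prev_gene.end
            intervening = pos - prev_pos - 1
            if gap_bp > params.max_gap_bp or intervening > params.max_intervening_genes:
                chains.append(current)
                current = []
        current.append((pos, gene))
    if current:
        chains.append(current)
    return chains


def _best_hit(hits: list[Hit], gene_start: dict[str, int]) -> Hit:
    return min(
        hits,
        key=lambda h: (-h.score, -h.identity, gene_start[h.subject_gene_id]),
    )


def _make_candidate(
    chain: list[tuple[int, GeneModel]],
    hits_by_gene: dict[str, list[Hit]],
    genome_id: str,
    scaffold,
    params: DetectionParams,
) -> ClusterCandidate | None:
    genes = [g for _, g in chain]
    per_query: dict[str, list[Hit]] = {}
    for g in genes:
        for hit in hits_by_gene[g.id]:
            per_query.setdefault(hit.query_id, []).append(hit)
    if len(per_query) < params.min_unique_queries:
        return None
    gene_start = {g.id: g.start for g in genes}
    best = {q: _best_hit(hlist, gene_start) for q, hlist in per_query.items()}
    start, end = genes[0].start, genes[-1].end
    # a locus running to the first/last gene of its scaffold may be truncated
    # by the assembly rather than genuinely ending there
    partial = bool(scaffold.genes) and (
        genes[0].id == scaffold.genes[0].id or genes[-1].id == scaffold.genes[-1].id
    )
    return ClusterCandidate(
        genome_id=genome_id,
        scaffold_id=scaffold.id,
        gene_span=[g.id for g in genes],
        start=start,
        end=end,
        queries_covered=frozenset(per_query),
        score=sum(h.score for h in best.values()),
        best_hits=best,
        partial=partial,
    )


def _merge_overlapping(
    candidates: list[ClusterCandidate],
    hits_by_gene: dict[str, list[Hit]],
    params: DetectionParams,
) -> list[ClusterCandidate]:
    """Merge candidates sharing >= 1 gene (one locus, one call).

    Chains produced by :func:`_chain` are disjoint, so this is a no-op on
    the standard path; it guards alternative front-ends feeding candidate
    lists directly.
    """
    merged: list[ClusterCandidate] = []
    for cand in sorted(candidates, key=lambda c: (c.scaffold_id, c.start)):
        if merged:
            last = merged[-1]
            if last.scaffold_id == cand.scaffold_id and set(last.gene_span) & set(
                cand.gene_span
            ):
                union_genes = list(dict.fromkeys(last.gene_span + cand.gene_span))
                per_query: dict[str, list[Hit]] = {}
                for gid in union_genes:
                    for hit in hits_by_gene.get(gid, []):
                        per_query.setdefault(hit.query_id, []).append(hit)
                order = {gid: i for i, gid in enumerate(union_genes)}
                best = {
                    q: min(hl, key=lambda h: (-h.score, -h.identity, order[h.subject_gene_id]))
                    for q, hl in per_query.items()
                }
                merged[-1] = ClusterCandidate(
                    genome_id=last.genome_id,
                    scaffold_id=last.scaffold_id,
                    gene_span=union_genes,
                    start=min(last.start, cand.start),
                    end=max(last.end, cand.end),
                    queries_covered=frozenset(per_query),
                    score=sum(h.score for h in best.values()),
                    best_hits=best,
                    partial=last.partial or cand.partial,
                )
                continue
        merged.append(cand)
    return merged


def conserved_queries(candidates: list[ClusterCandidate]) -> frozenset[str]:
    """Query ids covered in ALL given candidates (one per genome)."""
    if len(candidates) < 2:
        raise ValueError("conserved_queries needs >= 2 candidates")
    covered = set(candidates[0].queries_covered)
    for cand in candidates[1:]:
        covered &= cand.queries_covered
    return frozenset(covered)


def write_candidates(candidates: list[ClusterCandidate], tsv_path, bed_path) -> None:
    """Write a TSV report and a BED6 of candidate loci.

    BED lines are 0-based half-open, sorted by (scaffold, start); the BED
    score column is min(1000, round(score)).
    """
    with open(tsv_path, "w") as fh:
        fh.write(
            "genome\tscaffold\tstart\tend\tn_queries\tscore\tpartial\tbest_hits\n"
        )
        for c in candidates:
            best = ";".join(
                f"{q}={c.best_hits[q].subject_gene_id}:{c.best_hits[q].identity:.1f}"
                for q in sorted(c.best_hits)
            )
            fh.write(
                f"{c.genome_id}\t{c.scaffold_id}\t{c.start}\t{c.end}\t"
                f"{c.n_queries}\t{c.score:.1f}\t{str(c.partial).lower()}\t{best}\n"
            )
    with open(bed_path, "w") as fh:
        for i, c in enumerate(
            sorted(candidates, key=lambda c: (c.scaffold_id, c.start))
        ):
            bed_score = min(1000, round(c.score))
            fh.write(
                f"{c.scaffold_id}\t{c.start}\t{c.end}\tcluster_{i + 1}\t{bed_score}\t+\n"
            )
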