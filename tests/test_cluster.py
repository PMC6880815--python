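"""Co-localization chaining, conserved-gene intersection, and reports."""

import random

import pytest

from chound.cluster import (
    ClusterCandidate,
    DetectionParams,
    conserved_queries,
    detect_clusters,
    write_candidates,
)
from chound.genome_io import GeneModel, Genome, Scaffold
from chound.homology import Hit
from oracles import window_chains_oracle


def _genome(gene_layout, scaffold_len=None, genome_id="G"):
    """gene_layout: list of (gene_id, start, end) on one scaffold."""
    length = scaffold_len or max(end for _, _, end in gene_layout) + 5000
    scaffold = Scaffold(id="s1", length=length)
    for gid, start, end in gene_layout:
        scaffold.genes.append(
            GeneModel(id=gid, scaffold_id="s1", start=start, end=end,
                      strand="+", protein="M")
        )
    scaffold.sort()
    return Genome(id=genome_id, scaffolds={"s1": scaffold})


def _hit(q, g, score=100.0, identity=80.0):
    return Hit(query_id=q, subject_gene_id=g, identity=identity,
               coverage_query=90.0, score=score)


def _layout(n, gene_len=1000, gap=500, start=10_000):
    out, pos = [], start
    for i in range(n):
        out.append((f"g{i}", pos, pos + gene_len))
        pos += gene_len + gap
    return out


class TestDetectClusters:
    def test_contiguous_planted_hits_give_one_candidate(self):
        layout = _layout(46)
        genome = _genome(layout)
        # six contiguous hit-bearing genes in the middle of 40 decoys
        hits = [_hit(f"q{k}", f"g{20 + k}") for k in range(6)]
        (cand,) = detect_clusters(hits, genome)
        assert cand.queries_covered == frozenset(f"q{k}" for k in range(6))
        assert cand.gene_span == [f"g{20 + k}" for k in range(6)]
        assert cand.start == layout[20][1] and cand.end == layout[25][2]
        assert not cand.partial

    def test_split_locus_emits_both_halves_when_large_enough(self):
        # 3+3 split across a 50 kb gap: both chains clear min_unique_queries=3
        layout = _layout(3) + [
            (f"h{i}", 70_000 + i * 1500, 70_000 + i * 1500 + 1000) for i in range(3)
        ]
        genome = _genome(layout)
        hits = [_hit(f"q{i}", f"g{i}") for i in range(3)] + [
            _hit(f"q{3 + i}", f"h{i}") for i in range(3)
        ]
        cands = detect_clusters(hits, genome)
        assert len(cands) == 2
        spans = {tuple(c.gene_span) for c in cands}
        assert spans == {("g0", "g1", "g2"), ("h0", "h1", "h2")}

    def test_split_locus_drops_fragment_below_min_queries(self):
        # 5+1 split: only the 5-gene chain survives
        layout = _layout(5) + [("h0", 90_000, 91_000)]
        genome = _genome(layout)
        hits = [_hit(f"q{i}", f"g{i}") for i in range(5)] + [_hit("q5", "h0")]
        (cand,) = detect_clusters(hits, genome)
        assert tuple(cand.gene_span) == ("g0", "g1", "g2", "g3", "g4")

    def test_intervening_gene_limit_breaks_chain(self):
        # two hit genes separated by 6 non-hit genes but only 4 kb
        layout = _layout(8, gene_len=500, gap=100)
        genome = _genome(layout)
        hits = [_hit("q0", "g0"), _hit("q1", "g7"), _hit("q2", "g7")]
        assert detect_clusters(hits, genome, DetectionParams(min_unique_queries=1)) \
            == detect_clusters(hits, genome, DetectionParams(min_unique_queries=1))
        cands = detect_clusters(hits, genome, DetectionParams(min_unique_queries=1))
        assert {tuple(c.gene_span) for c in cands} == {("g0",), ("g7",)}

    def test_zero_hits_give_empty_list(self):
        assert detect_clusters([], _genome(_layout(5))) == []

    def test_hit_referencing_unknown_gene_is_error(self):
        with pytest.raises(ValueError, match="ghost"):
            detect_clusters([_hit("q", "ghost")], _genome(_layout(3)))

    def test_best_hit_tie_break_prefers_score_identity_then_leftmost(self):
        genome = _genome(_layout(4))
        hits = [
            _hit("q0", "g1", score=50, identity=60),
            _hit("q0", "g2", score=90, identity=40),   # highest score wins
            _hit("q1", "g0"), _hit("q2", "g3"),
        ]
        (cand,) = detect_clusters(hits, genome)
        assert cand.best_hits["q0"].subject_gene_id == "g2"
        assert cand.score == 90 + 100 + 100

    def test_candidate_touching_scaffold_end_is_flagged_partial(self):
        layout = _layout(4)
        genome = _genome(layout)
        hits = [_hit(f"q{i}", f"g{i}") for i in range(3)]  # includes first gene
        (cand,) = detect_clusters(hits, genome)
        assert cand.partial

    def test_equivalence_with_window_enumeration_oracle(self):
        # random gene layouts and hit assignments vs the exhaustive oracle
        rng = random.Random(20_21)
        params = DetectionParams(min_unique_queries=1, max_gap_bp=4000,
                                 max_intervening_genes=2)
        for trial in range(120):
            n = rng.randint(1, 60)
            pos, layout = 0, []
            for i in range(n):
                pos += rng.randint(100, 8000)
                L = rng.randint(300, 3000)
                layout.append((f"g{i}", pos, pos + L))
                pos += L
            genome = _genome(layout)
            hits = []
            for i in range(n):
                if rng.random() < 0.4:
                    hits.append(_hit(f"q{rng.randint(0, 7)}", f"g{i}"))
            got = {
                tuple(c.gene_span)
                for c in detect_clusters(hits, genome, params)
            }
            expected = {
                chain
                for chain in window_chains_oracle(
                    genome.scaffolds["s1"].genes,
                    {h.subject_gene_id for h in hits},
                    params.max_gap_bp,
                    params.max_intervening_genes,
                )
            }
            assert got == expected, f"trial {trial}"

    def test_wider_gap_never_reduces_best_candidate_coverage(self):
        rng = random.Random(31)
        for _ in range(25):
            n = rng.randint(5, 40)
            pos, layout = 0, []
            for i in range(n):
                pos += rng.randint(100, 15000)
                layout.append((f"g{i}", pos, pos + 900))
                pos += 900
            genome = _genome(layout)
            hits = [
                _hit(f"q{rng.randint(0, 5)}", f"g{i}")
                for i in range(n) if rng.random() < 0.5
            ]
            cover = []
            for gap in (2000, 10000, 50000):
                cands = detect_clusters(
                    hits, genome,
                    DetectionParams(min_unique_queries=1, max_gap_bp=gap),
                )
                cover.append(max((c.n_queries for c in cands), default=0))
            assert cover[0] <= cover[1] <= cover[2]


class TestConservedQueries:
    def _cand(self, queries):
        return ClusterCandidate(
            genome_id="G", scaffold_id="s1", gene_span=["g"], start=0, end=1,
            queries_covered=frozenset(queries), score=1.0, best_hits={},
        )

    def test_full_intersection(self):
        six = [f"q{i}" for i in range(6)]
        assert conserved_queries([self._cand(six)] * 3) == frozenset(six)

    def test_one_genome_missing_a_homolog(self):
        six = {f"q{i}" for i in range(6)}
        cands = [self._cand(six), self._cand(six - {"q3"}), self._cand(six)]
        assert conserved_queries(cands) == frozenset(six - {"q3"})

    def test_disjoint_coverage_is_empty(self):
        assert conserved_queries([self._cand({"a"}), self._cand({"b"})]) == frozenset()

    def test_fewer_than_two_candidates_rejected(self):
        with pytest.raises(ValueError):
            conserved_queries([self._cand({"a"})])


class TestReports:
    def test_tsv_and_bed_for_one_candidate(self, tmp_path):
        genome = _genome(_layout(4))
        hits = [_hit(f"q{i}", f"g{i}") for i in range(3)]
        cands = detect_clusters(hits, genome)
        write_candidates(cands, tmp_path / "c.tsv", tmp_path / "c.bed")
        tsv = (tmp_path / "c.tsv").read_text().splitlines()
        bed = (tmp_path / "c.bed").read_text().splitlines()
        assert len(tsv) == 2 and tsv[0].startswith("genome\t")
        assert len(bed) == 1
        scaffold, start, end, name, score, strand = bed[0].split("\t")
        assert (scaffold, name, strand) == ("s1", "cluster_1", "+")
        assert int(score) == min(1000, round(cands[0].score))

    def test_empty_candidate_list_gives_header_only(self, tmp_path):
        write_candidates([], tmp_path / "c.tsv", tmp_path / "c.bed")
        assert (tmp_path / "c.tsv").read_text().startswith("genome\t")
        assert (tmp_path / "c.bed").read_text() == ""

    def test_bed_sorted_by_start_on_shared_scaffold(self, tmp_path):
        layout = _layout(3) + [
            (f"h{i}", 80_000 + i * 1500, 80_000 + i * 1500 + 1000) for i in range(3)
        ]
        genome = _genome(layout)
        hits = [_hit(f"q{i}", f"g{i}", score=50) for i in range(3)] + [
            _hit(f"q{3 + i}", f"h{i}", score=500) for i in range(3)
        ]
        cands = detect_clusters(hits, genome)
        write_candidates(cands, tmp_path / "c.tsv", tmp_path / "c.bed")
        starts = [int(l.split("\t")[1]) for l in (tmp_path / "c.bed").read_text().splitlines()]
        assert starts == sorted(starts)
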