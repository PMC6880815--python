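"""Gene pairing between clusters and the identity-shaded SVG rendering."""

import random
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from chound.genome_io import GeneModel
from chound.homology import local_align
from chound.simulate import mutate_protein, reference_cluster_proteins
from chound.synteny import (
    ClusterTrack,
    FigureSpec,
    Link,
    compute_links,
    normalise_orientation,
    render_comparison,
)
from oracles import optimal_assignment_oracle

SVG_NS = "{http://www.w3.org/2000/svg}"


def _track(label, proteins, strand="+", gene_len=None, gap=500):
    genes, pos = [], 1000
    for gid, protein in proteins.items():
        L = gene_len or 3 * len(protein)
        genes.append(
            GeneModel(id=gid, scaffold_id="s", start=pos, end=pos + L,
                      strand=strand, protein=protein)
        )
        pos += L + gap
    return ClusterTrack(label=label, genes=genes)


@pytest.fixture(scope="module")
def reference_track():
    prots = reference_cluster_proteins()
    return _track("ref", {f"A_{name}": seq for name, seq in prots.items()})


class TestComputeLinks:
    def test_cluster_vs_identical_copy_links_all_genes_at_100(self, reference_track):
        copy = _track(
            "copy",
            {g.id.replace("A_", "B_"): g.protein for g in reference_track.genes},
        )
        links = compute_links(reference_track, copy)
        assert len(links) == 6
        assert all(l.identity == 100.0 for l in links)
        assert {(l.gene_a.removeprefix("A_"), l.gene_b.removeprefix("B_"))
                for l in links} == {(n, n) for n in reference_cluster_proteins()}

    def test_greedy_assignment_equals_exhaustive_optimum(self, reference_track):
        # mutate to ~70% and verify against brute force over all pairings
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mutated = {
                g.id.replace("A_", "B_"): mutate_protein(g.protein, 70, rng)[0]
                for g in reference_track.genes
            }
            other = _track("mut", mutated)
            links = compute_links(reference_track, other)
            # eligibility mirrors the documented link rule: identity and
            # mutual coverage thresholds; the oracle then optimises the
            # one-to-one assignment exhaustively
            identity = {}
            for ga in reference_track.genes:
                for gb in other.genes:
                    r = local_align(ga.protein, gb.protein)
                    paired = r.coverage_query * len(ga.protein) / 100.0
                    cov_b = 100.0 * paired / len(gb.protein)
                    if min(r.coverage_query, cov_b) >= 50.0:
                        identity[(ga.id, gb.id)] = r.identity
            expected = optimal_assignment_oracle(identity, 30.0)
            assert {(l.gene_a, l.gene_b) for l in links} == set(expected), seed

    def test_all_pairs_below_threshold_give_no_links(self, reference_track):
        rng = np.random.default_rng(0)
        # unrelated random proteins: local identity far below 90
        links = compute_links(reference_track, reference_track,
                              link_min_identity=99.0)
        assert [l for l in links if l.identity < 99.0] == []

    def test_role_swap_symmetry(self, reference_track):
        rng = np.random.default_rng(3)
        mutated = {
            g.id.replace("A_", "B_"): mutate_protein(g.protein, 60, rng)[0]
            for g in reference_track.genes
        }
        other = _track("mut", mutated)
        ab = {(l.gene_a, l.gene_b) for l in compute_links(reference_track, other)}
        ba = {(l.gene_b, l.gene_a) for l in compute_links(other, reference_track)}
        assert ab == ba

    def test_empty_cluster_yields_no_links(self, reference_track):
        assert compute_links(reference_track, ClusterTrack("empty", [])) == []


class TestOrientation:
    def _pair(self, strand_b):
        prots = {"a1": "MKLVRSTGAWQE" * 5, "a2": "MHEAGAWGHEEF" * 5}
        track_a = _track("A", prots)
        track_b = _track("B", {"b1": prots["a1"], "b2": prots["a2"]}, strand=strand_b)
        links = [Link("a1", "b1", 100.0), Link("a2", "b2", 100.0)]
        return track_a, track_b, links

    def test_reversed_copy_is_flipped(self):
        a, b, links = self._pair("-")
        out = normalise_orientation([a, b], [links])
        assert all(g.strand == "+" for g in out[1].genes)
        # mirrored display order: b2 now leftmost
        assert out[1].genes[0].id == "b2"

    def test_no_links_leaves_tracks_unchanged(self):
        a, b, _ = self._pair("-")
        out = normalise_orientation([a, b], [[]])
        assert [g.strand for g in out[1].genes] == ["-", "-"]

    def test_exact_tie_requires_strict_majority(self):
        prots = {"a1": "MKLVRSTGAWQE" * 5, "a2": "MHEAGAWGHEEF" * 5}
        track_a = _track("A", prots)
        genes_b = _track("B", {"b1": prots["a1"]}, strand="+").genes + _track(
            "B2", {"b2": prots["a2"]}, strand="-"
        ).genes
        track_b = ClusterTrack("B", sorted(genes_b, key=lambda g: g.start))
        links = [Link("a1", "b1", 100.0), Link("a2", "b2", 100.0)]
        out = normalise_orientation([track_a, track_b], [links])
        assert {g.id: g.strand for g in out[1].genes} == {"b1": "+", "b2": "-"}


class TestRendering:
    def _render(self, identity):
        prots = {"a1": "MKLVRSTGAWQE" * 5}
        a = _track("A", prots)
        b = _track("B", {"b1": prots["a1"]})
        svg = render_comparison([a, b], [[Link("a1", "b1", identity)]],
                                FigureSpec(normalise=False))
        return ET.fromstring(svg)

    @pytest.mark.parametrize(
        "identity,opacity", [(100.0, 1.0), (0.0, 0.0), (50.0, 0.5), (73.0, 0.73)]
    )
    def test_link_opacity_maps_identity_linearly(self, identity, opacity):
        root = self._render(identity)
        (link,) = [p for p in root.iter(f"{SVG_NS}polygon")
                   if p.get("class") == "link"]
        assert float(link.get("fill-opacity")) == pytest.approx(opacity)
        assert link.get("fill") == "#000000"

    def test_svg_is_valid_xml_with_one_polygon_per_gene_and_link(self, reference_track):
        copy = _track(
            "copy", {g.id.replace("A_", "B_"): g.protein for g in reference_track.genes}
        )
        links = compute_links(reference_track, copy)
        root = ET.fromstring(
            render_comparison([reference_track, copy], [links], FigureSpec())
        )
        polys = list(root.iter(f"{SVG_NS}polygon"))
        assert sum(p.get("class") == "gene" for p in polys) == 12
        assert sum(p.get("class") == "link" for p in polys) == len(links) == 6

    def test_gene_arrow_length_is_bp_times_scale(self):
        gene = GeneModel(id="g", scaffold_id="s", start=5000, end=8000,
                         strand="+", protein="M")
        track = ClusterTrack("t", [gene])
        svg = render_comparison([track], [], FigureSpec(px_per_bp=0.01, normalise=False))
        root = ET.fromstring(svg)
        (poly,) = [p for p in root.iter(f"{SVG_NS}polygon") if p.get("class") == "gene"]
        xs = [float(pt.split(",")[0]) for pt in poly.get("points").split()]
        assert max(xs) - min(xs) == pytest.approx(30.0)  # 3000 bp * 0.01 px/bp

    def test_link_referencing_absent_gene_is_error(self):
        a = _track("A", {"a1": "MKLVRSTGAWQE" * 5})
        b = _track("B", {"b1": "MKLVRSTGAWQE" * 5})
        with pytest.raises(ValueError, match="ghost"):
            render_comparison([a, b], [[Link("ghost", "b1", 50.0)]],
                              FigureSpec(normalise=False))
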