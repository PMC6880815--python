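"""Cluster-to-cluster gene correspondence and to-scale comparison figures.

Genes of two clusters are paired one-to-one by amino-acid identity
(greedy, descending identity) and rendered as horizontal tracks of
strand-aware arrow polygons, with shaded quadrilaterals connecting
paired genes between adjacent tracks.  Link shading encodes identity
linearly: 0% identity is fully transparent, 100% is solid black.

The identity definition is shared with the homology-search module (local
alignment, gap columns counted), so figures and hit tables agree.
"""

from __future__ import annotations

import itertools
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

from .genome_io import GeneModel
from .homology import SearchParams, local_align

__all__ = [
    "Link",
    "ClusterTrack",
    "FigureSpec",
    "compute_links",
    "normalise_orientation",
    "render_comparison",
]


@dataclass(frozen=True)
class Link:
    """A gene pairing between two clusters, weighted by % aa identity."""

    gene_a: str
    gene_b: str
    identity: float


@dataclass
class ClusterTrack:
    """One cluster as a displayable row: a label and its ordered genes."""

    label: str
    genes: list[GeneModel]

    @property
    def span(self) -> tuple[int, int]:
        if not self.genes:
            return (0, 0)
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))

    def flipped(self) -> "ClusterTrack":
        """Mirror the track in display coordinates (strands inverted)."""
        lo, hi = self.span
        out = []
        for g in self.genes:
            out.append(
                replace(
                    g,
                    start=lo + (hi - g.end),
                    end=lo + (hi - g.start),
                    strand="-" if g.strand == "+" else "+",
                )
            )
        out.sort(key=lambda g: g.start)
        return ClusterTrack(label=self.label, genes=out)


@dataclass
class FigureSpec:
    px_per_bp: float = 0.02
    link_min_identity: float = 30.0
    normalise: bool = True
    track_gap: float = 60.0   # vertical px between tracks
    gene_height: float = 14.0
    margin: float = 20.0

    def __post_init__(self) -> None:
        if self.px_per_bp <= 0:
            raise ValueError("px_per_bp must be > 0")


def compute_links(
    cluster_a: ClusterTrack,
    cluster_b: ClusterTrack,
    params: SearchParams | None = None,
    link_min_identity: float = 30.0,
) -> list[Link]:
    """Pair genes of two clusters one-to-one by descending identity.

    All cross-pairs are aligned; a pair is eligible when its identity is at
    least ``link_min_identity`` AND the alignment covers at least
    ``params.min_coverage`` percent of BOTH proteins (symmetric, so the
    link set is invariant to cluster order) — without the coverage
    requirement a few-residue local match between unrelated proteins can
    carry a spuriously high identity.  Eligible pairs are
    assigned greedily by descending identity, ties broken by the smaller
    sum of gene start positions.
    """
    params = params or SearchParams()
    scored: list[tuple[float, int, GeneModel, GeneModel]] = []
    for ga, gb in itertools.product(cluster_a.genes, cluster_b.genes):
        result = local_align(ga.protein, gb.protein, params)
        if result.score <= 0 or result.identity < link_min_identity:
            continue
        paired = result.coverage_query * len(ga.protein) / 100.0
        coverage_b = 100.0 * paired / len(gb.protein)
        if min(result.coverage_query, coverage_b) < params.min_coverage:
            continue
        scored.append((result.identity, ga.start + gb.start, ga, gb))
    scored.sort(key=lambda t: (-t[0], t[1], t[2].id, t[3].id))

    used_a: set[str] = set()
    used_b: set[str] = set()
    links: list[Link] = []
    for identity, _, ga, gb in scored:
        if ga.id in used_a or gb.id in used_b:
            continue
        used_a.add(ga.id)
        used_b.add(gb.id)
        links.append(Link(gene_a=ga.id, gene_b=gb.id, identity=identity))
    return links


def normalise_orientation(
    tracks: list[ClusterTrack],
    links_between: list[list[Link]],
) -> list[ClusterTrack]:
    """Flip tracks so linked genes are co-oriented with the track above.

    Walking down from the first track, a track is mirrored when a strict
    majority of its linked genes lie on the opposite strand from their
    partners; an exact 50/50 split leaves it unchanged.
    """
    if len(links_between) != max(0, len(tracks) - 1):
        raise ValueError("need one link set per adjacent track pair")
    out = [tracks[0]] if tracks else []
    for i in range(1, len(tracks)):
        upper = out[i - 1]
        lower = tracks[i]
        links = links_between[i - 1]
        strand_upper = {g.id: g.strand for g in upper.genes}
        strand_lower = {g.id: g.strand for g in lower.genes}
        discordant = concordant = 0
        for link in links:
            if link.gene_a in strand_upper and link.gene_b in strand_lower:
                if strand_upper[link.gene_a] == strand_lower[link.gene_b]:
                    concordant += 1
                else:
                    discordant += 1
        if discordant > concordant:
            lower = lower.flipped()
        out.append(lower)
    return out


def _arrow_points(
    x0: float, x1: float, y: float, height: float, strand: str
) -> list[tuple[float, float]]:
    """Strand-aware arrow polygon spanning [x0, x1] horizontally."""
    head = min(0.3 * (x1 - x0), height * 0.7)
    ymid = y + height / 2
    if strand == "+":
        return [
            (x0, y),
            (x1 - head, y),
            (x1, ymid),
            (x1 - head, y + height),
            (x0, y + height),
        ]
    return [
        (x1, y),
        (x0 + head, y),
        (x0, ymid),
        (x0 + head, y + height),
        (x1, y + height),
    ]


def _fmt_points(points: list[tuple[float, float]]) -> str:
    return " ".join(f"{x:.2f},{y:.2f}" for x, y in points)


def render_comparison(
    tracks: list[ClusterTrack],
    links_between: list[list[Link]],
    spec: FigureSpec | None = None,
) -> str:
    """Render clusters as stacked tracks with identity-shaded links (SVG).

    Gene pixel length is bp length x ``px_per_bp`` (drawn to scale); link
    quadrilaterals are filled black with fill-opacity = identity / 100.
    A link naming a gene absent from its track is an error.
    """
    spec = spec or FigureSpec()
    if not tracks:
        raise ValueError("need at least one cluster to render")
    if len(links_between) != max(0, len(tracks) - 1):
        raise ValueError("need one link set per adjacent track pair")
    if spec.normalise:
        tracks = normalise_orientation(tracks, links_between)

    h = spec.gene_height
    width = (
        max((t.span[1] - t.span[0]) for t in tracks) * spec.px_per_bp
        + 2 * spec.margin
    )
    height = 2 * spec.margin + len(tracks) * h + (len(tracks) - 1) * spec.track_gap

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=f"{width:.0f}",
        height=f"{height:.0f}",
        viewBox=f"0 0 {width:.0f} {height:.0f}",
    )

    # per-track pixel geometry for gene lookup by the link pass
    geometry: list[dict[str, tuple[float, float, float]]] = []
    for i, track in enumerate(tracks):
        y = spec.margin + i * (h + spec.track_gap)
        lo, _ = track.span
        row: dict[str, tuple[float, float, float]] = {}
        group = ET.SubElement(svg, "g", attrib={"class": "track", "id": f"track-{i}"})
        label = ET.SubElement(
            group, "text", x=f"{spec.margin:.2f}", y=f"{y - 4:.2f}",
            attrib={"class": "track-label", "font-size": "10"},
        )
        label.text = track.label
        for gene in track.genes:
            x0 = spec.margin + (gene.start - lo) * spec.px_per_bp
            x1 = spec.margin + (gene.end - lo) * spec.px_per_bp
            row[gene.id] = (x0, x1, y)
            ET.SubElement(
                group,
                "polygon",
                attrib={
                    "class": "gene",
                    "id": f"gene-{gene.id}",
                    "points": _fmt_points(_arrow_points(x0, x1, y, h, gene.strand)),
                    "fill": "#9ecae1",
                    "stroke": "#333333",
                    "stroke-width": "0.5",
                },
            )
        geometry.append(row)

    for i, links in enumerate(links_between):
        upper, lower = geometry[i], geometry[i + 1]
        group = ET.SubElement(svg, "g", attrib={"class": "links"})
        for link in links:
            if link.gene_a not in upper:
                raise ValueError(f"link references gene {link.gene_a!r} absent from track {i}")
            if link.gene_b not in lower:
                raise ValueError(f"link references gene {link.gene_b!r} absent from track {i + 1}")
            ax0, ax1, ay = upper[link.gene_a]
            bx0, bx1, by = lower[link.gene_b]
            points = [(ax0, ay + h), (ax1, ay + h), (bx1, by), (bx0, by)]
            ET.SubElement(
                group,
                "polygon",
                attrib={
                    "class": "link",
                    "points": _fmt_points(points),
                    "fill": "#000000",
                    "fill-opacity": f"{link.identity / 100.0:.4g}",
                    "stroke": "none",
                },
            )
    return ET.tostring(svg, encoding="unicode")


def links_report(links_between: list[list[Link]]) -> list[dict]:
    """JSON-serialisable link report (one record per adjacent-track link)."""
    return [
        {
            "track_pair": i,
            "gene_a": link.gene_a,
            "gene_b": link.gene_b,
            "identity": round(link.identity, 2),
        }
        for i, links in enumerate(links_between)
        for link in links
    ]
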