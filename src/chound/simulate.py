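"""Seeded synthetic genomes with planted homologous gene clusters.

The generator emulates the study system: a multi-scaffold fungal genome
carrying one six-gene secondary-metabolite cluster — a highly-reducing
polyketide synthase, a HAD-like terpene synthase, an FAD-binding
oxidoreductase, a cytochrome P450, an alpha/beta hydrolase and a
short-chain dehydrogenase — embedded contiguously among unrelated genes.
Planted genes are derived from the reference query proteins by seeded
point mutation to a controllable amino-acid identity, then
back-translated; decoy genes are i.i.d.-random proteins drawn from
background residue frequencies, giving a clean negative background for
threshold tests (a ``hard_decoys`` mode plants ~25%-identity paralogs
for stress testing).  Degraded-cluster variants (split loci, gene
dropout) are supported.  All output is byte-deterministic given the
spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "FixtureSpec",
    "Fixture",
    "reference_cluster_proteins",
    "mutate_protein",
    "back_translate",
    "generate_fixture",
    "write_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Approximate background residue frequencies (Robinson & Robinson style),
# normalised over the 20 standard residues.
_BACKGROUND = np.array(
    [
        0.079, 0.019, 0.054, 0.063, 0.040, 0.074, 0.022, 0.052, 0.058, 0.091,
        0.022, 0.045, 0.052, 0.042, 0.051, 0.068, 0.059, 0.066, 0.013, 0.032,
    ]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()

# Functional roles of the six conserved cluster genes, with desk-scale
# protein lengths (real HR-PKSs run ~2400 aa; lengths here are scaled to
# keep all-vs-all alignment cheap while preserving relative size).
_REFERENCE_GENES = (
    ("HR_PKS", 420),
    ("terpene_synthase", 320),
    ("FAD_oxidoreductase", 300),
    ("P450", 330),
    ("AB_hydrolase", 280),
    ("SDR", 260),
)

_REFERENCE_SEED = 716257  # fixed: the reference proteins are a constant


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=_BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def reference_cluster_proteins() -> dict[str, str]:
    """The six deterministic query proteins of the planted cluster."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    return {name: _random_protein(rng, length) for name, length in _REFERENCE_GENES}


def query_fasta(proteins: dict[str, str] | None = None) -> str:
    """Reference cluster queries as FASTA text."""
    proteins = proteins or reference_cluster_proteins()
    lines = []
    for name, seq in proteins.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"


_blosum62 = substitution_matrices.load("BLOSUM62")


def _substitution_weights() -> dict[str, tuple[str, np.ndarray]]:
    """Per-residue BLOSUM62-weighted replacement distributions."""
    table: dict[str, tuple[str, np.ndarray]] = {}
    for orig in AMINO_ACIDS:
        others = [aa for aa in AMINO_ACIDS if aa != orig]
        weights = np.array([2.0 ** _blosum62[orig, aa] for aa in others])
        table[orig] = ("".join(others), weights / weights.sum())
    return table


_SUB_WEIGHTS = _substitution_weights()


def mutate_protein(
    protein: str, target_identity: float, seed: int | np.random.Generator
) -> tuple[str, float]:
    """Point-mutate a protein to a target percent identity.

    Exactly ``round(L * (1 - target/100))`` positions, chosen uniformly
    without replacement, are substituted; replacements are drawn
    BLOSUM62-weighted among the 19 other residues, so every substitution
    changes the residue and the realised identity is exact.  Returns
    (mutated sequence, realised identity percent).
    """
    if not 0 < target_identity <= 100:
        raise ValueError(f"target_identity must be in (0, 100], got {target_identity}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(protein)
    n_sub = round(L * (1 - target_identity / 100.0))
    if n_sub == 0:
        return protein, 100.0
    positions = rng.choice(L, size=n_sub, replace=False)
    residues = list(protein)
    for pos in sorted(positions):
        alphabet, weights = _SUB_WEIGHTS[residues[pos]]
        residues[pos] = alphabet[rng.choice(len(alphabet), p=weights)]
    realised = 100.0 * (L - n_sub) / L
    return "".join(residues), realised


_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for codons in _CODONS_FOR.values():
    codons.sort()
_STOP_CODONS = sorted(_CODON_TABLE.stop_codons)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous codon choice; stop appended."""
    parts = []
    for aa in protein:
        codons = _CODONS_FOR[aa]
        parts.append(codons[rng.integers(len(codons))])
    parts.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(parts)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic annotated genome."""

    seed: int = 0
    n_scaffolds: int = 2
    genes_per_scaffold: int = 40
    gene_length_range: tuple[int, int] = (600, 1500)      # decoy CDS length, bp
    intergenic_range: tuple[int, int] = (200, 2000)       # bp between genes
    planted_identity: float = 70.0
    planted_cluster: tuple[tuple[str, str, float], ...] | None = None
    # entries (name, protein, target_identity); None -> reference six at
    # planted_identity
    split_gap_bp: int | None = None   # extra gap splitting the cluster 3+3
    dropout: frozenset[str] = frozenset()
    hard_decoys: bool = False
    max_scaffold_bp: int | None = None

    def resolved_cluster(self) -> list[tuple[str, str, float]]:
        if self.planted_cluster is not None:
            planted = list(self.planted_cluster)
        else:
            planted = [
                (name, seq, self.planted_identity)
                for name, seq in reference_cluster_proteins().items()
            ]
        planted = [p for p in planted if p[0] not in self.dropout]
        if not planted:
            raise ValueError("all planted genes dropped out")
        return planted


@dataclass
class Fixture:
    fasta_text: str
    gff_text: str
    truth: dict


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate FASTA + GFF3 + truth record for a planted-cluster genome."""
    rng = np.random.default_rng(spec.seed)
    genome_id = f"synth{spec.seed}"
    planted = spec.resolved_cluster()

    fasta_lines: list[str] = []
    gff_lines: list[str] = ["##gff-version 3"]
    truth_genes: list[dict] = []
    sub_loci: list[list[int]] = []
    locus: list[int] | None = None
    truth_scaffold = None

    # gene plan per scaffold: decoys everywhere, planted run on scaffold 0
    insert_at = int(rng.integers(0, spec.genes_per_scaffold + 1))

    gene_counter = 0
    for s in range(spec.n_scaffolds):
        sid = f"scaffold_{s + 1}"
        plan: list[tuple[str, str | None, float | None]] = []
        for j in range(spec.genes_per_scaffold):
            if s == 0 and j == insert_at:
                for name, qseq, ident in planted:
                    plan.append(("planted", name, ident))
            plan.append(("decoy", None, None))
        if s == 0 and insert_at == spec.genes_per_scaffold:
            for name, qseq, ident in planted:
                plan.append(("planted", name, ident))

        seq_parts: list[str] = []
        pos = 0
        scaffold_gff: list[str] = []
        planted_seen = 0
        n_planted = len(planted)
        cluster_bounds: list[int] = []
        current_sub: list[int] | None = None
        plan_proteins = {name: seq for name, seq, _ in planted}

        for kind, name, ident in plan:
            gap = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
            if (
                kind == "planted"
                and spec.split_gap_bp is not None
                and planted_seen == (n_planted + 1) // 2
                and planted_seen > 0
            ):
                gap += spec.split_gap_bp
                if current_sub is not None:
                    sub_loci.append(current_sub)
                    current_sub = None
            seq_parts.append(_random_dna(rng, gap))
            pos += gap

            gene_counter += 1
            gid = f"{genome_id}_g{gene_counter:04d}"
            strand = "+" if rng.integers(2) == 0 else "-"
            if kind == "planted":
                planted_seen += 1
                protein, realised = mutate_protein(plan_proteins[name], ident, rng)
                cds = back_translate(protein, rng)
            else:
                aa_len = int(
                    rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1)
                ) // 3
                if spec.hard_decoys and rng.random() < 0.25:
                    template_name = list(plan_proteins)[
                        int(rng.integers(len(plan_proteins)))
                    ]
                    protein, realised = mutate_protein(plan_proteins[template_name], 25.0, rng)
                else:
                    protein = _random_protein(rng, aa_len)
                    realised = None
                cds = back_translate(protein, rng)

            start, end = pos, pos + len(cds)
            gene_dna = cds if strand == "+" else str(Seq(cds).reverse_complement())
            seq_parts.append(gene_dna)
            pos = end

            scaffold_gff.append(
                f"{sid}\tchound\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
            scaffold_gff.append(
                f"{sid}\tchound\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}"
            )
            scaffold_gff.append(
                f"{sid}\tchound\tCDS\t{start + 1}\t{end}\t.\t{strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}.t1"
            )

            if kind == "planted":
                truth_scaffold = sid
                truth_genes.append(
                    {
                        "id": gid,
                        "query": name,
                        "realised_identity": realised,
                        "strand": strand,
                        "start": start,
                        "end": end,
                    }
                )
                cluster_bounds += [start, end]
                if current_sub is None:
                    current_sub = [start, end]
                else:
                    current_sub[1] = end

        if current_sub is not None:
            sub_loci.append(current_sub)
        if cluster_bounds:
            locus = [min(cluster_bounds), max(cluster_bounds)]

        tail = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
        seq_parts.append(_random_dna(rng, tail))
        pos += tail
        if spec.max_scaffold_bp is not None and pos > spec.max_scaffold_bp:
            raise ValueError(
                f"scaffold {sid} ({pos} bp) exceeds max_scaffold_bp="
                f"{spec.max_scaffold_bp}; cluster does not fit"
            )

        seq = "".join(seq_parts)
        fasta_lines.append(f">{sid}")
        fasta_lines.extend(seq[i : i + 80] for i in range(0, len(seq), 80))
        gff_lines.extend(scaffold_gff)

    truth = {
        "genome_id": genome_id,
        "seed": spec.seed,
        "scaffold": truth_scaffold,
        "locus": locus,
        "sub_loci": sub_loci,
        "genes": truth_genes,
    }
    return Fixture(
        fasta_text="\n".join(fasta_lines) + "\n",
        gff_text="\n".join(gff_lines) + "\n",
        truth=truth,
    )


def write_fixture(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write FASTA, GFF3, truth JSON and the query FASTA to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixture = generate_fixture(spec)
    paths = {
        "fasta": out_dir / "genome.fa",
        "gff": out_dir / "genome.gff3",
        "truth": out_dir / "truth.json",
        "queries": out_dir / "queries.faa",
    }
    paths["fasta"].write_text(fixture.fasta_text)
    paths["gff"].write_text(fixture.gff_text)
    paths["truth"].write_text(json.dumps(fixture.truth, indent=2) + "\n")
    paths["queries"].write_text(query_fasta())
    return paths
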