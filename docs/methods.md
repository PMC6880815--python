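# Methods

## Problem setting

`chound` mines annotated fungal genomes for homologs of a query
biosynthetic gene cluster (BGC). The model system is a six-gene cluster
encoding a highly-reducing polyketide synthase (HR-PKS), a HAD-like
terpene synthase, an FAD-binding oxidoreductase, a cytochrome P450, an
α/β hydrolase and a short-chain dehydrogenase — the gene complement
expected for acylated drimane sesquiterpenoid (nanangenine-type)
biosynthesis in *Aspergillus*. Detection rests on two signals used
jointly: protein-level homology of the individual genes, and their
physical co-localization on one scaffold.

## Coordinates and gene models

Internally every interval is 0-based half-open; GFF3 and GenBank
(1-based inclusive) are converted at the file boundary only. Genes, not
transcripts, are the unit of analysis; when a gene has several mRNAs the
longest CDS set is kept, since cluster detection operates per locus.
Translation uses the standard code, trailing stops are stripped, and a
CDS with an internal stop is skipped with a warning rather than poisoning
the proteome.

## Local alignment and hit thresholds

Homology is scored by optimal Smith–Waterman local alignment with affine
gaps (Biopython's `PairwiseAligner` in local mode). The gap convention is
BLAST-style: a gap of length *k* costs `open + k·extend`, defaults
BLOSUM62 with 11/1. Identity is defined as identical columns over all
alignment columns (gap columns count); query coverage is the fraction of
query residues aligned. Because co-optimal alignments can differ in
identity depending on argument order, a pair is always aligned in
lexicographic order internally — this makes identity exactly symmetric.

There is no E-value machinery: at desk scale (≤ ~10 query proteins
against an annotated proteome) explicit identity ≥ 30% and coverage
≥ 50% thresholds are transparent, deterministic, and sufficient to
separate planted homologs from a random-protein background. E-values are
honoured only when hits are imported from external 12-column tabular
("outfmt 6") search output.

## Co-localization chaining

Hit-bearing genes on a scaffold, ordered by start, are chained while BOTH
the intergenic distance to the previous hit-bearing gene is ≤ 10 kb AND
at most 5 non-hit genes intervene. The dual criterion tolerates fungal
intergenic spacing while preventing isolated scattered hits from smearing
into one scaffold-wide call. A chain covering ≥ 3 distinct queries
becomes a candidate; its score is the sum over covered queries of the
best hit score, with per-query ties broken by score, then identity, then
leftmost gene. All three limits are exposed in the CLI and config. A
candidate whose chain includes the first or last gene of its scaffold is
flagged `partial` — a locus running to the scaffold edge may be truncated
by the assembly rather than genuinely ending there — and is never
silently dropped. Queries are treated equally; `--require` optionally
anchors candidates on one query (e.g. the terpene synthase).

## Synteny links and rendering

Between two clusters, all cross-pairs of genes are aligned and a pair is
link-eligible when identity ≥ 30% AND the alignment covers ≥ 50% of both
proteins. The coverage condition is deliberate: the best local alignment
of two *unrelated* ~300-aa proteins routinely contains a handful of
aligned residues at high identity (e.g. 7 residues at 71%), and without
a coverage floor such flukes outrank genuine homolog pairs and break the
one-to-one assignment. Eligible pairs are assigned greedily by descending
identity (ties: smaller combined start positions). Greedy is transparent
and, at cluster sizes ≤ ~10, verified equal to the exhaustive optimal
assignment in the test suite.

Figures are SVG: one horizontal track per cluster, each gene an arrow
polygon whose length is bp × `px_per_bp` (drawn to scale) and whose point
encodes strand; links between adjacent tracks are quadrilaterals filled
black with `fill-opacity = identity/100`, i.e. 0% identity fully
transparent, 100% solid black, linear in between. Tracks are optionally
co-oriented: a track is mirrored when a strict majority of its linked
genes are on the opposite strand from their partners (an exact tie leaves
it unchanged).

## Motif scanning

Class I terpene synthases carry the Mg²⁺-binding DDxxD/E motif; class II
enzymes carry DxDD, with the DxDTT variant characteristic of HAD-like
drimane synthases; the known Asp→Asn substitution in the class I motif is
matched by a dedicated DNxxD/E pattern. Patterns are position-wise
residue sets (data, not code; editable via JSON config) scanned
exhaustively over unaligned sequences, reporting every occurrence
including overlaps. Classification: any class I pattern ⇒ class_I, any
DxDD/DxDTT ⇒ class_II, both ⇒ bifunctional_motifs. The QW dipeptide is
reported as supporting evidence but never drives classification — as a
2-mer it matches far too often to be diagnostic on its own, a deliberate
simplification relative to alignment-anchored motif calling. With
`collapse_variants`, a DxDD report overlapping a DxDTT match is
suppressed (the variant subsumes it).

## Exact-mass arithmetic

Monoisotopic atomic masses are hard-coded from the IUPAC/CODATA tables at
≥ 6 decimals, and one electron mass (0.000548579909 Da) is subtracted per
positive charge — omitting the electron shifts a singly-charged ion by
~0.5 mDa, enough to miss published values at the fourth decimal. Reported
m/z is rounded half-even to 4 decimals; full precision is kept
internally. DBE = C − H/2 + N/2 + 1 with Na treated as monovalent
(H-like) and O/S ignored; the DBE of an adduct ion is always computed on
the neutral formula. Formula search enumerates the full CHNO grid
(defaults C ≤ 40, H ≤ 80, N ≤ 5, O ≤ 15, vectorised) and keeps candidates
with |ppm| within tolerance, 0 ≤ DBE ≤ 20 and integer DBE (even-electron
consistency), ranked by |ppm|. Supported adducts: [M+H]⁺, [M+Na]⁺ and the
dehydration ion [M−H₂O+H]⁺; negative mode and isotope patterns are out of
scope.

## Synthetic data

The generator emulates the study system without any downloaded sequence:
decoy genes are i.i.d.-random proteins drawn from background residue
frequencies (a clean negative background — real proteomes contain
paralogs, so false-positive behaviour on real data is *not* bounded by
these tests; a `hard_decoys` mode planting ~25%-identity paralogs probes
that direction). The six reference query proteins are deterministic
synthetic sequences at scaled-down lengths (260–420 aa; a real HR-PKS is
~2400 aa — scaled to keep all-vs-all alignment cheap while preserving
relative size). Planted genes are derived from the queries by seeded
point substitution: exactly `round(L·(1−t/100))` positions are mutated,
BLOSUM62-weighted among the 19 alternative residues, so the realised
identity is exact and reported in the truth record. Coding sequences are
back-translated with uniform synonymous codon choice (no codon-usage
realism) and placed contiguously with sampled intergenic gaps; strands
are random; split-locus and gene-dropout variants are supported. All
output is byte-deterministic given the spec.

What passing the planted-recovery study (100 seeded fixtures, 70%
identity, ≥ 95 recovered) shows: the aligner, thresholds, and chaining
rule jointly recover a co-localized cluster under realistic divergence.
What it does not show: robustness to paralog-rich backgrounds,
fragmented assemblies beyond the single split-gap case, or annotation
error — real-genome behaviour must be validated against real genomes.

## Numerical and degenerate-input choices

- An all-negative scoring pair yields a score-0 empty local alignment
  (not an error); search simply drops it.
- Empty annotation files yield a genome with scaffolds and zero genes.
- Chains produced by the split rule are maximal and disjoint, so the
  merge-overlapping step is a structural no-op kept as a guard for
  alternative front-ends.
- Problem sizes in the test suite (fixtures of 1–2 scaffolds × ~40 genes,
  queries ≤ 420 aa, 100–120 oracle trials) were chosen to exercise every
  code path at full fidelity while keeping the whole suite in the
  minutes range on one CPU.

## Known limitations

Proteome-vs-proteome only (no six-frame tBLASTn of unannotated
assemblies); no heuristic seeding, so alignment cost is quadratic —
appropriate for cluster-scale queries, not genome-vs-genome; no HMM
motif or cluster-family models; link identity uses local alignment,
which reads slightly higher than global identity for partially
homologous pairs.
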