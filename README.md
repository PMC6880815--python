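# chound

**chound** is a desk-scale toolkit for mining annotated genomes for
homologs of a query biosynthetic gene cluster (BGC) and validating the
compound annotations attached to it. It was built around the gene
cluster proposed for the acylated drimane sesquiterpenoids of
*Aspergillus* — six co-localized genes encoding a highly-reducing
polyketide synthase (HR-PKS), a HAD-like terpene synthase, an
FAD-binding oxidoreductase, a cytochrome P450, an α/β hydrolase and a
short-chain dehydrogenase — but the machinery is generic: any
multi-protein query cluster against any FASTA+GFF3 or GenBank genome.

It is aimed at natural-product genome miners who want a transparent,
fully deterministic alternative to ad-hoc BLAST-and-eyeball workflows:

- **Homology search** — optimal Smith–Waterman local alignment with
  affine gaps (BLOSUM62, gap open 11 / extend 1 by default) of every
  query protein against every annotated gene, filtered by percent
  identity and query coverage; external DIAMOND/BLAST tabular output
  (12-column "outfmt 6") can be imported instead.
- **Cluster detection** — hit-bearing genes are chained while both the
  intergenic distance (≤ 10 kb) and the number of intervening non-hit
  genes (≤ 5) stay bounded; chains covering ≥ 3 distinct queries become
  scored candidate loci. Genes conserved across all candidate loci of
  several genomes are reported as the cluster core.
- **Synteny figures** — genes of two clusters are paired one-to-one by
  amino-acid identity and drawn to scale as SVG arrow tracks, with link
  shading linear in identity (0% transparent → 100% black).
- **Motif scanning** — candidate terpene synthases are scanned for the
  class I ionisation motif DDxxD/E (and its Asp→Asn variant), the
  class II protonation motifs DxDD / DxDTT, and the supporting QW
  dipeptide; proteins carrying both classes are called
  `bifunctional_motifs`.
- **Exact-mass validation** — monoisotopic adduct m/z (with electron-mass
  correction), double-bond equivalents, ppm error, and exhaustive
  constrained formula search for observed ions.
- **Synthetic fixtures** — seeded generator of annotated genomes with a
  planted six-gene cluster at controllable identity, so the whole
  pipeline is testable without downloading a single sequence.

The ion m/z of a neutral formula M under adduct A is

    m/z = ( Σ_atoms m_mono  −  z·m_e ) / |z|

and DBE = C − H/2 + N/2 + 1 (Na counted as H-like). See
`docs/methods.md` for every convention and design choice.

## Worked example

Generate a synthetic genome with a cluster planted at 70% amino-acid
identity, index it, search, and detect:

```sh
chound fixture --seed 7 --identity 70 --out fx/
chound makedb  --fasta fx/genome.fa --gff fx/genome.gff3 --out db/
chound search  --query fx/queries.faa --db db/ --out hits.tsv
chound detect  --hits hits.tsv --db db/ --out det/
```

which prints

```
fixture -> fx
indexed 86 genes on 2 scaffolds -> db
6 hits -> hits.tsv
1 candidate cluster(s) -> det
```

and `det/candidates.tsv` contains one locus covering all six queries:

```
genome  scaffold    start   end     n_queries  score   partial  best_hits
genome  scaffold_1  81962   94312   6          7058.0  false    AB_hydrolase=synth7_g0043:70.0;FAD_oxidoreductase=synth7_g0041:70.2;HR_PKS=synth7_g0039:70.2;P450=synth7_g0042:70.0;SDR=synth7_g0044:70.3;terpene_synthase=synth7_g0040:70.2
```

— the six planted genes (`g0039`–`g0044`), each recovered at ~70%
identity, exactly the identity the generator's truth record reports, and
the locus bounds match the planted truth. `score` is the summed best
alignment score over covered queries; `partial` would flag a locus
running to a scaffold edge (a possibly truncated assembly).

Mass validation of a compound annotation:

```sh
$ chound mass --formula C15H22O5 --adduct "[M+Na]+"
C15H22O5        [M+Na]+ m/z 305.1359    DBE 5

$ chound mass --mz 305.1363 --adduct "[M+Na]+" --ppm 5
C15H22O5        m/z 305.1359    +1.17 ppm       DBE 5
C16H18N4O       m/z 305.1373    -3.22 ppm       DBE 10
```

The observed sodiated ion at 305.1363 is 1.17 ppm from the theoretical
value for C15H22O5 (5 DBE — the drimane decalin plus lactone ring and
carbonyls), which ranks first among all CHNO formulas within 5 ppm.

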