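# fcgrkit

Gene-discovery toolkit for low-affinity Fc gamma receptor (FcγR) loci,
modelled on the workflow that assembled the Göttingen minipig *FCGR*
locus and identified the putative porcine FcγRIIa (CD32a).

Low-affinity FcγRs (FcγRIIa, FcγRIIb, FcγRIIIa) bind IgG immune
complexes and decide whether an antibody triggers activating or
inhibitory signalling — a central question when a minipig is used as a
preclinical model for therapeutic antibodies. The genes sit in one
repetitive chromosomal cluster that genome drafts routinely leave
fragmented, so finding a "missing" receptor gene means stitching the
locus back together from raw shotgun contigs, reconstructing its
transcript from RACE and clone sequencing, and annotating and comparing
the encoded receptor across species. `fcgrkit` packages each of those
steps as a tested, reusable library:

- **`fcgrkit.locus_assembly`** — anchor-guided contig scaffolding.
  Exon sequences of known *FCGR* genes seed an iterative seed-and-extend
  walk over one or two contig pools; two sequences are considered
  identical when a local alignment reaches ≥ 95% identity over ≥ 200 bp
  (either strand). `compare_assemblies` globally aligns two assembled
  sequences and reports substituted and gap columns, binned in 300-bp
  alignment windows.
- **`fcgrkit.transcripts`** — full-length transcript reconstruction
  from 5′/3′ RACE fragments and RT-PCR clone reads (overlap layout,
  per-column majority vote), spliced exon mapping with GT..AG
  splice-site validation, and clone-set variant calling: exon-boundary
  deletions become splice variants with protein-level HGVS-style names
  (`Gly192_Gln215del`), isolated substitutions become SNV calls
  (`H205Y`) with per-allele clone counts.
- **`fcgrkit.annotation`** — longest-ORF finding (length excludes the
  stop codon, so 822 nt ↔ 274 aa), signal-peptide transfer from an
  annotated homolog, domain segmentation (signal / Ig1 / Ig2 / stalk /
  TM / cytoplasmic; homology-projected TM with a Kyte–Doolittle
  fallback), motif scanning with the field's literal single-unit
  patterns (sequon `N-X-S/T`, ITAM `Y-X-X-L/I`, ITIM
  `S/I/V/L-X-Y-X-X-I/V/L`), TM charge reporting, and HGVS-style variant
  naming.
- **`fcgrkit.comparative`** — region-restricted pairwise similarity
  (EMBOSS convention: % of aligned columns with a positive BLOSUM62
  score), mosaic-region cluster assignment, GBLOCKS-style conserved
  block filtering, p-distance matrices, neighbor-joining trees and
  column-resampling bootstrap supports.
- **`fcgrkit.synthetic`** — truth-known generators for every stage:
  multi-gene loci with GT..AG introns on both strands, "breed" pairs at
  stated substitution/indel rates, overlapping shredded contigs,
  RACE/clone read sets with planted variants at set clone fractions, and
  protein homolog families at controlled divergence. It bundles a
  synthetic FCGR2A-scale gene model reproducing every published
  coordinate of the real gene (1,241-nt transcript, 822-nt ORF, 274-aa
  precursor, nine exons, the three exon-skip isoforms, the A11S and
  H205Y polymorphisms).

## Worked example

`examples/` contains one narrative script per capability. Reconstructing
the transcript from simulated RACE/clone reads
(`python examples/02_transcript_reconstruction.py`) prints:

```
assembled transcript: 1241 nt (matches truth: True)
ORF 101..922 (822 nt), polyA signal at 1210
9 exons on strand -; all introns canonical: True
splice variant (233, 490): Ala45_Ser130del, 2 clones, exon skip: True
splice variant (491, 745): Asp131_Gln215del, 2 clones, exon skip: True
splice variant (674, 745): Gly192_Gln215del, 5 clones, exon skip: True
SNV G131T: A11S, ref/alt clones 27/3
SNV C713T: H205Y, ref/alt clones 21/2
```

The 30 sequenced clones reassemble the 1,241-nt mRNA exactly; its
822-nt ORF encodes the 274-aa precursor; the nine exons map back to the
genomic locus on the reverse strand with canonical GT..AG introns; and
the planted isoforms and polymorphisms are recovered with their exact
clone support (the 24-aa Ig2 deletion `Gly192_Gln215del` is carried both
alone and combined with the Ig1 skip, hence 5 supporting clones).

A thin CLI mirrors the stages:

```sh
fcgrkit simulate --what contigs --seed 1 --out scratch/contigs
fcgrkit assemble --anchors anchors.fa --pool-a contigs.fa --out scratch/asm
fcgrkit compare --a breed_a.fa --b breed_b.fa --window 300
fcgrkit tree --msa ecd_aln.fa --bootstrap 1000 --seed 42
```

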