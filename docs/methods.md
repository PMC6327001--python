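# Methods

This note documents the models, conventions and design choices behind
`fcgrkit`, and what the synthetic data do and do not demonstrate.

## Locus assembly

**Overlap criterion.** Two sequences are joined when a local alignment
spans ≥ 200 bp at ≥ 95% identity (both parameters exposed). Identity is
matches over all alignment columns, gap columns included in the
denominator; `N` never counts as a match but stays in the denominator.
Scoring is BLAST-like: match +1, mismatch −2, gap open −5, gap
extension −2 (the first gap position costs 7). The original analysis
named the thresholds but not the aligner or its scoring; results on
borderline overlaps can therefore differ from other toolchains at the
decision boundary.

**Walking.** Anchors (exon sequences of known genes, supplied in locus
order) seed sub-scaffolds; anchors shorter than 200 bp are accepted at
`min(200, 0.9 × anchor length)` aligned columns. Each round, the
terminal 1,000 bp of every sub-scaffold end are searched against the
pooled contigs (a shared-16-mer prefilter skips hopeless candidates);
the best qualifying dangling contig (highest identity, then longest
extension) is merged in its resolved orientation, with existing
scaffold bases kept on overlap disagreements. If the two best
candidates tie on identity but disagree in their extension, both are
rejected and the conflict is logged — a conservative policy mirroring
gap closure by resequencing rather than by guessing. Contained contigs
are placed without extending. When coverage holes leave several
sub-scaffolds, they are concatenated in anchor order with a fixed 100-N
spacer recorded as a `Gap` (the true gap length is unknowable from the
contigs). Scaffold orientation follows the first seeding anchor and is
therefore arbitrary up to reverse complement of the simulated strand.

**Assembly comparison.** `compare_assemblies` uses a banded
edit-distance global alignment (edlib), which handles the 115-kb scale
of the real locus in seconds. Affine-gap scoring is not used at this
step; at the divergence involved (< 2% of columns) the difference in
column counts is negligible, and substitutions are still preferred over
spurious gap pairs by the unit-cost model. Substituted columns are
binned in 300-bp windows on the alignment coordinate, trailing partial
window reported as-is; the window counts sum to the substitution total
by construction.

## Transcript reconstruction

**Read layout.** RACE fragments and clone reads are merged when they
overlap by ≥ 40 bp at ≥ 98% identity (chosen for Sanger-length reads;
the original protocol does not state thresholds). Reads are placed by
breadth-first propagation of pairwise offsets from a 5′ fragment; an
assembly that cannot connect a 5′ to a 3′ fragment raises
`disconnected`. The consensus is a per-column majority vote; ties are
emitted as `N` with a warning. Minority reads carrying large deletions
(isoform clones) place by their longest matching segment and are
outvoted in the consensus — with ≥ 5× coverage and sub-percent error
rates the consensus error is below the per-read error.

**Exon mapping.** The transcript is anchored to the locus by exact
15-mers, anchors are grouped per diagonal, and a colinear chain over
diagonals is selected by dynamic programming (diagonal jumps ≥ 40 bp
count as introns; shorter gaps are treated as alignment noise). Exact
junction placement between two diagonals is chosen to maximise base
agreement first and splice-site canonicality (GT..AG on the coding
strand) second, so a canonical site is never bought with sequence
mismatches; non-canonical sites are flagged on the exon record, never
dropped. When the gene lies on the reverse strand of the supplied
locus the donors/acceptors are reported as the coding-strand GT/AG
(they read CT/AC on the forward strand). Both strands are tried unless
a hint is given; the strand with the larger anchored coverage wins.

**Clone variant calling.** Clones are aligned to the reference
transcript with an affine-gap overlap alignment (match +1, mismatch −3,
gap open −10, extension −0.5, free end gaps). Affine gaps are essential
here: a unit-cost edit path smears a 250-nt exon skip into scattered
mismatches. Clone quality is identity over aligned (non-gap) columns —
large deletions are candidate variants, not divergence — with clones
below 90% excluded and logged. A deletion whose breakpoints land within
2 nt of annotated exon boundaries is classified as a splice variant and
snapped to them; other deletions are reported unclassified. Identical
deviations are pooled across clones. In-frame, codon-aligned deletions
inside the ORF receive protein-level deletion names; SNVs require at
least one clone per allele (a single animal can only show "potential"
polymorphisms) and receive compact substitution names when
non-synonymous. Reference exon boundaries come from the transcript
model (an optional field) or are passed explicitly; without them all
deletions are reported unclassified.

## Receptor annotation

**Conventions.** All amino-acid positions are precursor positions
(signal peptide included); ORF lengths exclude the stop codon, so an
822-nt ORF encodes exactly 274 aa. The longest ATG-initiated,
stop-terminated frame wins, ties going to the 5′-most start.

**Signal and TM.** The signal-peptide cleavage site is projected from
an annotated homolog through a global BLOSUM62 alignment and requires
≥ 50% identity over the reference signal region; a projection landing
in a gap is refused. The TM helix is likewise projected from a
reference when given; otherwise the maximal-scoring Kyte–Doolittle
19-residue window run above 1.6 is adjusted to 17–25 aa. This
homology-transfer design replaces the original ensemble of external
prediction servers; replicating their exact outputs is a non-goal.

**Segmentation.** Ig subdomains are the inter-cysteine spans (C..C
plus 3-aa flanks) within the extracellular region. When two cysteine
pairs are found, the ECD is taken to end 3 residues after the last Ig
cysteine; the membrane-proximal stalk between ECD and TM (9 aa in the
bundled model, matching the published segment arithmetic) is reported
as *unassigned* rather than silently absorbed — the source material
never names this region. Signal, ECD, unassigned, TM and cytoplasmic
segments always partition the precursor.

**Motifs.** Patterns are matched exactly as written in the field's
single-unit notation: the sequon does not exclude proline at X (a
strict option exists, default off), and ITAM is the single Y-X-X-L/I
half-unit rather than the canonical tandem repeat — a documented
divergence from convention, kept for fidelity to the motif definitions
the analysis used. Matches may overlap; a hit is reported when the
whole match lies inside the queried region.

## Comparative analysis

Pairwise similarity follows the EMBOSS convention: BLOSUM62, gap open
10, extension 0.5, similarity = % of aligned columns whose residue
pair scores positive, identity analogous, gap columns counted in the
length. Global and local modes are exposed because the original
percentages do not state which was used. Mosaic assignment scores a
query region against each cluster by mean pairwise similarity with
deterministic label-order tie-breaks. Conserved-block filtering keeps
maximal runs (≥ 5 columns) where the gap fraction is ≤ 0.5 and the
modal residue frequency is ≥ 0.5 — fixture thresholds, since the
original filtering parameters are unstated. Distances are simple
p-distances over pairwise-ungapped columns (no rate correction, matching
the unstated-model situation). Neighbor joining is delegated to
scikit-bio (negative branch lengths clamped to zero) and cross-checked
against dendropy's independent implementation in the test suite; it
recovers additive matrices exactly. Bootstrap resamples alignment
columns with replacement, rebuilds distance + NJ per replicate, and
maps bipartition counts onto the full-data tree; fixed seeds make runs
bit-reproducible. Multiple alignment, where needed, goes through the
external `mafft` binary; the synthetic protein families are
substitution-only and therefore already aligned.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their seeds. `simulate_locus`
produces multi-gene loci with GT..AG introns on both strands;
`mutate_breed` plants i.i.d. substitutions and indel events (insertion
or deletion with equal odds, geometric lengths of mean 2, uniform base
composition — fixtures, as no generative model was published) and
records every event so the pair replays exactly. Note the distinction:
`indel_rate` is a per-base *event* probability, while the published
1.25% counts gap *columns*; an event rate of 0.00625 therefore emulates
the printed figure. `shred_contigs` tiles a sequence with guaranteed
minimum overlaps, optional reverse-complemented contigs and shuffled
emission order. `simulate_reads` plants variants in deterministic clone
counts (`round(fraction × n)`, assigned in order) and i.i.d. read
errors.

The bundled FCGR2A-scale gene model and the receptor-family stand-ins
are **synthetic sequences**, not database entries: they reproduce the
published coordinates, motif positions, variant structures and
divergence levels (e.g. ECD similarity 95.3%, full-length 88%/61%,
cross-species ECD 79%) as *generating conditions*, chosen because those
are the documented properties of the real material, which cannot be
bundled. Tests therefore demonstrate that the pipeline *recovers its
generating conditions* — exact reassembly, exact variant calls,
similarity within binomial sampling error, correct tree topology — not
that it reproduces the published values on the real accessions. Real
data add features the generators omit: non-uniform base composition,
repeats that break the shared-k-mer prefilter's assumptions,
chromatogram artefacts, splice-site heterogeneity, and alignment
ambiguity near true biological indels.

## Problem sizes and numerical choices

The acceptance script runs the breed comparison at 115,000 bp, the
locus walk at ~35 kb / 20 contigs / 5 genes, read simulation at 30
clones, and the bootstrap at 1,000 replicates; unit tests use smaller
instances of the same generators. Exact-match examples are asserted
exactly; stochastic recoveries are asserted within 3 binomial standard
deviations of their generating conditions; alignment-representation
slack (equal-cost paths trading a substitution against adjacent gaps)
is allowed 15% on event-count recovery. Degenerate inputs error
loudly: empty sequences, N-only queries, anchor sets that hit nothing
("no seed"), disconnected read sets, proteins with no hydrophobic run
and no TM reference.

## Known limitations

No k-mer indexing for genome-scale pools; the walker is quadratic in
contig count. No base-quality awareness anywhere. Exon mapping assumes
≥ 95% transcript-to-locus identity and exact 15-mer anchors; highly
diverged or heavily repetitive loci need a real spliced aligner.
Insertions in clones are counted but not reported as variants. The
progressive-alignment stage is delegated to mafft rather than
reimplemented; fidelity to any specific MSA tool is not claimed.
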