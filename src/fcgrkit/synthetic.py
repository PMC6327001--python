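"""Synthetic truth-known data for every pipeline stage.

Generates multi-gene loci with GT..AG intron structure on both strands,
"breed" pairs differing by stated substitution/indel rates, overlapping
shredded contig pools, RACE/clone read sets with planted splice variants
and SNVs at set clone frequencies, and protein families with controlled
divergence. Every generator is a pure function of its seed.

The module also bundles two synthetic stand-ins for reference material
that the real study obtained from databases and supplementary files:

* :func:`fcgr2a_like` — a gene model at the exact scale of the putative
  porcine FCGR2A (1,241-nt transcript, 822-nt ORF, 274-aa precursor,
  9 exons, the three exon-skip deletions and both coding SNVs);
* :func:`simulate_receptor_family` — receptor homolog stand-ins whose
  generating divergences emulate the published cross-species similarity
  levels.

Both are synthetic sequences, not the database entries they emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from ._seq import revcomp, translate
from .locus_assembly import AnchorSeq, Contig
from .transcripts import CloneRead, RaceFragment, TranscriptModel, make_transcript_model

BASES = np.array(list("ACGT"))

_B62 = substitution_matrices.load("BLOSUM62")
_AA20 = list("ARNDCQEGHILKMFPSTWYV")
#: For each residue, the replacements scoring <= 0 against it in BLOSUM62
#: (used to plant "dissimilar" substitutions with predictable effect on
#: percent-similarity).
_DISSIMILAR = {
    a: [b for b in _AA20 if b != a and _B62[a][b] <= 0] for a in _AA20
}

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for v in _BACK_TABLE.values():
    v.sort()


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _random_protein(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# loci and breeds


@dataclass(frozen=True)
class SyntheticGene:
    name: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # forward-strand 1-based, transcript order
    transcript: str  # spliced, coding strand


@dataclass(frozen=True)
class SyntheticLocus:
    seq: str
    genes: tuple[SyntheticGene, ...]

    @property
    def truth_transcripts(self) -> dict[str, str]:
        return {g.name: g.transcript for g in self.genes}

    def anchors(self) -> list[AnchorSeq]:
        """Exon sequences of every gene, in locus order, usable as walk seeds."""
        out = []
        for g in self.genes:
            pos = 0
            for i, (lo, hi) in enumerate(g.exons, start=1):
                length = hi - lo + 1
                out.append(
                    AnchorSeq(g.name, f"{g.name}_exon{i}", g.transcript[pos : pos + length])
                )
                pos += length
        return out


def simulate_locus(
    n_genes: int = 3,
    exon_count_range: tuple[int, int] = (3, 9),
    exon_len_range: tuple[int, int] = (80, 300),
    intron_len_range: tuple[int, int] = (100, 400),
    strand_mix: float = 0.5,
    seed: int = 0,
    intergenic_len_range: tuple[int, int] = (300, 800),
) -> SyntheticLocus:
    """A multi-gene locus with GT..AG introns and genes on both strands.

    ``strand_mix`` is the probability that a gene lies on the reverse
    strand. Reproducible for a fixed seed.
    """
    for name, rng_ in (
        ("exon_count_range", exon_count_range),
        ("exon_len_range", exon_len_range),
        ("intron_len_range", intron_len_range),
        ("intergenic_len_range", intergenic_len_range),
    ):
        if rng_[0] < 1 or rng_[0] > rng_[1]:
            raise ValueError(f"infeasible {name}: {rng_}")
    if intron_len_range[0] < 10:
        raise ValueError("introns shorter than 10 bp are not representable")
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    parts: list[str] = [_random_dna(rng, int(rng.integers(*intergenic_len_range)))]
    pos = len(parts[0])
    genes = []
    for g in range(n_genes):
        n_ex = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_seqs = [
            _random_dna(rng, int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)))
            for _ in range(n_ex)
        ]
        intron_seqs = [
            "GT" + _random_dna(rng, int(rng.integers(*intron_len_range)) - 4) + "AG"
            for _ in range(n_ex - 1)
        ]
        gene_parts = []
        coding_exons = []  # 1-based within gene, coding strand
        p = 0
        for i, ex in enumerate(exon_seqs):
            gene_parts.append(ex)
            coding_exons.append((p + 1, p + len(ex)))
            p += len(ex)
            if i < n_ex - 1:
                gene_parts.append(intron_seqs[i])
                p += len(intron_seqs[i])
        gene_seq = "".join(gene_parts)
        strand = "-" if rng.random() < strand_mix else "+"
        G = len(gene_seq)
        if strand == "+":
            fwd_exons = [(pos + lo, pos + hi) for lo, hi in coding_exons]
            parts.append(gene_seq)
        else:
            fwd_exons = [(pos + G - hi + 1, pos + G - lo + 1) for lo, hi in coding_exons]
            parts.append(revcomp(gene_seq))
        genes.append(
            SyntheticGene(
                name=f"gene{g + 1}",
                strand=strand,
                exons=tuple(fwd_exons),
                transcript="".join(exon_seqs),
            )
        )
        spacer = _random_dna(rng, int(rng.integers(*intergenic_len_range)))
        parts.append(spacer)
        pos += G + len(spacer)
    return SyntheticLocus(seq="".join(parts), genes=tuple(genes))


@dataclass(frozen=True)
class BreedPair:
    """Two 'breed' copies of a locus differing by recorded mutation events."""

    seq_a: str
    seq_b: str
    truth_substitutions: tuple[tuple[int, str, str], ...]  # (pos1, ref, alt)
    truth_indels: tuple[tuple[int, str, str], ...]  # (pos1, kind, seq)
    rates: tuple[float, float]

    def replay(self) -> str:
        """Re-apply the truth events onto seq_a; must equal seq_b."""
        events: dict[int, list] = {}
        for pos, ref, alt in self.truth_substitutions:
            events.setdefault(pos, []).append(("sub", ref, alt))
        for pos, kind, seq in self.truth_indels:
            events.setdefault(pos, []).append((kind, seq))
        out = []
        i = 1
        L = len(self.seq_a)
        while i <= L:
            evs = events.get(i, [])
            skip = 1
            base = self.seq_a[i - 1]
            emitted = None
            for ev in evs:
                if ev[0] == "ins":
                    out.append(ev[1])
                elif ev[0] == "del":
                    skip = len(ev[1])
                    emitted = ""
                elif ev[0] == "sub":
                    emitted = ev[2]
            out.append(base if emitted is None else emitted)
            i += skip
        return "".join(out)


def mutate_breed(
    locus: SyntheticLocus | str,
    sub_rate: float,
    indel_rate: float,
    seed: int = 0,
) -> BreedPair:
    """Derive a second 'breed' by i.i.d. per-base substitutions and indels.

    Substitutions occur with probability ``sub_rate`` per base; indel events
    with probability ``indel_rate`` per base (insertion or deletion with
    equal odds, geometric length of mean 2). All events are recorded so the
    pair replays exactly.
    """
    seq_a = locus.seq if isinstance(locus, SyntheticLocus) else locus
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    subs = []
    indels = []
    i = 1
    L = len(seq_a)
    while i <= L:
        if indel_rate and rng.random() < indel_rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                ins = _random_dna(rng, length)
                indels.append((i, "ins", ins))
                out.append(ins)
            else:
                length = min(length, L - i + 1)
                indels.append((i, "del", seq_a[i - 1 : i - 1 + length]))
                i += length
                continue
        base = seq_a[i - 1]
        if sub_rate and rng.random() < sub_rate:
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            subs.append((i, base, alt))
            out.append(alt)
        else:
            out.append(base)
        i += 1
    return BreedPair(
        seq_a=seq_a,
        seq_b="".join(out),
        truth_substitutions=tuple(subs),
        truth_indels=tuple(indels),
        rates=(sub_rate, indel_rate),
    )


# ---------------------------------------------------------------------------
# contig shredding


@dataclass(frozen=True)
class ShredResult:
    contigs: tuple[Contig, ...]
    truth_placements: tuple[tuple[str, int, int, str], ...]  # (id, start1, end1, strand)


def shred_contigs(
    seq: str,
    n: int,
    min_overlap: int = 300,
    revcomp_fraction: float = 0.0,
    seed: int = 0,
    source: str = "synthetic",
) -> ShredResult:
    """Shred a sequence into n contigs tiling it with guaranteed overlaps.

    Adjacent contigs overlap by at least ``min_overlap`` bp; a
    ``revcomp_fraction`` of contigs is emitted reverse-complemented, and the
    emission order is shuffled. Truth placements are recorded.
    """
    L = len(seq)
    if n < 1:
        raise ValueError("n must be positive")
    if n > 1 and L < n * 2 * min_overlap:
        raise ValueError("sequence too short to tile with the requested overlaps")
    rng = np.random.default_rng(seed)
    cuts = [round(i * L / n) for i in range(n + 1)]
    intervals = []
    for i in range(n):
        start, end = cuts[i], cuts[i + 1]
        if i > 0:
            o = min_overlap - min_overlap // 2 + int(rng.integers(0, min_overlap // 4 + 1))
            start = max(0, start - o)
        if i < n - 1:
            o = min_overlap // 2 + int(rng.integers(0, min_overlap // 4 + 1))
            end = min(L, end + o)
        intervals.append((start, end))
    flip = rng.random(n) < revcomp_fraction
    order = rng.permutation(n)
    contigs = []
    placements = []
    for rank, idx in enumerate(order):
        start, end = intervals[idx]
        sub = seq[start:end]
        strand = "-" if flip[idx] else "+"
        cid = f"ctg{rank + 1:03d}"
        contigs.append(Contig(cid, source, revcomp(sub) if strand == "-" else sub))
        placements.append((cid, start + 1, end, strand))
    return ShredResult(contigs=tuple(contigs), truth_placements=tuple(placements))


# ---------------------------------------------------------------------------
# RACE / clone reads


@dataclass(frozen=True)
class PlannedVariant:
    """A transcript variant to plant into a clone set.

    ``deletions`` are 1-based inclusive transcript intervals removed from
    the reference; ``snvs`` are (pos, alt) substitutions. ``fraction`` is
    the clone fraction carrying the variant (rounded deterministically).
    """

    name: str
    fraction: float
    deletions: tuple[tuple[int, int], ...] = ()
    snvs: tuple[tuple[int, str], ...] = ()

    def apply(self, seq: str) -> str:
        s = list(seq)
        for pos, alt in self.snvs:
            s[pos - 1] = alt
        for lo, hi in sorted(self.deletions, reverse=True):
            del s[lo - 1 : hi]
        return "".join(s)


@dataclass(frozen=True)
class ReadSet:
    race5: tuple[RaceFragment, ...]
    race3: tuple[RaceFragment, ...]
    clones: tuple[CloneRead, ...]
    truth_variants: tuple[tuple[str, int], ...]  # (variant name, clone count)


def simulate_reads(
    transcript: str,
    variants: Sequence[PlannedVariant] = (),
    n_clones: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
    race_len: int = 450,
    n_race: int = 2,
) -> ReadSet:
    """RACE fragments covering the transcript ends plus a sequenced clone set.

    The first ``round(fraction * n_clones)`` clones carry each planted
    variant (assigned in order, disjointly); remaining clones are
    reference. Sequencing errors are i.i.d. substitutions at
    ``error_rate`` per base.
    """
    rng = np.random.default_rng(seed)
    L = len(transcript)

    def _errs(seq: str) -> str:
        if error_rate <= 0:
            return seq
        s = list(seq)
        hits = np.nonzero(rng.random(len(s)) < error_rate)[0]
        for i in hits:
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
        return "".join(s)

    race5 = []
    race3 = []
    for i in range(n_race):
        ln = min(L, race_len + int(rng.integers(0, 60)))
        race5.append(RaceFragment("five_prime", _errs(transcript[:ln])))
        ln = min(L, race_len + int(rng.integers(0, 60)))
        race3.append(RaceFragment("three_prime", _errs(transcript[-ln:])))

    counts = [int(round(v.fraction * n_clones)) for v in variants]
    if sum(counts) > n_clones:
        raise ValueError("variant fractions exceed the clone set")
    clones = []
    truth = []
    cid = 0
    for v, k in zip(variants, counts):
        truth.append((v.name, k))
        for _ in range(k):
            cid += 1
            clones.append(CloneRead(f"clone{cid:02d}", _errs(v.apply(transcript))))
    while cid < n_clones:
        cid += 1
        clones.append(CloneRead(f"clone{cid:02d}", _errs(transcript)))
    return ReadSet(
        race5=tuple(race5),
        race3=tuple(race3),
        clones=tuple(clones),
        truth_variants=tuple(truth),
    )


# ---------------------------------------------------------------------------
# the bundled FCGR2A-scale gene model (synthetic stand-in)


@dataclass(frozen=True)
class Fcgr2aLikeModel:
    """Synthetic gene model at the scale of the putative porcine FCGR2A.

    All sequences are randomly generated stand-ins (not database entries)
    constructed so that every published coordinate of the real gene is
    reproduced: 1,241-nt transcript = 100-nt 5'UTR + 822-nt ORF + stop +
    316-nt 3'UTR with an AATAAA signal; a 274-aa precursor with signal
    peptide 1–45 (Ala11), ECD 46–215 carrying two cysteine-bracketed
    Ig-like parts (74 and 78 aa), sequons at Asn79/89/187/211, Ser130,
    Asp131, Gly192, His205, Gln215, a 9-residue stalk, a 23-aa
    transmembrane helix with an aspartate, and a 27-aa cytoplasmic tail
    free of ITAM/ITIM motifs; nine exons whose boundaries make the three
    published exon-skip deletions and both coding SNVs representable.
    """

    protein: str
    cds: str
    transcript: TranscriptModel
    exons: tuple[tuple[int, int], ...]  # transcript coords, 1-based
    locus: str
    strand: str
    genomic_exons: tuple[tuple[int, int], ...]  # forward locus coords, transcript order
    signal: tuple[int, int]
    ecd: tuple[int, int]
    tm: tuple[int, int]
    cytoplasmic: tuple[int, int]
    splice_variants: tuple[PlannedVariant, ...]
    snvs: tuple[PlannedVariant, ...]

    def anchors(self) -> list[AnchorSeq]:
        out = []
        pos = 0
        for i, (lo, hi) in enumerate(self.exons, start=1):
            length = hi - lo + 1
            out.append(
                AnchorSeq("FCGR2A", f"FCGR2A_exon{i}", self.transcript.seq[pos : pos + length])
            )
            pos += length
        return out


#: Transcript-coordinate exon intervals of the bundled gene model.
FCGR2A_EXONS = (
    (1, 120),
    (121, 232),
    (233, 360),
    (361, 490),
    (491, 580),
    (581, 673),
    (674, 745),
    (746, 1000),
    (1001, 1241),
)

_UTR5_LEN = 100
_UTR3_LEN = 316
_PROT_LEN = 274


def _build_protein(rng: np.random.Generator) -> str:
    signal_alpha = "ALSTPGQV"
    ecd_alpha = "ADEFGHIKLPQRSTVWY"  # no Cys, no Asn, no Met
    stalk_alpha = "STPGQE"
    tm_alpha = "LIVF"
    cyto_alpha = "RKHSTPGAQEDL"  # no Tyr: the tail carries no ITAM/ITIM
    p = ["?"] * _PROT_LEN
    p[0] = "M"
    for i in range(1, 45):
        p[i] = str(rng.choice(list(signal_alpha)))
    for i in range(45, 215):
        p[i] = str(rng.choice(list(ecd_alpha)))
    for i in range(215, 224):
        p[i] = str(rng.choice(list(stalk_alpha)))
    for i in range(224, 247):
        p[i] = str(rng.choice(list(tm_alpha)))
    for i in range(247, 274):
        p[i] = str(rng.choice(list(cyto_alpha)))
    planted = {
        11: "A", 45: "A", 49: "C", 79: "N", 81: "S", 89: "N", 91: "T",
        116: "C", 130: "S", 131: "D", 141: "C", 187: "N", 189: "S",
        192: "G", 205: "H", 211: "N", 212: "C", 213: "S", 215: "Q",
        238: "D",
    }
    for pos, aa in planted.items():
        p[pos - 1] = aa
    return "".join(p)


def fcgr2a_like(seed: int = 20181218) -> Fcgr2aLikeModel:
    """Build the bundled FCGR2A-scale synthetic gene model (deterministic)."""
    rng = np.random.default_rng(seed)
    protein = _build_protein(rng)

    codons = [str(rng.choice(_BACK_TABLE[aa])) for aa in protein]
    codons[10] = "GCC"  # Ala11: a C>T SNV at codon position 1 gives Ser (A11S)
    codons[204] = "CAC"  # His205: C>T gives Tyr (H205Y)
    cds = "".join(codons)
    assert translate(cds) == protein

    utr5 = _random_dna(rng, _UTR5_LEN)
    while "ATG" in utr5:
        i = utr5.index("ATG")
        utr5 = utr5[: i + 1] + "C" + utr5[i + 2 :]
    utr3 = _random_dna(rng, _UTR3_LEN)
    polya_offset = 284  # 0-based within the 3'UTR
    while "AATAAA" in utr3[:polya_offset]:
        i = utr3.index("AATAAA")
        utr3 = utr3[: i + 2] + "C" + utr3[i + 3 :]
    utr3 = utr3[:polya_offset] + "AATAAA" + utr3[polya_offset + 6 :]
    seq = utr5 + cds + "TAA" + utr3
    assert len(seq) == 1241

    transcript = make_transcript_model(seq, exon_boundaries=FCGR2A_EXONS)
    assert transcript.orf == (101, 922)

    # genomic context: gene on the reverse strand, GT..AG introns
    intron_lens = [int(rng.integers(100, 301)) for _ in range(len(FCGR2A_EXONS) - 1)]
    gene_parts = []
    coding_exons = []
    p = 0
    for i, (lo, hi) in enumerate(FCGR2A_EXONS):
        ex = seq[lo - 1 : hi]
        gene_parts.append(ex)
        coding_exons.append((p + 1, p + len(ex)))
        p += len(ex)
        if i < len(FCGR2A_EXONS) - 1:
            intron = "GT" + _random_dna(rng, intron_lens[i] - 4) + "AG"
            gene_parts.append(intron)
            p += len(intron)
    gene_seq = "".join(gene_parts)
    flank5 = _random_dna(rng, 400)
    flank3 = _random_dna(rng, 400)
    locus = flank5 + revcomp(gene_seq) + flank3
    F, G = len(flank5), len(gene_seq)
    genomic_exons = tuple(
        (F + G - hi + 1, F + G - lo + 1) for lo, hi in coding_exons
    )

    splice_variants = (
        PlannedVariant("FcgRIIa.1", 0.10, deletions=((674, 745),)),
        PlannedVariant("FcgRIIa.2", 2 / 30, deletions=((491, 745),)),
        PlannedVariant("FcgRIIa.3", 2 / 30, deletions=((233, 490), (674, 745))),
    )
    snvs = (
        PlannedVariant("A11S", 0.10, snvs=((131, "T"),)),
        PlannedVariant("H205Y", 2 / 30, snvs=((713, "T"),)),
    )
    return Fcgr2aLikeModel(
        protein=protein,
        cds=cds,
        transcript=transcript,
        exons=FCGR2A_EXONS,
        locus=locus,
        strand="-",
        genomic_exons=genomic_exons,
        signal=(1, 45),
        ecd=(46, 215),
        tm=(225, 247),
        cytoplasmic=(248, 274),
        splice_variants=splice_variants,
        snvs=snvs,
    )


# ---------------------------------------------------------------------------
# protein homolog stand-ins


def mutate_protein(
    seq: str, dissimilar_fraction: float, rng: np.random.Generator
) -> str:
    """Substitute a fraction of residues with BLOSUM62-nonpositive partners.

    Each position is replaced with probability ``dissimilar_fraction`` by a
    residue scoring <= 0 against the original, so the expected
    percent-similarity (positive-score columns) of the mutant against the
    original is 100*(1 - dissimilar_fraction). Substitution-only: positions
    are preserved.
    """
    if not 0 <= dissimilar_fraction <= 1:
        raise ValueError("dissimilar_fraction must be in [0, 1]")
    out = list(seq)
    for i, aa in enumerate(out):
        if aa in _DISSIMILAR and rng.random() < dissimilar_fraction:
            out[i] = str(rng.choice(_DISSIMILAR[aa]))
    return "".join(out)


def make_homolog(
    protein: str,
    target_similarity: float,
    seed: int = 0,
    region_targets: Optional[Sequence[tuple[tuple[int, int], float]]] = None,
) -> str:
    """A homolog stand-in with a chosen expected percent-similarity.

    ``target_similarity`` is on the 0–100 scale; ``region_targets``
    overrides it for specific 1-based intervals (e.g. a conserved ECD
    inside otherwise divergent flanks).
    """
    rng = np.random.default_rng(seed)
    rates = np.full(len(protein), 1.0 - target_similarity / 100.0)
    for (lo, hi), sim in region_targets or ():
        rates[lo - 1 : hi] = 1.0 - sim / 100.0
    out = list(protein)
    for i, aa in enumerate(out):
        if aa in _DISSIMILAR and rng.random() < rates[i]:
            out[i] = str(rng.choice(_DISSIMILAR[aa]))
    return "".join(out)


@dataclass(frozen=True)
class ReceptorFamilyStandin:
    """Synthetic receptor homologs emulating the published divergence levels.

    ``conditions`` records the generating expected similarities (percent)
    for the documented pairs; recovered values are expected to match them
    within binomial sampling error, not the published figures exactly.
    """

    pig_iia: str
    pig_iib: str  # signal cleavage after residue 45, like the receptor it mimics
    pig_iiia: str
    human_iia: str  # 265 aa; ECD at 37..206 mirroring the human numbering
    human_iia_ecd: tuple[int, int]
    ecd_panel: dict[str, str]  # label -> equal-length ECD, for tree building
    signal_clusters: dict[str, list[str]]
    tmc_clusters: dict[str, list[str]]
    conditions: dict[str, float]


def simulate_receptor_family(seed: int = 0) -> ReceptorFamilyStandin:
    """Build the receptor-family stand-in panel (synthetic sequences).

    Divergence conditions: pig IIa vs IIb — ECD similarity 95.3%, signal
    and TM/C 76% (full-length expectation 88%); pig IIa vs IIIa 61%
    throughout; human IIa ECD 79%. The ECD tree panel gives each species a
    closely related IIa/IIb pair (within-species divergence ~2.4% each
    from the species ancestor) and a distant, interspecies-conserved IIIa
    group, mirroring the published tree structure.
    """
    model = fcgr2a_like()
    rng = np.random.default_rng(seed)
    pig_iia = model.protein
    ecd_lo, ecd_hi = model.ecd

    pig_iib = make_homolog(
        pig_iia,
        76.0,
        seed=seed + 1,
        region_targets=[((ecd_lo, ecd_hi), 95.3)],
    )
    pig_iiia = make_homolog(pig_iia, 61.0, seed=seed + 2)

    pig_ecd = pig_iia[ecd_lo - 1 : ecd_hi]
    human_signal = _random_protein(rng, 36, "ALSTPGQVWR")
    human_ecd = make_homolog(pig_ecd, 79.0, seed=seed + 3)
    human_tmc = _random_protein(rng, 59, "LIVFRKHSTQAGY")
    human_iia = human_signal + human_ecd + human_tmc

    species_div = {"PIG": 0.0, "CAT": 0.12, "HUM": 0.20, "MUS": 0.25}
    iiia_base = mutate_protein(pig_ecd, 0.35, np.random.default_rng(seed + 4))
    ecd_panel: dict[str, str] = {}
    for i, (sp, d) in enumerate(sorted(species_div.items())):
        sp_rng = np.random.default_rng(seed + 10 + i)
        ancestor = mutate_protein(pig_ecd, d, sp_rng)
        ecd_panel[f"{sp}_FcgRIIa"] = mutate_protein(ancestor, 0.024, sp_rng)
        ecd_panel[f"{sp}_FcgRIIb"] = mutate_protein(ancestor, 0.024, sp_rng)
        ecd_panel[f"{sp}_FcgRIIIa"] = mutate_protein(iiia_base, 0.05, sp_rng)

    # three unrelated signal and TM/C clusters, combined mosaic-fashion
    clus_rng = np.random.default_rng(seed + 99)
    signal_clusters = {}
    tmc_clusters = {}
    for name in ("artiodactyl", "primate", "rodent"):
        sig_seed = _random_protein(clus_rng, 45, "ALSTPGQVWRFI")
        tmc_seed = _random_protein(clus_rng, 50, "LIVFRKHSTQAG")
        signal_clusters[name] = [
            mutate_protein(sig_seed, 0.10, clus_rng) for _ in range(3)
        ]
        tmc_clusters[name] = [
            mutate_protein(tmc_seed, 0.10, clus_rng) for _ in range(3)
        ]

    conditions = {
        "ecd_iia_vs_iib": 95.3,
        "full_iia_vs_iib": 100 * (0.76 * 45 + 0.953 * 170 + 0.76 * 59) / 274,
        "full_iia_vs_iiia": 61.0,
        "ecd_pig_vs_human": 79.0,
    }
    return ReceptorFamilyStandin(
        pig_iia=pig_iia,
        pig_iib=pig_iib,
        pig_iiia=pig_iiia,
        human_iia=human_iia,
        human_iia_ecd=(37, 206),
        ecd_panel=ecd_panel,
        signal_clusters=signal_clusters,
        tmc_clusters=tmc_clusters,
        conditions=conditions,
    )
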