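"""Full-length transcript reconstruction from RACE and clone reads.

Assembles 5'/3' RACE fragments and RT-PCR clone reads into a consensus
mRNA by overlap layout and per-column majority vote, locates the ORF,
UTRs and poly-adenylation signal, maps the exons of the transcript back
onto a genomic locus with splice-site validation (GT..AG on the coding
strand), and calls splice variants and single-nucleotide variants from a
set of sequenced clones.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from . import annotation
from ._seq import check_dna, revcomp, translate

logger = logging.getLogger(__name__)

#: Read-merging criterion for Sanger-length fragments.
MIN_READ_OVERLAP = 40
MIN_READ_IDENTITY = 0.98

#: Introns below this length are treated as alignment artefacts.
MIN_INTRON = 40

#: Tolerance for a clone-deletion breakpoint to coincide with an exon boundary.
EXON_BOUNDARY_TOL = 2


@dataclass(frozen=True)
class RaceFragment:
    end: str  # "five_prime" | "three_prime"
    seq: str

    def __post_init__(self):
        if self.end not in ("five_prime", "three_prime"):
            raise ValueError("end must be five_prime or three_prime")
        object.__setattr__(self, "seq", check_dna(self.seq, "RACE fragment"))


@dataclass(frozen=True)
class CloneRead:
    clone_id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", check_dna(self.seq, f"clone {self.clone_id}"))


@dataclass(frozen=True)
class TranscriptModel:
    """A reconstructed mRNA. Intervals are 1-based inclusive; the ORF
    excludes its stop codon (the codon immediately after it is a stop)."""

    seq: str
    orf: tuple[int, int]
    utr5: Optional[tuple[int, int]]
    utr3: Optional[tuple[int, int]]
    polya_signal_pos: Optional[int]
    exon_boundaries: Optional[tuple[tuple[int, int], ...]] = None

    @property
    def protein(self) -> str:
        return translate(self.seq[self.orf[0] - 1 : self.orf[1]])


@dataclass(frozen=True)
class ExonMap:
    exon_index: int
    genomic_interval: tuple[int, int]  # forward-strand 1-based on the locus
    strand: str
    donor_dinucleotide: Optional[str]  # coding-strand 2-mers flanking the exon
    acceptor_dinucleotide: Optional[str]
    violations: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpliceVariant:
    variant_id: str
    missing_transcript_interval: tuple[int, int]
    protein_change: Optional[str]
    supporting_clones: tuple[str, ...]
    exon_skip: bool = True


@dataclass(frozen=True)
class SnvCall:
    transcript_pos: int
    ref_base: str
    alt_base: str
    coding: bool
    protein_change: Optional[str]
    clone_counts: tuple[int, int]  # (reference clones, alternate clones)


def make_transcript_model(seq: str, exon_boundaries=None) -> TranscriptModel:
    """Build a TranscriptModel around the longest ORF of *seq*."""
    seq = check_dna(seq, "transcript")
    orf = annotation.find_orf(seq)
    start, end = orf.nt_interval
    utr5 = (1, start - 1) if start > 1 else None
    utr3 = (end + 4, len(seq)) if end + 3 < len(seq) else None
    polya = None
    if utr3 is not None:
        idx = seq.find("AATAAA", utr3[0] - 1, utr3[1])
        polya = idx + 1 if idx >= 0 else None
    return TranscriptModel(
        seq=seq,
        orf=(start, end),
        utr5=utr5,
        utr3=utr3,
        polya_signal_pos=polya,
        exon_boundaries=tuple(exon_boundaries) if exon_boundaries else None,
    )


def _overlap_offset(a: str, b: str):
    """Relative placement of b against a via their best semi-global alignment.

    Returns (offset, identity, columns) where offset is the position of b's
    first base in a's coordinate system, or None when the best overlap fails
    the merging criterion.
    """
    # Infix alignment both ways captures dovetail and containment layouts.
    best = None
    for query, target, flip in ((b, a, False), (a, b, True)):
        res = edlib.align(query, target, task="path", mode="HW")
        if res["editDistance"] < 0:
            continue
        t0 = res["locations"][0][0]
        cols, matches, qlen = _cigar_stats(res["cigar"])
        identity = matches / cols if cols else 0.0
        offset = -t0 if flip else t0
        cand = (identity, cols, offset)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    if best is None:
        return None
    identity, cols, offset = best
    if cols < MIN_READ_OVERLAP or identity < MIN_READ_IDENTITY:
        return None
    return offset, identity, cols


def _cigar_stats(cigar: str):
    cols = matches = qlen = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n, num = int(num), ""
        cols += n
        if ch == "=":
            matches += n
        if ch in "=XI":
            qlen += n
    return cols, matches, qlen


def assemble_transcript(
    race5: Sequence[RaceFragment],
    race3: Sequence[RaceFragment],
    bridge_reads: Sequence[CloneRead] = (),
) -> TranscriptModel:
    """Assemble a full-length transcript from RACE fragments and clone reads.

    Reads are laid out by pairwise overlaps (>= 40 bp at >= 98% identity)
    starting from a 5' fragment; the consensus is the per-column majority
    vote across all reads covering the column, with ties reported as N.
    Raises ``disconnected`` when no overlap chain joins a 5' fragment to a
    3' fragment.
    """
    if not race5 or not race3:
        raise ValueError("need at least one 5' and one 3' RACE fragment")
    reads: list[tuple[str, str]] = []
    for i, f in enumerate(race5):
        reads.append((f"race5_{i}", f.seq))
    for c in bridge_reads:
        reads.append((c.clone_id, c.seq))
    for i, f in enumerate(race3):
        reads.append((f"race3_{i}", f.seq))
    n = len(reads)
    offsets: dict[int, int] = {0: 0}
    frontier = [0]
    while frontier:
        new_frontier = []
        for i in frontier:
            for j in range(n):
                if j in offsets:
                    continue
                ov = _overlap_offset(reads[i][1], reads[j][1])
                if ov is None:
                    continue
                offsets[j] = offsets[i] + ov[0]
                new_frontier.append(j)
        frontier = new_frontier
    three_prime_ids = {n - len(race3) + i for i in range(len(race3))}
    if not three_prime_ids & offsets.keys():
        raise ValueError("disconnected: no overlap chain joins the 5' and 3' ends")
    unplaced = [reads[j][0] for j in range(n) if j not in offsets]
    if unplaced:
        logger.warning("reads not connected to the layout: %s", ", ".join(unplaced))
    origin = min(offsets.values())
    length = max(offsets[j] + len(reads[j][1]) for j in offsets) - origin
    columns: list[Counter] = [Counter() for _ in range(length)]
    for j, off in offsets.items():
        for k, base in enumerate(reads[j][1]):
            columns[off - origin + k][base] += 1
    consensus = []
    ties = 0
    for counter in columns:
        if not counter:
            consensus.append("N")
            continue
        ranked = counter.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            consensus.append("N")
            ties += 1
        else:
            consensus.append(ranked[0][0])
    if ties:
        warnings.warn(f"{ties} consensus column(s) had tied majority votes (N)")
    return make_transcript_model("".join(consensus))


def find_polya_signal(t: TranscriptModel) -> Optional[int]:
    """1-based position of the first AATAAA in the 3' UTR, or None."""
    if t.utr3 is None:
        raise ValueError("transcript has no 3' UTR")
    idx = t.seq.find("AATAAA", t.utr3[0] - 1, t.utr3[1])
    return idx + 1 if idx >= 0 else None


# ---------------------------------------------------------------------------
# exon mapping


def _kmer_chain(tseq: str, locus: str, k: int = 15):
    """Colinear chain of exact k-mer diagonals between transcript and locus.

    Returns a list of blocks (t_start, t_end, diag) with 0-based inclusive
    transcript anchor coordinates (anchors cover t..t+k-1), or None when the
    transcript cannot be tiled.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(locus) - k + 1):
        index.setdefault(locus[j : j + k], []).append(j)
    # group anchors per diagonal
    diag_anchors: dict[int, list[int]] = {}
    for i in range(len(tseq) - k + 1):
        for j in index.get(tseq[i : i + k], ()):
            if len(index[tseq[i : i + k]]) > 10:
                continue
            diag_anchors.setdefault(j - i, []).append(i)
    blocks = []
    for diag, starts in diag_anchors.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i - prev <= k:  # contiguous or near-contiguous coverage
                prev = i
            else:
                blocks.append((run_start, prev, diag))
                run_start = prev = i
        blocks.append((run_start, prev, diag))
    if not blocks:
        return None
    blocks.sort(key=lambda b: (b[0], b[2]))
    # DP: maximise covered transcript length over chains with increasing
    # diagonals (intron >= MIN_INTRON) and increasing transcript positions.
    m = len(blocks)
    score = [0] * m
    back = [-1] * m
    for x in range(m):
        t0, t1, d = blocks[x]
        cov = t1 - t0 + k
        score[x] = cov
        for y in range(x):
            p0, p1, pd = blocks[y]
            if p1 < t0 and (d == pd or d - pd >= MIN_INTRON):
                cand = score[y] + cov
                if cand > score[x]:
                    score[x] = cand
                    back[x] = y
    best = max(range(m), key=lambda x: score[x])
    chain = []
    x = best
    while x != -1:
        chain.append(blocks[x])
        x = back[x]
    chain.reverse()
    # merge same-diagonal neighbours
    merged = [list(chain[0])]
    for t0, t1, d in chain[1:]:
        if d == merged[-1][2]:
            merged[-1][1] = t1
        else:
            merged.append([t0, t1, d])
    return [(t0, t1, d) for t0, t1, d in merged]


def map_exons(
    t: TranscriptModel,
    locus: str,
    strand_hint: Optional[str] = None,
    k: int = 15,
) -> list[ExonMap]:
    """Map the transcript's exons onto a genomic locus.

    The spliced mapping requires introns of at least 40 bp; every internal
    intron is expected to start with GT and end with AG on the gene's coding
    strand (seen as CT..AC on the supplied forward strand when the gene lies
    on the reverse strand). Non-canonical sites are flagged, never dropped.
    """
    locus = check_dna(locus, "locus")
    tseq = t.seq
    candidates = []
    strands = (strand_hint,) if strand_hint in ("+", "-") else ("+", "-")
    for strand in strands:
        work = locus if strand == "+" else revcomp(locus)
        chain = _kmer_chain(tseq, work, k=k)
        if chain is None:
            continue
        covered = sum(t1 - t0 + k for t0, t1, _ in chain)
        candidates.append((covered, strand, work, chain))
    if not candidates:
        raise ValueError("exon 1 unmappable: no anchor match on either strand")
    candidates.sort(key=lambda c: -c[0])
    _, strand, work, chain = candidates[0]

    # resolve exact exon boundaries between consecutive diagonal blocks
    exons = []  # (t_lo, t_hi, diag) 0-based inclusive
    first_t0 = chain[0][0]
    last_t1 = chain[-1][1] + k - 1
    if first_t0 > 10 or last_t1 < len(tseq) - 1 - 10:
        missing = 1 if first_t0 > 10 else len(chain) + 1
        raise ValueError(f"exon {missing} unmappable: transcript ends not anchored")
    t_lo = 0
    for idx in range(len(chain)):
        t0, t1, d = chain[idx]
        if idx == len(chain) - 1:
            exons.append((t_lo, len(tseq) - 1, d))
            break
        nt0, _, nd = chain[idx + 1]
        anchor_end = t1 + k - 1  # last transcript base covered on diag d
        lo = min(anchor_end, nt0 - 1)
        hi = max(anchor_end, nt0 - 1)
        lo = max(lo - 2, t_lo)
        hi = min(hi + 2, len(tseq) - 2)
        best_split = None  # (canonical, matches, -s)
        for s in range(lo, hi + 1):
            donor = work[s + d + 1 : s + d + 3]
            acceptor = work[s + nd - 1 : s + nd + 1]
            matches = 0
            for p in range(t0, s + 1):
                if tseq[p] == work[p + d]:
                    matches += 1
            for p in range(s + 1, nt0 + k):
                if tseq[p] == work[p + nd]:
                    matches += 1
            canonical = donor == "GT" and acceptor == "AG"
            # matches first: never sacrifice sequence agreement for a
            # canonical site; canonical breaks ties among equal splits
            cand = (matches, canonical, -s)
            if best_split is None or cand > best_split[0]:
                best_split = (cand, s)
        s = best_split[1]
        exons.append((t_lo, s, d))
        t_lo = s + 1
    maps = []
    L = len(locus)
    n_exons = len(exons)
    for i, (e_lo, e_hi, d) in enumerate(exons):
        g_lo, g_hi = e_lo + d, e_hi + d  # 0-based on coding strand
        donor = work[g_hi + 1 : g_hi + 3] if i < n_exons - 1 else None
        acceptor = work[g_lo - 2 : g_lo] if i > 0 else None
        violations = []
        if donor is not None and donor != "GT":
            violations.append(f"non-canonical donor {donor}")
        if acceptor is not None and acceptor != "AG":
            violations.append(f"non-canonical acceptor {acceptor}")
        if strand == "+":
            interval = (g_lo + 1, g_hi + 1)
        else:
            interval = (L - g_hi, L - g_lo)
        maps.append(
            ExonMap(
                exon_index=i + 1,
                genomic_interval=interval,
                strand=strand,
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
                violations=tuple(violations),
            )
        )
    # sanity: strand-resolved concatenation must reproduce the transcript
    rebuilt = "".join(work[e_lo + d : e_hi + d + 1] for e_lo, e_hi, d in exons)
    mismatch = sum(1 for a, b in zip(rebuilt, tseq) if a != b)
    if len(rebuilt) != len(tseq) or mismatch > 0.05 * len(tseq):
        raise ValueError("exon mapping failed to reproduce the transcript")
    return maps


def exon_boundaries_from_maps(t: TranscriptModel, maps: Sequence[ExonMap]):
    """Transcript-coordinate exon intervals implied by a genomic exon map."""
    out = []
    pos = 1
    for m in maps:
        lo, hi = m.genomic_interval
        length = hi - lo + 1
        out.append((pos, pos + length - 1))
        pos += length
    if pos - 1 != len(t.seq):
        raise ValueError("exon maps do not tile the transcript")
    return tuple(out)


# ---------------------------------------------------------------------------
# clone variant calling


def _clone_aligner():
    # Affine gaps keep an exon-skip deletion as one block instead of the
    # mismatch smear a unit-cost edit path prefers; reference overhangs
    # are free so partial clones align semi-globally.
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -3.0
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    a.end_gap_score = 0.0  # overlap mode: unaligned overhangs are free
    return a


def _align_clone(clone: CloneRead, ref: str):
    aln = _clone_aligner().align(ref, clone.seq)[0]
    rblocks, cblocks = aln.aligned
    if len(rblocks) == 0:
        return 0, 0, {}, [], 0, 0.0
    subs: dict[int, str] = {}
    deletions: list[tuple[int, int]] = []
    insertions = 0
    matched = aligned_cols = 0
    for (r0, r1), (c0, c1) in zip(rblocks, cblocks):
        r0, r1, c0, c1 = int(r0), int(r1), int(c0), int(c1)
        for k, (x, y) in enumerate(zip(ref[r0:r1], clone.seq[c0:c1])):
            aligned_cols += 1
            if x == y:
                matched += 1
            else:
                subs[r0 + k + 1] = y
    for i in range(1, len(rblocks)):
        rgap = int(rblocks[i][0]) - int(rblocks[i - 1][1])
        cgap = int(cblocks[i][0]) - int(cblocks[i - 1][1])
        if rgap > 0:
            deletions.append((int(rblocks[i - 1][1]) + 1, int(rblocks[i][0])))
        if cgap > 0:
            insertions += cgap
    start = int(rblocks[0][0]) + 1
    end = int(rblocks[-1][1])
    identity = matched / aligned_cols if aligned_cols else 0.0
    return start, end, subs, deletions, insertions, identity


def call_clone_variants(
    clones: Sequence[CloneRead],
    reference: TranscriptModel,
    exon_boundaries=None,
    min_clone_identity: float = 0.9,
) -> tuple[list[SpliceVariant], list[SnvCall]]:
    """Call splice variants and SNVs from a set of sequenced clones.

    Each clone is aligned to the reference transcript; clones below
    ``min_clone_identity`` over their aligned (non-gap) columns are excluded
    and logged. A contiguous clone deletion is classified as a splice
    variant when both breakpoints coincide with reference exon boundaries
    (within 2 nt); other deletions are reported unclassified. Identical
    deviations are merged with pooled clone support. An SNV is reported
    when at least one clone carries each allele.
    """
    if not clones:
        raise ValueError("no clones supplied")
    boundaries = exon_boundaries or reference.exon_boundaries
    ref = reference.seq
    orf_start, orf_end = reference.orf
    ref_protein = reference.protein

    per_clone = {}
    for clone in clones:
        start, end, subs, dels, ins, ident = _align_clone(clone, ref)
        if ident < min_clone_identity:
            logger.warning(
                "clone %s excluded: %.1f%% identity to reference",
                clone.clone_id,
                100 * ident,
            )
            continue
        per_clone[clone.clone_id] = (start, end, subs, dels)

    # --- deletions -> splice variants
    del_support: dict[tuple[int, int], list[str]] = {}
    for cid, (_s, _e, _subs, dels) in per_clone.items():
        for d in dels:
            if d[1] - d[0] + 1 < 3:
                continue
            del_support.setdefault(d, []).append(cid)
    starts = [b[0] for b in boundaries] if boundaries else []
    ends = [b[1] for b in boundaries] if boundaries else []
    merged: dict[tuple[int, int], tuple[list[str], bool]] = {}
    for (d0, d1), cids in del_support.items():
        snapped = None
        for s in starts:
            if abs(d0 - s) <= EXON_BOUNDARY_TOL:
                for e in ends:
                    if abs(d1 - e) <= EXON_BOUNDARY_TOL and e > s:
                        snapped = (s, e)
                        break
            if snapped:
                break
        key = snapped if snapped else (d0, d1)
        prev = merged.get(key, ([], snapped is not None))
        merged[key] = (prev[0] + cids, snapped is not None)
    variants = []
    for i, ((d0, d1), (cids, is_skip)) in enumerate(
        sorted(merged.items()), start=1
    ):
        protein_change = None
        if (
            orf_start <= d0 <= d1 <= orf_end
            and (d1 - d0 + 1) % 3 == 0
            and (d0 - orf_start) % 3 == 0
        ):
            aa_start = (d0 - orf_start) // 3 + 1
            aa_end = (d1 - orf_start + 1) // 3
            protein_change = annotation.name_protein_deletion(
                ref_protein, aa_start, aa_end
            ).hgvs
        variants.append(
            SpliceVariant(
                variant_id=f"var{i}",
                missing_transcript_interval=(d0, d1),
                protein_change=protein_change,
                supporting_clones=tuple(sorted(set(cids))),
                exon_skip=is_skip,
            )
        )

    # --- substitutions -> SNVs
    alt_support: dict[tuple[int, str], list[str]] = {}
    for cid, (_s, _e, subs, _dels) in per_clone.items():
        for pos, alt in subs.items():
            alt_support.setdefault((pos, alt), []).append(cid)
    snvs = []
    for (pos, alt), cids in sorted(alt_support.items()):
        ref_n = 0
        for cid, (s, e, subs, dels) in per_clone.items():
            if s <= pos <= e and pos not in subs:
                if any(d0 <= pos <= d1 for d0, d1 in dels):
                    continue
                ref_n += 1
        if ref_n < 1:
            continue
        coding = orf_start <= pos <= orf_end
        protein_change = None
        if coding:
            ci = (pos - orf_start) // 3
            codon = list(ref[orf_start - 1 + 3 * ci : orf_start - 1 + 3 * ci + 3])
            codon[(pos - orf_start) % 3] = alt
            new_aa = translate("".join(codon))
            if new_aa != ref_protein[ci] and new_aa != "*":
                protein_change = annotation.name_substitution(
                    ref_protein, ci + 1, new_aa
                ).compact
        snvs.append(
            SnvCall(
                transcript_pos=pos,
                ref_base=ref[pos - 1],
                alt_base=alt,
                coding=coding,
                protein_change=protein_change,
                clone_counts=(ref_n, len(cids)),
            )
        )
    return variants, snvs
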