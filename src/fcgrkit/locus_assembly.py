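"""Anchor-guided contig scaffolding and cross-assembly comparison.

Stitches whole-genome-shotgun contigs from one or two assemblies into a
contiguous locus by iterative seed-and-extend walking from exon anchor
sequences, using an explicit overlap criterion (by default 95% identity
over at least 200 bp, on either strand), and profiles the differences
between two assembled sequences in fixed windows along their alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
from Bio import Align

from ._seq import check_dna, revcomp

logger = logging.getLogger(__name__)

#: Terminal window searched against the contig pools at each walking round.
WALK_WINDOW_BP = 1000

#: Spacer written into the consensus where adjacent sub-scaffolds could not
#: be joined by an overlap satisfying the criterion.
GAP_SPACER_BP = 100

# BLAST-like scoring: match +1, mismatch -2, gap open -5, gap extend -2
# (the first gap position costs open+extend).
_MATCH = 1.0
_MISMATCH = -2.0
_GAP_OPEN = -7.0
_GAP_EXTEND = -2.0


@dataclass(frozen=True)
class Contig:
    """A raw assembly fragment."""

    id: str
    source: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", check_dna(self.seq, f"contig {self.id}"))


@dataclass(frozen=True)
class AnchorSeq:
    """An exon sequence from a known gene, used to seed the walk."""

    gene: str
    label: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", check_dna(self.seq, f"anchor {self.label}"))


@dataclass(frozen=True)
class OverlapHit:
    """A local alignment between a query and a contig passing the criterion.

    Intervals are 1-based inclusive; the subject interval is always given in
    the subject's forward coordinates, with ``subject_strand`` recording the
    orientation of the match.
    """

    query_id: str
    subject_id: str
    identity: float
    aligned_length: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    subject_strand: str


@dataclass(frozen=True)
class Placement:
    contig_id: str
    offset: int  # 1-based start of the oriented contig on the consensus
    strand: str


@dataclass(frozen=True)
class Gap:
    """An unresolved junction, written into the consensus as an N spacer."""

    scaffold_interval: tuple[int, int]
    left_flank_id: str
    right_flank_id: str


@dataclass
class Scaffold:
    placements: list[Placement]
    consensus: str
    gaps: list[Gap]
    conflicts: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MismatchProfile:
    """Windowed substitution counts along a pairwise global alignment."""

    window_bp: int
    window_counts: list[int]
    alignment_length: int
    mismatch_pct: float
    indel_pct: float


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = _MATCH
    a.mismatch_score = _MISMATCH
    a.open_gap_score = _GAP_OPEN
    a.extend_gap_score = _GAP_EXTEND
    return a


def _best_local(query: str, subject: str):
    """Best local alignment of query vs subject (given orientation).

    Returns (identity, columns, q0, q1, s0, s1) with 0-based half-open
    endpoints, or None when no alignment with positive score exists.
    Identity counts exact non-N matches over all alignment columns
    (gap columns included in the denominator).
    """
    aln = _aligner().align(query, subject)
    try:
        best = aln[0]
    except IndexError:
        return None
    qblocks, sblocks = best.aligned
    if len(qblocks) == 0:
        return None
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        columns += qe - qs
        for qc, sc in zip(query[qs:qe], subject[ss:se]):
            if qc == sc and qc != "N":
                matches += 1
    for i in range(1, len(qblocks)):
        columns += qblocks[i][0] - qblocks[i - 1][1]
        columns += sblocks[i][0] - sblocks[i - 1][1]
    q0, q1 = qblocks[0][0], qblocks[-1][1]
    s0, s1 = sblocks[0][0], sblocks[-1][1]
    identity = matches / columns if columns else 0.0
    return identity, columns, q0, q1, s0, s1


def find_overlaps(
    query: str,
    targets: Iterable[Contig],
    min_identity: float = 0.95,
    min_length: int = 200,
    query_id: str = "query",
) -> list[OverlapHit]:
    """Find local alignments between *query* and each target on either strand.

    A hit is reported when the alignment spans at least ``min_length``
    columns at an identity of at least ``min_identity`` (matches over all
    columns, N bases never counted as matches). Hits are sorted by
    descending identity, then aligned length.
    """
    query = check_dna(query, "query")
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0, 1]")
    if min_length < 1:
        raise ValueError("min_length must be positive")
    if set(query) == {"N"}:
        return []
    hits: list[OverlapHit] = []
    for contig in targets:
        if set(contig.seq) == {"N"}:
            continue
        for strand in "+-":
            subject = contig.seq if strand == "+" else revcomp(contig.seq)
            res = _best_local(query, subject)
            if res is None:
                continue
            identity, columns, q0, q1, s0, s1 = res
            if columns < min_length or identity < min_identity:
                continue
            if strand == "+":
                s_iv = (s0 + 1, s1)
            else:
                L = len(contig.seq)
                s_iv = (L - s1 + 1, L - s0)
            hits.append(
                OverlapHit(
                    query_id=query_id,
                    subject_id=contig.id,
                    identity=identity,
                    aligned_length=columns,
                    query_interval=(q0 + 1, q1),
                    subject_interval=s_iv,
                    subject_strand=strand,
                )
            )
    hits.sort(key=lambda h: (-h.identity, -h.aligned_length, h.subject_id))
    return hits


def _shares_kmer(window: str, seq: str, k: int = 16) -> bool:
    """Cheap pre-filter: a ≥200-bp overlap at ≥95% identity almost surely
    shares an exact k-mer with the window on one strand."""
    if len(window) < k or len(seq) < k:
        return True
    kmers = {window[i : i + k] for i in range(0, len(window) - k + 1, 4)}
    rc = revcomp(seq)
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] in kmers or rc[i : i + k] in kmers:
            return True
    return False


class _Sub:
    """A growing sub-scaffold (mutable working state of the walk)."""

    def __init__(self, consensus: str, placements: list[tuple[str, int, int, str]]):
        self.consensus = consensus
        # placements: (contig_id, start0, length, strand) in current orientation
        self.placements = placements
        self.conflicts: list[str] = []

    def revcomp(self) -> None:
        L = len(self.consensus)
        self.consensus = revcomp(self.consensus)
        self.placements = [
            (cid, L - (start + length), length, "-" if strand == "+" else "+")
            for cid, start, length, strand in self.placements
        ]


def _extend_right(
    sub: _Sub,
    contigs: Sequence[Contig],
    used: set[str],
    min_identity: float,
    min_length: int,
) -> None:
    while True:
        window = sub.consensus[-WALK_WINDOW_BP:]
        woff = len(sub.consensus) - len(window)
        candidates = []  # (identity, ext_len, contig, strand, q0, s0, s1, oriented)
        for contig in contigs:
            if contig.id in used or not _shares_kmer(window, contig.seq):
                continue
            for strand in "+-":
                oriented = contig.seq if strand == "+" else revcomp(contig.seq)
                res = _best_local(window, oriented)
                if res is None:
                    continue
                identity, columns, q0, q1, s0, s1 = res
                if columns < min_length or identity < min_identity:
                    continue
                if s0 == 0 and s1 == len(oriented):
                    # contained contig: place it, never an extension
                    used.add(contig.id)
                    sub.placements.append(
                        (contig.id, woff + q0 - s0, len(oriented), strand)
                    )
                    continue
                if q1 < len(window) - 5:
                    continue  # overlap does not reach the scaffold end
                ext = oriented[s1:]
                if not ext:
                    continue
                candidates.append(
                    (identity, len(ext), contig, strand, q0, s0, s1, oriented)
                )
        if not candidates:
            return
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2].id))
        best = candidates[0]
        if len(candidates) > 1:
            second = candidates[1]
            if abs(second[0] - best[0]) < 1e-9:
                ext_a, ext_b = best[7][best[6] :], second[7][second[6] :]
                n = min(len(ext_a), len(ext_b))
                if ext_a[:n] != ext_b[:n]:
                    msg = (
                        f"conflicting junction at scaffold end: contigs "
                        f"{best[2].id} and {second[2].id} disagree; both rejected"
                    )
                    logger.warning(msg)
                    sub.conflicts.append(msg)
                    return
        identity, _, contig, strand, q0, s0, s1, oriented = best
        used.add(contig.id)
        sub.placements.append((contig.id, woff + q0 - s0, len(oriented), strand))
        sub.consensus = sub.consensus + oriented[s1:]


def _anchor_hits(anchor: AnchorSeq, targets, min_identity, min_length):
    thr = max(20, min(min_length, int(0.9 * len(anchor.seq))))
    return find_overlaps(
        anchor.seq, targets, min_identity, thr, query_id=anchor.label
    )


def walk_extend(
    anchors: Sequence[AnchorSeq],
    pools: Sequence[Iterable[Contig]],
    min_identity: float = 0.95,
    min_length: int = 200,
) -> Scaffold:
    """Iteratively stitch contigs into a scaffold, seeded by exon anchors.

    Contigs hit by an anchor seed sub-scaffolds; each round the terminal
    windows of every sub-scaffold are searched against the pooled contigs
    and any contig passing the overlap criterion is merged in its resolved
    orientation. Sub-scaffolds that cannot be connected by an overlap are
    concatenated in anchor order, separated by an N spacer recorded as a
    :class:`Gap`. Anchors are expected in locus order.
    """
    contigs: list[Contig] = []
    seen = set()
    for pool in pools:
        for c in pool:
            if c.id in seen:
                raise ValueError(f"duplicate contig id {c.id!r}")
            seen.add(c.id)
            contigs.append(c)
    if not contigs:
        raise ValueError("no contigs supplied")
    if not anchors:
        raise ValueError("no anchors supplied")

    used: set[str] = set()
    subs: list[_Sub] = []
    for anchor in anchors:
        placed = False
        for sub in subs:
            probe = Contig("_consensus", "scaffold", sub.consensus)
            if _anchor_hits(anchor, [probe], min_identity, min_length):
                placed = True
                break
        if placed:
            continue
        hits = _anchor_hits(
            anchor, [c for c in contigs if c.id not in used], min_identity, min_length
        )
        if not hits:
            continue
        best = hits[0]
        seed = next(c for c in contigs if c.id == best.subject_id)
        oriented = seed.seq if best.subject_strand == "+" else revcomp(seed.seq)
        used.add(seed.id)
        sub = _Sub(oriented, [(seed.id, 0, len(oriented), best.subject_strand)])
        _extend_right(sub, contigs, used, min_identity, min_length)
        sub.revcomp()
        _extend_right(sub, contigs, used, min_identity, min_length)
        sub.revcomp()
        subs.append(sub)

    if not subs:
        raise ValueError("no seed: no anchor matched any contig")

    consensus_parts: list[str] = []
    placements: list[Placement] = []
    gaps: list[Gap] = []
    conflicts: list[str] = []
    pos = 0
    for i, sub in enumerate(subs):
        conflicts.extend(sub.conflicts)
        if i > 0:
            left_flank = max(subs[i - 1].placements, key=lambda p: p[1] + p[2])[0]
            right_flank = min(sub.placements, key=lambda p: p[1])[0]
            gaps.append(Gap((pos + 1, pos + GAP_SPACER_BP), left_flank, right_flank))
            consensus_parts.append("N" * GAP_SPACER_BP)
            pos += GAP_SPACER_BP
        for cid, start0, _length, strand in sorted(sub.placements, key=lambda p: p[1]):
            placements.append(Placement(cid, pos + start0 + 1, strand))
        consensus_parts.append(sub.consensus)
        pos += len(sub.consensus)
    placements.sort(key=lambda p: p.offset)
    return Scaffold(
        placements=placements,
        consensus="".join(consensus_parts),
        gaps=gaps,
        conflicts=conflicts,
    )


def compare_assemblies(a: str, b: str, window_bp: int = 300) -> MismatchProfile:
    """Globally align two assembled sequences and profile their differences.

    Substituted and gap columns are counted over the whole alignment;
    substitutions are additionally binned in ``window_bp``-column windows on
    the alignment coordinate (the trailing partial window is reported as-is).
    """
    a = check_dna(a, "sequence a")
    b = check_dna(b, "sequence b")
    if window_bp < 1:
        raise ValueError("window_bp must be positive")
    res = edlib.align(a, b, task="path", mode="NW")
    cigar = res["cigar"]
    if cigar is None:
        raise RuntimeError("alignment failed")
    col = 0
    mismatches = 0
    gap_cols = 0
    counts: list[int] = []

    def _bump(n_cols: int, is_sub: bool):
        nonlocal col
        for _ in range(n_cols):
            w = col // window_bp
            while len(counts) <= w:
                counts.append(0)
            if is_sub:
                counts[w] += 1
            col += 1

    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            _bump(n, False)
        elif ch == "X":
            _bump(n, True)
            mismatches += n
        elif ch in "ID":
            _bump(n, False)
            gap_cols += n
        else:  # pragma: no cover
            raise RuntimeError(f"unexpected CIGAR op {ch!r}")
    total = col
    return MismatchProfile(
        window_bp=window_bp,
        window_counts=counts,
        alignment_length=total,
        mismatch_pct=100.0 * mismatches / total,
        indel_pct=100.0 * gap_cols / total,
    )


def report_gaps(s: Scaffold) -> list[Gap]:
    """Gaps of a scaffold, sorted by consensus coordinate (empty iff contiguous)."""
    return sorted(s.gaps, key=lambda g: g.scaffold_interval)
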