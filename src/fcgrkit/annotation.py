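"""Precursor protein annotation for Fc gamma receptors.

Derives the protein from a transcript (longest open reading frame),
transfers the signal-peptide cleavage site from an annotated homolog,
segments the precursor into signal / extracellular (Ig1, Ig2) /
transmembrane / cytoplasmic regions, scans the short immunoreceptor
motifs (N-glycosylation sequon, ITAM, ITIM), reports charged residues in
the transmembrane helix, and names protein-level variants in HGVS style.

Numbering convention: all amino-acid positions are precursor positions,
i.e. they include the signal peptide, and open-reading-frame lengths
exclude the stop codon (822 nt <-> 274 aa).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import aa3, translate

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Kyte–Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

MOTIF_PATTERNS = {
    # Patterns written exactly as the single-unit motifs: the sequon does not
    # exclude proline at X unless strict=True, and ITAM is the single
    # Y-X-X-L/I half-unit rather than the canonical tandem repeat.
    "NGLYC": r"N.[ST]",
    "NGLYC_STRICT": r"N[^P][ST]",
    "ITAM": r"Y..[LI]",
    "ITIM": r"[SIVL].Y..[ILV]",
    "POLYA": r"AATAAA",
}


@dataclass(frozen=True)
class OrfResult:
    nt_interval: tuple[int, int]  # 1-based inclusive, stop codon excluded
    nt_length: int
    protein: str


@dataclass(frozen=True)
class DomainSegmentation:
    """Precursor segmentation; intervals are 1-based inclusive aa positions.

    ``signal``, ``ecd``, ``tm``, ``cytoplasmic`` and ``unassigned`` jointly
    partition 1..length; ``ig1``/``ig2`` lie inside ``ecd``.
    """

    signal: tuple[int, int]
    ecd: tuple[int, int]
    tm: tuple[int, int]
    cytoplasmic: Optional[tuple[int, int]]
    ig1: Optional[tuple[int, int]]
    ig2: Optional[tuple[int, int]]
    unassigned: list[tuple[int, int]]


@dataclass(frozen=True)
class MotifHit:
    motif_type: str
    aa_position: int  # 1-based start in precursor numbering
    matched_text: str


@dataclass(frozen=True)
class TmChargeReport:
    charged_positions: list[tuple[int, str]]  # (precursor position, residue)


@dataclass(frozen=True)
class ProteinVariantName:
    hgvs: str
    aa_span: int
    compact: Optional[str] = None  # one-letter form for substitutions


def find_orf(transcript) -> OrfResult:
    """Longest ATG-initiated reading frame terminated by a stop codon.

    Scans the three forward frames of the transcript (mRNA sense strand).
    Reported length excludes the stop codon; ties are broken by the
    5'-most start.
    """
    seq = transcript.seq if hasattr(transcript, "seq") else transcript
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("transcript shorter than 6 nt cannot contain an ORF")
    best = None  # (length, -start) maximized
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for p in range(start, len(seq) - 2, 3):
            if seq[p : p + 3] in STOP_CODONS:
                length = p - start
                if length >= 3 and (best is None or (length, -start) > (best[0], -best[1])):
                    best = (length, start)
                break
    if best is None:
        raise ValueError("no open reading frame found")
    length, start = best
    protein = translate(seq[start : start + length])
    return OrfResult(
        nt_interval=(start + 1, start + length),
        nt_length=length,
        protein=protein,
    )


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    return a


def _column_map(alignment):
    """Yield (query_pos, ref_pos) per column, None on the gapped side (0-based)."""
    qb, rb = alignment.aligned  # target = query protein, query = reference
    cols = []
    prev_q = prev_r = None
    for (q0, q1), (r0, r1) in zip(qb, rb):
        if prev_q is not None:
            for q in range(prev_q, q0):
                cols.append((q, None))
            for r in range(prev_r, r0):
                cols.append((None, r))
        for q, r in zip(range(q0, q1), range(r0, r1)):
            cols.append((q, r))
        prev_q, prev_r = q1, r1
    return cols


def transfer_signal_peptide(
    protein: str, ref_protein: str, ref_signal_end: int
) -> tuple[int, int]:
    """Project a homolog's signal-peptide cleavage site onto *protein*.

    The two precursors are globally aligned (BLOSUM62); the reference
    cleavage position ``ref_signal_end`` (last residue of the reference
    signal peptide) is carried through the alignment. Requires at least 50%
    identity over the reference signal region.
    """
    if not 1 <= ref_signal_end <= len(ref_protein):
        raise ValueError("ref_signal_end outside reference protein")
    aln = _protein_aligner().align(protein, ref_protein)[0]
    cols = _column_map(aln)
    matches = 0
    signal_cols = 0
    target = None
    for q, r in cols:
        if r is not None and r < ref_signal_end:
            signal_cols += 1
            if q is not None and protein[q] == ref_protein[r]:
                matches += 1
        if r == ref_signal_end - 1:
            target = q
    if signal_cols == 0 or matches / signal_cols < 0.5:
        raise ValueError(
            "reference signal region aligns below 50% identity; refusing transfer"
        )
    if target is None:
        raise ValueError("unalignable cleavage site")
    return (1, target + 1)


def _project_interval(protein: str, ref_protein: str, ref_interval) -> tuple[int, int]:
    aln = _protein_aligner().align(protein, ref_protein)[0]
    cols = _column_map(aln)
    lo, hi = ref_interval
    qpos = [q for q, r in cols if r is not None and lo - 1 <= r <= hi - 1 and q is not None]
    if not qpos:
        raise ValueError("reference interval unalignable")
    return (min(qpos) + 1, max(qpos) + 1)


def _hydropathy_tm(protein: str, window: int, threshold: float) -> tuple[int, int]:
    """Maximal-scoring hydrophobic run, trimmed/extended to 17–25 aa."""
    n = len(protein)
    if n < window:
        raise ValueError("protein shorter than hydropathy window")
    scores = []
    for i in range(n - window + 1):
        w = protein[i : i + window]
        scores.append(sum(KYTE_DOOLITTLE.get(c, 0.0) for c in w) / window)
    runs = []  # (mean score, start, end) of window-centre runs above threshold
    i = 0
    while i < len(scores):
        if scores[i] > threshold:
            j = i
            while j < len(scores) and scores[j] > threshold:
                j += 1
            run_scores = scores[i:j]
            runs.append((max(run_scores), i, j - 1))
            i = j
        else:
            i += 1
    if not runs:
        raise ValueError("no hydrophobic run above threshold and no TM reference")
    _, i0, i1 = max(runs)
    # residues covered by the qualifying windows
    start, end = i0, i1 + window - 1  # 0-based inclusive
    length = end - start + 1
    if length > 25:
        # trim to the best-scoring 25-residue stretch
        best_i, best_s = start, None
        for i in range(start, end - 25 + 2):
            s = sum(KYTE_DOOLITTLE.get(c, 0.0) for c in protein[i : i + 25])
            if best_s is None or s > best_s:
                best_s, best_i = s, i
        start, end = best_i, best_i + 24
    elif length < 17:
        grow = 17 - length
        start = max(0, start - grow // 2)
        end = min(n - 1, start + 16)
        start = max(0, end - 16)
    return (start + 1, end + 1)


def segment_domains(
    protein: str,
    signal: tuple[int, int],
    tm_ref: Optional[tuple[str, tuple[int, int]]] = None,
    hydropathy_window: int = 19,
    hydropathy_threshold: float = 1.6,
) -> DomainSegmentation:
    """Segment a receptor precursor into signal / ECD / TM / cytoplasmic parts.

    The transmembrane helix is projected from ``tm_ref`` (a reference
    protein with a known TM interval) when supplied, otherwise predicted as
    the maximal-scoring Kyte–Doolittle window run above ``hydropathy_threshold``
    adjusted to 17–25 aa. Ig subdomains are the inter-cysteine spans
    (C..C plus 3-aa flanks) within the ECD; when two cysteine pairs are
    found, the ECD is taken to end 3 residues after the last Ig cysteine
    and the membrane-proximal stalk up to the TM is reported unassigned.
    """
    n = len(protein)
    if signal[0] != 1 or not 1 <= signal[1] < n:
        raise ValueError("signal interval must start at 1 and end inside the protein")
    if tm_ref is not None:
        ref_protein, ref_tm = tm_ref
        tm = _project_interval(protein, ref_protein, ref_tm)
    else:
        tm = _hydropathy_tm(protein, hydropathy_window, hydropathy_threshold)
    if tm[0] <= signal[1]:
        raise ValueError("predicted TM overlaps the signal peptide")
    cyto = (tm[1] + 1, n) if tm[1] < n else None

    ecd_start = signal[1] + 1
    cys = [i + 1 for i in range(ecd_start - 1, tm[0] - 1) if protein[i] == "C"]
    ig1 = ig2 = None
    ecd_end = tm[0] - 1
    if len(cys) >= 4:
        c1, c2, c3, c4 = cys[0], cys[1], cys[-2], cys[-1]
        ig1 = (max(ecd_start, c1 - 3), c2 + 3)
        ig2 = (c3 - 3, min(c4 + 3, tm[0] - 1))
        ecd_end = min(c4 + 3, tm[0] - 1)
    ecd = (ecd_start, ecd_end)
    unassigned = []
    if ecd_end + 1 <= tm[0] - 1:
        unassigned.append((ecd_end + 1, tm[0] - 1))
    return DomainSegmentation(
        signal=signal,
        ecd=ecd,
        tm=tm,
        cytoplasmic=cyto,
        ig1=ig1,
        ig2=ig2,
        unassigned=unassigned,
    )


def scan_motifs(
    protein: str,
    region: tuple[int, int],
    motif_type: str,
    strict_sequon: bool = False,
) -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences lying within *region*.

    Positions are 1-based precursor positions; a hit is reported when the
    entire match lies inside the region.
    """
    lo, hi = region
    if not 1 <= lo <= hi <= len(protein):
        raise ValueError("region outside protein")
    key = motif_type.upper()
    if key == "NGLYC" and strict_sequon:
        key = "NGLYC_STRICT"
    if key not in MOTIF_PATTERNS:
        raise ValueError(f"unknown motif type {motif_type!r}")
    pattern = re.compile(f"(?=({MOTIF_PATTERNS[key]}))")
    hits = []
    for m in pattern.finditer(protein):
        start = m.start() + 1
        text = m.group(1)
        if start >= lo and start + len(text) - 1 <= hi:
            hits.append(
                MotifHit(
                    motif_type=motif_type.upper(), aa_position=start, matched_text=text
                )
            )
    return hits


def tm_charges(protein: str, tm: tuple[int, int]) -> TmChargeReport:
    """Negatively charged residues (D/E) inside the transmembrane interval."""
    lo, hi = tm
    if not 1 <= lo <= hi <= len(protein):
        raise ValueError("TM interval outside protein")
    charged = [
        (i, protein[i - 1]) for i in range(lo, hi + 1) if protein[i - 1] in "DE"
    ]
    return TmChargeReport(charged_positions=charged)


def name_protein_deletion(ref_protein: str, start: int, end: int) -> ProteinVariantName:
    """HGVS-style name of a residue-range deletion, e.g. ``Gly192_Gln215del``."""
    if not 1 <= start <= end <= len(ref_protein):
        raise ValueError("deletion coordinates out of range")
    if start == end:
        name = f"{aa3(ref_protein[start - 1])}{start}del"
    else:
        name = (
            f"{aa3(ref_protein[start - 1])}{start}_"
            f"{aa3(ref_protein[end - 1])}{end}del"
        )
    return ProteinVariantName(hgvs=name, aa_span=end - start + 1)


def apply_deletion(ref_protein: str, start: int, end: int) -> str:
    """The protein with residues start..end removed (1-based inclusive)."""
    if not 1 <= start <= end <= len(ref_protein):
        raise ValueError("deletion coordinates out of range")
    return ref_protein[: start - 1] + ref_protein[end:]


def name_substitution(ref_protein: str, pos: int, alt: str) -> ProteinVariantName:
    """Substitution name in both compact (H205Y) and three-letter HGVS form."""
    if not 1 <= pos <= len(ref_protein):
        raise ValueError("position out of range")
    ref = ref_protein[pos - 1]
    alt = alt.upper()
    if alt == ref:
        raise ValueError("not a variant: alternate equals reference residue")
    return ProteinVariantName(
        hgvs=f"{aa3(ref)}{pos}{aa3(alt)}",
        aa_span=1,
        compact=f"{ref}{pos}{alt}",
    )
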