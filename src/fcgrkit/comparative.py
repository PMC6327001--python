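"""Cross-species receptor comparison: similarity, mosaicism, phylogeny.

Region-restricted pairwise protein similarity (EMBOSS-style: percentage of
aligned columns with a positive BLOSUM62 score), assignment of a receptor
region to one of several separately conserved sequence clusters
("mosaic" regions), conserved-block filtering of a multiple alignment,
p-distance matrices, neighbor-joining trees and bootstrap supports.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from ._seq import as_fasta

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive amino-acid interval of a named sequence."""

    seq_id: str
    aa_interval: tuple[int, int]

    def slice(self, seq: str) -> str:
        lo, hi = self.aa_interval
        if not 1 <= lo <= hi <= len(seq):
            raise ValueError(
                f"interval {lo}-{hi} outside sequence {self.seq_id} (len {len(seq)})"
            )
        return seq[lo - 1 : hi]


@dataclass(frozen=True)
class SimilarityResult:
    pct_identity: float
    pct_similarity: float
    aligned_length: int
    gap_columns: int


@dataclass(frozen=True)
class MosaicAssignment:
    region: str
    best_cluster: str
    per_cluster_similarity: dict[str, float]
    margin: float


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.d, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "d", m)


@dataclass(frozen=True)
class PhyloTree:
    newick: str

    @property
    def tree(self) -> TreeNode:
        return TreeNode.read(StringIO(self.newick))


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = _BLOSUM62
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    return a


def pairwise_similarity(a: str, b: str, mode: str = "local") -> SimilarityResult:
    """Affine-gap alignment of two protein (sub)sequences.

    ``pct_similarity`` is the percentage of aligned columns whose residue
    pair has a positive BLOSUM62 score; ``pct_identity`` is the analogous
    exact-match percentage. Gap columns count toward the alignment length.
    """
    if not a or not b:
        raise ValueError("empty region")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    aln = _aligner(mode).align(a, b)[0]
    ablocks, bblocks = aln.aligned
    identical = positive = columns = 0
    for (a0, a1), (b0, b1) in zip(ablocks, bblocks):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            columns += 1
            if x == y:
                identical += 1
            if _BLOSUM62[x][y] > 0:
                positive += 1
    gap_columns = 0
    for i in range(1, len(ablocks)):
        gap_columns += ablocks[i][0] - ablocks[i - 1][1]
        gap_columns += bblocks[i][0] - bblocks[i - 1][1]
    columns += gap_columns
    if columns == 0:
        raise ValueError("alignment is empty")
    return SimilarityResult(
        pct_identity=100.0 * identical / columns,
        pct_similarity=100.0 * positive / columns,
        aligned_length=columns,
        gap_columns=gap_columns,
    )


def assign_mosaic_region(
    query: str,
    clusters: Mapping[str, Sequence[str]],
    region: str = "region",
    mode: str = "local",
) -> MosaicAssignment:
    """Assign a region to the cluster with the highest mean similarity.

    Ties are broken deterministically by label order; the margin between
    the best and second-best cluster is reported.
    """
    if not clusters:
        raise ValueError("empty cluster set")
    sims = {}
    for label in sorted(clusters):
        members = clusters[label]
        if not members:
            raise ValueError(f"cluster {label!r} is empty")
        sims[label] = float(
            np.mean([pairwise_similarity(query, m, mode).pct_similarity for m in members])
        )
    ranked = sorted(sims.items(), key=lambda kv: (-kv[1], kv[0]))
    margin = ranked[0][1] - ranked[1][1] if len(ranked) > 1 else ranked[0][1]
    return MosaicAssignment(
        region=region,
        best_cluster=ranked[0][0],
        per_cluster_similarity=sims,
        margin=margin,
    )


def _check_msa(msa: Sequence[tuple[str, str]]):
    if not msa:
        raise ValueError("empty alignment")
    labels = [x[0] for x in msa]
    rows = [x[1].upper() for x in msa]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate row labels")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    return labels, rows


def filter_conserved_columns(
    msa: Sequence[tuple[str, str]],
    max_gap_fraction: float = 0.5,
    min_conservation: float = 0.5,
    min_block: int = 5,
) -> tuple[list[tuple[str, str]], list[int]]:
    """Keep conserved blocks of an alignment (GBLOCKS-style).

    A column is kept when its gap fraction is <= ``max_gap_fraction`` and
    its modal residue frequency (over all rows) is >= ``min_conservation``;
    only maximal runs of at least ``min_block`` such columns survive.
    Returns the filtered alignment and the kept column indices (0-based,
    original coordinates).
    """
    labels, rows = _check_msa(msa)
    n = len(rows)
    L = len(rows[0])
    good = []
    for c in range(L):
        col = [r[c] for r in rows]
        gaps = sum(1 for x in col if x in GAP_CHARS)
        residues = [x for x in col if x not in GAP_CHARS]
        modal = max((residues.count(r) for r in set(residues)), default=0)
        good.append(gaps / n <= max_gap_fraction and modal / n >= min_conservation)
    kept: list[int] = []
    c = 0
    while c < L:
        if good[c]:
            j = c
            while j < L and good[j]:
                j += 1
            if j - c >= min_block:
                kept.extend(range(c, j))
            c = j
        else:
            c += 1
    if not kept:
        warnings.warn("no alignment columns survived conserved-block filtering")
    filtered = [
        (label, "".join(row[c] for c in kept)) for label, row in zip(labels, rows)
    ]
    return filtered, kept


def distance_matrix(msa: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """p-distance matrix: d(i,j) = 1 - identical fraction over columns where
    neither row is gapped."""
    labels, rows = _check_msa(msa)
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ident = 0
            for x, y in zip(rows[i], rows[j]):
                if x in GAP_CHARS or y in GAP_CHARS:
                    continue
                shared += 1
                if x == y:
                    ident += 1
            if shared == 0:
                warnings.warn(
                    f"rows {labels[i]} and {labels[j]} share no ungapped columns"
                )
                d[i, j] = d[j, i] = 1.0
            else:
                d[i, j] = d[j, i] = 1.0 - ident / shared
    return DistanceMatrix(labels=tuple(labels), d=d)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining; negative branch lengths are clamped to 0."""
    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    skdm = _SkbioDM(d.d, ids=list(d.labels))
    tree = nj(skdm)  # skbio clamps negative branch lengths by default
    for node in tree.traverse():
        if node.length is not None and node.length < 0:  # pragma: no cover
            warnings.warn("negative branch length clamped to 0")
            node.length = 0.0
    return PhyloTree(newick=str(tree).strip())


def _bipartitions(tree: TreeNode, taxa: frozenset[str]):
    """Non-trivial bipartitions of an unrooted tree, as canonical frozensets
    (the side not containing the alphabetically first taxon)."""
    anchor = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def bootstrap_support(
    msa: Sequence[tuple[str, str]],
    replicates: int = 1000,
    seed: int = 0,
) -> tuple[PhyloTree, dict[frozenset, int]]:
    """Column-resampling bootstrap of the distance/NJ tree.

    Alignment columns are resampled with replacement per replicate, a
    p-distance NJ tree is built from each, and bipartition counts are
    mapped onto the internal nodes of the full-data tree (stored as node
    support labels in the returned newick).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    labels, rows = _check_msa(msa)
    taxa = frozenset(labels)
    full = nj_tree(distance_matrix(msa)).tree
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(full, taxa)}
    rng = np.random.default_rng(seed)
    L = len(rows[0])
    arr = np.array([list(r) for r in rows])
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = [(lab, "".join(arr[i, cols])) for i, lab in enumerate(labels)]
        rep_tree = nj_tree(distance_matrix(rep)).tree
        for bp in _bipartitions(rep_tree, taxa):
            if bp in counts:
                counts[bp] += 1
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if min(taxa) not in side else taxa - side
        if canon in counts:
            node.name = str(counts[canon])
    return PhyloTree(newick=str(full).strip()), counts


def align_with_mafft(seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Multiple protein alignment via the mafft command-line tool."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        inp.write_text(as_fasta(seqs))
        res = subprocess.run(
            ["mafft", "--quiet", "--auto", "--amino", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
    records = list(SeqIO.parse(StringIO(res.stdout), "fasta"))
    return [(r.id, str(r.seq).upper()) for r in records]
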