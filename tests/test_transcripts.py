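"""Transcript assembly, exon mapping, and clone variant calling."""

import numpy as np
import pytest

from fcgrkit import synthetic, transcripts
from fcgrkit._seq import revcomp
from fcgrkit.transcripts import (
    CloneRead,
    RaceFragment,
    assemble_transcript,
    call_clone_variants,
    exon_boundaries_from_maps,
    find_polya_signal,
    make_transcript_model,
    map_exons,
)


def test_assembly_round_trip_from_shredded_reads(model):
    """RACE + clone reads shredded from a known transcript reassemble it
    base-perfectly."""
    rs = synthetic.simulate_reads(model.transcript.seq, seed=2)
    out = assemble_transcript(rs.race5, rs.race3, rs.clones)
    assert out.seq == model.transcript.seq
    assert out.orf == model.transcript.orf
    assert out.polya_signal_pos == model.transcript.polya_signal_pos


def test_assembly_majority_vote_beats_read_errors(model):
    """With 0.1% per-base errors and >5x coverage the consensus carries
    fewer errors than any single read."""
    truth = model.transcript.seq
    rs = synthetic.simulate_reads(truth, n_clones=30, error_rate=0.001, seed=8)
    out = assemble_transcript(rs.race5, rs.race3, rs.clones)
    consensus_err = sum(1 for a, b in zip(out.seq, truth) if a != b)
    worst_read = min(
        sum(1 for a, b in zip(c.seq, truth) if a != b) for c in rs.clones
    )
    assert len(out.seq) == len(truth)
    assert consensus_err < max(1, worst_read)


def test_single_fragment_covers_transcript(model):
    seq = model.transcript.seq
    frag5 = RaceFragment("five_prime", seq)
    frag3 = RaceFragment("three_prime", seq)
    out = assemble_transcript([frag5], [frag3])
    assert out.seq == seq


def test_disconnected_fragments_error():
    a = RaceFragment("five_prime", "ACGTACGTACGTAAACCCGGGTTTACGTACGTACGTACGTACGTACGTAC")
    b = RaceFragment("three_prime", "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATT")
    with pytest.raises(ValueError, match="disconnected"):
        assemble_transcript([a], [b])


def test_polya_signal_positions():
    rng = np.random.default_rng(3)
    stem = "ATG" + "GCT" * 40 + "TAA"

    def utr(n):
        s = "".join(rng.choice(list("CGT"), size=n))
        return s

    one = make_transcript_model(stem + utr(30) + "AATAAA" + utr(20))
    assert find_polya_signal(one) == len(stem) + 31
    none = make_transcript_model(stem + utr(50))
    assert find_polya_signal(none) is None
    two = make_transcript_model(stem + utr(10) + "AATAAA" + utr(10) + "AATAAA" + utr(5))
    assert find_polya_signal(two) == len(stem) + 11  # first occurrence wins


def test_map_exons_reverse_strand_truth(model):
    """The nine exons of the bundled gene map back to their genomic truth
    coordinates on the reverse strand with canonical GT..AG introns."""
    maps = map_exons(model.transcript, model.locus)
    assert len(maps) == 9
    assert all(m.strand == "-" for m in maps)
    assert tuple(m.genomic_interval for m in maps) == model.genomic_exons
    internal_donors = [m.donor_dinucleotide for m in maps[:-1]]
    internal_acceptors = [m.acceptor_dinucleotide for m in maps[1:]]
    assert internal_donors == ["GT"] * 8
    assert internal_acceptors == ["AG"] * 8
    assert maps[-1].donor_dinucleotide is None
    assert maps[0].acceptor_dinucleotide is None
    assert all(m.violations == () for m in maps)
    assert exon_boundaries_from_maps(model.transcript, maps) == model.exons


def test_map_exons_forward_strand():
    locus = synthetic.simulate_locus(n_genes=1, seed=31, strand_mix=0.0,
                                     exon_count_range=(7, 7))
    gene = locus.genes[0]
    t = make_transcript_model_safe(gene.transcript)
    maps = map_exons(t, locus.seq)
    assert len(maps) == 7
    assert all(m.strand == "+" for m in maps)
    assert tuple(m.genomic_interval for m in maps) == gene.exons


def make_transcript_model_safe(seq):
    """Wrap a spliced transcript that may lack an ORF in a minimal model."""
    try:
        return make_transcript_model(seq)
    except ValueError:
        return transcripts.TranscriptModel(
            seq=seq, orf=(1, 3), utr5=None, utr3=None, polya_signal_pos=None
        )


def test_map_exons_flags_noncanonical_donor(model):
    """A GC..AG intron is mapped but flagged, never dropped."""
    locus = model.locus
    # the gene lies on the reverse strand: the donor GT of the first intron
    # appears as AC on the forward strand, immediately left of exon 1's start
    g_lo = model.genomic_exons[0][0]
    # coding-strand donor GT <-> forward-strand AC at (g_lo-2, g_lo-1)
    assert locus[g_lo - 3 : g_lo - 1] == "AC"
    # coding-strand T (second donor base) is the forward-strand A at 1-based
    # g_lo-2; A -> G there turns the coding donor into GC
    edited = locus[: g_lo - 3] + "G" + locus[g_lo - 2 :]
    maps = map_exons(model.transcript, edited)
    assert len(maps) == 9
    flagged = [m for m in maps if m.violations]
    assert any("donor" in v for m in flagged for v in m.violations)


def test_map_single_exon_transcript():
    rng = np.random.default_rng(5)
    exon = "ATG" + "".join(rng.choice(list("ACGT"), size=300)) + "TAATAA"
    locus = "".join(rng.choice(list("ACGT"), size=400)) + exon + \
        "".join(rng.choice(list("ACGT"), size=400))
    t = make_transcript_model_safe(exon)
    maps = map_exons(t, locus)
    assert len(maps) == 1
    assert maps[0].donor_dinucleotide is None
    assert maps[0].acceptor_dinucleotide is None
    assert maps[0].genomic_interval == (401, 400 + len(exon))


def test_map_exons_unmappable_error(model):
    rng = np.random.default_rng(7)
    noise = "".join(rng.choice(list("ACGT"), size=5000))
    with pytest.raises(ValueError, match="unmappable"):
        map_exons(model.transcript, noise)


def test_clone_variants_planted_mixture(model):
    """24 reference + 3 exon-skip + 3 coding-SNV clones give exactly one
    splice variant (support 3) and one SNV (alt count 3)."""
    variants = [
        synthetic.PlannedVariant("skip7", 0.1, deletions=((674, 745),)),
        synthetic.PlannedVariant("H205Y", 0.1, snvs=((713, "T"),)),
    ]
    rs = synthetic.simulate_reads(model.transcript.seq, variants, n_clones=30, seed=4)
    sv, snv = call_clone_variants(rs.clones, model.transcript)
    assert len(sv) == 1
    assert sv[0].missing_transcript_interval == (674, 745)
    assert sv[0].protein_change == "Gly192_Gln215del"
    assert sv[0].exon_skip is True
    assert len(sv[0].supporting_clones) == 3
    assert len(snv) == 1
    assert snv[0].transcript_pos == 713
    assert snv[0].protein_change == "H205Y"
    assert snv[0].coding is True
    assert snv[0].clone_counts == (24, 3)


def test_clone_variants_full_planted_set(model):
    """All three published-style deletions and both coding SNVs are
    recovered with exact clone support at zero error."""
    rs = synthetic.simulate_reads(
        model.transcript.seq, model.splice_variants + model.snvs, seed=3
    )
    sv, snv = call_clone_variants(rs.clones, model.transcript)
    by_change = {v.protein_change: v for v in sv}
    assert set(by_change) == {
        "Gly192_Gln215del", "Asp131_Gln215del", "Ala45_Ser130del"
    }
    assert len(by_change["Gly192_Gln215del"].supporting_clones) == 5  # .1 + .3
    assert len(by_change["Asp131_Gln215del"].supporting_clones) == 2
    assert len(by_change["Ala45_Ser130del"].supporting_clones) == 2
    assert all(v.exon_skip for v in sv)
    got_snvs = {s.protein_change: s for s in snv}
    assert got_snvs["A11S"].clone_counts == (27, 3)
    assert got_snvs["H205Y"].clone_counts == (21, 2)


def test_clone_variants_no_false_positives(model):
    rs = synthetic.simulate_reads(model.transcript.seq, n_clones=10, seed=6)
    assert call_clone_variants(rs.clones, model.transcript) == ([], [])


def test_clone_deletion_off_exon_boundary_unclassified(model):
    """A deletion not aligned to exon boundaries is reported but not
    classified as an exon skip."""
    ref = model.transcript.seq
    clone = CloneRead("odd", ref[:520] + ref[550:])
    sv, _ = call_clone_variants([clone, CloneRead("ref", ref)], model.transcript)
    assert len(sv) == 1
    assert sv[0].exon_skip is False


def test_low_identity_clone_excluded(model):
    rng = np.random.default_rng(9)
    junk = CloneRead("junk", "".join(rng.choice(list("ACGT"), size=900)))
    ref = CloneRead("ref", model.transcript.seq)
    sv, snv = call_clone_variants([junk, ref], model.transcript)
    assert (sv, snv) == ([], [])
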