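"""Receptor precursor annotation: ORF, domains, motifs, variant names.

Derives the 274-aa precursor from the bundled transcript, transfers the
signal-peptide cleavage site from an annotated FcgRIIb-like homolog,
segments the precursor (signal / Ig1 / Ig2 / stalk / TM / cytoplasmic),
scans the immunoreceptor motifs, and names the published-style variants.
"""

from fcgrkit import annotation, synthetic

model = synthetic.fcgr2a_like()
family = synthetic.simulate_receptor_family(seed=0)

orf = annotation.find_orf(model.transcript.seq)
print(f"ORF: {orf.nt_length} nt -> {len(orf.protein)} aa precursor")

signal = annotation.transfer_signal_peptide(orf.protein, family.pig_iib, 45)
seg = annotation.segment_domains(orf.protein, signal,
                                 tm_ref=(family.pig_iib, (225, 247)))
print(f"signal {seg.signal}, ECD {seg.ecd} (Ig1 {seg.ig1}, Ig2 {seg.ig2}), "
      f"stalk {seg.unassigned}, TM {seg.tm}, cytoplasmic {seg.cytoplasmic}")

nglyc = annotation.scan_motifs(orf.protein, seg.ecd, "NGLYC")
print(f"N-glycosylation sequons in the ECD: "
      f"{[h.aa_position for h in nglyc]}")
itam = annotation.scan_motifs(orf.protein, seg.cytoplasmic, "ITAM")
itim = annotation.scan_motifs(orf.protein, seg.cytoplasmic, "ITIM")
print(f"cytoplasmic ITAM/ITIM hits: {len(itam)}/{len(itim)} "
      f"(signaling must go through an adaptor such as the FcR gamma-chain)")
charges = annotation.tm_charges(orf.protein, seg.tm)
print(f"charged TM residues: {charges.charged_positions} "
      f"(the TM aspartate enabling gamma-chain association)")

print(annotation.name_protein_deletion(orf.protein, 192, 215).hgvs,
      "- the 24-aa Ig2 deletion of isoform 1")
print(annotation.name_substitution(orf.protein, 205, "Y").compact,
      "- the Ig2 polymorphism")
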