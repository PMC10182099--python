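"""Build the default synthetic reference and validate its restriction geometry.

The recipient chromosome carries a cleavable HO site inside a MATa-like
locus; the donor chromosome carries a 1.3-kb homologous insert with 23
polymorphisms around an uncleavable HO-inc site.  An in-silico EcoRI digest
reproduces the Southern-blot band sizes the locus was engineered for.
"""

import dsbseq

genome = dsbseq.build_reference(seed=1)

print(f"chromosomes: { {c: len(s) for c, s in genome.chromosomes.items()} }")
print(f"HO cut at {genome.recipient_name}:{genome.ho_site}, "
      f"HO-inc at {genome.donor_name}:{genome.ho_inc_site}")
print(f"donor insert: {genome.donor_region[2] - genome.donor_region[1]} nt, "
      f"{len(genome.polymorphisms)} polymorphisms "
      f"({sum(p.creates_ecori for p in genome.polymorphisms)} EcoRI-creating)")

probe = (genome.recipient_name, genome.ho_site - 650, genome.ho_site + 650)
uncut = dsbseq.fragment_for_probe(dsbseq.in_silico_digest(genome, "EcoRI"), probe)
print(f"uncut EcoRI fragment over the MATa locus: {uncut.length / 1000:.1f} kb")

cut_frags = dsbseq.in_silico_digest(
    genome, "EcoRI", extra_cuts=[(genome.recipient_name, genome.ho_site)])
left = dsbseq.fragment_for_probe(
    cut_frags, (genome.recipient_name, genome.ho_site - 650, genome.ho_site))
print(f"left cut product after HO cleavage:        {left.length / 1000:.1f} kb")
print("(the uncut band disappearing into the cut product is how HO cutting")
print(" efficiency is read off a Southern blot)")
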