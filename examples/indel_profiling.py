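"""Amplicon indel profiling: rate, signed size spectrum, motif disruption.

Simulates amplicon reads carrying the 5-20 nt deletion spectrum
characteristic of Cas12i editing over a GATAA-style motif, then profiles
them.
"""

from cutscan.indels import AmpliconReference, profile_reads
from cutscan.simulate import gen_amplicon_reads, random_genome

seq = random_genome(250, seed=2)["chr1"]
seq = seq[:120] + "GATAA" + seq[125:]
ref = AmpliconReference("enhancer_amplicon", seq,
                        motif_interval=(120, 125), motif="GATAA")

spectrum = {-s: 1 / 16 for s in range(5, 21)}  # deletions of 5-20 nt
reads, truth = gen_amplicon_reads(ref, 5000, indel_rate=0.6,
                                  size_spectrum=spectrum,
                                  motif_disrupt_fraction=0.5, seed=2)

profile = profile_reads(reads, ref)
print(f"reads analyzed:      {profile.n_aligned}")
print(f"indel rate:          {profile.indel_rate:.3f} "
      f"(planted {truth.planted['indel_fraction']:.3f})")
print(f"motif disruption:    {profile.motif_disruption_fraction:.3f} "
      f"(planted {truth.planted['disrupt_fraction']:.3f})")
top = sorted(profile.size_bins.items(), key=lambda kv: -kv[1])[:5]
print("top signed-size bins (negative = deletion):")
for size, frac in top:
    print(f"  {size:+4d} nt  {frac:.3f} of indel reads")
# the indel rate counts each read once; the size spectrum fractions sum
# to 1 over indel reads; motif disruption counts reads whose alignment
# deletes into (or inserts inside) the motif interval.
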