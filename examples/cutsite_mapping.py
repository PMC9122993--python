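"""Cut-site mapping from in vitro cleavage products.

Simulates fragment reads from a staggered double-strand break — a tight
template-strand (TS) nick and a dispersed non-template-strand (NTS)
pattern, as seen for Cas12 nucleases cutting PAM-distal — and rebuilds
the per-strand cut distribution from the four (treated x end-type)
sequencing arms.
"""

import numpy as np

from cutscan.cutsites import (FragmentRead, SubstrateAnnotation,
                              build_distribution, from_protospacer_coord)

sub = SubstrateAnnotation(length=300, proto_start=100, proto_end=124)
rng = np.random.default_rng(5)

reads = []
for _ in range(500):
    # untreated 3' products report the TS nick at position 22
    reads.append(FragmentRead("3prime_product", False,
                              from_protospacer_coord(22, sub)))
    # untreated 5' products report NTS nicks spread over 24-35
    nts = int(rng.integers(24, 36))
    reads.append(FragmentRead("5prime_product", False,
                              from_protospacer_coord(nts, sub),
                              count=3 if nts == 27 else 1))
    # mung-bean-treated 5' products expose the additional TS nicks
    reads.append(FragmentRead("5prime_product", True,
                              from_protospacer_coord(22, sub)))

dist = build_distribution(reads, sub)
print("positions are protospacer-relative: 1 = PAM-proximal base")
print(f"TS  mode: {dist.mode('TS')}   (planted 22)")
print(f"NTS mode: {dist.mode('NTS')}  (planted 27)")
print("NTS distribution:",
      {p: round(f, 3) for p, f in sorted(dist.nts.items())})
# both strands cut PAM-distal (positions > protospacer length indicate
# cuts beyond the R-loop); the NTS spread reflects its wider nicking
# window.
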