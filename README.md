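# cutscan

A Python toolkit for the computational side of CRISPR nuclease
engineering campaigns, built around the Cas12i2 workflow: design and
score a cell-free scanning-mutagenesis screen, profile amplicon indels,
discover off-target cleavage sites from tag-integration sequencing
(TTISS), predict off-targets in silico with maximum-likelihood
background correction, and map double-strand cut positions per strand
from in vitro cleavage products. A synthetic-data module generates every
input with known ground truth, so each stage can be validated end to end
without sequencing data.

## Who this is for

Groups engineering compact type V nucleases (Cas12i and relatives) who
need a reproducible analysis path from raw screen plates and FASTQ files
to hit lists and specificity reports — and who want the statistics they
rely on (plate normalization, edit-distance matching, background
correction) to be testable against independent oracles.

## The statistics at the core

**Screen Z-scores.** For variant *v* with replicate depletion ratios
*r*<sub>*v,t,p*</sub> on plate *p* (ratio of RFP-normalized GFP signal,
non-targeting over targeting guide), the wild-type controls *W*<sub>*p*</sub>
over replicates *T*<sub>*p*</sub> define

μ<sub>p</sub> = Σ<sub>w,t</sub> r<sub>w,t,p</sub> / (|W<sub>p</sub>||T<sub>p</sub>|),  σ<sub>p</sub> = √( Σ<sub>w,t</sub> (r<sub>w,t,p</sub> − μ<sub>p</sub>)² / (|W<sub>p</sub>||T<sub>p</sub>|) )

and each variant is scored with standard-error scaling,

Z<sub>v</sub> = ( mean<sub>t</sub> r<sub>v,t,p</sub> − μ<sub>p</sub> ) / ( σ<sub>p</sub> / √|T<sub>p</sub>| ).

QC keeps variants with replicate CV < 20% and all fluorescence endpoints
≥ 60 rfu; a variant is a hit when Z > 2 for at least one GFP target.

**Indel profiling.** Reads (sampled up to 50,000) are aligned to the
amplicon by k-mer anchoring plus unit-cost dynamic programming; the
indel rate is the fraction of aligned reads with ≥ 1 insertion or
deletion, and the size spectrum bins indel reads by net signed size
(negative = deletion).

**TTISS.** Pairs whose read1 begins with the dsODN primer are trimmed to
25/15 bp of genomic sequence, aligned (fragment ≤ 1000 bp), deduplicated,
and clustered into 100 bp windows with ≥ 2 unique reads. Each window's
predicted cut (modal junction) is matched against the guide within
Levenshtein distance 6; sites survive only with a cut offset ≤ 8 bp, an
NTTN PAM 5′ of the protospacer, and no negative-control overlap.

**Off-target prediction.** Every PAM occurrence on both strands is
scored by PAM-anchored Levenshtein distance to the spacer and ranked
ascending. Targeted-sequencing counts (k/n treated, k0/n0 control) are
corrected under a binomial background mixture, p̂ = max(0, (k/n − b̂) /
(1 − b̂)) with b̂ = k0/n0, and called detected above the 0.2% limit of
detection.

**Cut-site mapping.** Untreated 5′/3′ cleavage products report the
non-template/template strand nick respectively; mung-bean-treated
products report the complementary assignments. The four arms merge into
per-strand cut distributions in protospacer-relative coordinates.

## Worked example

```bash
python examples/ttiss_offtargets.py
```

```
windows considered:  8
sites retained:      6 (5 off-target)
on-target fraction:  0.500 (planted 0.500)
  ON  chr1:12700 ed=0 pam=ATTC reads=40
  off chr1:79156 ed=1 pam=ATTC reads=8
  ...
```

The generator planted one on-target locus (40 unique read pairs) and
five off-targets (8 each) on a 100 kb genome, plus 200 noise singletons
and two negative-control artifacts. The pipeline retains exactly the six
planted sites — singletons never reach the 2-read window threshold and
the artifacts are removed by control overlap — and the on-target read
fraction (unique reads at the on-target site over unique reads at all
retained sites) reproduces the planted 0.5 share. The other examples
(`screen_statistics.py`, `indel_profiling.py`, `offtarget_prediction.py`,
`cutsite_mapping.py`) walk the remaining capabilities the same way.

A `cutscan` command wraps the same functions for shell use
(`cutscan --help`; subcommands `screen`, `indel`, `ttiss`, `predict`,
`cutsites`, `simulate`).

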