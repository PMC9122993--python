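# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic generators do and do not emulate, and the
known limitations.

## Screen statistics (`cutscan.screen`)

The cell-free screen couples in vitro protein synthesis of a nuclease
variant with a GFP reporter template (cleavable by the targeting guide)
and an RFP control template. The depletion ratio
r = (GFP_nt/RFP_nt)/(GFP_t/RFP_t) is RFP-normalized in both arms before
ratioing; it is scale-invariant (multiplying all four endpoints by c > 0
leaves r unchanged), so plate-wide intensity drift cancels.

Normalization stratum. The plate statistics are formally indexed by
plate only, but hit calling compares Z per GFP target, so statistics are
computed per (plate, target) stratum: each target's ratios are
standardized against the same-plate, same-target wild-type controls.
This is the only reading under which "Z > 2 for at least one GFP target"
is well defined when the two targets are assayed side by side.

Conventions, with defaults:

- σ_p is the population standard deviation (divide by |W_p||T_p|).
- Z uses standard-error scaling: σ_p/√|T_p| in the denominator, with
  |T_p| = 3 replicates by default.
- CV = 100 × population SD / mean of a variant's replicate ratios; QC
  passes strictly below 20%. The population convention matches σ_p; the
  strict inequality implements "variants with CV less than 20% were
  used".
- Any fluorescence endpoint below 60 rfu discards the variant entirely
  for that stratum (no averaging over surviving replicates), as does any
  replicate whose ratio cannot be formed (non-positive fluorescence).
- Hit rule: Z > 2 on ≥ 1 target, among QC-passing results. Averaging Z
  across targets before calling was considered and rejected: the
  any-target rule is the stated screening criterion, applied literally.

Under the null (a variant behaving like a control), Z is approximately
standard normal, so the per-stratum false-positive rate at Z > 2 is
≈ 2.3%; the acceptance suite verifies ≤ 5% empirically and full recall
of planted 3-fold depleters at 5% replicate CV.

## Indel profiling (`cutscan.indels`, `cutscan.align`)

Edit operations are called by exact k-mer anchoring (k = 10, k-mers
unique in both read and reference) chained to the longest mutually
consistent set, with the unanchored interior and flanks resolved by
full Needleman–Wunsch-style DP at unit mismatch and unit per-base indel
cost. When no anchors exist the whole read falls back to full DP and is
declared unaligned if its edit distance exceeds 30% of the read length.
The k-mer length and the fallback threshold are heuristics; correctness
is defined not by the internals but by agreement of per-read indel
totals with an independent full-DP Levenshtein oracle, which the
acceptance suite requires on ≥ 99% of noisy simulated reads. Ties in the
DP traceback prefer diagonal moves, then deletions, then insertions,
which left-aligns gaps in homopolymers; a final left-shift pass
normalizes indels crossing anchor boundaries. Coordinates are 0-based;
an insertion's position is the reference base before which it occurs.

Aggregation: a read counts once toward the indel rate regardless of how
many indels it carries; reads with both insertions and deletions are
binned by net signed size (inserted − deleted bases), so one read lands
in exactly one bin and bin fractions sum to 1 over indel reads. Net size
equals the read-minus-reference length difference for any minimal-cost
alignment, which is why spectrum recovery is exact up to generator
sampling noise. Up to 50,000 reads are sampled (uniform, without
replacement, order-preserving, seed-reproducible) before calling.

Motif disruption counts reads whose alignment carries a deletion
overlapping the motif interval or an insertion strictly inside it;
mismatch counting is opt-in and off by default, so disruption ≤ indel
rate. The denominator is all analyzed reads (not indel reads); the
choice is recorded in the profile metadata because the alternative
reading is defensible.

## TTISS (`cutscan.ttiss`)

Filtering requires read1 to begin with the dsODN primer exactly;
"low sequencing quality" is implemented as mean Phred < 20 over the
genomic portion (configurable; no standard definition exists). Genomic
sequence is truncated to 25 bp (forward) and 15 bp (reverse).

The built-in aligner (exact 15-mer seed, exact extension, unique
placement required) is sufficient for the synthetic genomes used in
validation; real-genome work ingests externally produced SAM, converted
from 1-based to the internal 0-based half-open convention. Alignment is
a pluggable contract, not a reimplementation claim. Proper pairs are
capped at 1000 bp fragments; duplicates are pairs with identical outer
coordinates and strand, and "unique reads" means non-duplicate fragments
(recorded in report metadata; unique junction coordinates would be the
alternative reading).

Window calling clusters unique-read junctions separated by more than the
window width, then greedily emits the maximum-support 100 bp window
within each cluster, so overlapping candidates merge to the
best-supported one. Cut-site prediction takes the modal junction; ties
prefer a coordinate supported by both strands, then the leftmost. Guide
matching pads the window by spacer length + max edit distance + PAM
length and takes the best Levenshtein match (edlib, infix mode) on
either strand; ties break by distance, then proximity of the implied cut
to the predicted cut, then leftmost coordinate.

Site filters: |matched cut − predicted cut| ≤ 8 bp; IUPAC- and
strand-aware PAM check 5′ of the protospacer on the protospacer strand
(configurable to 3′ for Cas9-style nucleases); negative-control
subtraction by ≥ 1 bp window overlap rather than exact identity. The
filters are independent predicates, so their order cannot change the
retained set. The matched protospacer's implied cut uses a per-guide
`cut_offset` (default 24 nt from the PAM-proximal protospacer end,
consistent with PAM-distal cleavage by Cas12i); the offset is a modeling
convention, not a measured quantity, and is configurable.

The on-target read fraction divides unique reads at the on-target site
by unique reads over retained sites only; reads in dropped windows are
excluded from the denominator (noted in metadata).

## Off-target prediction and MLE (`cutscan.offtarget`)

Genome scanning enumerates every PAM occurrence on both strands and
aligns the spacer anchored at the PAM-proximal protospacer end with up
to `max_ed` extra PAM-distal bases of slack (edlib prefix mode), so
insertions, mismatches and deletions all count. Candidates within
distance 6 are ranked ascending, ties broken by genomic coordinate for
determinism. Minus-strand candidates report the reverse-complemented
protospacer with a strand flag. The top 10 are the default assay set.

The background correction model: treated reads carry an indel with
probability q = b + p(1 − b), where b is background error and p the true
editing rate. With b estimated from the control (b̂ = k0/n0), the MLE is
p̂ = clip((k/n − b̂)/(1 − b̂), 0, 1). Maximum-likelihood background
correction admits many models; this two-sample binomial mixture with
plug-in background is an interpretation, adopted because it is the simplest
model whose MLE exists in closed form, and its correctness is defined by
a grid-search maximizer of the stated likelihood (1e-4 grid) in the test
suite. Per-position error profiles are not modeled. p̂ is monotone
non-decreasing in k and bounded by the raw rate k/n. Detection calls use
a 0.2% limit of detection on the corrected rate.

## Cut-site mapping (`cutscan.cutsites`)

The treated × end-type mapping is a fixed bijection: untreated 5′/3′
products report NTS/TS nicks; treated products the complements. Reported
positions are protospacer-relative (1 = PAM-proximal protospacer base,
increasing PAM-distal), with an exact round-trip to substrate
coordinates on both protospacer strands. When merging arms, each arm
(treated/untreated) is first normalized to its own read total so
unequal sequencing depth does not reweight the pattern — no arm
weighting is canonical, and this equal-arm choice is recorded in the distribution metadata. An empty arm yields a
distribution flagged `partial`. Junction calling from raw fragment reads
is out of this module's scope; it consumes junction coordinates (the
anchor machinery in `cutscan.align` can produce them), keeping
library-prep-specific trimming out of the core.

## Synthetic data (`cutscan.simulate`)

One global seed fans out to per-generator streams via `SeedSequence`, so
datasets regenerate independently and byte-identically; every generator
returns a `TruthRecord` of what was planted, and validation always
compares pipeline output to that truth.

Study-condition defaults: plates carry 3 replicates, 20 wild-type
controls, 5% replicate CV, 3-fold planted depletion effects, and
endpoints back-computed around 1000 rfu (well above the 60 rfu floor);
amplicon reads are 250 nt with 5–20 nt deletion spectra at the cut
region, 0.2% substitution noise, and 30% indel reads unless stated;
TTISS runs on a 100 kb uniform-composition genome with planted sites at
edit distances ≤ 6 behind concrete NTTN PAMs, ≥ 3 unique read pairs per
site with distinct fragment lengths on alternating strands, 200 noise
singletons, and negative-control artifacts generated like real sites;
off-target genomes realize requested distances exactly, verified in
genomic context by anchored alignment before the genome is returned
(the NTTN realization `ATTC` is used because no shifted overlap of it
recreates the PAM pattern, which would plant spurious near-distance
candidates).

What the generators do not emulate — and hence what passing tests do
not show about real data: sequencing quality-score structure and PCR
chimeras; GC bias and repetitive genome content (uniform base
composition means the seed-and-extend aligner never faces ambiguity a
real genome would pose); translocations, large rearrangements and HDR;
correlated replicate noise and plate-position effects; mixed
insertion+deletion reads beyond what the net-size convention captures.
Noise singletons are deliberately spaced farther apart than the window
width, so the no-singleton-window property is by construction, not a
statistical claim.

## Numerical choices and problem sizes

- Unit-cost Levenshtein throughout; edlib carries the distance
  computations in matchers, the in-package DP carries op-level calls.
- Chain agreement is asserted at 1e-9 relative tolerance; size-bin
  fractions sum to 1 within 1e-12; MLE agreement with the grid oracle
  within the 1e-4 grid spacing.
- Degenerate inputs raise typed errors: zero-SD plates, missing
  controls, non-positive fluorescence, background rate of 1, empty
  reads, junctions outside the substrate.
- Validation problem sizes — 1000 plates for the chain check, 200
  plates for recall/false-positive rates, 1000 reads for caller-oracle
  agreement, 20,000 reads for rate and spectrum recovery, 100 kb TTISS
  genomes, 50 kb brute-force scan genomes, 500 tuples and 200 replicates
  for the MLE checks — are the package's validation defaults, chosen so
  the whole suite runs in a few minutes on a laptop while keeping every
  statistical bound well-powered.

## Known limitations

- The internal TTISS aligner requires exact seeds and unique placement;
  divergent or repetitive loci need an external aligner via SAM.
- The indel caller assumes reads span the amplicon (as in targeted
  amplicon sequencing); partial coverage and soft-clipping are not
  modeled.
- The MLE model treats reads as exchangeable Bernoulli trials; UMI
  structure, strand bias and position-dependent error are out of scope.
- Whole-genome (GRCh38-scale) scanning works through the same API but is
  not an optimized or tested artifact path; validation uses toy genomes.
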