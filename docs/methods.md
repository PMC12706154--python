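# Methods

## Forward copy model

A star allele is represented by its REF/VAR status at each of seven
interrogated core variants (g.100C>T, g.1022C>T, g.1847G>A, g.2851C>T,
g.2989G>A, g.3184G>A, g.4181G>C; coordinates 1-based on NG_008376.4 with
ATG = +1) plus an origin map over ordered gene regions (5′UTR, exon 1 …
exon 9, with intervening introns). Hybrid alleles mark regions as
*CYP2D7*-derived: \*68 converts after intron 1, \*36 carries a
*CYP2D7*-derived exon 9. Two silencing rules apply before status lookup —
a deleted haplotype (\*5) contributes nothing anywhere, and a gene copy
contributes nothing at a target whose region is *CYP2D7*-derived, because
the assays are *CYP2D6*-specific. Breakpoints are region-granular, not
base-granular: all reasoning about hybrids happens in terms of which gene
region a target falls in (g.100 → exon 1, g.1022 → exon 2, g.1847 → the
intron-3/exon-4 boundary region, g.2851 → exon 6, g.2989 → intron 6,
g.3184 → exon 7, g.4181 → exon 9).

The allele matrix ships only what validated genotyping data force. \*1,
\*2, \*4, \*10, \*17, \*29, \*41, \*36, \*68 have full rows; \*45, \*154
and \*158 are resolved only at the targets their reference samples were
assayed with, and any query of an unresolved combination raises
`MatrixIncompleteError` naming the allele and target rather than guessing.
Two encodings deserve note:

* g.1022T is carried by \*154 rather than \*29. This is forced jointly by
  the \*29/\*154 reference sample producing 1/1 at both CN_1022 and
  CN_3184 and by the panel's allele-definition diagram; the assignment is
  flagged as figure-derived in the matrix file.
* For \*2x2/\*68+\*4 the model predicts a 3-copy total at g.1847 and
  g.2851 (the \*68 copy is silent there) but a 4-copy total at g.100
  (2 × g.100C from \*2x2, one g.100T each from \*68 and \*4), since g.100
  lies in exon 1, upstream of the \*68 conversion breakpoint.

Hatched (suballele-variable) variants of \*4 are carried by the default
definition, with a `suballeles` override mechanism for definitions that
lack them. Non-targeted core SNVs (\*45 g.1717G>A, \*29 V136I, \*154
g.4046G>A, \*158 g.3187A>C) are stored as annotations only.

## Quantification

Per channel, partition amplitudes are gated into negatives and positives;
occupancy is `λ̂ = −ln(n_neg / n_total)` and concentration is
`λ̂ / v_partition × dilution` in copies per µL of undiluted reaction
(adopted convention: concentrations refer to reaction volume, not
partitioned volume).

**Gating.** 1-D two-means, computed exactly: the two-means optimum in one
dimension is a contiguous split of the sorted sample, found by a
prefix-sum scan — deterministic, no initialization. The threshold is the
midpoint of the two cluster means; a tie at the threshold counts positive.
A secondary positive cluster at intermediate amplitude (the double-positive
reference artifact) stays above the midpoint and is counted positive, so
CN calls are unaffected. When the two cluster means are closer than
`min_separation` (default 1,000 RFU) the channel is dominated by a single
cluster; the gate then falls back to a fixed `single_cluster_boundary`
threshold (default 2,000 RFU, between the nominal 500/6,000 RFU cluster
means). This fallback matters at near-saturation: once fewer than roughly
twenty negative partitions remain, the two-means split moves inside the
large positive cluster (splitting it costs less variance than isolating
the tiny negative one), and classifying the well as all-positive there
would censor the reference channel hundreds of ng of DNA input too early.
The boundary fallback still counts those stray negatives, so a 1- or
2-copy sample keeps copy-number integrity across the whole dilution range.
A lone cluster sitting near the boundary itself is genuinely ungateable
and raises `NoSeparationError`. Joint 2-D (channel-pair) gating and
optical crosstalk are out of scope.

**Uncertainty and censoring.** The 95% interval on λ is a Wilson binomial
interval on the negative fraction propagated through −ln; Wilson was
chosen for its behavior at extreme fractions. With zero negative
partitions λ̂ is censored at `−ln(0.5 / n_total)`; fewer than 3 negatives
sets `saturated_flag` (the estimator's variance explodes below that
floor), and zero positives sets `empty_flag`. Flags propagate into CN
results rather than raising.

## CN calling

`CN = ref_copies × C_target / C_ref` with `ref_copies = 2`. A call is the
nearest integer `n ≤ max_cn` (default 8) with `|CN − n| ≤ 0.25`; the
window boundaries are inclusive (the rule is stated as "between 1.75 and
2.25" without open/closed qualification; closed was chosen and is asserted
in tests). Outside every window the result is NO_CALL, a first-class
value carrying the raw calculated CN — never silently rounded. A zero
reference concentration raises `ReferenceFailureError`.

## Inverse resolution

Given per-channel integer calls and the two haplotype units of a prior
unphased consensus genotype (e.g. `("*1", "*2")` or `("*2", "*68+*4")`),
the resolver enumerates every per-gene-copy multiplicity from 1 to
`max_multiplicity` (default 5 — covers \*41x3 with headroom; the space is
tiny, so enumeration is exhaustive, not heuristic), keeps configurations
whose forward copy vector matches every valid call exactly, and orders
them lexicographically by rendered label. NO_CALL channels contribute no
constraint but are reported. Hybrid configurations are only generated when
the candidate units name a hybrid: the engine does not invent hybrids from
calls alone, mirroring a workflow in which a consensus genotype exists
before SV resolution. Phase-equivalent configurations with identical copy
vectors (e.g. \*10x2/\*36+\*10 vs \*10/\*36+\*10x2) are all returned with
`unique = False`; the method cannot phase gene copies and the ambiguity is
reported, not hidden. If nothing matches, `InconsistentCallsError` carries
the closest configuration's per-target residual — the signature of
interference, wrong candidates, or a novel SV.

The g.4181C channel doubles as an internal copy-control: the check passes
iff the observed count equals the forward expectation of at least one
consistent configuration, with hybrid exon-9 dropouts excluded by the
forward model itself.

Interference diagnostics operate on gated cluster statistics:
`amplitude-suppression` when a positive cluster mean falls below 0.5× its
nominal 6,000 RFU with dispersion above 2× the nominal 200 RFU sd, and
`reference-multimodal` when the reference channel's positives split into
two modes (recommendation: confirm with an alternative reference gene
assay). Activity-score annotation sums user-supplied per-allele values
across all gene copies; only the values forced by the worked phenotype
examples (\*1 = 1.0, \*2 = 1.0, \*4 = 0.0) ship as defaults, and any
unlisted allele raises.

## Simulator

The generator emulates the physical chain of one well: restriction-digested
genomic DNA at `dna_input_ng`, with `genomes_per_ng = 250` haploid
genome-equivalents per ng, loaded into `n_partitions = 20,480` chambers of
`v_partition = 0.5 nL` from a 10 µL reaction. For a channel carried by
*c* copies per diploid genome, λ per partition is
`c/2 × dna × genomes_per_ng / reaction_volume × v_partition`; counts are
Poisson per partition. Defaults place a 2-copy target at 10 ng near the
100–500 copies/µL operating band (λ ≈ 0.125), and `genomes_per_ng` sits
deliberately below the theoretical ≈303/ng for 3.3 pg haploid genomes to
represent sub-unity amplifiable fraction; both are overridable.

Amplitudes are Gaussian around 500 (negative) and 6,000 RFU (positive),
sd 200, clipped at zero. Interference is modelled at amplitude level so
that *gating*, not molecule deletion, produces the downstream effect:

* **amplitude-suppression** scales the positive mean by 0.25, widens its
  sd 3×, and drops a fraction (`suppression_dropout = 0.4`) of occupied
  partitions to negative-like amplitude. Suppression and scatter alone do
  not push a 1-copy channel out of the valid window under midpoint gating;
  the partial drop-out term represents occupied partitions whose probe
  binding fails outright, and with the defaults a 1-copy carrier's
  calculated CN lands near 0.5 — out of window, NO_CALL.
* **double-positive** moves 30% of occupied partitions to an intermediate
  3,500 RFU cluster; under default gating both positive clusters stay above
  threshold and all CN calls remain valid.

Incomplete digestion enters as a linkage parameter: a tandem of *k*
same-haplotype copies of a target yields on average `1 + (k−1)·d`
independent fragments, `d` = probability each junction is cut (default 1).
`d < 1` strictly lowers the duplicated allele's calculated CN (fully
linked, a \*2x3 haplotype quantifies as 1 copy). The reference gene sits
on two independent chromosomes and is never linked. This expected-fragment
approximation ignores the size distribution of partially digested
fragments; only the count of separable molecules matters for a binary
partition readout.

All randomness flows from a single seed; simulated wells are bitwise
reproducible. `cni_sweep` chains simulate → quantify → call across a DNA
input series and emits a tidy table (input, replicate, target, calculated
CN, call, target and reference copies/µL).

### What the simulator does and does not emulate

It reproduces Poisson loading, 4-dye cluster structure, the 2-copy
reference, input scaling with saturation-driven CNI decay, both
interference artifacts, and digestion linkage. It does not model thermal
cycling kinetics, probe chemistry, optical crosstalk, partition-volume
variation, or the absolute copies/µL thresholds at which a real
instrument's CNI degrades — those depend on unpublished platform
constants, so only the qualitative structure (decay onset ordering in true
CN, compression toward 2, integrity for 1–2 copies) is asserted. With the
default constants the simulated decay onsets are ≈300 ng for a 6-copy,
≈450 ng for a 4-copy and ≈600 ng for a 3-copy genome, preserving the
ordering and rough scale of the behavior the assay exhibits. Passing
tests therefore validate the pipeline's logic and calibration under the
stated generative assumptions, not instrument-specific absolute limits.

## Problem sizes and tolerances in the test suite

Forward-model, call-rule and resolver checks are exact and instantaneous.
Stochastic checks use 20,480-partition wells: recovery of the
homozygous-reference sample runs 200 seeded replicates (≥95% correct
calls required); estimator calibration checks the mean of 60 replicate λ̂
against 3 SE and Wilson coverage across 500 replicates at λ ∈ {0.1, 0.5,
2} (coverage required in [90%, 99%]); the CNI study sweeps 12–13 input
levels at 6 replicates per level and asserts medians. The whole suite
completes in well under a minute on one CPU.

## Known limitations

* No phase information within or between haplotypes beyond what the
  candidate units assert; \*10x2/\*36+\*10 vs \*10x3/\*36 is reported as
  ambiguous by design.
* Star alleles outside the shipped matrix require a user-supplied
  registry; unresolved allele/target combinations raise rather than
  default.
* Triallelic targets (e.g. a third allele at an interrogated position) and
  rare SNVs under primers/probes can silence or suppress signal; the
  engine surfaces these as inconsistent-call residuals or interference
  flags but cannot identify the causal variant.
* Variant-only multiplexing (three SNV targets plus reference in one well)
  amplifies the ambiguity between "variant absent" and "region
  *CYP2D7*-derived"; the shipped panel model keeps the GT ref/var pairing.
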