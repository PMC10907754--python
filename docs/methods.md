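# Methods

## The generative model

`digiseq.simulate` emulates a two-PCR UMI-barcoding protocol as a branching
process with explicit strand bookkeeping.

**Templates.** Each assay receives `n_molecules` template molecules,
single-stranded (cDNA) or double-stranded (gDNA). Spike-in variants are
substitutions at known amplicon offsets; the number of mutant molecules per
variant is a binomial draw `Binomial(n, fraction)`, and variants at the same
position occupy disjoint molecules (fractions at one position must sum to
≤ 1). Molecules are stored as sparse substitution deltas against the assay
reference; the model is substitution-only at the template level, with an
optional per-read single-base indel rate (`read_indel_rate`, default 0) to
exercise deletion/insertion accounting downstream.

**Reverse transcription** (single-stranded input only). Each molecule is
retained with probability `rt_efficiency`; each retained base substitutes
with probability `rt_error_rate` to a uniformly chosen other base. RT errors
precede UMI tagging, are recorded in the truth as UMI-uncorrectable, and set
the error floor of the whole method.

**Barcoding PCR.** For `barcode_cycles` cycles (default 3) every strand is
copied with probability `barcode_efficiency` (default 1.0). A copy primed on
a template that does not yet carry a UMI receives a fresh UMI drawn
uniformly over `4^umi_length`; copies of UMI-carrying strands inherit their
lineage. This reproduces the protocol identities exactly at efficiency 1.0:
a single-stranded molecule yields 3 UMI lineages over 3 cycles, a
double-stranded molecule 6 (the second strand's unbarcoded copies are
tagged in later cycles: 3 + 2 + 1). Polymerase substitutions are injected
per synthesized base at `pol_error_rate`; UMI collisions between origins
are allowed and logged.

**Dilution.** Each UMI lineage survives independently with
`dilution_fraction` (default 1/3), giving on average 1 (ss) / 2 (ds)
sequenced lineages per input molecule.

**Adapter PCR and sequencing.** The first `jackpot_cycles` (default 3) of
the `adapter_cycles` (default 30) are simulated as an explicit doubling
tree, so an early polymerase error is shared by the corresponding subtree
of reads and can survive consensus ("jackpot" errors). The remaining cycles
contribute independent per-read substitutions at
`1 − (1 − pol_error_rate)^(remaining cycles)` per base; the sequencer adds
substitutions at `seq_error_rate` per base over the whole read (UMI and
anchor included, so UMI sequencing errors and anchor rejections are
exercised realistically). Reads per lineage are Poisson
(`mean_reads_per_family`, default 6). Each read is
`UMI + anchor + insert` at a constant Phred quality (the pipeline's
consensus is count-based and never conditions on quality).

A full doubling tree over all 30 adapter cycles would be exponential; the
jackpot-tree-plus-independent-residuals approximation keeps the
consensus-breaking shared errors (early cycles) while treating late-cycle
errors, which are effectively private to single reads, independently.

### Default rates

| parameter | default | basis |
| --- | --- | --- |
| `rt_error_rate` | 1e-4 | reported reverse-transcriptase fidelity range 9e-5–1e-4 |
| `pol_error_rate` | 3e-7 /base/synthesis | a high-fidelity polymerase >300× more accurate than Taq (Taq ≈ 1e-4–5e-5) |
| `seq_error_rate` | 2e-3 /base | free instrument parameter, typical short-read substitution rate; not a protocol constant |
| `barcode_cycles` / `adapter_cycles` | 3 / 30 | the emulated protocol's thermal programs |
| `dilution_fraction` | 1/3 | volume carried between the two PCRs |
| `mean_reads_per_family` | 6 | depth at which the ≥3-read family cutoff keeps ~94% of lineages |
| `umi_length` | 12 nt | mid-range of the 6–16 nt UMIs used in practice |

The anchor sequence between UMI and insert is a synthetic stand-in
(`ACGCAGTCGT`); real primer/linker structures are assay-specific and are a
config parameter, not a model output.

## The correction pipeline

1. **UMI extraction**: first `umi_length` bases; the fixed anchor is
   verified with ≤1 mismatch; failures are counted by reason.
2. **Assay assignment**: exact amplicon match, else edlib semiglobal edit
   distance against every amplicon; assigned when identity ≥ 0.8 over the
   insert, ties to panel order.
3. **Alignment**: equal-length inserts with ≤ max(2, 10% of length)
   mismatches are treated as substitution overlays (the normal case for
   fixed-length amplicon reads); everything else goes through affine-gap
   semiglobal DP (match 2, mismatch −4, gap open −6, extend −1, free end
   gaps on the insert) via Bio.Align. Insertions are anchored to the
   left-flanking reference offset. The substitution fast path can in
   principle differ from the DP optimum when ≥4 mismatches cluster into a
   shiftable block; with isolated sequencing errors this does not occur,
   and the DP path is always available (`force_dp=True`).
4. **UMI families**: exact grouping per assay, then directional merging —
   family B is absorbed by A when their UMIs differ by one substitution and
   `count_A ≥ 2·count_B − 1`, processed in descending count order,
   transitively. For fixed-length extracted UMIs, edit distance 1 is
   exactly Hamming distance 1. `cluster_distance=0` disables merging.
5. **Consensus**: families below `min_reads_per_umi` (default 3) are
   dropped. Per reference position the plurality symbol (base or deletion)
   among covering members is called when its support is ≥ 0.6 of the
   covering members; otherwise the position is *ambiguous* and excluded
   from that read's pileup contribution (the read itself is kept, which
   preserves per-position coverage semantics). Insertions need the same
   0.6 support. Ties break to the lexicographically smaller symbol; all
   orderings are deterministic, so a rerun is bit-identical.
6. **Pileups**: raw counts accumulate over *all* assigned reads (not only
   reads in surviving families); consensus counts over consensus reads.
   Coverage is defined as A+C+G+T+N+del per row, so conservation holds by
   construction and consensus coverage ≤ raw coverage everywhere.

## Statistics

* `e_p = (coverage − reference + insertions) / coverage` per included
  position; insertions count as non-reference events at their left anchor
  so the denominator stays equal to coverage. Excluded (known SNP /
  pseudogene / RNA-editing) and zero-coverage positions are omitted and
  flagged; an all-excluded assay has an undefined (NaN) mean.
* Assay and panel means are unweighted over included positions (the panel
  mean is *not* coverage-weighted).
* Correction factor `F = raw mean / consensus mean`, undefined when the
  consensus mean is zero — "no errors detected" is reported as such, never
  as infinity.
* Molecule counting: `M = C` (single-stranded), `M = C/2` (double-stranded);
  yields normalize by `reference_ng / loaded_ng`; replicate CV is
  `100 · sd / mean` (sample SD).
* MAF at a position is alt consensus count / consensus coverage.
  Significance: unpaired Student's t-test between replicate arms, and a
  two-way (position × condition) ANOVA whose per-position contrasts use the
  pooled residual MSE with Šidák adjustment `1 − (1 − p)^m` across the m
  positions screened. A one-sided binomial test against the panel
  background consensus error rate is provided as a clearly-labelled
  single-sample extension for designs without replicates.
* Error typing bins every non-reference event into transition (A↔G, C↔T),
  transversion, deletion, insertion, plus an N-call bin, each as events /
  total coverage, so the bins partition the overall rate exactly.
* Detectability is bounded by the background: a variant whose MAF is below
  the mean error rate of its read level cannot be called. This — not a
  t-test on deep counts, which can separate arbitrarily small consistent
  shifts — is the criterion under which a 0.078% spike-in is detectable
  only after consensus correction when raw error rates are ~1%.

## Randomness and reproducibility

One master seed drives a `numpy` `SeedSequence` tree with fixed per-stage,
per-assay substreams: changing one assay's molecule count never perturbs
another assay's draws, and a fixed seed gives byte-identical FASTQ and
truth output (gzip written with zeroed mtime). Per-origin substreams were
considered and rejected: one generator per molecule defeats the vectorized
sampling that keeps 10^5-molecule runs in seconds, and the per-(assay,
stage) granularity preserves the isolation that matters in practice.

## What the simulation does and does not show

The generator reproduces the *mechanics* that make digital sequencing work
— UMI lineage multiplicities, dilution thinning, family-size statistics,
jackpot error sharing, and the separation of correctable (post-tagging)
from uncorrectable (RT) errors — under uniform random amplicons and
position-independent error rates. It does not model sequence-context error
hotspots, GC/length amplification bias, chimeras, polymerase slippage,
quality-score structure or paired-end reads. Passing tests therefore
demonstrate the correctness of the pipeline's combinatorics and statistics
under the stated stochastic model, not the error spectrum of any particular
enzyme or instrument.

Two desk-scale artifacts are worth knowing about. With 12 nt UMIs and 10^5
molecules per assay, ~3% of true lineage pairs sit within Hamming distance
1 and can be merged by directional clustering (plus ~0.3% exact
collisions); the loss hits variant and wild-type families proportionally,
so MAF estimates stay unbiased while absolute molecule counts are slightly
conservative. And recovered MAFs fluctuate around the realized spike-in
fraction with a variance somewhat above the plain binomial band, because
each molecule contributes a Binomial(3, 1/3) number of consensus reads
rather than exactly one.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the spike-in recovery at
10^5 molecules × 3 replicates per arm (0.078%) and 10^4 × 3 (25%), the
error-suppression run at 5 assays × 2×10^4 molecules, and the Monte Carlo
dilution checks at 10^5 (ss) / 5×10^4 (ds) origins — sizes chosen so the
whole suite completes in a few minutes on a single CPU while leaving the
stochastic bands narrow enough to be meaningful.
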