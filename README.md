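# digiseq

Digital UMI-based amplicon sequencing, end to end and in silico: a generative
simulator of a two-PCR molecular-barcoding library protocol, the matching
UMI-consensus error-correction pipeline, and the quantification statistics
needed to evaluate ultrasensitive RNA/DNA mutation analysis.

## The problem

Detecting mutant allele frequencies (MAF) below 0.1% by amplicon deep
sequencing is impossible on raw reads: polymerase and sequencer substitution
errors accumulate to ~0.1–1% per position. Unique molecular identifiers
(UMIs) fix this. During a short *barcoding PCR* every template molecule is
tagged with a random `N`-mer; after dilution and a long *adapter PCR*, reads
sharing a UMI are collapsed to a single **consensus read** per tagged strand
lineage, cancelling all errors introduced after tagging. For RNA the
template is single-stranded cDNA, so the reverse-transcription (RT) step
happens *before* tagging and its errors are the floor the method cannot
correct.

Two identities drive quantification in this design (3 barcoding cycles,
one-third dilution between the PCRs):

* a single-stranded cDNA molecule acquires exactly **3** UMIs, a
  double-stranded gDNA molecule exactly **6** (both strands are tagged);
* after the 1/3 dilution, on average **1** (ss) or **2** (ds) tagged
  lineages per input molecule are sequenced — so one consensus read ≈ one
  cDNA molecule, and two consensus reads ≈ one gDNA molecule
  (`M = C / 2` for double-stranded input).

Per nucleotide position the error rate is
`e_p = (non-reference reads) / (total reads)`; assay and panel means are
unweighted averages of `e_p` over analyzed positions, and the
**error-correction factor** is `F = mean raw error / mean consensus error`.
Consensus reads require at least 3 raw reads per UMI family.

## What is in the package

| module | contents |
| --- | --- |
| `digiseq.panel` | `Assay`/`Panel` definitions, panel config files, BED exclusion lists |
| `digiseq.seqio` | streaming FASTQ reader/writer (gzip-aware) |
| `digiseq.pileup` | per-position `CountMatrix` (A/C/G/T/N/del + insertions), TSV IO |
| `digiseq.simulate` | the generative simulator: templates → RT → barcoding PCR → dilution → adapter PCR + sequencing, with full ground truth (`SimTruth`) |
| `digiseq.correct` | UMI extraction, assay assignment, semiglobal alignment, directional UMI clustering, ≥3-read plurality consensus, raw/consensus pileups |
| `digiseq.quantstats` | error rates, correction factors, molecule counting, CV, MAF estimation, t-test / two-way ANOVA with Šidák correction, error typing, Spearman error profiles, dilution linearity, per-mL plasma normalization |
| `digiseq.cli` | `digiseq simulate \| correct \| stats \| full-run` |

## Worked example

Simulate 10,000 cDNA molecules per assay for a five-assay panel with a 0.5%
spike-in variant, run the consensus pipeline, and score recovery against the
simulation truth:

```bash
digiseq full-run --config examples/simulation.yaml \
                 --panel examples/panel.tsv \
                 --out-dir out --seed 7
```

`out/summary.json` from this exact command contains (abridged):

```
raw mean error        0.208512 %
consensus mean error  0.006668 %
correction factor     31.3
TP53_A: UMIs/origin 3.0, surviving lineages/origin 0.994,
        9286 consensus reads -> 9286 molecules of 10000 loaded
variant @50 A>T: realized fraction 0.00580, estimated MAF 0.00485 (45/9286)
```

Reading this: every cDNA molecule received exactly 3 UMIs and about one
tagged lineage per molecule survived the 1/3 dilution, so consensus reads
count molecules (93% recovered; the missing fraction is mostly UMI families
with fewer than 3 reads). UMI correction pushed the mean error rate from
0.21% down to 0.0067% — a 31-fold correction factor — and the spiked-in
variant is recovered at its (binomially thinned) true fraction.

The same stages are available as a library:

```python
import digiseq as dq

panel = dq.synthetic_panel(n_assays=5)
cfg = dq.SimConfig(seed=7, n_molecules=10_000, rt_error_rate=5e-5)
records, truth = dq.simulate_reads(cfg, panel)
result = dq.run_pipeline(records, panel)
report = dq.error_report({n: p.consensus for n, p in result.pileups.items()})
print(report.panel_mean)
```

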