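# One simulated library: 10,000 cDNA molecules per assay with a 0.5% spike-in
# variant in assay TP53_A at amplicon offset 50 (reference A -> T).
seed: 7
n_molecules: 10000
strandedness: single
rt_error_rate: 5.0e-5
pol_error_rate: 3.0e-7
seq_error_rate: 2.0e-3
mean_reads_per_family: 6.0
variants:
  - {assay: TP53_A, position: 50, alt: T, fraction: 0.005}
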