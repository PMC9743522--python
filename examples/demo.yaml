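# Demo: simulated 6-sample cohort with one planted canonical-type fusion
# (tandem duplication joining PARTNER's 5' end to GENE's retained
# C-terminal), on a two-chromosome toy genome.
seed: 7
outdir: demo_run

resolutions:
  fine: 10000
  coarse: 50000
  report: 500000

thresholds:
  tolerance: 1000
  min_size: 10000
  min_callers: 2
  z_threshold: 4.0
  exclusion_flank: 1000000

anchors:
  gene: GENE
  c_terminal: {chrom: chr7, start: 3900000, end: 3980000}
  n_terminal: {chrom: chr7, start: 3980000, end: 4120000}
  background: {chrom: chr7, start: 3900000, end: 4120000}

genes: demo_genes.bed

simulate:
  reference: [[chr7, 6000000], [chr3, 4000000]]
  depth: 1000000
  decay_exponent: 1.0
  trans_rate: 0.01
  compartments: {block: 10, boost: 1.5}
  n_samples: 6
  fusion:
    sample_index: 0
    event:
      type: tandem_duplication
      chrom: chr7
      start: 2000000
      end: 3980000
      name: PARTNER-GENE_dup
  callers: {n: 4, jitter_sd: 300, dropout: 0.1, fp_per_caller: 3}

fusions:
  priority_genes: [GENE]
  callsets:
    rna_caller1: demo_fusions_caller1.tsv
    rna_caller2: demo_fusions_caller2.tsv
    rna_caller3: demo_fusions_caller3.tsv
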