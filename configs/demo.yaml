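# Demo end-to-end run: small synthetic cohort, completes in well under a
# minute on one CPU and yields a non-empty recurrence catalog.
#   edscape run --config configs/demo.yaml --outdir demo_run
outdir: demo_run
seed: 31
min_fraction: 0.10
fdr: 0.05
max_gap: 50
classifier_threshold: 0.9
sim:
  n_tumor: 3
  n_control: 2
  n_chroms: 1
  chrom_length: 50000
  n_genes: 16
  n_edit_sites: 200
  coverage: 30.0
  n_germline_snv: 80
  n_somatic_snv: 8
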