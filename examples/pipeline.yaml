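# Demo configuration for `fertqtl run --config examples/pipeline.yaml`.
# All thresholds default to the study values (GWAS MAF 0.01, eQTL MAF 0.05,
# accuracy 0.4, cis window 2 Mb, trans 5 Mb, stepwise P 5e-6 / r2 0.1,
# eGene alpha 0.01, SMR 5e-8 / 5e-3, CPM 3 at 25%, 4 expression PCs);
# only the cohort size and output directory are set here.
outdir: scratch/pipeline_demo
seed: 2024
sim:
  n_samples: 500
  n_chromosomes: 5
  variants_per_chrom: 2000
  n_genes: 300
  n_expr_samples: 350
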