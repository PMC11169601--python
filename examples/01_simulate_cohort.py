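"""Simulate a small cattle-style cohort and inspect its structure.

Generates Markov-haplotype genotypes over 3 chromosomes, four correlated
fertility traits (one binarised, emulating pregnancy status) with three
pleiotropic causal variants, and RNA-seq-like expression counts with planted
cis effects.
"""

import numpy as np

from fertqtl.simulate import SimConfig, simulate_expression, simulate_genotypes, \
    simulate_traits

cfg = SimConfig(n_samples=500, n_chromosomes=3, variants_per_chrom=1000,
                n_genes=100, n_expr_samples=300, seed=1)
geno = simulate_genotypes(cfg)
traits, truth = simulate_traits(geno, cfg)
counts, annot, covars, etruth = simulate_expression(geno, cfg)

d = geno.dosage.astype(float)
adj_r2 = np.mean([np.corrcoef(d[:, i], d[:, i + 1])[0, 1] ** 2
                  for i in range(500)])
print(f"genotypes: {geno.n_samples} samples x {geno.n_variants} variants")
print(f"mean adjacent-variant r^2: {adj_r2:.3f} (ld_rho={cfg.ld_rho} -> "
      f"expectation ~{cfg.ld_rho**2:.2f})")
print(f"traits: {traits.traits}; preg_st success rate "
      f"{traits.data['preg_st'].mean():.2f}")
print(f"planted causal variants: {truth.causal_variants['variant_id'].nunique()} "
      f"({truth.causal_variants.query('shared')['variant_id'].nunique()} pleiotropic)")
print(f"expression: {counts.shape[0]} genes x {counts.shape[1]} samples; "
      f"{(etruth.egene_truth['kind'] == 'cis').sum()} planted cis eGenes")
# The r^2 line shows the block-LD structure the clumping stage relies on;
# the truth tables are what the recovery analyses below are scored against.
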