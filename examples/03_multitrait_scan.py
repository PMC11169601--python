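"""Conditional multi-trait GWAS: the pleiotropy chi-squared statistic and
LD-aware stepwise selection of putative causal variants.

Effects are planted so each pleiotropic QTL is marginally sub-significant in
every single trait, yet clearly significant in the 4-df multi-trait
statistic — the power gain the conditional multi-trait design is built for.
"""

from fertqtl import cmt, lmm
from fertqtl.simulate import SimConfig, simulate_genotypes, simulate_traits

cfg = SimConfig(n_samples=1000, n_chromosomes=3, variants_per_chrom=1200,
                n_causal_shared=3, n_causal_private=0, causal_h2_frac=0.15,
                spread_shared_across_chromosomes=True, seed=23)
geno = simulate_genotypes(cfg)
traits, truth = simulate_traits(geno, cfg)
grm = lmm.compute_grm(geno, maf_min=0.01)

causal, sumstats, mgwas = cmt.stepwise_conditional_selection(
    geno, traits.data[traits.traits], traits.design_matrix(), grm,
    p_threshold=5e-6, r2_max=0.1)

v = cmt.compute_v_matrix(sumstats)
print("signed-t correlation matrix V:")
print(v.round(2).to_string())
print(f"\nselected causal set ({len(causal.records)} variants):")
print(causal.records[["ID", "CHR", "POS", "cycle", "P"]].to_string(index=False))

marginal = {t: lmm.assoc_scan(geno, traits.data[t].to_numpy(float),
                              traits.design_matrix(), grm, trait=t)
            for t in traits.traits}
shared = truth.causal_variants.query("shared")["variant_idx"].unique()
for s in shared:
    best = max(cmt.ld_r2(geno, int(s), c) for c in causal.variant_indices)
    marg = min(ss["P"].iloc[int(s)] for ss in marginal.values())
    print(f"planted QTL {geno.variants['id'].iloc[s]}: best r^2 with a "
          f"selection {best:.2f}; best marginal single-trait P={marg:.1e}")
# every selected pair on a chromosome satisfies r^2 <= 0.1 (asserted inside
# the selection routine), so each entry tags an independent QTL.
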