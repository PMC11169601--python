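# Methods

This note documents the models, numerical choices and limitations of the
`fertqtl` package: what each stage computes, what the synthetic cohorts do
and do not emulate, and where genuinely open design decisions were resolved.

## Mixed-model association

The association model per variant is `y = 1μ + Xβ + W_i α_i + g + e` with
`g ~ N(0, G σ_g²)` and `e ~ N(0, σ_e² I)`.  `G` is the allele-frequency-
standardised GRM computed from sample allele frequencies; variants below the
MAF floor or monomorphic in the sample are excluded.  Because the GRM's
information content saturates well below the full variant panel, pipelines
may build it from a random sub-panel (`grm_max_variants`, default 10,000) —
the analogue of building a GRM from an HD-array subset rather than the whole
sequence panel.

REML maximises the restricted likelihood through a single eigendecomposition
`G = U D Uᵀ`: with `h² = σ_g²/(σ_g²+σ_e²)` the rotated covariance is
diagonal, the total scale is profiled out analytically, and the remaining
one-dimensional problem in `h²` is solved by bounded scalar minimisation
(`xatol` 1e-8) with endpoint checks.  The returned restricted log-likelihood
follows the standard Patterson–Thompson definition
`ℓ_R = −½[log|V| + log|XᵀV⁻¹X| + yᵀPy + (n−p)log 2π]`, verified in the test
suite against a dense-matrix evaluation at a grid of variance components.

For the scan, the variance **ratio** is estimated once per trait under the
null and held fixed (the fit-once design of fast mixed-model GWAS tools);
the residual **scale** is re-estimated per variant from the whitened
residuals.  This choice makes the `σ_g² = 0` limit coincide exactly with the
OLS t-test, keeps the scan calibrated, and costs one vector operation per
variant.  p-values use the standard-normal reference; at very small n they
differ from the t reference in the obvious way (the tests compare the
statistic exactly and the p-value to the documented tolerance).  Binary
traits (pregnancy status) are analysed on the observed 0/1 scale with the
same linear model.  Missing phenotypes are handled by per-trait
complete-case subsetting of y, X and the GRM.  Monomorphic or
conditioned-away variants are reported with β = 0, p = 1 and a flag.

## Conditional multi-trait scan

`X² = tᵀV⁻¹t` with `V` the Pearson correlation of signed t-values across all
variants between trait pairs, evaluated with a linear solve (never an
explicit inverse), upper-tail χ²(k) p-values.  Under the complete null `V`
absorbs both residual trait correlation and sample overlap, so `X² ~ χ²(k)`;
this calibration is asserted at 50,000 variants in the acceptance suite.

Design points the source procedure leaves open, resolved as follows:

* `V` is computed once from the unconditional scans and held fixed across
  conditional cycles — recomputing it per cycle would shift the statistic's
  null reference mid-run.
* Variance components are likewise fitted once per trait, not per cycle.
* Ties in significance break by (smaller p, lower chromosome, lower
  position) for reproducibility.
* Cross-chromosome LD is not checked; the r² ≤ 0.1 rule applies within a
  chromosome only.  The pairwise-r² invariant of the selected set is
  asserted on every run.
* `max_cycles` defaults to 10 with a convergence log; selection stops when a
  cycle adds nothing.

## Closed-form FDR

`FDR = P(1−A/T)/((A/T)(1−P))`, capped at 1; `A = 0` is defined as FDR 1 and
logged.  Reports truncate (not round) — 0.5190 prints as 0.51, 3.89% as
3.8% — matching the truncation convention of the published worked examples
the acceptance script recomputes.

## eQTL mapping

Genes are filtered by CPM: a gene is excluded iff the fraction of samples
with CPM < 3 is ≥ 0.25 (the boundary is inclusive).  Expression is analysed
as log2(CPM + 1).  The first four expression PCs (genes centred; sign fixed
by the largest-magnitude loading) are computed **after** the CPM filter and
before any genotype is touched, so no genotype information leaks into the
covariates.  Fixed covariates: contemporary group (class), lactation status,
weeks pregnant, plus the PCs; random animal effect with GRM covariance.

"Gene start site" is read as the annotated, strand-aware TSS; the cis window
(±2 Mb) is symmetric, so strand affects only the sign of the reported TSS
distance, never membership.  Window boundaries are closed (≤ 2 Mb included);
the trans rule is strict (> 5 Mb) and restricted to same-chromosome pairs
(cross-chromosome testing is out of scope).  The trans test set is the
deduplicated union of lead cis-eQTLs, genome-wide-significant GWAS variants
(P ≤ 5×10⁻⁸, single- and multi-trait), and all panel variants within ±100 bp
of any of these.

The hierarchical correction is two-step Bonferroni: `p_local = min(1, p·m_g)`
and eGene ⇔ `min(p_local)·n_genes < α` — algebraically identical to applying
`α/n_genes` to `p_local`, which is how the two superficially different
phrasings of the procedure coincide.  Output labels follow the common
"global-FDR" usage although the control is family-wise.  Lead ties break by
|TSS distance|, then position.  The per-gene engine shares one GRM
eigendecomposition and one rotated genotype matrix across all genes, so a
489-sample, 10-thousand-variant cis scan over hundreds of genes takes
seconds.

Passing `grm=None` runs the same scan as a fixed-effects-only linear model
(the `σ_g² = 0` specialisation); it is the correctly specified model when
the response carries no polygenic component, and the test suite uses it for
the large null-replicate calibration of the hierarchical correction.

## SMR

Instrument: the per-gene lead cis-eQTL, admitted at P < 5×10⁻⁸ with the
variant's GWAS P < 5×10⁻³ per trait.  Alleles are harmonised by (chrom, pos)
with sign flips for swapped A1/A2; unalignable pairs are skipped.
`T_SMR = z_g²z_e²/(z_g²+z_e²)` is bounded by `min(z_g², z_e²)` and symmetric
in its arguments — both asserted as properties.  Bonferroni correction uses
the pooled (across-trait) test count by default, with per-trait counts also
reported.  The HEIDI heterogeneity test and multi-SNP SMR are out of scope.

## Enrichment and validation

Interval membership is a 1-based point-in-interval test after BED (0-based,
half-open) conversion, backed by interval trees and verified against a
brute-force scan.  Enrichment is upper-tail hypergeometric with fold
`(k/n_lead)/(K/n_background)`; the default background is all variants tested
in the corresponding scan.  Regulatory-category definitions come from
user-supplied BED files — no window sizes are hard-coded.  Gene-set overlap
is two-sided Fisher's exact (one-sided by flag) over an **explicit** gene
universe supplied by the caller; ortholog mapping is an input table, never
computed.  Variance explained by a variant subset is the REML `h²` under a
GRM built from the subset only, contrasted with the mean over (default) five
equally sized random subsets.  The validation re-test counts discovery hits
with validation P < 0.002 and reports the closed-form FDR at (P, A, T).

## Synthetic cohorts

The generator reproduces the statistical structure the stages assume, not
cattle demography:

* **Genotypes.**  Haplotypes follow a renewal-style first-order Markov chain:
  each allele copies its left neighbour with probability `ld_rho`, otherwise
  it is a fresh Bernoulli draw at the site's target frequency (uniform on
  `maf_range`).  Adjacent-site dosage correlation is ≈ `ld_rho` (exactly
  independent at 0), giving an analytically checkable r²-decay for clumping
  at negligible cost.  An exact per-site-correlation Markov
  parameterisation is infeasible when neighbouring target frequencies
  differ widely (Fréchet bounds), which is why the renewal form is used.
  Dosages are the sum of two haplotypes; MAF is recorded from realised
  frequencies; per-variant imputation accuracy is drawn uniform on
  (0.3, 1.0) so the accuracy filter has work to do.  `add_ld_proxy` plants a
  near-duplicate variant at a controlled r² for clumping tests.
* **Traits.**  Standardised scale: fixed covariates (year of birth,
  contemporary group with 7 levels, age at joining) + planted variant
  effects + a polygenic term built from the standardised genotypes (so its
  covariance is exactly `G σ_poly²`) + residuals correlated across traits
  (`residual_corr`, default 0.5 off-diagonal).  A fraction `causal_h2_frac`
  of each trait's `h²` (default 0.4) is split equally across its planted
  variants; the trait at `binary_trait_index` is binarised at the
  `liability_threshold` quantile, emulating pregnancy status.  Shared
  (pleiotropic) causal variants are common to all traits, optionally spread
  one-per-chromosome for selection experiments.
* **Expression.**  Negative-binomial counts (gamma–Poisson, gene-specific
  dispersion ~ lognormal around 0.1) whose log2 mean carries the baseline,
  batch factors (captured downstream by expression PCs), library-size
  offsets, and planted cis (±2 Mb of TSS) and trans (> 5 Mb, same
  chromosome) effects.  Effect sizes `cis_effect_sd` / `trans_effect_sd`
  are fixed magnitudes with random sign, expressed in units of the gene's
  NB-implied residual log2-expression SD, so "a 1.5-SD effect" is
  well-defined across genes.  Trans effects preferentially sit on variants
  that already carry a cis effect, so the two-stage trans design (test only
  cis leads and GWAS hits) can detect them, as in the real study design.

Default sizes mirror the discovery design where it is statistically
meaningful — 2,119 animals, four traits, residual correlation 0.5, 489
expression samples, ~40% of genes with a cis effect — while the genome is a
desk-scale stand-in (5 chromosomes × 2,000 variants over 100 Mb each).

**What passing tests do and do not show.**  The generator has no
recombination-map realism, no allele-frequency spectrum from demography, no
cryptic relatedness beyond what random mating of standardised genotypes
induces, no distance-dependent concentration of cis effects near the TSS
(planted variants are uniform in the window, so TSS-distance profiles are
flat by construction), and no read-level RNA-seq artefacts.  Recovery and
calibration results therefore validate the statistical machinery — not
robustness to real-data pathologies such as batch-genotype confounding or
expression outliers.

## Problem sizes used in the checks

Null calibration runs at n = 1000 samples × 50,000 independent variants with
four traits (residual correlation 0.5); the hierarchical-correction control
uses 200 null replicates of 500 genes × 200 cis variants at n = 200 with a
fixed genotype panel (the replicated noise is the expression); REML recovery
averages 50 replicates at n = 1000; the planted-subset variance contrast
uses 20 replicates at n = 800; the end-to-end demo is 500 samples,
5 × 2,000 variants, 300 genes.  All complete in minutes on one CPU.

## Known limitations

* Exact per-variant REML (rather than fit-once) is out of scope, as are
  sparse-GRM approximations and leave-one-chromosome-out GRMs.
* Binary traits use the linear model; no liability-scale transformation of
  the estimates is applied.
* Conditionally independent secondary cis signals per gene, interaction
  eQTLs and allele-specific expression are not modelled.
* Approximate conditional analysis from summary statistics alone
  (COJO-style) is not implemented — the stepwise procedure refits on
  individual-level data each cycle.
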