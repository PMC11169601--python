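"""Synthetic cohort generator: genotypes with block LD, four correlated
fertility traits with shared (pleiotropic) causal variants and a polygenic
background, and RNA-seq-like expression counts with planted cis and trans
effects.

The generator emulates the statistical structure the downstream stages
assume rather than any particular demography:

* haplotypes follow a renewal-style first-order Markov chain along each
  chromosome — each allele copies its left neighbour with probability
  ``ld_rho``, otherwise it is a fresh Bernoulli draw at the site's target
  frequency.  Adjacent-site dosage correlation is ~``ld_rho`` (exactly 0 at
  ``ld_rho = 0``), giving realistic r^2-decay for LD clumping at trivial cost;
* traits are standardised: fixed covariate effects + planted variant effects
  + a polygenic term with covariance GRM * sigma_g^2 + residuals correlated
  across traits; one trait is binarised at a liability threshold (pregnancy
  status);
* expression counts are negative binomial with gene-specific dispersion;
  planted cis effects sit within +-2 Mb of the TSS, trans effects > 5 Mb away
  on the same chromosome; batch factors and library-size variation provide
  the structure the expression PCs are meant to absorb.

Everything is deterministic given ``SimConfig.seed``; stage-level generators
derive independent sub-streams from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import VARIANT_COLUMNS, GenotypeMatrix, TraitTable

TRAIT_NAMES = ("DTC", "AFC", "preg_st", "wks_preg")


def _default_residual_corr():
    r = np.full((4, 4), 0.5)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the discovery design: 2,119 genotyped animals, four
    fertility traits with moderate residual correlation, 489 expression
    samples, ~40% of genes carrying a cis effect.  Genome size is a desk-scale
    stand-in (5 chromosomes x 2,000 variants over 100 Mb each).
    """

    n_samples: int = 2119
    n_chromosomes: int = 5
    variants_per_chrom: int = 2000
    chrom_length_bp: int = 100_000_000
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.6
    n_traits: int = 4
    n_causal_shared: int = 3
    n_causal_private: int = 2
    h2: tuple = (0.4, 0.4, 0.4, 0.4)
    residual_corr: np.ndarray = field(default_factory=_default_residual_corr)
    liability_threshold: float = 0.5
    n_genes: int = 300
    prop_egenes: float = 0.4
    n_trans_egenes: int = 10
    cis_effect_sd: float = 1.5
    trans_effect_sd: float = 1.5
    n_batch_factors: int = 2
    n_expr_samples: int = 489
    causal_h2_frac: float = 0.3
    spread_shared_across_chromosomes: bool = False
    missing_rate: float = 0.0
    binary_trait_index: int = 2
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.h2, (int, float)):
            self.h2 = tuple([float(self.h2)] * self.n_traits)
        self.residual_corr = np.asarray(self.residual_corr, dtype=float)
        for name in ("n_samples", "n_chromosomes", "variants_per_chrom",
                     "chrom_length_bp", "n_traits", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if any(not (0 <= h < 1) for h in self.h2):
            raise ValueError("per-trait h2 must be in [0, 1)")
        if not (0 <= self.prop_egenes <= 1):
            raise ValueError("prop_egenes must be in [0, 1]")
        R = self.residual_corr
        if R.shape != (self.n_traits, self.n_traits) or not np.allclose(R, R.T):
            raise ValueError("residual_corr must be a symmetric k x k matrix")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("residual_corr must be positive definite")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    causal_variants: pd.DataFrame  # variant_idx, variant_id, trait, effect
    egene_truth: pd.DataFrame      # gene_id, variant_idx, variant_id, kind, effect...
    varcomp_truth: pd.DataFrame    # trait, sigma_g2, sigma_e2


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Markov-haplotype genotypes; dosages in {0, 1, 2}, positions strictly
    increasing and 1-based, MAF recorded from realised frequencies."""
    rng = config.rng(1)
    n_hap = 2 * config.n_samples
    m = config.variants_per_chrom
    rho = config.ld_rho
    all_dosage = []
    rows = []
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        pos = np.sort(rng.integers(1, config.chrom_length_bp + 1, size=m))
        while len(np.unique(pos)) < m:  # resolve rare position collisions
            pos = np.unique(pos)
            pos = np.sort(np.concatenate(
                [pos, rng.integers(1, config.chrom_length_bp + 1,
                                   size=m - len(pos))]))
        freq = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        fresh = rng.random((n_hap, m)) < freq
        if rho == 0:
            H = fresh
        else:
            copy = rng.random((n_hap, m)) < rho
            H = np.empty((n_hap, m), dtype=bool)
            H[:, 0] = fresh[:, 0]
            for t in range(1, m):
                H[:, t] = np.where(copy[:, t], H[:, t - 1], fresh[:, t])
        dos = (H[0::2].astype(np.int8) + H[1::2].astype(np.int8))
        all_dosage.append(dos)
        af = dos.mean(axis=0) / 2.0
        acc = rng.uniform(0.3, 1.0, size=m)
        for j in range(m):
            rows.append((chrom, int(pos[j]), f"{chrom}:{pos[j]}", "A", "G",
                         float(min(af[j], 1 - af[j])), float(acc[j])))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.hstack(all_dosage)
    samples = [f"S{i:05d}" for i in range(config.n_samples)]
    return GenotypeMatrix(samples, variants, dosage)


def add_ld_proxy(geno: GenotypeMatrix, idx: int, refresh_frac: float,
                 rng: np.random.Generator, pos_offset: int = 1) -> GenotypeMatrix:
    """Insert a near-duplicate of variant ``idx`` next to it.

    A fraction ``refresh_frac`` of samples get a fresh draw at the variant's
    allele frequency, so the realised r^2 with the original is roughly
    (1 - refresh_frac)^2.  Useful for planting known-LD pairs.
    """
    col = geno.dosage[:, idx].astype(np.int8).copy()
    p = col.mean() / 2.0
    redraw = rng.random(len(col)) < refresh_frac
    col[redraw] = (rng.random(redraw.sum()) < p).astype(np.int8) + (
        rng.random(redraw.sum()) < p).astype(np.int8)
    src = geno.variants.iloc[idx]
    row = src.copy()
    row["pos"] = int(src["pos"]) + pos_offset
    row["id"] = f"{src['chrom']}:{row['pos']}"
    row["maf"] = float(min(col.mean() / 2.0, 1 - col.mean() / 2.0))
    variants = pd.concat(
        [geno.variants.iloc[: idx + 1], row.to_frame().T, geno.variants.iloc[idx + 1:]],
        ignore_index=True,
    )
    variants["pos"] = variants["pos"].astype(int)
    dosage = np.insert(geno.dosage, idx + 1, col, axis=1)
    return GenotypeMatrix(geno.samples, variants, dosage)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _eligible_variants(geno, maf_min=0.1, acc_min=0.4):
    maf = geno.variants["maf"].to_numpy()
    acc = geno.variants["accuracy"].to_numpy()
    return np.flatnonzero((maf >= maf_min) & (acc > acc_min))


def simulate_traits(geno: GenotypeMatrix, config: SimConfig):
    """Four correlated traits with planted pleiotropic and private effects.

    Returns (TraitTable, SimTruth).  Per trait, total genetic variance is
    ``h2`` on a unit-variance scale: a fraction ``causal_h2_frac`` comes from
    the planted variants (split equally), the rest from a polygenic term with
    covariance GRM * sigma_poly^2.  Residuals across traits follow
    ``residual_corr``.  The trait at ``binary_trait_index`` is binarised at
    the ``liability_threshold`` quantile of its liability.
    """
    k = config.n_traits
    n = geno.n_samples
    total_causal = config.n_causal_shared + k * config.n_causal_private
    if total_causal > geno.n_variants:
        raise ValueError("more causal variants requested than simulated variants")
    if n != config.n_samples:
        raise ValueError("genotype matrix does not match config.n_samples")
    rng = config.rng(2)

    # fixed covariates: year of birth and contemporary group (class, 7 levels
    # mirroring the year-season grouping), age at joining (continuous)
    yob = rng.integers(0, 5, size=n)
    cg = rng.integers(0, 7, size=n)
    age = rng.normal(0, 1, size=n)
    cov_effect = (0.3 * yob / 4.0) + (0.2 * cg / 6.0) + 0.1 * age

    eligible = _eligible_variants(geno)
    if len(eligible) < total_causal:
        eligible = np.arange(geno.n_variants)
    if config.spread_shared_across_chromosomes and config.n_causal_shared > 0:
        # one pleiotropic variant per chromosome (round-robin), the rest free
        chroms = geno.variants["chrom"].to_numpy()
        shared = []
        order = rng.permutation(sorted(set(chroms)))
        for i in range(config.n_causal_shared):
            pool = eligible[chroms[eligible] == order[i % len(order)]]
            pool = np.setdiff1d(pool, shared)
            shared.append(int(rng.choice(pool)))
        shared = np.asarray(shared, dtype=int)
        rest_pool = np.setdiff1d(eligible, shared)
        rest = rng.choice(rest_pool, size=k * config.n_causal_private,
                          replace=False)
        picked = np.concatenate([shared, rest]).astype(int)
    else:
        picked = rng.choice(eligible, size=total_causal, replace=False)
        shared = picked[: config.n_causal_shared]
    private = picked[config.n_causal_shared:].reshape(k, config.n_causal_private) \
        if config.n_causal_private > 0 else np.empty((k, 0), dtype=int)

    W = geno.dosage.astype(float)
    var_w = W.var(axis=0)

    Y = np.zeros((n, k))
    truth_rows = []
    varcomp_rows = []
    # polygenic background shared machinery: standardised genotypes
    p_all = W.mean(axis=0) / 2.0
    poly_ok = (p_all > 0) & (p_all < 1)
    Z = (W[:, poly_ok] - 2 * p_all[poly_ok]) / np.sqrt(
        2 * p_all[poly_ok] * (1 - p_all[poly_ok]))
    m_bg = Z.shape[1]

    chol = np.linalg.cholesky(config.residual_corr)
    E = rng.normal(size=(n, k)) @ chol.T

    for t in range(k):
        name = TRAIT_NAMES[t] if t < len(TRAIT_NAMES) else f"trait{t}"
        h2 = config.h2[t]
        causal_idx = np.concatenate([shared, private[t]]) if h2 > 0 else np.array([], int)
        causal_var = h2 * config.causal_h2_frac if len(causal_idx) else 0.0
        y = cov_effect.copy()
        if len(causal_idx):
            per_var = causal_var / len(causal_idx)
            betas = rng.choice([-1.0, 1.0], size=len(causal_idx)) * np.sqrt(
                per_var / np.maximum(var_w[causal_idx], 1e-12))
            y = y + W[:, causal_idx] @ betas
            for j, b in zip(causal_idx, betas):
                truth_rows.append((int(j), geno.variants["id"].iloc[j], name,
                                   float(b), bool(j in shared)))
        poly_var = max(h2 - causal_var, 0.0)
        if poly_var > 0:
            u = rng.normal(0, np.sqrt(poly_var / m_bg), size=m_bg)
            y = y + Z @ u
        y = y + np.sqrt(1 - h2) * E[:, t]
        Y[:, t] = y
        varcomp_rows.append((name, h2, 1 - h2))

    data = pd.DataFrame(Y, columns=[TRAIT_NAMES[t] if t < len(TRAIT_NAMES)
                                    else f"trait{t}" for t in range(k)],
                        index=pd.Index(geno.samples, name="sample_id"))
    bt = config.binary_trait_index
    if bt is not None and 0 <= bt < k:
        col = data.columns[bt]
        thresh = np.quantile(data[col], config.liability_threshold)
        data[col] = (data[col].to_numpy() > thresh).astype(float)
    if config.missing_rate > 0:
        for col in data.columns:
            drop = rng.random(n) < config.missing_rate
            data.loc[drop, col] = np.nan
    data["year_of_birth"] = yob
    data["contemp_group"] = cg
    data["age_at_joining"] = age
    tt = TraitTable(data, traits=list(data.columns[:k]),
                    class_covariates=["year_of_birth", "contemp_group"],
                    continuous_covariates=["age_at_joining"])
    truth = SimTruth(
        causal_variants=pd.DataFrame(
            truth_rows, columns=["variant_idx", "variant_id", "trait", "effect",
                                 "shared"]),
        egene_truth=pd.DataFrame(
            columns=["gene_id", "variant_idx", "variant_id", "kind",
                     "effect_sd_units", "effect_log2"]),
        varcomp_truth=pd.DataFrame(varcomp_rows,
                                   columns=["trait", "sigma_g2", "sigma_e2"]),
    )
    return tt, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(geno: GenotypeMatrix, config: SimConfig):
    """Negative-binomial expression counts with planted cis/trans effects.

    Returns (counts DataFrame genes x samples, gene annotation DataFrame,
    sample covariate DataFrame, SimTruth).  Effects are planted on the log2
    mean; their size is expressed in units of the gene's residual log2-
    expression SD implied by the NB noise at the gene's baseline mean, so a
    "1.5 SD" effect has a well-defined, gene-independent meaning.
    """
    if not (0 <= config.prop_egenes <= 1):
        raise ValueError("prop_egenes outside [0, 1]")
    rng = config.rng(3)
    n_expr = min(config.n_expr_samples, geno.n_samples)
    samples = geno.samples[:n_expr]
    W = geno.dosage[:n_expr].astype(float)
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    positions = geno.variants["pos"].to_numpy()
    vchrom = geno.variants["chrom"].to_numpy()

    # gene annotation
    g_chrom = rng.choice(chroms, size=config.n_genes)
    g_tss = rng.integers(1, config.chrom_length_bp, size=config.n_genes)
    g_strand = rng.choice(["+", "-"], size=config.n_genes)
    g_len = rng.integers(5_000, 200_000, size=config.n_genes)
    starts = np.where(g_strand == "+", g_tss, np.maximum(g_tss - g_len, 1))
    ends = starts + g_len
    annot = pd.DataFrame({
        "gene_id": [f"G{i:04d}" for i in range(config.n_genes)],
        "chrom": g_chrom, "tss": g_tss, "strand": g_strand,
        "start": starts, "end": ends,
    })

    base = rng.uniform(1.0, 8.0, size=config.n_genes)       # log2 CPM
    disp = np.exp(rng.normal(np.log(0.1), 0.5, size=config.n_genes))
    libsize = np.exp(rng.normal(np.log(15e6), 0.3, size=n_expr))
    batch = rng.normal(size=(n_expr, config.n_batch_factors))
    loadings = rng.normal(0, 0.5, size=(config.n_genes, config.n_batch_factors))

    eligible = set(_eligible_variants(geno, maf_min=0.1))
    n_eg = int(round(config.prop_egenes * config.n_genes))
    egene_rows = []
    log2mu = base[:, None] + loadings @ batch.T          # genes x samples
    mu0 = libsize.mean() / 1e6 * 2.0 ** base             # baseline counts
    resid_sd_log2 = np.sqrt(1.0 / mu0 + disp) / np.log(2)

    def _plant(gene_order, kind, window_fn, effect_sd, n_wanted):
        planted = 0
        for gi in gene_order:
            if planted >= n_wanted:
                break
            cand = window_fn(gi)
            cand = [j for j in cand if j in eligible]
            if not cand:
                continue
            j = int(rng.choice(cand))
            sign = float(rng.choice([-1.0, 1.0]))
            eff_log2 = sign * effect_sd * resid_sd_log2[gi]
            w = W[:, j]
            log2mu[gi] += eff_log2 * (w - w.mean())
            egene_rows.append((annot["gene_id"].iloc[gi], j,
                               geno.variants["id"].iloc[j], kind,
                               sign * effect_sd, eff_log2))
            planted += 1

    gene_order = rng.permutation(config.n_genes)

    # cis: variant within +-2 Mb of TSS on the gene's chromosome
    def cis_candidates(gi):
        m = (vchrom == g_chrom[gi]) & (np.abs(positions - g_tss[gi]) <= 2_000_000)
        return list(np.flatnonzero(m))

    _plant(gene_order, "cis", cis_candidates, config.cis_effect_sd, n_eg)

    # trans: > 5 Mb away on the same chromosome; variants already carrying a
    # cis effect are preferred so the trans test set (lead cis-eQTLs + GWAS
    # hits) can actually contain them, as in the two-stage study design
    cis_used = {r[1] for r in egene_rows}

    def trans_candidates(gi):
        m = (vchrom == g_chrom[gi]) & (np.abs(positions - g_tss[gi]) > 5_000_000)
        cand = np.flatnonzero(m)
        pref = [j for j in cand if j in cis_used]
        return pref if pref else list(cand)

    _plant(gene_order[::-1], "trans", trans_candidates, config.trans_effect_sd,
           config.n_trans_egenes)

    mu = 2.0 ** log2mu * (libsize[None, :] / 1e6)
    r = 1.0 / disp
    # NB via gamma-Poisson mixture for vectorised gene-specific dispersion
    lam = rng.gamma(shape=r[:, None], scale=mu / r[:, None])
    counts = rng.poisson(lam).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=annot["gene_id"], columns=samples)

    covars = pd.DataFrame({
        "contemp_group": rng.integers(0, 7, size=n_expr),
        "lactation": rng.integers(0, 2, size=n_expr),
        "weeks_pregnant": rng.integers(0, 40, size=n_expr).astype(float),
    }, index=pd.Index(samples, name="sample_id"))

    truth = SimTruth(
        causal_variants=pd.DataFrame(
            columns=["variant_idx", "variant_id", "trait", "effect", "shared"]),
        egene_truth=pd.DataFrame(
            egene_rows, columns=["gene_id", "variant_idx", "variant_id", "kind",
                                 "effect_sd_units", "effect_log2"]),
        varcomp_truth=pd.DataFrame(columns=["trait", "sigma_g2", "sigma_e2"]),
    )
    return counts_df, annot, covars, truth
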