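"""Enrichment and validation analyses: regulatory-interval overlap of lead
eQTLs with hypergeometric enrichment, Fisher's-exact gene-set overlap,
variance explained by a variant subset against a random-subset baseline, and
significance re-testing of discovery variants in a validation cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, IntervalSet
from .lmm import Grm, compute_grm, fdr_from_counts, fit_null_lmm

logger = logging.getLogger(__name__)


def annotate_variants(variants: pd.DataFrame, intervals: IntervalSet) -> pd.DataFrame:
    """Per-variant category membership (1-based point-in-interval tests); a
    variant may belong to several categories."""
    out = pd.DataFrame(index=variants.index)
    for cat in intervals.categories:
        out[cat] = [intervals.contains(cat, str(c), int(p))
                    for c, p in zip(variants["chrom"], variants["pos"])]
    return out


@dataclass
class EnrichmentRecord:
    category: str
    n_lead_in: int
    n_lead: int
    n_background_in: int
    n_background: int
    fold: float
    p_hyper: float


def hypergeometric_enrichment(lead_flags, background_flags,
                              category: str) -> EnrichmentRecord:
    """Upper-tail hypergeometric test of drawing >= n_lead_in category
    members in n_lead draws from the background composition.  The lead set
    must be a subset of the background."""
    lead = np.asarray(lead_flags[category], dtype=bool)
    bg = np.asarray(background_flags[category], dtype=bool)
    n_lead, n_bg = len(lead), len(bg)
    k, K = int(lead.sum()), int(bg.sum())
    if K == 0:
        logger.warning("category %s empty in background; fold undefined", category)
        return EnrichmentRecord(category, k, n_lead, K, n_bg, float("nan"), 1.0)
    fold = (k / n_lead) / (K / n_bg)
    p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_lead))
    return EnrichmentRecord(category, k, n_lead, K, n_bg, float(fold), p)


@dataclass
class OverlapResult:
    table: tuple          # (in both, A only, B only, neither)
    odds_ratio: float
    p_fisher: float
    haldane: bool = False


def fisher_gene_overlap(set_a, set_b, universe, alternative="two-sided"
                        ) -> OverlapResult:
    """Fisher's exact test on the 2x2 membership table over ``universe``.

    Odds ratio uses the Haldane 0.5 correction (flagged) when a cell is 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    _, p = stats.fisher_exact(table, alternative=alternative)
    haldane = bool((table == 0).any())
    t = table + 0.5 if haldane else table
    odds = float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    return OverlapResult((both, a_only, b_only, neither), odds, float(p), haldane)


@dataclass
class VarExpResult:
    h2_subset: float
    h2_random_mean: float
    h2_random_sd: float
    n_random_reps: int


def variance_explained_subset(geno: GenotypeMatrix, subset, y, X,
                              n_random_reps: int = 5, seed: int = 0,
                              maf_min: float = 0.0) -> VarExpResult:
    """Proportion of phenotypic variance captured by a GRM built from
    ``subset`` only, with a baseline from equally sized random subsets.

    Fits y = 1 mu + X beta + u + e with u ~ N(0, G_subset sigma_g2) by REML
    and returns sigma_g2 / (sigma_g2 + sigma_e2); the baseline repeats the
    fit ``n_random_reps`` times on random variant subsets and averages.
    """
    subset = np.asarray(subset, dtype=int)
    if len(subset) == 0:
        raise ValueError("empty variant subset")

    def h2_of(idx):
        g = compute_grm(geno.subset_variants(idx), maf_min=maf_min)
        vc = fit_null_lmm(y, X, g)
        return vc.h2

    h2_subset = h2_of(subset)
    rng = np.random.default_rng(seed)
    h2_rand = []
    for _ in range(n_random_reps):
        idx = rng.choice(geno.n_variants, size=len(subset), replace=False)
        try:
            h2_rand.append(h2_of(idx))
        except (ValueError, RuntimeError) as exc:
            logger.warning("random-subset replicate skipped: %s", exc)
    h2_rand = np.asarray(h2_rand)
    return VarExpResult(float(h2_subset), float(h2_rand.mean()),
                        float(h2_rand.std()), len(h2_rand))


def validation_retest(discovery_hits, validation_stats: pd.DataFrame,
                      p_threshold: float = 0.002):
    """Count discovery variants re-tested significant in the validation
    cohort; FDR from the closed-form estimator with (P, A, T).

    ``discovery_hits`` is an iterable of variant IDs; hits absent from the
    validation summary stats are excluded from T with a warning.
    """
    hits = list(discovery_hits)
    idx = validation_stats.set_index("ID")
    present = [h for h in hits if h in idx.index]
    if len(present) < len(hits):
        logger.warning("%d discovery hits absent from validation stats",
                       len(hits) - len(present))
    if not present:
        raise ValueError("no discovery hits found in validation stats")
    pvals = idx.loc[present, "P"].to_numpy(dtype=float)
    n_validated = int((pvals < p_threshold).sum())
    fdr = fdr_from_counts(p_threshold, n_validated, len(present))
    return n_validated, fdr
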