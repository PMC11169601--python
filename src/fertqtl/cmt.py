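"""Conditional multi-trait GWAS: the signed-t correlation matrix V, the
k-df chi-squared pleiotropy statistic, LD r^2, and the cyclic stepwise
conditional selection of independent putative causal variants.

The pleiotropy statistic for variant i is X^2 = t_i' V^{-1} t_i, where t_i
stacks the signed t-values across the k traits and V is the k x k Pearson
correlation matrix of signed t-values over all variants.  Under the complete
null X^2 ~ chi-squared(k) because V absorbs both residual trait correlation
and sample overlap.

V is computed once from the unconditional scans and held fixed across
conditional cycles; recomputing it mid-run would change the statistic's null
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix
from .lmm import Grm, NullModel, assoc_scan

logger = logging.getLogger(__name__)


def ld_r2(geno: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosage vectors over samples non-missing
    at both variants."""
    x = np.asarray(geno.dosage[:, i], dtype=float)
    y = np.asarray(geno.dosage[:, j], dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("monomorphic variant in ld_r2")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def compute_v_matrix(sumstats: dict) -> pd.DataFrame:
    """Pearson correlation of signed t-values across all variants, per trait
    pair; diagonal forced to 1.  Regularised toward the identity if not
    positive definite (logged)."""
    traits = list(sumstats)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits for V")
    T = np.column_stack([np.asarray(sumstats[t]["T"], dtype=float) for t in traits])
    if T.shape[0] < 100:
        raise ValueError("need at least 100 shared variants to estimate V")
    V = np.corrcoef(T, rowvar=False)
    np.fill_diagonal(V, 1.0)
    eps = 0.0
    while np.linalg.eigvalsh(V).min() <= 1e-10:
        eps = max(eps * 10, 1e-6)
        V = (1 - eps) * V + eps * np.eye(len(traits))
        np.fill_diagonal(V, 1.0)
        logger.warning("V matrix regularised toward identity (eps=%g)", eps)
        if eps > 0.5:
            raise ValueError("V matrix singular even after regularisation")
    return pd.DataFrame(V, index=traits, columns=traits)


def multi_trait_chi2(t_vec, v: pd.DataFrame) -> dict:
    """X^2 = t' V^{-1} t via a linear solve; p from chi-squared(k)."""
    t = np.asarray(t_vec, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite t-values")
    V = np.asarray(v, dtype=float)
    chi2 = float(t @ np.linalg.solve(V, t))
    k = len(t)
    return {"chi2": chi2, "df": k, "p": float(stats.chi2.sf(chi2, df=k))}


def multi_trait_scan(sumstats: dict, v: pd.DataFrame) -> pd.DataFrame:
    """Vectorised M-GWAS over all variants; one row per variant with the
    chi-squared statistic and its upper-tail p-value."""
    traits = list(v.index)
    T = np.column_stack([np.asarray(sumstats[t]["T"], dtype=float) for t in traits])
    sol = np.linalg.solve(np.asarray(v, dtype=float), T.T)
    chi2 = np.einsum("ij,ji->i", T, sol)
    first = sumstats[traits[0]]
    out = pd.DataFrame({
        "CHR": first["CHR"].to_numpy(),
        "POS": first["POS"].to_numpy(),
        "ID": first["ID"].to_numpy(),
        "CHI2": chi2,
        "DF": len(traits),
        "P": stats.chi2.sf(chi2, df=len(traits)),
    })
    return out


@dataclass
class CausalSet:
    """Ordered list of selected putative causal variants."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["variant_idx", "ID", "CHR", "POS", "cycle", "P"]))

    @property
    def variant_indices(self):
        return list(self.records["variant_idx"].astype(int))

    def assert_ld_invariant(self, geno, r2_max):
        """Within each chromosome, all pairwise r^2 among members <= r2_max."""
        for _, sub in self.records.groupby("CHR"):
            idx = list(sub["variant_idx"].astype(int))
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    r2 = ld_r2(geno, idx[a], idx[b])
                    if r2 > r2_max + 1e-9:
                        raise AssertionError(
                            f"causal set LD invariant violated: r2={r2:.3f}")


def _select_cycle(mgwas, geno, existing: CausalSet, p_threshold, r2_max, cycle):
    """Greedy per-chromosome selection among significant variants.

    Most significant first; every same-chromosome significant variant with
    r^2 > r2_max to a selected variant (this cycle or previously selected)
    drops out; ties broken by (P, CHR, POS).
    """
    sig = mgwas[mgwas["P"] < p_threshold].copy()
    taken = set(existing.variant_indices)
    sig = sig[~sig.index.isin(taken)]
    rows = []
    for chrom, sub in sig.groupby("CHR", sort=True):
        sub = sub.sort_values(["P", "CHR", "POS"])
        chosen = []
        prior = [i for i in existing.variant_indices
                 if str(geno.variants["chrom"].iloc[i]) == str(chrom)]
        for vidx, rec in sub.iterrows():
            ok = True
            for s in chosen + prior:
                if ld_r2(geno, int(vidx), int(s)) > r2_max:
                    ok = False
                    break
            if ok:
                chosen.append(int(vidx))
                rows.append((int(vidx), rec["ID"], rec["CHR"], rec["POS"],
                             cycle, rec["P"]))
    return pd.DataFrame(rows, columns=["variant_idx", "ID", "CHR", "POS",
                                       "cycle", "P"])


def stepwise_conditional_selection(
    geno: GenotypeMatrix,
    Y: pd.DataFrame,
    X,
    grm: Grm,
    p_threshold: float = 5e-6,
    r2_max: float = 0.1,
    max_cycles: int = 10,
):
    """Cycle between conditional single-trait scans and the M-GWAS statistic.

    ``Y`` is a samples x traits DataFrame (NaN = missing), ``X`` the shared
    fixed-covariate design.  Returns (CausalSet, final per-trait summary
    stats dict, final M-GWAS DataFrame).

    Algorithm: run unconditional scans and compute V once; then per cycle,
    re-run all single-trait scans conditioning on the current causal set,
    recompute X^2 for every variant, and greedily select significant
    (p < ``p_threshold``) variants per chromosome subject to the pairwise
    r^2 <= ``r2_max`` rule.  Stops when a cycle selects nothing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    traits = list(Y.columns)
    # the GRM is eigendecomposed once and shared across traits and cycles
    d, U = np.linalg.eigh(np.asarray(grm.values, dtype=float))
    eig = (np.clip(d, 0.0, None), U)
    null_models = {}
    varcomps = {}
    for t in traits:
        nm = NullModel(Y[t].to_numpy(dtype=float), X, grm.values, eig=eig)
        varcomps[t] = nm.fit()
        null_models[t] = nm

    def scans(cond):
        out = {}
        for t in traits:
            nm = null_models[t] if not cond else None
            out[t] = assoc_scan(geno, Y[t].to_numpy(dtype=float), X, grm,
                                varcomp=varcomps[t], conditioning_set=cond,
                                trait=t, null_model=nm, eig=eig)
        return out

    sumstats = scans([])
    v = compute_v_matrix(sumstats)
    causal = CausalSet()
    mgwas = multi_trait_scan(sumstats, v)
    log = []
    for cycle in range(1, max_cycles + 1):
        if cycle > 1:
            sumstats = scans(causal.variant_indices)
            mgwas = multi_trait_scan(sumstats, v)
        new = _select_cycle(mgwas, geno, causal, p_threshold, r2_max, cycle)
        log.append((cycle, len(new)))
        if new.empty:
            break
        causal.records = (new if causal.records.empty else
                          pd.concat([causal.records, new], ignore_index=True))
    else:
        logger.warning("stepwise selection hit max_cycles=%d", max_cycles)
    # final conditional scans reflecting the full causal set
    if not causal.records.empty:
        sumstats = scans(causal.variant_indices)
        mgwas = multi_trait_scan(sumstats, v)
    causal.assert_ld_invariant(geno, r2_max)
    logger.info("stepwise selection: %s", log)
    return causal, sumstats, mgwas
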