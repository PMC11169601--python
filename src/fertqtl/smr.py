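"""Summary-data-based Mendelian randomisation (SMR).

For each eGene the lead cis-eQTL serves as the (single) instrument.  With
z_g = b_gwas/se_gwas and z_e = b_eqtl/se_eqtl the statistic is

    T_SMR = z_g^2 z_e^2 / (z_g^2 + z_e^2),     p from chi-squared(1),

and the putative expression-to-trait effect is b_xy = b_gwas / b_eqtl.
T_SMR is symmetric in (z_g, z_e) and bounded by min(z_g^2, z_e^2), so a weak
instrument can never push the test past its own GWAS or eQTL evidence.

Alleles are harmonised before testing: when the GWAS effect allele (A1) is
the eQTL's other allele, the GWAS beta sign is flipped; unalignable allele
pairs are skipped with a warning.  The HEIDI heterogeneity test is out of
scope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def smr_test(b_gwas, se_gwas, b_eqtl, se_eqtl) -> dict:
    """One SMR test; returns b_xy, t_smr and the chi-squared(1) p-value."""
    if se_gwas <= 0 or se_eqtl <= 0:
        raise ValueError("standard errors must be positive")
    if b_eqtl == 0:
        raise ValueError("b_eqtl = 0: no instrument strength")
    z_g = b_gwas / se_gwas
    z_e = b_eqtl / se_eqtl
    denom = z_g**2 + z_e**2
    t_smr = 0.0 if denom == 0 else (z_g**2 * z_e**2) / denom
    return {
        "b_xy": float(b_gwas / b_eqtl),
        "t_smr": float(t_smr),
        "p_smr": float(stats.chi2.sf(t_smr, df=1)),
    }


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """alpha / n_tests at full precision (reports round to 2 sig figs)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def select_instruments(egenes: pd.DataFrame, gwas: dict,
                       p_eqtl_max: float = 5e-8,
                       p_gwas_max: float = 5e-3) -> pd.DataFrame:
    """Per-(gene, trait) instruments: the lead cis-eQTL when its p-value
    passes ``p_eqtl_max`` and the same variant's GWAS p-value passes
    ``p_gwas_max``.  Variants are aligned by (CHR, POS); swapped A1/A2 flips
    the GWAS beta sign."""
    rows = []
    for trait, ss in gwas.items():
        idx = ss.set_index(["CHR", "POS"])
        for _, eg in egenes.iterrows():
            if eg["P"] >= p_eqtl_max:
                continue
            key = (str(eg["CHR"]), int(eg["POS"]))
            try:
                g = idx.loc[key]
            except KeyError:
                continue
            if isinstance(g, pd.DataFrame):
                g = g.iloc[0]
            b_gwas, se_gwas, p_gwas = float(g["BETA"]), float(g["SE"]), float(g["P"])
            if {"A1", "A2"} <= set(eg.index):
                if (g["A1"], g["A2"]) == (eg["A2"], eg["A1"]):
                    b_gwas = -b_gwas
                elif (g["A1"], g["A2"]) != (eg["A1"], eg["A2"]):
                    logger.warning("unalignable alleles at %s; pair skipped", key)
                    continue
            if p_gwas >= p_gwas_max:
                continue
            rows.append({
                "gene_id": eg["gene_id"], "trait": trait,
                "CHR": eg["CHR"], "POS": eg["POS"], "ID": eg["ID"],
                "b_gwas": b_gwas, "se_gwas": se_gwas, "p_gwas": p_gwas,
                "b_eqtl": float(eg["BETA"]), "se_eqtl": float(eg["SE"]),
                "p_eqtl": float(eg["P"]),
            })
    return pd.DataFrame(rows)


def run_smr(egenes: pd.DataFrame, gwas: dict, alpha: float = 0.05,
            p_eqtl_max: float = 5e-8, p_gwas_max: float = 5e-3) -> pd.DataFrame:
    """SMR across all traits; Bonferroni threshold applied to the pooled test
    count (the per-trait count is also reported in ``attrs``)."""
    inst = select_instruments(egenes, gwas, p_eqtl_max, p_gwas_max)
    if inst.empty:
        out = pd.DataFrame(columns=["gene_id", "trait", "ID", "b_xy", "t_smr",
                                    "p_smr", "significant"])
        out.attrs["threshold"] = alpha
        return out
    res = inst.apply(lambda r: smr_test(r["b_gwas"], r["se_gwas"],
                                        r["b_eqtl"], r["se_eqtl"]),
                     axis=1, result_type="expand")
    out = pd.concat([inst, res], axis=1)
    n_tests = len(out)
    thr = bonferroni_threshold(alpha, n_tests)
    out["significant"] = out["p_smr"] < thr
    out.attrs["threshold"] = thr
    out.attrs["n_tests_pooled"] = n_tests
    out.attrs["n_tests_per_trait"] = out.groupby("trait").size().to_dict()
    return out
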