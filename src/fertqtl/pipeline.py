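"""End-to-end pipeline: simulate -> GRM -> single-trait GWAS -> CMT-GWAS ->
cis-eQTL -> trans-eQTL -> SMR -> enrichment/validation, with one config, a
manifest of output digests, and per-stage logging.

The synthetic demo splits one simulated cohort into a discovery subsample
(GWAS, eQTL, SMR) and a held-out validation subsample in which discovery
hits are re-tested — mirroring a two-population discovery/validation design
on a shared variant panel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cmt, enrichment, eqtl, io, lmm, simulate, smr

logger = logging.getLogger(__name__)

STAGES = ("simulate", "grm", "gwas", "cmt", "eqtl_cis", "eqtl_trans",
          "smr", "enrich", "varexp", "validate")


@dataclass
class PipelineConfig:
    """All thresholds default to the study's values: GWAS MAF 0.01, eQTL MAF
    0.05, imputation accuracy 0.4, cis window 2 Mb, trans distance 5 Mb,
    flank 100 bp, stepwise P 5e-6, LD r^2 0.1, eGene alpha 0.01, SMR eQTL
    p 5e-8 / GWAS p 5e-3, CPM 3 at 25%, 4 expression PCs."""

    outdir: str = "fertqtl_out"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic-cohort settings (None = SimConfig default)
    sim: dict = field(default_factory=dict)
    validation_frac: float = 0.3
    # thresholds
    gwas_maf_min: float = 0.01
    eqtl_maf_min: float = 0.05
    acc_min: float = 0.4
    grm_maf_min: float = 0.01
    grm_max_variants: int = 10_000
    cis_window_bp: int = 2_000_000
    trans_min_bp: int = 5_000_000
    flank_bp: int = 100
    stepwise_p: float = 5e-6
    stepwise_r2: float = 0.1
    max_cycles: int = 10
    gwas_sig_p: float = 5e-8
    egene_alpha: float = 0.01
    smr_p_eqtl: float = 5e-8
    smr_p_gwas: float = 5e-3
    smr_alpha: float = 0.05
    min_cpm: float = 3.0
    max_low_prop: float = 0.25
    n_expression_pcs: int = 4
    validation_p: float = 0.002
    varexp_random_reps: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path, **kw):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g", **kw)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Any missing upstream dependency raises a named error before compute.
    """
    enabled = set(config.stages)
    deps = {"grm": {"simulate"}, "gwas": {"grm"}, "cmt": {"gwas"},
            "eqtl_cis": {"grm"}, "eqtl_trans": {"eqtl_cis", "cmt"},
            "smr": {"eqtl_cis", "gwas"}, "enrich": {"eqtl_cis"},
            "varexp": {"cmt"}, "validate": {"cmt"}}
    for st in enabled:
        missing = deps.get(st, set()) - enabled
        if missing:
            raise ValueError(f"stage '{st}' requires disabled stage(s) {sorted(missing)}")

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "outputs": {}, "counts": {}}
    t_all = time.time()

    def record(stage, t0, *paths):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    sim_cfg = simulate.SimConfig(**{**config.sim, "seed": config.seed})

    # ---- simulate -------------------------------------------------------
    t0 = time.time()
    geno = simulate.simulate_genotypes(sim_cfg)
    traits, truth_g = simulate.simulate_traits(geno, sim_cfg)
    counts, annot, covars, truth_e = simulate.simulate_expression(geno, sim_cfg)
    n_val = int(round(config.validation_frac * geno.n_samples))
    n_disc = geno.n_samples - n_val
    disc = np.arange(n_disc)
    val = np.arange(n_disc, geno.n_samples)
    paths = []
    if "simulate" in enabled:
        p1 = out / "inputs" / "genotypes.tsv"
        p1.parent.mkdir(parents=True, exist_ok=True)
        io.write_dosage_tsv(geno, p1)
        p2 = out / "inputs" / "traits.tsv"
        io.write_trait_table(traits, p2)
        p3 = _write(annot, out / "inputs" / "gene_annotation.tsv")
        p4 = out / "inputs" / "expression_counts.tsv"
        counts.to_csv(p4, sep="\t")
        p5 = _write(truth_g.causal_variants, out / "truth" / "causal_variants.tsv")
        p6 = _write(truth_e.egene_truth, out / "truth" / "egenes.tsv")
        paths = [p1, p2, p3, p4, p5, p6]
    record("simulate", t0, *paths)

    # discovery-side objects; GWAS panel filter MAF>=0.01 & accuracy>0.4
    geno_d = geno.subset_samples(disc)
    keep = np.flatnonzero((geno.variants["maf"] >= config.gwas_maf_min)
                          & (geno.variants["accuracy"] > config.acc_min))
    geno_gwas = geno_d.subset_variants(keep)
    manifest["counts"]["gwas_panel_variants"] = int(len(keep))
    Yd = traits.data.iloc[disc][traits.traits]
    Xd = simulate.TraitTable(traits.data.iloc[disc], traits.traits,
                             traits.class_covariates,
                             traits.continuous_covariates).design_matrix()

    # ---- GRM ------------------------------------------------------------
    grm = None
    if "grm" in enabled:
        t0 = time.time()
        rng = np.random.default_rng([config.seed, 10])
        m = geno_gwas.n_variants
        sub = (np.sort(rng.choice(m, size=config.grm_max_variants, replace=False))
               if m > config.grm_max_variants else np.arange(m))
        grm = lmm.compute_grm(geno_gwas.subset_variants(sub),
                              maf_min=config.grm_maf_min)
        (out / "grm").mkdir(parents=True, exist_ok=True)
        io.write_grm(grm, str(out / "grm" / "discovery"))
        record("grm", t0, out / "grm" / "discovery.grm.id",
               out / "grm" / "discovery.grm.tsv")

    # ---- single-trait GWAS ---------------------------------------------
    sumstats = {}
    if "gwas" in enabled:
        t0 = time.time()
        d, U = np.linalg.eigh(grm.values)
        eig = (np.clip(d, 0.0, None), U)
        paths = []
        for t in traits.traits:
            ss = lmm.assoc_scan(geno_gwas, Yd[t].to_numpy(dtype=float), Xd,
                                grm, trait=t, eig=eig)
            sumstats[t] = ss
            p = out / "gwas" / f"{t}.sumstats.tsv"
            p.parent.mkdir(parents=True, exist_ok=True)
            io.write_summary_stats(ss, p)
            paths.append(p)
            n_sig = int((ss["P"] < config.gwas_sig_p).sum())
            manifest["counts"][f"gwas_sig_{t}"] = n_sig
            manifest["counts"][f"gwas_fdr_{t}"] = lmm.fdr_from_counts(
                config.gwas_sig_p, n_sig, len(ss))
        record("gwas", t0, *paths)

    # ---- CMT-GWAS -------------------------------------------------------
    causal, mgwas = None, None
    if "cmt" in enabled:
        t0 = time.time()
        causal, sumstats, mgwas = cmt.stepwise_conditional_selection(
            geno_gwas, Yd, Xd, grm, p_threshold=config.stepwise_p,
            r2_max=config.stepwise_r2, max_cycles=config.max_cycles)
        p1 = _write(causal.records, out / "cmt" / "causal_set.tsv")
        p2 = _write(mgwas, out / "cmt" / "mgwas.tsv")
        manifest["counts"]["cmt_causal_set"] = len(causal.records)
        record("cmt", t0, p1, p2)

    # ---- cis-eQTL -------------------------------------------------------
    cis_egenes, cis_records, expr, geno_eqtl, grm_e = None, None, None, None, None
    if "eqtl_cis" in enabled:
        t0 = time.time()
        n_expr = counts.shape[1]
        keep_e = np.flatnonzero((geno.variants["maf"] >= config.eqtl_maf_min)
                                & (geno.variants["accuracy"] > config.acc_min))
        geno_eqtl = geno.subset_samples(np.arange(n_expr)).subset_variants(keep_e)
        manifest["counts"]["eqtl_panel_variants"] = int(len(keep_e))
        expr = eqtl.prepare_expression(counts, annot, covars,
                                       q_pcs=config.n_expression_pcs,
                                       min_cpm=config.min_cpm,
                                       max_low_prop=config.max_low_prop)
        manifest["counts"]["genes_after_cpm_filter"] = expr.counts.shape[0]
        rng = np.random.default_rng([config.seed, 11])
        m = geno_eqtl.n_variants
        sub = (np.sort(rng.choice(m, size=config.grm_max_variants, replace=False))
               if m > config.grm_max_variants else np.arange(m))
        grm_e = lmm.compute_grm(geno_eqtl.subset_variants(sub),
                                maf_min=config.grm_maf_min)
        cis_records = eqtl.map_cis_eqtl(expr, geno_eqtl, grm_e,
                                        window_bp=config.cis_window_bp)
        n_genes = cis_records["gene_id"].nunique()
        cis_egenes, cis_sig = eqtl.hierarchical_correction(
            cis_records, n_genes, alpha=config.egene_alpha)
        p1 = _write(cis_egenes.drop(columns=["lead"], errors="ignore"),
                    out / "eqtl" / "cis_egenes.tsv")
        p2 = _write(cis_sig, out / "eqtl" / "cis_significant.tsv")
        manifest["counts"]["cis_genes_tested"] = int(n_genes)
        manifest["counts"]["cis_egenes"] = len(cis_egenes)
        manifest["counts"]["epercent"] = round(
            eqtl.epercent(len(cis_egenes), n_genes), 4) if n_genes else None
        record("eqtl_cis", t0, p1, p2)

    # ---- trans-eQTL -----------------------------------------------------
    if "eqtl_trans" in enabled:
        t0 = time.time()
        gwas_hits = []
        eqtl_ids = set(zip(geno_eqtl.variants["chrom"].astype(str),
                           geno_eqtl.variants["pos"]))
        pos_index = {(c, p): i for i, (c, p) in enumerate(
            zip(geno_eqtl.variants["chrom"].astype(str),
                geno_eqtl.variants["pos"]))}
        for t, ss in sumstats.items():
            sig = ss[ss["P"] <= config.gwas_sig_p]
            for _, r in sig.iterrows():
                k = (str(r["CHR"]), int(r["POS"]))
                if k in pos_index:
                    gwas_hits.append(pos_index[k])
        if mgwas is not None:
            for _, r in mgwas[mgwas["P"] <= config.gwas_sig_p].iterrows():
                k = (str(r["CHR"]), int(r["POS"]))
                if k in pos_index:
                    gwas_hits.append(pos_index[k])
        test_set = eqtl.select_trans_test_set(cis_egenes, gwas_hits, geno_eqtl,
                                              flank_bp=config.flank_bp)
        manifest["counts"]["trans_test_set"] = int(len(test_set))
        if len(test_set):
            trans_records, trans_egenes = eqtl.map_trans_eqtl(
                test_set, expr, geno_eqtl, grm_e,
                min_distance_bp=config.trans_min_bp, alpha=config.egene_alpha)
            p1 = _write(trans_egenes.drop(columns=["lead"], errors="ignore")
                        if len(trans_egenes) else trans_egenes,
                        out / "eqtl" / "trans_egenes.tsv")
            manifest["counts"]["trans_egenes"] = len(trans_egenes)
            record("eqtl_trans", t0, p1)
        else:
            manifest["counts"]["trans_egenes"] = 0
            record("eqtl_trans", t0)

    # ---- SMR ------------------------------------------------------------
    if "smr" in enabled:
        t0 = time.time()
        smr_res = smr.run_smr(cis_egenes, sumstats, alpha=config.smr_alpha,
                              p_eqtl_max=config.smr_p_eqtl,
                              p_gwas_max=config.smr_p_gwas)
        p1 = _write(smr_res, out / "smr" / "smr.tsv")
        manifest["counts"]["smr_tests"] = len(smr_res)
        manifest["counts"]["smr_significant"] = int(smr_res["significant"].sum()) \
            if len(smr_res) else 0
        record("smr", t0, p1)

    # ---- enrichment -----------------------------------------------------
    if "enrich" in enabled:
        t0 = time.time()
        rng = np.random.default_rng([config.seed, 12])
        rows = []
        for cat in ("promoter", "H3K4me1", "ATAC"):
            for c in range(sim_cfg.n_chromosomes):
                starts = np.sort(rng.integers(
                    1, sim_cfg.chrom_length_bp - 100_000, size=60))
                for s in starts:
                    rows.append((cat, str(c + 1), int(s),
                                 int(s + rng.integers(500, 20_000))))
        iset = io.IntervalSet(pd.DataFrame(
            rows, columns=["category", "chrom", "start", "end"]))
        io.write_intervals(iset, out / "inputs" / "regulatory.bed")
        enr_rows = []
        if cis_egenes is not None and len(cis_egenes):
            leads = cis_egenes[["CHR", "POS"]].rename(
                columns={"CHR": "chrom", "POS": "pos"})
            bg = geno_eqtl.variants[["chrom", "pos"]]
            lead_flags = enrichment.annotate_variants(leads, iset)
            bg_flags = enrichment.annotate_variants(bg, iset)
            for cat in iset.categories:
                r = enrichment.hypergeometric_enrichment(lead_flags, bg_flags, cat)
                enr_rows.append(dataclasses.asdict(r))
        p1 = _write(pd.DataFrame(enr_rows), out / "enrich" / "enrichment.tsv")
        record("enrich", t0, p1)

    # ---- variance explained by the causal set --------------------------
    if "varexp" in enabled and (causal is None or causal.records.empty):
        manifest["counts"]["h2_causal_subset"] = None
        record("varexp", time.time())
    elif "varexp" in enabled:
        t0 = time.time()
        geno_val = geno.subset_samples(val).subset_variants(keep)
        Yv = traits.data.iloc[val][traits.traits[0]].to_numpy(dtype=float)
        Xv = simulate.TraitTable(traits.data.iloc[val], traits.traits,
                                 traits.class_covariates,
                                 traits.continuous_covariates).design_matrix()
        res = enrichment.variance_explained_subset(
            geno_val, causal.variant_indices, Yv, Xv,
            n_random_reps=config.varexp_random_reps, seed=config.seed)
        p1 = _write(pd.DataFrame([dataclasses.asdict(res)]),
                    out / "validate" / "variance_explained.tsv")
        manifest["counts"]["h2_causal_subset"] = res.h2_subset
        manifest["counts"]["h2_random_mean"] = res.h2_random_mean
        record("varexp", t0, p1)

    # ---- validation re-test --------------------------------------------
    if "validate" in enabled:
        t0 = time.time()
        hits = set()
        for t, ss in sumstats.items():
            hits.update(ss.loc[ss["P"] <= config.gwas_sig_p, "ID"])
        if causal is not None:
            hits.update(causal.records["ID"])
        if hits:
            geno_val = geno.subset_samples(val).subset_variants(keep)
            Yv = traits.data.iloc[val][traits.traits[0]].to_numpy(dtype=float)
            Xv = simulate.TraitTable(traits.data.iloc[val], traits.traits,
                                     traits.class_covariates,
                                     traits.continuous_covariates).design_matrix()
            grm_v = lmm.compute_grm(geno_val.subset_variants(
                np.arange(min(geno_val.n_variants, config.grm_max_variants))),
                maf_min=config.grm_maf_min)
            val_ss = lmm.assoc_scan(geno_val, Yv, Xv, grm_v,
                                    trait=traits.traits[0])
            io.write_summary_stats(val_ss, out / "validate" / "validation.sumstats.tsv")
            n_ok, fdr = enrichment.validation_retest(
                sorted(hits), val_ss, p_threshold=config.validation_p)
            manifest["counts"]["n_validated"] = n_ok
            manifest["counts"]["validation_fdr"] = fdr
            record("validate", t0, out / "validate" / "validation.sumstats.tsv")
        else:
            manifest["counts"]["n_validated"] = 0
            record("validate", t0)

    manifest["total_seconds"] = round(time.time() - t_all, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete in %.1fs", manifest["total_seconds"])
    return manifest
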