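"""Expression filtering, PCs, cis/trans windows, hierarchical correction,
test-set construction and TSS profiling."""

import numpy as np
import pandas as pd
import pytest

from fertqtl import eqtl, lmm, simulate
from fertqtl.eqtl import (ExpressionData, cpm, cpm_filter, expression_pcs,
                          hierarchical_correction, log_cpm, map_cis_eqtl,
                          map_trans_eqtl, prepare_expression,
                          select_trans_test_set, tss_distance_profile)

from conftest import make_geno


# ---------------------------------------------------------------------------
# CPM filter and PCs
# ---------------------------------------------------------------------------


def test_cpm_proportional_to_counts_at_equal_library_sizes():
    counts = pd.DataFrame([[10, 10], [30, 30], [60, 60]],
                          index=["a", "b", "c"], columns=["s1", "s2"])
    c = cpm(counts)
    np.testing.assert_allclose(c.loc["b"] / c.loc["a"], 3.0)


def test_cpm_filter_excludes_all_zero_gene():
    counts = pd.DataFrame({"s1": [0, 100], "s2": [0, 100]}, index=["z", "ok"])
    kept = cpm_filter(counts)
    assert list(kept.index) == ["ok"]


def test_cpm_filter_boundary_is_inclusive():
    # gene "edge" has CPM < 3 in exactly 25% of samples -> excluded
    counts = pd.DataFrame(
        {"s1": [0, 1_000_000], "s2": [500, 1_000_000], "s3": [500, 1_000_000],
         "s4": [500, 1_000_000]}, index=["edge", "big"])
    c = cpm(counts)
    assert ((c.loc["edge"] < 3).mean()) == 0.25
    kept = cpm_filter(counts)
    assert "edge" not in kept.index and "big" in kept.index


def test_cpm_filter_hand_enumeration():
    counts = pd.DataFrame(
        {"s1": [5, 0, 100], "s2": [6, 1, 120], "s3": [7, 0, 90],
         "s4": [8, 2, 110]}, index=["g1", "g2", "g3"])
    c = cpm(counts)
    low = (c < 3).mean(axis=1)
    expected = list(counts.index[low < 0.25])
    assert list(cpm_filter(counts).index) == expected


def test_cpm_zero_library_raises():
    counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
    with pytest.raises(ValueError):
        cpm(counts)


def test_expression_pcs_recover_planted_batch():
    rng = np.random.default_rng(0)
    n, g = 60, 200
    batch = rng.normal(size=n)
    load = rng.normal(size=g)
    M = np.outer(load, batch) * 3 + rng.normal(size=(g, n)) * 0.1
    lc = pd.DataFrame(M, index=[f"g{i}" for i in range(g)],
                      columns=[f"s{i}" for i in range(n)])
    pcs = expression_pcs(lc, q=2)
    assert abs(np.corrcoef(pcs[:, 0], batch)[0, 1]) > 0.99


def test_expression_pcs_edge_cases():
    rng = np.random.default_rng(1)
    lc = pd.DataFrame(rng.normal(size=(30, 10)))
    assert expression_pcs(lc, q=0).shape == (10, 0)
    with pytest.raises(ValueError):
        expression_pcs(lc, q=10)
    lc2 = lc.copy()
    lc2[9] = lc2[0]  # duplicated sample column
    pcs = expression_pcs(lc2, q=2)
    np.testing.assert_allclose(pcs[0], pcs[9], atol=1e-8)


# ---------------------------------------------------------------------------
# window conventions
# ---------------------------------------------------------------------------


def _tiny_expression(geno, tss, chrom="1", strand="+", y=None, n_genes=1):
    n = geno.n_samples
    rng = np.random.default_rng(2)
    lc = pd.DataFrame(
        rng.normal(size=(n_genes, n)) if y is None else np.atleast_2d(y),
        index=[f"g{i}" for i in range(n_genes)],
        columns=geno.samples)
    annot = pd.DataFrame({
        "gene_id": lc.index, "chrom": chrom, "tss": tss, "strand": strand,
        "start": max(tss - 1000, 1), "end": tss + 1000})
    covars = pd.DataFrame(index=pd.Index(geno.samples, name="sample_id"))
    return ExpressionData(counts=lc, annot=annot, covariates=covars,
                          log_cpm=lc, pcs=np.zeros((n, 0)),
                          class_covariates=[], continuous_covariates=[])


def test_cis_window_boundary_closed():
    rng = np.random.default_rng(3)
    dosage = rng.integers(0, 3, size=(80, 3)).astype(float)
    geno = make_geno(dosage, start_pos=1_000_000, spacing=0)
    geno.variants.loc[0, "pos"] = 1_000_000          # exactly TSS - 2 Mb
    geno.variants.loc[1, "pos"] = 3_000_000          # at TSS
    geno.variants.loc[2, "pos"] = 5_000_001          # 1 bp past +2 Mb
    expr = _tiny_expression(geno, tss=3_000_000)
    rec = map_cis_eqtl(expr, geno, grm=None)
    assert sorted(rec["POS"]) == [1_000_000, 3_000_000]


def test_trans_distance_rule_strict():
    rng = np.random.default_rng(4)
    dosage = rng.integers(0, 3, size=(80, 2)).astype(float)
    geno = make_geno(dosage)
    geno.variants.loc[0, "pos"] = 4_900_000 + 10_000_000   # 4.9 Mb from TSS
    geno.variants.loc[1, "pos"] = 7_000_000 + 10_000_000   # 7 Mb from TSS
    expr = _tiny_expression(geno, tss=10_000_000)
    rec, _ = map_trans_eqtl([0, 1], expr, geno, grm=None)
    assert sorted(rec["POS"]) == [17_000_000]


def test_tss_distance_sign_respects_strand():
    rng = np.random.default_rng(5)
    dosage = rng.integers(0, 3, size=(60, 1)).astype(float)
    geno = make_geno(dosage, start_pos=3_100_000)
    expr_fwd = _tiny_expression(geno, tss=3_000_000, strand="+")
    expr_rev = _tiny_expression(geno, tss=3_000_000, strand="-")
    d_fwd = map_cis_eqtl(expr_fwd, geno, None)["tss_distance"].iloc[0]
    d_rev = map_cis_eqtl(expr_rev, geno, None)["tss_distance"].iloc[0]
    assert d_fwd == 100_000 and d_rev == -100_000


# ---------------------------------------------------------------------------
# hierarchical correction
# ---------------------------------------------------------------------------


def _records(rows):
    return pd.DataFrame(rows, columns=["gene_id", "variant_idx", "CHR", "POS",
                                       "ID", "BETA", "SE", "T", "P",
                                       "tss_distance", "scope"])


def test_hierarchical_threshold_arithmetic():
    n_genes = 50
    p = 0.01 / (2 * n_genes)
    rec = _records([("g1", 0, "1", 100, "v0", 1, 0.1, 5, p, 10, "cis")])
    egenes, sig = hierarchical_correction(rec, n_genes, alpha=0.01)
    assert list(egenes["gene_id"]) == ["g1"]
    assert len(sig) == 1


def test_hierarchical_p_local_capped_at_one():
    rec = _records([("g1", i, "1", 100 + i, f"v{i}", 1, 0.1, 1, 0.5, 10, "cis")
                    for i in range(10)])
    egenes, sig = hierarchical_correction(rec, 1, alpha=0.01)
    # p * m_g = 5 -> capped
    assert egenes.empty


def test_hierarchical_rejects_understated_gene_count():
    rec = _records([("g1", 0, "1", 1, "a", 1, 1, 1, 0.5, 1, "cis"),
                    ("g2", 1, "1", 2, "b", 1, 1, 1, 0.5, 1, "cis")])
    with pytest.raises(ValueError):
        hierarchical_correction(rec, 1)


def test_hierarchical_adjustment_ordering_invariants():
    rng = np.random.default_rng(6)
    rows = []
    for g in range(20):
        for v in range(rng.integers(1, 30)):
            rows.append((f"g{g}", v, "1", v + 1, f"v{v}", 0, 1, 0,
                         rng.random(), rng.integers(-2e6, 2e6), "cis"))
    rec = _records(rows)
    egenes, sig = hierarchical_correction(rec, 25, alpha=0.5)
    if len(sig):
        assert (sig["p_local"] >= sig["P"] - 1e-15).all()
        assert (sig["p_global"] >= sig["p_local"] - 1e-15).all()
        assert (sig["p_local"] <= 1).all()


def test_epercent_worked_example():
    assert lmm.truncate(eqtl.epercent(4376, 10455), 1) == 41.8
    assert eqtl.epercent(0, 100) == 0.0
    assert eqtl.epercent(100, 100) == 100.0
    with pytest.raises(ValueError):
        eqtl.epercent(5, 4)


# ---------------------------------------------------------------------------
# trans test set
# ---------------------------------------------------------------------------


def test_trans_test_set_construction(small_geno):
    assert len(select_trans_test_set(None, [], small_geno)) == 0
    # two seeds 150 bp apart with one variant between them, 80 bp from each
    rng = np.random.default_rng(7)
    dosage = rng.integers(0, 3, size=(10, 4)).astype(float)
    geno = make_geno(dosage)
    geno.variants["pos"] = [1000, 1080, 1150, 5000]
    seeds = [0, 2]
    got = select_trans_test_set(None, seeds, geno, flank_bp=100)
    assert list(got) == [0, 1, 2]
    assert list(select_trans_test_set(None, seeds, geno, flank_bp=0)) == [0, 2]


# ---------------------------------------------------------------------------
# TSS profile
# ---------------------------------------------------------------------------


def test_tss_profile_hand_placed_leads():
    leads = pd.DataFrame({"gene_id": ["a", "b", "c"],
                          "POS": [10_000, 150_000, 3_000_000],
                          "tss_distance": [10_000, 150_000, 3_000_000]})
    prof = tss_distance_profile(leads)
    assert prof["count"].sum() == 3
    assert prof.set_index("bin").loc["0-50000", "count"] == 1
    assert prof.set_index("bin").loc["100000-250000", "count"] == 1
    assert prof["proportion"].sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        tss_distance_profile(leads.iloc[:0])


# ---------------------------------------------------------------------------
# planted-effect recovery and scope bookkeeping (integration)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def expression_world():
    cfg = simulate.SimConfig(n_samples=489, n_expr_samples=489,
                             n_chromosomes=2, variants_per_chrom=1200,
                             chrom_length_bp=40_000_000, n_genes=60,
                             prop_egenes=0.4, n_trans_egenes=4, seed=19)
    geno = simulate.simulate_genotypes(cfg)
    counts, annot, covars, truth = simulate.simulate_expression(geno, cfg)
    keep = np.flatnonzero((geno.variants["maf"] >= 0.05)
                          & (geno.variants["accuracy"] > 0.4))
    g = geno.subset_variants(keep)
    remap = {int(o): i for i, o in enumerate(keep)}
    grm = lmm.compute_grm(g, maf_min=0.01)
    expr = prepare_expression(counts, annot, covars, q_pcs=4)
    return cfg, g, remap, grm, expr, truth


def test_cis_mapping_recovers_planted_egenes(expression_world):
    cfg, g, remap, grm, expr, truth = expression_world
    rec = map_cis_eqtl(expr, g, grm)
    egenes, _ = hierarchical_correction(rec, rec["gene_id"].nunique())
    planted = set(truth.egene_truth.query("kind == 'cis'")["gene_id"])
    planted &= set(expr.counts.index)
    found = set(egenes["gene_id"])
    assert len(planted & found) / len(planted) >= 0.9


def test_gene_with_cis_and_trans_effect_appears_in_both_scopes(
        expression_world):
    cfg, g, remap, grm, expr, truth = expression_world
    rec = map_cis_eqtl(expr, g, grm)
    egenes, _ = hierarchical_correction(rec, rec["gene_id"].nunique())
    trans_truth = truth.egene_truth.query("kind == 'trans'")
    hits = [remap[i] for i in trans_truth["variant_idx"] if i in remap]
    ts = select_trans_test_set(egenes, hits, g, flank_bp=100)
    trec, tegenes = map_trans_eqtl(ts, expr, g, grm)
    assert (rec["scope"] == "cis").all()
    assert (trec["scope"] == "trans").all()
    assert (np.abs(trec["tss_distance"]) > 5_000_000).all()
    both = set(truth.egene_truth.query("kind=='cis'")["gene_id"]) & set(
        trans_truth["gene_id"])
    if both and len(tegenes):
        assert both & set(tegenes["gene_id"]) <= set(tegenes["gene_id"])


def test_split_half_reproducibility_strong_effects(expression_world):
    cfg, g, remap, grm, expr, truth = expression_world
    p12, p21, corr = eqtl.split_half_reproducibility(
        expr.counts, expr.annot, expr.covariates, g, grm, seed=4)
    assert p12 >= 0.8 and p21 >= 0.8
    assert corr >= 0.95
    # determinism
    again = eqtl.split_half_reproducibility(
        expr.counts, expr.annot, expr.covariates, g, grm, seed=4)
    assert (p12, p21, corr) == again
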