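"""Mixed-model engine: GRM formula, REML against a dense-matrix oracle,
the OLS limit of the scan, null calibration, and the closed-form FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fertqtl import lmm
from fertqtl.lmm import (NullModel, assoc_scan, compute_grm, fdr_from_counts,
                         fit_null_lmm, genomic_lambda, reml_loglik, truncate)

from conftest import make_geno


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def grm_brute_force(dosage, maf_min=0.0):
    X = np.asarray(dosage, dtype=float)
    p = X.mean(axis=0) / 2
    keep = (np.minimum(p, 1 - p) >= maf_min) & (p > 0) & (p < 1)
    X, p = X[:, keep], p[keep]
    n, m = X.shape
    G = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            G[j, k] = np.mean((X[j] - 2 * p) * (X[k] - 2 * p) / (2 * p * (1 - p)))
    return G


def test_grm_matches_direct_formula():
    dosage = np.array([[0, 2], [1, 1], [2, 0]])
    g = compute_grm(make_geno(dosage), maf_min=0.0)
    np.testing.assert_allclose(g.values, grm_brute_force(dosage), atol=1e-12)


def test_grm_duplicate_individuals_share_relationship():
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, size=(6, 50)).astype(float)
    dosage[5] = dosage[2]  # duplicate individual
    g = compute_grm(make_geno(dosage), maf_min=0.0)
    assert g.values[5, 2] == pytest.approx(g.values[2, 2], rel=1e-12)


def test_grm_diagonal_near_one_under_hwe(small_geno):
    g = compute_grm(small_geno, maf_min=0.01)
    assert abs(np.mean(np.diag(g.values)) - 1.0) < 0.05
    # PSD up to numerical tolerance
    assert np.linalg.eigvalsh(g.values).min() > -1e-8


def test_grm_rejects_all_monomorphic():
    with pytest.raises(ValueError):
        compute_grm(make_geno(np.ones((4, 3)) * 2), maf_min=0.0)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def dense_restricted_loglik(y, X, G, sg2, se2):
    """Brute-force restricted likelihood from the matrix definition."""
    n, p = X.shape
    V = sg2 * G + se2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return float(-0.5 * (ldV + ldX + y @ P @ y + (n - p) * np.log(2 * np.pi)))


def test_reml_loglik_matches_dense_oracle_on_grid():
    rng = np.random.default_rng(3)
    n = 8
    Z = rng.normal(size=(n, 5))
    G = Z @ Z.T / 5
    grm = lmm.Grm(samples=[f"s{i}" for i in range(n)], values=G, n_variants_used=5)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    for sg2 in (0.1, 0.5, 1.0):
        for se2 in (0.2, 0.7, 1.5):
            ours = reml_loglik(y, X, grm, sg2, se2)
            oracle = dense_restricted_loglik(y, X, G, sg2, se2)
            assert ours == pytest.approx(oracle, abs=1e-6)


def test_reml_optimum_beats_grid(small_geno, small_grm):
    rng = np.random.default_rng(1)
    n = small_geno.n_samples
    X = np.ones((n, 1))
    L = np.linalg.cholesky(small_grm.values + 1e-6 * np.eye(n))
    y = 0.6 * (L @ rng.normal(size=n)) + 0.8 * rng.normal(size=n)
    vc = fit_null_lmm(y, X, small_grm)
    best_grid = max(reml_loglik(y, X, small_grm, h * s, (1 - h) * s)
                    for h in np.linspace(0.01, 0.99, 25)
                    for s in (0.5, 1.0, 1.5, 2.0))
    assert vc.reml_loglik >= best_grid - 1e-4


def test_reml_null_trait_estimates_near_zero_h2(small_geno, small_grm):
    rng = np.random.default_rng(2)
    n_low = 0
    for rep in range(10):
        y = rng.normal(size=small_geno.n_samples)
        vc = fit_null_lmm(y, np.ones((small_geno.n_samples, 1)), small_grm)
        n_low += vc.h2 <= 0.08
    assert n_low >= 8


def test_reml_rejects_rank_deficient_design(small_geno, small_grm):
    n = small_geno.n_samples
    X = np.ones((n, 2))  # duplicated intercept
    with pytest.raises(ValueError):
        fit_null_lmm(np.zeros(n) + np.arange(n), X, small_grm)


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


def test_scan_equals_ols_when_no_genetic_variance():
    rng = np.random.default_rng(7)
    n, m = 120, 30
    geno = make_geno(rng.integers(0, 3, size=(n, m)))
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    vc = lmm.VarianceComponents(0.0, 1.0, 0.0)
    ss = assoc_scan(geno, y, X, grm=None, varcomp=vc)
    for j in range(m):
        w = geno.dosage[:, j]
        D = np.column_stack([X, w])
        beta, res, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        s2 = resid @ resid / (n - D.shape[1])
        cov = s2 * np.linalg.inv(D.T @ D)
        t_ols = beta[-1] / np.sqrt(cov[-1, -1])
        assert ss["BETA"].iloc[j] == pytest.approx(beta[-1], abs=1e-8)
        assert ss["SE"].iloc[j] == pytest.approx(np.sqrt(cov[-1, -1]), abs=1e-8)
        assert ss["T"].iloc[j] == pytest.approx(t_ols, abs=1e-8)
        # normal-reference p differs from the t reference only slightly at n=120
        p_t = 2 * stats.t.sf(abs(t_ols), df=n - D.shape[1])
        assert ss["P"].iloc[j] == pytest.approx(p_t, abs=5e-3)


def test_scan_null_calibration_binomial(small_geno, small_grm, small_traits):
    tt, _ = small_traits
    rng = np.random.default_rng(9)
    y = rng.permutation(tt.data["DTC"].to_numpy(dtype=float))
    ss = assoc_scan(small_geno, y, tt.design_matrix(), small_grm)
    frac = (ss["P"] < 0.01).mean()
    m = len(ss)
    ci = 2.58 * np.sqrt(0.01 * 0.99 / m)
    # LD makes variants dependent; allow twice the binomial band
    assert abs(frac - 0.01) < 2 * ci + 0.005


def test_scan_p_invariant_under_affine_rescaling(small_geno, small_grm,
                                                 small_traits):
    tt, _ = small_traits
    y = tt.data["AFC"].to_numpy(dtype=float)
    X = tt.design_matrix()
    a = assoc_scan(small_geno, y, X, small_grm)
    b = assoc_scan(small_geno, 3.7 * y + 11.0, X, small_grm)
    # invariance holds up to the REML optimiser's h2 tolerance
    np.testing.assert_allclose(a["P"], b["P"], rtol=1e-3, atol=1e-12)
    np.testing.assert_allclose(a["T"], b["T"], rtol=1e-3, atol=1e-6)


def test_conditioning_on_causal_removes_signal(small_geno, small_grm,
                                               small_traits):
    tt, truth = small_traits
    y = tt.data["DTC"].to_numpy(dtype=float)
    X = tt.design_matrix()
    causal = truth.causal_variants.query("trait == 'DTC'")
    j = int(causal["variant_idx"].iloc[0])
    ss = assoc_scan(small_geno, y, X, small_grm, conditioning_set=[j])
    # the conditioned variant is collinear with the covariates -> flagged null
    assert ss["BETA"].iloc[j] == 0.0
    assert ss["P"].iloc[j] == 1.0
    # strong LD proxies lose their marginal significance too
    from fertqtl.cmt import ld_r2

    free = assoc_scan(small_geno, y, X, small_grm)
    for k in range(small_geno.n_variants):
        if k != j and ld_r2(small_geno, j, k) > 0.8:
            assert ss["P"].iloc[k] > free["P"].iloc[j]


def test_monomorphic_variant_flagged():
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, size=(50, 3)).astype(float)
    dosage[:, 1] = 2.0
    geno = make_geno(dosage)
    ss = assoc_scan(geno, rng.normal(size=50), np.ones((50, 1)), grm=None,
                    varcomp=lmm.VarianceComponents(0.0, 1.0, 0.0))
    assert ss["P"].iloc[1] == 1.0 and ss["BETA"].iloc[1] == 0.0


def test_h2_recovery_on_simulated_trait(small_geno, small_grm, small_traits):
    tt, truth = small_traits
    vc = fit_null_lmm(tt.data["AFC"].to_numpy(dtype=float),
                      tt.design_matrix(), small_grm)
    target = truth.varcomp_truth.set_index("trait").loc["AFC", "sigma_g2"]
    assert abs(vc.h2 - target) < 0.25  # single replicate; tight bound in acceptance


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def test_fdr_worked_examples():
    assert truncate(fdr_from_counts(5e-8, 3, 31_140_417), 2) == 0.51
    assert truncate(100 * fdr_from_counts(0.002, 11, 225), 1) == 3.8
    assert fdr_from_counts(0.002, 11, 225) == pytest.approx(0.03899, abs=5e-5)


def test_fdr_degenerate_cases():
    assert fdr_from_counts(0.01, 100, 100) == 0.0  # A == T
    assert fdr_from_counts(0.01, 0, 100) == 1.0    # A == 0 convention
    with pytest.raises(ValueError):
        fdr_from_counts(0.01, 1, 0)
    with pytest.raises(ValueError):
        fdr_from_counts(0.0, 1, 10)


@settings(max_examples=200, deadline=None)
@given(p1=st.floats(1e-10, 0.5), p2=st.floats(1e-10, 0.5),
       a=st.integers(1, 99), t=st.integers(100, 10_000))
def test_fdr_monotone_in_p_and_a(p1, p2, a, t):
    lo, hi = sorted([p1, p2])
    assert fdr_from_counts(lo, a, t) <= fdr_from_counts(hi, a, t) + 1e-15
    assert fdr_from_counts(lo, a + 1, t) <= fdr_from_counts(lo, a, t) + 1e-15


def test_genomic_lambda_is_one_for_uniform_p():
    rng = np.random.default_rng(0)
    lam = genomic_lambda(rng.random(200_000))
    assert 0.98 < lam < 1.02
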