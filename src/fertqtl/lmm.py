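"""Linear mixed-model machinery: GRM construction, REML variance components,
single-trait association scans, and the closed-form FDR estimator.

The association model per variant is

    y = 1 mu + X beta + W_i alpha_i + g + e,     g ~ N(0, G sigma_g^2),
                                                 e ~ N(0, sigma_e^2 I)

with G the allele-frequency-standardised genomic relationship matrix.
Variance components are estimated once per trait under the null (no variant
term) and the variance *ratio* is then held fixed across the scan; the
residual scale is re-estimated per variant from the whitened residuals, so
that in the sigma_g^2 = 0 limit every record coincides exactly with an
ordinary least-squares t-test.  p-values use the standard-normal reference
(large-n); at tiny n they differ from the t reference accordingly.

Binary traits are analysed on the observed 0/1 scale with the same linear
model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SUMSTAT_COLUMNS, GenotypeMatrix

logger = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-10


@dataclass
class Grm:
    """Allele-frequency-standardised genomic relationship matrix."""

    samples: list
    values: np.ndarray
    n_variants_used: int

    def __post_init__(self):
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM not symmetric")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0


def compute_grm(geno: GenotypeMatrix, maf_min: float = 0.01) -> Grm:
    """G_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).

    p_i is the sample allele frequency; only variants with folded MAF >=
    ``maf_min`` enter; monomorphic variants are excluded with a warning.
    """
    X = np.asarray(geno.dosage, dtype=float)
    p = X.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    mono = maf <= 0
    if mono.any():
        warnings.warn(f"excluding {int(mono.sum())} monomorphic variants from GRM")
    keep = (~mono) & (maf >= maf_min)
    if not keep.any():
        raise ValueError("no polymorphic variants left for GRM")
    Xk = X[:, keep]
    pk = p[keep]
    Z = (Xk - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    m = Z.shape[1]
    values = (Z @ Z.T) / m
    return Grm(samples=list(geno.samples), values=values, n_variants_used=m)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


class NullModel:
    """Eigen-rotated workspace for one (y, X, GRM) triple.

    Holds the spectral decomposition G = U diag(d) U' restricted to the
    complete-case samples, the rotated response and design, and the fitted
    variance components; reused by :func:`assoc_scan`.
    """

    def __init__(self, y, X, grm_values, eig=None):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("y and X sample dimensions differ")
        self.mask = ~np.isnan(y)
        self.y = y[self.mask]
        self.X = X[self.mask]
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("X not of full column rank on non-missing samples")
        if grm_values is None:
            self.d = np.zeros(self.n)
            self.U = None
        elif eig is not None and self.mask.all():
            self.d, self.U = eig
        else:
            G = np.asarray(grm_values, dtype=float)[np.ix_(self.mask, self.mask)]
            d, U = np.linalg.eigh(G)
            if d.min() < -1e-6:
                raise ValueError(f"GRM not PSD after subsetting (min eig {d.min():.3g})")
            self.d, self.U = np.clip(d, 0.0, None), U
        self.ystar = self.y if self.U is None else self.U.T @ self.y
        self.Xstar = self.X if self.U is None else self.U.T @ self.X
        self.varcomp: VarianceComponents | None = None

    # restricted log-likelihood at h2, with the total scale profiled out
    def _profile(self, h2):
        v = h2 * self.d + (1.0 - h2)
        sw = 1.0 / np.sqrt(v)
        Xw = self.Xstar * sw[:, None]
        yw = self.ystar * sw
        Q, R = np.linalg.qr(Xw)
        coef = np.linalg.solve(R, Q.T @ yw)
        resid = yw - Xw @ coef
        rss = float(resid @ resid)
        df = self.n - self.p
        sigma2 = rss / df
        _, logdet_xtx = np.linalg.slogdet(R.T @ R)
        ll = -0.5 * (df * np.log(sigma2) + np.log(v).sum() + logdet_xtx
                     + df * (1.0 + np.log(2 * np.pi)))
        return ll, sigma2

    def fit(self, max_iter=200) -> VarianceComponents:
        if self.U is None:
            ll, sigma2 = self._profile(0.0)
            self.varcomp = VarianceComponents(0.0, sigma2, ll)
            return self.varcomp
        neg = lambda h2: -self._profile(h2)[0]
        res = optimize.minimize_scalar(neg, bounds=(1e-6, 1 - 1e-6),
                                       method="bounded",
                                       options={"maxiter": max_iter, "xatol": 1e-8})
        if not res.success:
            raise RuntimeError(f"REML did not converge: {res.message}")
        # the bounded optimum can sit at an interior local dip; compare endpoints
        cands = [res.x, 1e-12, 1 - 1e-9]
        h2 = min(cands, key=neg)
        ll, sigma2 = self._profile(h2)
        if h2 < 1e-8:
            h2 = 0.0
            ll, sigma2 = self._profile(h2)
        self.varcomp = VarianceComponents(h2 * sigma2, (1 - h2) * sigma2, ll)
        return self.varcomp

    def whitened(self, varcomp: VarianceComponents | None = None):
        """Return (yw, Xw, rotate) whitened by V^{-1/2} on the unit-variance
        scale v_i = h2 d_i + (1-h2)."""
        vc = varcomp or self.varcomp
        h2 = vc.h2
        v = h2 * self.d + (1.0 - h2)
        sw = 1.0 / np.sqrt(v)
        yw = self.ystar * sw
        Xw = self.Xstar * sw[:, None]
        return yw, Xw, sw


def fit_null_lmm(y, X, grm: Grm | None) -> VarianceComponents:
    """REML estimates of (sigma_g2, sigma_e2) via one eigendecomposition."""
    nm = NullModel(y, X, None if grm is None else grm.values)
    return nm.fit()


def reml_loglik(y, X, grm: Grm, sigma_g2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood at given variance components.

    l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2pi ]
    with V = sigma_g2 G + sigma_e2 I; computed through the eigen route.
    """
    nm = NullModel(y, X, grm.values)
    v = sigma_g2 * nm.d + sigma_e2
    sw = 1.0 / np.sqrt(v)
    Xw = nm.Xstar * sw[:, None]
    yw = nm.ystar * sw
    Q, R = np.linalg.qr(Xw)
    resid = yw - Q @ (Q.T @ yw)
    ypy = float(resid @ resid)
    _, logdet_xvx = np.linalg.slogdet(R.T @ R)
    return float(-0.5 * (np.log(v).sum() + logdet_xvx + ypy
                         + (nm.n - nm.p) * np.log(2 * np.pi)))


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


def _drop_collinear(X, cols, label="conditioning variant"):
    """Append columns of ``cols`` to X, dropping any that are collinear."""
    out = X
    kept = []
    for j in range(cols.shape[1]):
        c = cols[:, j:j + 1]
        beta, *_ = np.linalg.lstsq(out, c, rcond=None)
        resid = c - out @ beta
        if (resid.T @ resid).item() / max((c.T @ c).item(), 1e-300) < _COLLINEAR_TOL:
            warnings.warn(f"{label} {j} collinear with covariates; dropped")
            continue
        out = np.hstack([out, c])
        kept.append(j)
    return out, kept


def assoc_scan(
    geno: GenotypeMatrix,
    y,
    X,
    grm: Grm | None,
    varcomp: VarianceComponents | None = None,
    conditioning_set=(),
    trait: str = "trait",
    chunk_size: int = 4096,
    null_model: NullModel | None = None,
    eig=None,
) -> pd.DataFrame:
    """Mixed-model association scan over every variant in ``geno``.

    Returns a DataFrame in the fixed sumstat schema (CHR POS ID A1 A2 FREQ
    BETA SE T P N).  ``conditioning_set`` is an iterable of variant indices
    whose dosages are appended to X as fixed covariates.  Monomorphic or
    conditioned-away variants get beta=0, p=1 and a ``flag`` mark.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    conditioning_set = list(conditioning_set)
    if conditioning_set:
        cond = geno.dosage[:, conditioning_set].astype(float)
        X, _ = _drop_collinear(X, cond)
    if null_model is None:
        nm = NullModel(y, X, None if grm is None else grm.values, eig=eig)
    else:
        nm = null_model
    if varcomp is None:
        varcomp = nm.varcomp or nm.fit()
    yw, Xw, sw = nm.whitened(varcomp)
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    yry = float(yr @ yr)
    n, p = nm.n, Xw.shape[1]
    dof = n - p - 1
    mask = nm.mask

    m = geno.n_variants
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    tval = np.zeros(m)
    flag = np.zeros(m, dtype=bool)
    freq = np.empty(m)
    for lo in range(0, m, chunk_size):
        hi = min(lo + chunk_size, m)
        W = np.asarray(geno.dosage[mask, lo:hi], dtype=float)
        freq[lo:hi] = W.mean(axis=0) / 2.0
        Wstar = W if nm.U is None else nm.U.T @ W
        Ww = Wstar * sw[:, None]
        Wr = Ww - Q @ (Q.T @ Ww)
        denom = np.einsum("ij,ij->j", Wr, Wr)
        ok = denom > _COLLINEAR_TOL * np.maximum(
            np.einsum("ij,ij->j", Ww, Ww), 1e-300)
        b = np.zeros(hi - lo)
        b[ok] = (Wr[:, ok].T @ yr) / denom[ok]
        rss = np.maximum(yry - b**2 * denom, 0.0)
        s2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(s2 / denom)
        beta[lo:hi] = b
        se[lo:hi][ok] = s[ok]
        tval[lo:hi][ok] = b[ok] / s[ok]
        flag[lo:hi] = ~ok
    pvals = 2.0 * stats.norm.sf(np.abs(tval))
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    pvals[flag] = 1.0
    out = pd.DataFrame({
        "CHR": geno.variants["chrom"].to_numpy(),
        "POS": geno.variants["pos"].to_numpy(),
        "ID": geno.variants["id"].to_numpy(),
        "A1": geno.variants["alt"].to_numpy(),
        "A2": geno.variants["ref"].to_numpy(),
        "FREQ": freq,
        "BETA": beta,
        "SE": se,
        "T": tval,
        "P": pvals,
        "N": n,
    })
    out.attrs["trait"] = trait
    out.attrs["n_flagged"] = int(flag.sum())
    return out[SUMSTAT_COLUMNS]


# ---------------------------------------------------------------------------
# FDR and inflation
# ---------------------------------------------------------------------------


def fdr_from_counts(p_threshold: float, n_significant: int, n_tested: int) -> float:
    """Closed-form FDR: P(1 - A/T) / ((A/T)(1 - P)), capped at 1.

    ``p_threshold`` = P, ``n_significant`` = A, ``n_tested`` = T.  A = 0 is
    defined as FDR 1 by convention (and logged).
    """
    P, A, T = float(p_threshold), int(n_significant), int(n_tested)
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < P < 1):
        raise ValueError("P must be in (0, 1)")
    if A == 0:
        logger.info("fdr_from_counts: A=0, returning 1 by convention")
        return 1.0
    frac = A / T
    return float(min(1.0, P * (1 - frac) / (frac * (1 - P))))


def truncate(x: float, decimals: int) -> float:
    """Truncate (not round) towards zero, matching printed report style."""
    f = 10 ** decimals
    return np.trunc(x * f) / f


def genomic_lambda(pvals) -> float:
    """Genomic-control lambda: median observed chi2(1) over its null median."""
    chi2 = stats.chi2.isf(np.asarray(pvals, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
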