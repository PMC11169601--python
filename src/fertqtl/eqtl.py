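"""Expression filtering, expression PCs, mixed-model cis/trans eQTL scans,
hierarchical (two-step Bonferroni) multiple-testing correction, trans
test-set construction, split-half reproducibility and TSS-distance profiles.

Per gene, expression (log2-CPM) is the response of the same mixed model used
for the trait GWAS: fixed covariates (contemporary group, lactation status,
weeks pregnant) plus the first q expression principal components, and a
random animal effect with GRM covariance.  cis windows are closed
(|pos - TSS| <= 2 Mb includes the boundary); the trans rule is strict
(> 5 Mb, same chromosome).

Multiple testing follows the two-step hierarchical Bonferroni: Step 1
multiplies each p-value by the number of variants in the gene's window
(locally adjusted p, capped at 1); Step 2 declares a gene an eGene when its
minimum locally adjusted p times the number of genes tested falls below
alpha.  Output labels call Step 2 "global-FDR" following common usage, but
the procedure is Bonferroni-style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import _COLLINEAR_TOL, Grm, NullModel

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 2_000_000
TRANS_MIN_BP = 5_000_000


@dataclass
class ExpressionData:
    """Filtered counts, log2-CPM, gene annotation, covariates and PCs."""

    counts: pd.DataFrame          # genes x samples
    annot: pd.DataFrame           # gene_id, chrom, tss, strand, start, end
    covariates: pd.DataFrame      # samples x covariates
    log_cpm: pd.DataFrame = None
    pcs: np.ndarray = None
    class_covariates: list = field(default_factory=lambda: ["contemp_group",
                                                            "lactation"])
    continuous_covariates: list = field(default_factory=lambda: ["weeks_pregnant"])

    @property
    def samples(self):
        return list(self.counts.columns)

    def design_matrix(self) -> np.ndarray:
        n = self.counts.shape[1]
        blocks = [np.ones((n, 1))]
        for c in self.class_covariates:
            if c in self.covariates.columns:
                d = pd.get_dummies(self.covariates[c].astype("category"),
                                   drop_first=True)
                blocks.append(d.to_numpy(dtype=float))
        for c in self.continuous_covariates:
            if c in self.covariates.columns:
                blocks.append(self.covariates[[c]].to_numpy(dtype=float))
        if self.pcs is not None and self.pcs.shape[1] > 0:
            blocks.append(self.pcs)
        return np.hstack(blocks)


# ---------------------------------------------------------------------------
# filtering and PCs
# ---------------------------------------------------------------------------


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts * (1e6 / lib)


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 3.0,
               max_low_prop: float = 0.25) -> pd.DataFrame:
    """Exclude a gene iff the fraction of samples with CPM < ``min_cpm`` is
    >= ``max_low_prop`` ("at least 25%" is inclusive)."""
    c = cpm(counts)
    low_prop = (c < min_cpm).mean(axis=1)
    keep = low_prop < max_low_prop
    logger.info("CPM filter: retained %d of %d genes", int(keep.sum()), len(keep))
    return counts.loc[keep]


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    return np.log2(cpm(counts) + 1.0)


def expression_pcs(log_cpm_df: pd.DataFrame, q: int = 4) -> np.ndarray:
    """First q principal components of the sample x gene log-CPM matrix,
    genes centred; deterministic sign (largest-magnitude loading positive)."""
    n = log_cpm_df.shape[1]
    if q >= n:
        raise ValueError("q must be smaller than the number of samples")
    if q == 0:
        return np.zeros((n, 0))
    M = log_cpm_df.to_numpy(dtype=float).T          # samples x genes
    M = M - M.mean(axis=0)
    Uv, s, Vt = np.linalg.svd(M, full_matrices=False)
    scores = Uv[:, :q] * s[:q]
    for j in range(q):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            scores[:, j] *= -1
    return scores


def prepare_expression(counts, annot, covariates, q_pcs: int = 4,
                       min_cpm: float = 3.0, max_low_prop: float = 0.25
                       ) -> ExpressionData:
    """CPM-filter, compute log2-CPM and expression PCs, align annotation."""
    filtered = cpm_filter(counts, min_cpm, max_low_prop)
    lc = log_cpm(filtered)
    expr = ExpressionData(counts=filtered,
                          annot=annot[annot["gene_id"].isin(filtered.index)]
                          .reset_index(drop=True),
                          covariates=covariates.loc[filtered.columns],
                          log_cpm=lc)
    expr.pcs = expression_pcs(lc, q=q_pcs)
    return expr


# ---------------------------------------------------------------------------
# mapping engine
# ---------------------------------------------------------------------------


class _Workspace:
    """Shared eigen-rotated state for scanning many genes against one panel."""

    def __init__(self, geno, grm, X):
        self.geno = geno
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        n = geno.n_samples
        if grm is None:
            self.d, self.U = np.zeros(n), None
            self.Dstar = np.asarray(geno.dosage, dtype=float)
            self.Xstar = self.X
        else:
            G = np.asarray(grm.values, dtype=float)
            d, U = np.linalg.eigh(G)
            self.d, self.U = np.clip(d, 0.0, None), U
            self.Dstar = U.T @ np.asarray(geno.dosage, dtype=float)
            self.Xstar = U.T @ self.X
        self.n, self.p = self.X.shape

    def scan_gene(self, y, cols):
        """REML fit for one gene, then fixed-ratio stats for ``cols``."""
        y = np.asarray(y, dtype=float)
        ystar = y if self.U is None else self.U.T @ y
        nm = NullModel.__new__(NullModel)
        nm.mask = np.ones(self.n, dtype=bool)
        nm.y, nm.X = y, self.X
        nm.n, nm.p = self.n, self.p
        nm.d, nm.U = self.d, self.U
        nm.ystar, nm.Xstar = ystar, self.Xstar
        nm.varcomp = None
        vc = nm.fit()
        yw, Xw, sw = nm.whitened(vc)
        Q, _ = np.linalg.qr(Xw)
        yr = yw - Q @ (Q.T @ yw)
        yry = float(yr @ yr)
        dof = self.n - self.p - 1
        Ww = self.Dstar[:, cols] * sw[:, None]
        Wr = Ww - Q @ (Q.T @ Ww)
        denom = np.einsum("ij,ij->j", Wr, Wr)
        ok = denom > _COLLINEAR_TOL * np.maximum(
            np.einsum("ij,ij->j", Ww, Ww), 1e-300)
        beta = np.zeros(len(cols))
        beta[ok] = (Wr[:, ok].T @ yr) / denom[ok]
        rss = np.maximum(yry - beta**2 * denom, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt((rss / dof) / denom)
        se[~ok] = np.inf
        t = np.where(ok, beta / np.where(ok, se, 1.0), 0.0)
        p = 2.0 * stats.norm.sf(np.abs(t))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        p[~ok] = 1.0
        return beta, se, t, p, vc


def _map_pairs(expr: ExpressionData, geno, grm, pair_fn, scope: str):
    """Run the per-gene mixed-model scan over variant sets given by pair_fn."""
    ws = _Workspace(geno, grm, expr.design_matrix())
    vpos = geno.variants["pos"].to_numpy()
    recs = []
    annot = expr.annot.set_index("gene_id")
    n_empty = 0
    for gid in expr.log_cpm.index:
        a = annot.loc[gid]
        cols = pair_fn(a)
        if len(cols) == 0:
            n_empty += 1
            continue
        beta, se, t, p, vc = ws.scan_gene(expr.log_cpm.loc[gid].to_numpy(), cols)
        sign = 1 if a["strand"] == "+" else -1
        dist = (vpos[cols] - int(a["tss"])) * sign
        recs.append(pd.DataFrame({
            "gene_id": gid,
            "variant_idx": cols,
            "CHR": geno.variants["chrom"].to_numpy()[cols],
            "POS": vpos[cols],
            "ID": geno.variants["id"].to_numpy()[cols],
            "BETA": beta, "SE": se, "T": t, "P": p,
            "tss_distance": dist,
            "scope": scope,
        }))
    if n_empty:
        logger.info("%d genes had no testable variants (%s)", n_empty, scope)
    if not recs:
        return pd.DataFrame(columns=["gene_id", "variant_idx", "CHR", "POS", "ID",
                                     "BETA", "SE", "T", "P", "tss_distance",
                                     "scope"])
    return pd.concat(recs, ignore_index=True)


def map_cis_eqtl(expr: ExpressionData, geno, grm: Grm | None,
                 window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Test every variant within the closed +-``window_bp`` window around each
    gene's TSS (same chromosome).  ``geno`` must already carry the eQTL panel
    filters (MAF > 0.05, accuracy > 0.4) and be aligned to the expression
    samples."""
    vchrom = geno.variants["chrom"].to_numpy().astype(str)
    vpos = geno.variants["pos"].to_numpy()

    def pairs(a):
        m = (vchrom == str(a["chrom"])) & (np.abs(vpos - int(a["tss"])) <= window_bp)
        return np.flatnonzero(m)

    return _map_pairs(expr, geno, grm, pairs, "cis")


def hierarchical_correction(records: pd.DataFrame, n_genes_tested: int,
                            alpha: float = 0.01):
    """Two-step hierarchical Bonferroni correction.

    Step 1: p_local = min(1, p * m_g) with m_g the gene's tested-variant
    count.  Step 2: a gene is an eGene iff min(p_local) * n_genes_tested <
    alpha; its significant eQTLs are variants with p_local * n_genes_tested <
    alpha.  Lead = smallest p, ties by |tss_distance| then position.

    Returns (egenes DataFrame with one lead row per eGene, significant-eQTL
    DataFrame with p_local/p_global columns).
    """
    genes = records["gene_id"].unique()
    if n_genes_tested < len(genes):
        raise ValueError("n_genes_tested smaller than number of genes in records")
    rec = records.copy()
    m_g = rec.groupby("gene_id")["P"].transform("size")
    rec["p_local"] = np.minimum(1.0, rec["P"] * m_g)
    rec["p_global"] = np.minimum(1.0, rec["p_local"] * n_genes_tested)
    sig = rec[rec["p_local"] * n_genes_tested < alpha].copy()
    lead_rows = []
    for gid, sub in rec.groupby("gene_id"):
        best = sub.sort_values(["P", "tss_distance", "POS"],
                               key=lambda s: np.abs(s) if s.name == "tss_distance"
                               else s).iloc[0]
        if best["p_local"] * n_genes_tested < alpha:
            row = best.copy()
            row["lead"] = True
            row["n_variants_tested"] = int(sub.shape[0])
            lead_rows.append(row)
    egenes = pd.DataFrame(lead_rows).reset_index(drop=True)
    if egenes.empty:
        egenes = pd.DataFrame(columns=list(rec.columns)
                              + ["lead", "n_variants_tested"])
    egenes.attrs["n_genes_tested"] = int(n_genes_tested)
    sig.attrs["n_genes_tested"] = int(n_genes_tested)
    return egenes, sig


def epercent(n_egenes: int, n_tested: int) -> float:
    """Percentage of tested genes that are eGenes (reports truncate to one
    decimal)."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if n_egenes > n_tested:
        raise ValueError("n_egenes cannot exceed n_tested")
    return 100.0 * n_egenes / n_tested


# ---------------------------------------------------------------------------
# trans
# ---------------------------------------------------------------------------


def select_trans_test_set(egenes: pd.DataFrame, gwas_hits, geno,
                          flank_bp: int = 100) -> np.ndarray:
    """Deduplicated union of lead cis-eQTLs, GWAS-significant variants, and
    every panel variant within +-``flank_bp`` of any of these."""
    seeds = set()
    if egenes is not None and len(egenes):
        seeds.update(int(i) for i in egenes["variant_idx"])
    seeds.update(int(i) for i in gwas_hits)
    if not seeds:
        return np.array([], dtype=int)
    vchrom = geno.variants["chrom"].to_numpy().astype(str)
    vpos = geno.variants["pos"].to_numpy()
    out = set(seeds)
    if flank_bp > 0:
        for s in seeds:
            near = (vchrom == vchrom[s]) & (np.abs(vpos - vpos[s]) <= flank_bp)
            out.update(np.flatnonzero(near).tolist())
    return np.array(sorted(out), dtype=int)


def map_trans_eqtl(test_set, expr: ExpressionData, geno, grm: Grm | None,
                   min_distance_bp: int = TRANS_MIN_BP, alpha: float = 0.01):
    """Same mixed model as cis, restricted to (variant, gene) pairs on the
    same chromosome with |pos - TSS| strictly greater than
    ``min_distance_bp``; hierarchical correction with m_g = the number of
    test-set variants tested for that gene."""
    test_set = np.asarray(test_set, dtype=int)
    if len(test_set) == 0:
        raise ValueError("empty trans test set")
    vchrom = geno.variants["chrom"].to_numpy().astype(str)
    vpos = geno.variants["pos"].to_numpy()

    def pairs(a):
        sub = test_set[(vchrom[test_set] == str(a["chrom"]))
                       & (np.abs(vpos[test_set] - int(a["tss"])) > min_distance_bp)]
        return sub

    records = _map_pairs(expr, geno, grm, pairs, "trans")
    genes_tested = records["gene_id"].nunique()
    if genes_tested == 0:
        return records, pd.DataFrame()
    egenes, _sig = hierarchical_correction(records, genes_tested, alpha=alpha)
    return records, egenes


# ---------------------------------------------------------------------------
# reproducibility and profiling
# ---------------------------------------------------------------------------


def split_half_reproducibility(counts, annot, covariates, geno, grm,
                               seed: int, q_pcs: int = 4, alpha: float = 0.01,
                               window_bp: int = CIS_WINDOW_BP):
    """Random half-split of the samples; full cis pipeline per half.

    Returns (proportion of half-1 eGenes that are eGenes in half-2, the
    reverse proportion, and the Pearson correlation of half-1 lead effects
    with the same (gene, variant) effects in half-2).
    """
    n = counts.shape[1]
    if n < 40:
        raise ValueError("need at least 40 samples for a half-split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = [np.sort(perm[: n // 2]), np.sort(perm[n // 2:])]
    results = []
    for idx in halves:
        sub_counts = counts.iloc[:, idx]
        sub_geno = geno.subset_samples(idx)
        sub_grm = None
        if grm is not None:
            sub_grm = Grm(samples=[grm.samples[i] for i in idx],
                          values=grm.values[np.ix_(idx, idx)],
                          n_variants_used=grm.n_variants_used)
        expr = prepare_expression(sub_counts, annot, covariates.iloc[idx],
                                  q_pcs=q_pcs)
        records = map_cis_eqtl(expr, sub_geno, sub_grm, window_bp=window_bp)
        n_genes = records["gene_id"].nunique()
        egenes, _ = hierarchical_correction(records, max(n_genes, 1), alpha=alpha)
        results.append((set(egenes["gene_id"]) if len(egenes) else set(),
                        egenes, records))
    set1, eg1, rec1 = results[0]
    set2, eg2, rec2 = results[1]
    prop_1in2 = len(set1 & set2) / len(set1) if set1 else float("nan")
    prop_2in1 = len(set1 & set2) / len(set2) if set2 else float("nan")
    corr = float("nan")
    if len(eg1):
        other = rec2.set_index(["gene_id", "variant_idx"])["BETA"]
        pairs = [(row["BETA"], other.get((row["gene_id"], row["variant_idx"])))
                 for _, row in eg1.iterrows()]
        pairs = [(a, b) for a, b in pairs if b is not None and np.isfinite(b)]
        if len(pairs) >= 3:
            a, b = zip(*pairs)
            corr = float(np.corrcoef(a, b)[0, 1])
    return prop_1in2, prop_2in1, corr


def tss_distance_profile(leads: pd.DataFrame, annot: pd.DataFrame = None,
                         bin_edges=(0, 50_000, 100_000, 250_000, 500_000,
                                    1_000_000, 2_000_000, np.inf)):
    """Binned counts/proportions of |lead TSS distance| and, when annotation
    is given, the fraction of leads falling within their gene body."""
    if leads is None or len(leads) == 0:
        raise ValueError("no lead records to profile")
    d = np.abs(leads["tss_distance"].to_numpy(dtype=float))
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(d, bins=edges)
    labels = [f"{int(edges[i])}-{'inf' if np.isinf(edges[i+1]) else int(edges[i+1])}"
              for i in range(len(edges) - 1)]
    out = pd.DataFrame({"bin": labels, "count": counts,
                        "proportion": counts / counts.sum()})
    if annot is not None:
        a = annot.set_index("gene_id")
        inside = 0
        for _, row in leads.iterrows():
            g = a.loc[row["gene_id"]]
            if g["start"] <= row["POS"] <= g["end"]:
                inside += 1
        out.attrs["in_gene_body_fraction"] = inside / len(leads)
    return out
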