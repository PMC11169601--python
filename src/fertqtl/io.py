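"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 1-based inclusive (the VCF convention).  BED input is
0-based half-open and is converted at the boundary, so a BED line
``chr1  10  20`` covers 1-based positions 11..20.

Genotypes are stored as dosages in [0, 2] (fractional dosages are accepted
when a DS field is present; otherwise hard GT calls are used).  Allele
frequencies are folded to minor-allele frequencies at read time; the effect
allele is tracked as A1 in summary statistics.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: fixed column schema for per-trait summary-statistic files
SUMSTAT_COLUMNS = ["CHR", "POS", "ID", "A1", "A2", "FREQ", "BETA", "SE", "T", "P", "N"]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "maf", "accuracy"]


def _open(path, mode="rt"):
    """Open a path with gzip transparency (suffix-based)."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant metadata.

    ``variants`` is a DataFrame with columns chrom, pos, id, ref, alt, maf,
    accuracy, sorted by (chrom, pos); ``dosage`` is an (n_samples, n_variants)
    float array with values in [0, 2].
    """

    samples: list
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples x variants")

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def n_variants(self):
        return len(self.variants)

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.samples,
            self.variants.iloc[idx].reset_index(drop=True),
            np.ascontiguousarray(self.dosage[:, idx]),
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        samples = [self.samples[i] for i in idx]
        geno = GenotypeMatrix(samples, self.variants, self.dosage[idx])
        return geno


@dataclass
class TraitTable:
    """Phenotypes plus fixed covariates, indexed by sample id.

    ``data`` holds one column per trait and covariate; missing phenotypes are
    NaN.  Class covariates are expanded to treatment-coded dummies when a
    design matrix is requested.
    """

    data: pd.DataFrame
    traits: list
    class_covariates: list = field(default_factory=list)
    continuous_covariates: list = field(default_factory=list)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicated sample ids in trait table")

    @property
    def samples(self):
        return list(self.data.index)

    def design_matrix(self, extra_columns=None) -> np.ndarray:
        """Intercept + class-covariate dummies + continuous covariates."""
        n = len(self.data)
        blocks = [np.ones((n, 1))]
        for c in self.class_covariates:
            d = pd.get_dummies(self.data[c].astype("category"), drop_first=True)
            blocks.append(d.to_numpy(dtype=float))
        for c in self.continuous_covariates:
            blocks.append(self.data[[c]].to_numpy(dtype=float))
        if extra_columns is not None:
            blocks.append(np.asarray(extra_columns, dtype=float))
        return np.hstack(blocks)


@dataclass
class IntervalSet:
    """Labelled genomic intervals held 1-based inclusive, queried via trees.

    Overlapping intervals of the same category are retained as-is; overlap is
    resolved at query time.
    """

    table: pd.DataFrame  # columns: category, chrom, start, end (1-based inclusive)

    def __post_init__(self):
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            raise ValueError("interval with start > end")
        if (self.table["category"].astype(str) == "").any():
            raise ValueError("empty category label")
        self._trees = {}
        for (cat, chrom), sub in self.table.groupby(["category", "chrom"]):
            # IntervalTree is half-open; +1 on end restores inclusivity
            self._trees[(cat, chrom)] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"] + 1)
            )

    @property
    def categories(self):
        return sorted(self.table["category"].unique())

    def contains(self, category, chrom, pos) -> bool:
        """Is 1-based position ``pos`` inside any interval of ``category``?"""
        tree = self._trees.get((category, chrom))
        return bool(tree is not None and tree.overlaps_point(pos))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path, accuracy_key="DR2"):
    """Write a GenotypeMatrix as VCF v4.2 with GT and DS fields.

    Imputation accuracy goes into the INFO field under ``accuracy_key``.
    """
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={accuracy_key},Number=1,Type=Float,'
                 'Description="Imputation accuracy">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(geno.variants["chrom"]):
            sub = geno.variants[geno.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.samples)) + "\n")
        dos = geno.dosage
        for j, row in enumerate(geno.variants.itertuples(index=False)):
            af = float(np.mean(dos[:, j])) / 2.0
            info = f"AF={af:.6g};{accuracy_key}={row.accuracy:.4g}"
            fields = [str(row.chrom), str(int(row.pos)), str(row.id),
                      row.ref, row.alt, ".", "PASS", info, "GT:DS"]
            col = dos[:, j]
            gts = np.rint(col).astype(int)
            cells = [f"{'0/0' if g == 0 else ('0/1' if g == 1 else '1/1')}:{d:.4g}"
                     for g, d in zip(gts, col)]
            fh.write("\t".join(fields + cells) + "\n")


def read_genotypes(path, maf_min=0.0, acc_min=0.0, accuracy_key="DR2") -> GenotypeMatrix:
    """Read genotypes from VCF v4.2 or the dosage-TSV dialect.

    Variants with folded MAF below ``maf_min`` or imputation accuracy not
    strictly greater than ``acc_min`` are dropped (the accuracy filter is
    strict: a variant at exactly ``acc_min`` is removed).  Multi-allelic
    records are skipped with a warning.
    """
    path = str(path)
    if path.endswith((".tsv", ".tsv.gz", ".txt")):
        geno = _read_dosage_tsv(path)
    else:
        geno = _read_vcf(path, accuracy_key)
    n0 = geno.n_variants
    keep = (geno.variants["maf"].to_numpy() >= maf_min) & (
        geno.variants["accuracy"].to_numpy() > acc_min
    )
    geno = geno.subset_variants(np.flatnonzero(keep))
    logger.info("read %d variants, retained %d after MAF>=%g and accuracy>%g",
                n0, geno.n_variants, maf_min, acc_min)
    return geno


def _read_vcf(path, accuracy_key):
    import pysam

    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        rows, cols = [], []
        for i, rec in enumerate(vf):
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(f"skipping multi-allelic record at {rec.chrom}:{rec.pos}")
                continue
            try:
                acc = float(rec.info.get(accuracy_key, 1.0))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed INFO at line for {rec.chrom}:{rec.pos}") from exc
            ds = np.empty(len(samples))
            for k, s in enumerate(samples):
                fmt = rec.samples[s]
                if "DS" in fmt and fmt["DS"] is not None:
                    ds[k] = float(fmt["DS"])
                else:
                    gt = fmt["GT"]
                    ds[k] = sum(1 for a in gt if a)
            af = float(np.mean(ds)) / 2.0
            rows.append((rec.chrom, rec.pos, rec.id or f"var{i}",
                         rec.ref, rec.alts[0], min(af, 1 - af), acc))
            cols.append(ds)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = np.column_stack(cols) if cols else np.zeros((len(samples), 0))
    order = np.lexsort((variants["pos"], variants["chrom"]))
    variants = variants.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(samples, variants, np.ascontiguousarray(dosage[:, order]))


def write_dosage_tsv(geno: GenotypeMatrix, path):
    """Dosage-TSV dialect: variant metadata columns then one column per sample."""
    dos = pd.DataFrame(np.asarray(geno.dosage).T,
                       columns=[str(s) for s in geno.samples])
    df = pd.concat([geno.variants.reset_index(drop=True), dos], axis=1)
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def _read_dosage_tsv(path):
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", na_values=".")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns: {missing}")
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    variants = df[VARIANT_COLUMNS].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    dosage = df[samples].to_numpy(dtype=float).T
    order = np.lexsort((variants["pos"], variants["chrom"]))
    variants = variants.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(samples, variants, np.ascontiguousarray(dosage[:, order]))


# ---------------------------------------------------------------------------
# trait table / annotation / intervals
# ---------------------------------------------------------------------------


def write_trait_table(tt: TraitTable, path):
    with _open(path, "wt") as fh:
        fh.write(f"# traits: {','.join(tt.traits)}\n")
        fh.write(f"# class_covariates: {','.join(tt.class_covariates)}\n")
        fh.write(f"# continuous_covariates: {','.join(tt.continuous_covariates)}\n")
        tt.data.to_csv(fh, sep="\t", na_rep=".", index_label="sample_id")


def read_trait_table(path) -> TraitTable:
    meta = {}
    with _open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                meta[key.strip()] = [v for v in val.strip().split(",") if v]
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        data = pd.read_csv(fh, sep="\t", na_values=".", index_col="sample_id")
    return TraitTable(
        data,
        traits=meta.get("traits", []),
        class_covariates=meta.get("class_covariates", []),
        continuous_covariates=meta.get("continuous_covariates", []),
    )


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, tss, strand, start, end (1-based)."""
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "chrom", "tss", "strand", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if (df["start"] > df["end"]).any():
        raise ValueError("gene with start > end")
    return df


def write_annotation(df: pd.DataFrame, path):
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_intervals(path) -> IntervalSet:
    """Read a BED file (0-based half-open); name column = category."""
    rows = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"BED line {ln}: start >= end")
            category = parts[3] if len(parts) > 3 else "interval"
            rows.append((category, chrom, start + 1, end))  # to 1-based inclusive
    return IntervalSet(pd.DataFrame(rows, columns=["category", "chrom", "start", "end"]))


def write_intervals(iset: IntervalSet, path):
    """Write an IntervalSet back out as BED (0-based half-open)."""
    with _open(path, "wt") as fh:
        for row in iset.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.category}\n")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def write_summary_stats(df: pd.DataFrame, path):
    """Write one trait's association records in the fixed sumstat schema."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    with _open(path, "wt") as fh:
        df[SUMSTAT_COLUMNS].to_csv(fh, sep="\t", index=False, na_rep=".",
                                   float_format="%.15g")


def read_summary_stats(path) -> pd.DataFrame:
    with _open(path) as fh:
        df = pd.read_csv(fh, sep="\t", na_values=".", dtype={"CHR": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# GRM triplet
# ---------------------------------------------------------------------------


def write_grm(grm, prefix):
    """Persist a GRM as a text triplet: <prefix>.grm.id and <prefix>.grm.tsv
    (lower triangle: i, j, value)."""
    with _open(f"{prefix}.grm.id", "wt") as fh:
        for s in grm.samples:
            fh.write(f"{s}\n")
    n = len(grm.samples)
    with _open(f"{prefix}.grm.tsv", "wt") as fh:
        fh.write(f"# n_variants_used: {grm.n_variants_used}\n")
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i}\t{j}\t{grm.values[i, j]:.15g}\n")


def read_grm(prefix):
    from .lmm import Grm

    with _open(f"{prefix}.grm.id") as fh:
        samples = [line.strip() for line in fh if line.strip()]
    n = len(samples)
    values = np.zeros((n, n))
    n_used = 0
    with _open(f"{prefix}.grm.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                n_used = int(line.split(":")[1])
                continue
            i, j, v = line.split("\t")
            values[int(i), int(j)] = values[int(j), int(i)] = float(v)
    return Grm(samples=samples, values=values, n_variants_used=n_used)
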