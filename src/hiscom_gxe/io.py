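"""Genotype/phenotype containers, file readers, QC filters and SNP-to-gene mapping.

Genotypes are held as an N x K additive-dosage matrix (counts of the
alternate/minor allele, ``{0, 1, 2}``) with ``NaN`` as the missing sentinel.
Supported on-disk formats: plain dosage TSV, VCF (biallelic SNVs, GT field,
via cyvcf2) and PLINK bed/bim/fam.  All genomic coordinates are 1-based
inclusive internally; BED annotation input (0-based half-open) is converted
on read.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CHROM_POS_ID = re.compile(r"^(?:chr)?([0-9XYM]+)[:_](\d+)")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based bp
    id: str


@dataclass
class GenotypeMatrix:
    """N x K additive genotype matrix with per-column variant metadata.

    ``values`` stores alternate-allele counts as floats; missing genotypes
    are ``NaN``.  After :func:`apply_qc`, columns are missing-free
    (mean-imputed) and imputed entries are generally non-integral.
    """

    values: np.ndarray
    variants: list[VariantRecord]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("genotype values must be a 2-D matrix")
        n, k = self.values.shape
        if len(self.variants) != k:
            raise DataError(
                f"{k} genotype columns but {len(self.variants)} variant records"
            )
        if len(self.samples) != n:
            raise DataError(f"{n} genotype rows but {len(self.samples)} sample ids")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            # tolerate imputed dosages only if flagged by provenance: raw
            # construction must be hard calls
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
            if not getattr(self, "_allow_dosage", False):
                raise DataError(
                    f"non-{{0,1,2}} genotype value(s) present, e.g. {bad[0]!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def maf(self) -> np.ndarray:
        """Per-column minor allele frequency from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.values, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=0)

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        g = GenotypeMatrix.__new__(GenotypeMatrix)
        g.values = self.values[:, idx]
        g.variants = [self.variants[int(i)] for i in idx]
        g.samples = list(self.samples)
        g._allow_dosage = True
        return g


@dataclass
class PhenoTable:
    """Aligned quantitative phenotype, environment variable and covariates."""

    y: np.ndarray
    z: np.ndarray
    C: np.ndarray | None = None
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.z = np.asarray(self.z, dtype=float).ravel()
        n = self.y.size
        if self.z.size != n:
            raise DataError("phenotype and environment lengths differ")
        if self.C is not None:
            self.C = np.asarray(self.C, dtype=float)
            if self.C.ndim == 1:
                self.C = self.C[:, None]
            if self.C.shape[0] != n:
                raise DataError("covariate row count differs from phenotype length")
            if np.isnan(self.C).any():
                raise DataError("missing values in covariates")
        if np.isnan(self.y).any() or np.isnan(self.z).any():
            raise DataError("missing values in phenotype or environment")
        if self.samples is not None and len(self.samples) != n:
            raise DataError("sample id count differs from phenotype length")


@dataclass
class GeneSet:
    """A gene interval plus the genotype-matrix columns mapped to it."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    snp_indices: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers


def _variant_from_id(vid: str, ordinal: int) -> VariantRecord:
    m = _CHROM_POS_ID.match(vid)
    if m:
        return VariantRecord(chrom=m.group(1), pos=int(m.group(2)), id=vid)
    return VariantRecord(chrom="0", pos=ordinal + 1, id=vid)


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a plain dosage table: header = variant ids, first column = sample id.

    Entries must be 0/1/2 or empty/NA for missing.  Variant ids of the form
    ``chrom:pos`` (or ``chrom_pos``) populate genomic coordinates; otherwise
    placeholder coordinates are used.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse dosage TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"dosage TSV {path} has no variant columns")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = df.isna().to_numpy()
    bad = np.isnan(vals) & ~raw_na & (df != "NA").to_numpy() & (df != "").to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"dosage TSV {path}: non-numeric entry {df.iat[i, j]!r} "
            f"at sample {df.index[i]!r}, variant {df.columns[j]!r}"
        )
    variants = [_variant_from_id(str(v), j) for j, v in enumerate(df.columns)]
    return GenotypeMatrix(vals, variants, [str(s) for s in df.index])


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as a dosage TSV (round-trips with the reader)."""
    df = pd.DataFrame(
        G.values, index=G.samples, columns=[v.id for v in G.variants]
    )
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)) if v == int(v) else str(v))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF; non-biallelic records are skipped.

    Additive coding counts the alternate allele per the GT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping non-biallelic variant %s at %s:%d",
                rec.ID or ".", rec.CHROM, rec.POS,
            )
            continue
        g = np.asarray(rec.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        g[g == 3] = np.nan
        cols.append(g)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantRecord(chrom=str(rec.CHROM), pos=int(rec.POS), id=vid))
    if n_skipped:
        logger.warning("skipped %d non-biallelic variant(s) in %s", n_skipped, path)
    if not cols:
        raise DataError(f"no biallelic variants found in {path}")
    return GenotypeMatrix(np.column_stack(cols), variants, samples)


def read_plink_bed(path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam trio.  ``path`` may omit the .bed extension.

    Additive coding counts the A1 allele of the .bim file (PLINK's default
    A1 is the minor allele).  Only SNP-major .bed files are supported.
    """
    from pathlib import Path

    stem = Path(str(path))
    if stem.suffix == ".bed":
        stem = stem.with_suffix("")
    bim = pd.read_csv(
        stem.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    fam = pd.read_csv(
        stem.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    n, k = len(fam), len(bim)
    raw = np.fromfile(stem.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise DataError(f"{stem}.bed is not a PLINK .bed file")
    if raw[2] != 0x01:
        raise DataError(f"{stem}.bed is not SNP-major; re-export with modern PLINK")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * k:
        raise DataError(
            f"{stem}.bed length inconsistent with {n} samples x {k} variants"
        )
    codes = body.reshape(k, bytes_per_snp)
    # unpack 2-bit genotypes, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(k, -1)[:, :n]  # K x N
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    vals = lut[two_bit].T  # N x K
    variants = [
        VariantRecord(chrom=str(r.chrom), pos=int(r.pos), id=str(r.id))
        for r in bim.itertuples()
    ]
    return GenotypeMatrix(vals, variants, [str(i) for i in fam["iid"]])


_READERS = {"dosage-tsv": read_dosage_tsv, "vcf": read_vcf, "plink-bed": read_plink_bed}


def read_genotypes(path, format: str = "dosage-tsv") -> GenotypeMatrix:
    """Read genotypes in one of ``{vcf, plink-bed, dosage-tsv}``."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown genotype format {format!r}; expected one of {sorted(_READERS)}"
        ) from None
    return reader(path)


def read_pheno_table(
    path, y_col: str, z_col: str, covariate_cols: list[str] | None = None
) -> PhenoTable:
    """Read phenotype/environment/covariates from a single TSV by column name."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    missing = [c for c in [y_col, z_col, *(covariate_cols or [])] if c not in df.columns]
    if missing:
        raise DataError(f"pheno table {path} lacks column(s): {missing}")
    C = df[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
    return PhenoTable(
        y=df[y_col].to_numpy(dtype=float),
        z=df[z_col].to_numpy(dtype=float),
        C=C,
        samples=[str(s) for s in df.index],
    )


# ---------------------------------------------------------------------------
# QC


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Enumerates the full conditional distribution of the heterozygote count
    given the minor-allele count and sample size; the p-value sums the
    probabilities of all heterozygote counts no more likely than the
    observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        math.lgamma(n + 1)
        - np.array([math.lgamma(h + 1) for h in hets])
        - np.array([math.lgamma(r + 1) for r in rare_hom])
        - np.array([math.lgamma(c + 1) for c in common_hom])
        + hets * math.log(2)
        + math.lgamma(n_rare + 1)
        + math.lgamma(2 * n - n_rare + 1)
        - math.lgamma(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    hwe_min: float = 1e-6,
) -> GenotypeMatrix:
    """Filter variants and mean-impute remaining missing genotypes.

    A column is retained iff MAF > ``maf_min``, missing fraction <=
    ``miss_max`` and exact-HWE p > ``hwe_min``.  HWE counts use only exact
    hard calls (entries equal to 0, 1 or 2), so the operation is idempotent
    after imputation.  Mean imputation preserves each column's observed mean.
    """
    vals = G.values
    miss = np.isnan(vals).mean(axis=0)
    maf = G.maf()
    hwe_p = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        col = vals[:, j]
        hard = col[np.isin(col, (0.0, 1.0, 2.0))]
        hwe_p[j] = hwe_exact_test(
            int((hard == 0).sum()), int((hard == 1).sum()), int((hard == 2).sum())
        )
    keep = (maf > maf_min) & (miss <= miss_max) & (hwe_p > hwe_min)
    logger.info(
        "QC: %d/%d variants retained (%d failed MAF<=%.3g, %d missing>%.3g, "
        "%d HWE p<=%.3g)",
        keep.sum(), keep.size,
        int((maf <= maf_min).sum()), maf_min,
        int((miss > miss_max).sum()), miss_max,
        int((hwe_p <= hwe_min).sum()), hwe_min,
    )
    if not keep.any():
        raise DataError("all variants removed by QC")
    out = G.subset_variants(np.flatnonzero(keep))
    vals = out.values.copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        m = np.isnan(col)
        if m.any():
            col[m] = col[~m].mean()
    out.values = vals
    return out


# ---------------------------------------------------------------------------
# gene mapping


def read_gene_annotation(path, format: str = "bed") -> list[GeneSet]:
    """Read gene intervals from BED4 (0-based half-open) or TSV (1-based).

    The TSV dialect expects a header with columns gene_id, chrom, start, end
    where start/end are 1-based inclusive.
    """
    genes: list[GeneSet] = []
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=range(4), dtype=str,
        )
        for r in df.itertuples():
            genes.append(
                GeneSet(str(r.name), str(r.chrom), int(r.start) + 1, int(r.end))
            )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(df.columns):
            raise DataError(f"gene TSV {path} lacks column(s): {need - set(df.columns)}")
        for r in df.itertuples():
            genes.append(GeneSet(str(r.gene_id), str(r.chrom), int(r.start), int(r.end)))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    for g in genes:
        if g.end < g.start:
            raise DataError(f"gene {g.gene_id}: end < start")
    return genes


def map_snps_to_genes(
    variants: list[VariantRecord],
    genes: list[GeneSet],
    flank: int = 20_000,
) -> list[GeneSet]:
    """Assign SNPs to genes within the gene body plus a symmetric flank.

    A SNP belongs to a gene iff it is on the same chromosome and
    ``start - flank <= pos <= end + flank`` (inclusive boundaries).  A SNP
    may map to several overlapping genes; genes that collect no SNPs are
    omitted from the output.
    """
    chroms = np.array([v.chrom for v in variants])
    pos = np.array([v.pos for v in variants], dtype=np.int64)
    out: list[GeneSet] = []
    for g in genes:
        mask = (chroms == g.chrom) & (pos >= g.start - flank) & (pos <= g.end + flank)
        idx = np.flatnonzero(mask)
        if idx.size:
            out.append(replace(g, snp_indices=[int(i) for i in idx]))
    return out
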