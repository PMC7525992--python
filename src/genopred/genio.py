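"""Genotype and phenotype containers plus PLINK bed/bim/fam and TSV I/O.

Genotypes are stored as allele counts of the .bim A1 allele in an
``int8`` matrix (individuals x SNPs) with ``-1`` marking missing calls.
Coordinates follow .bim convention: 1-based inclusive base-pair
positions; all array indexing elsewhere in the package is 0-based, and
the conversion is confined to this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: 2-bit PLINK bed codes (SNP-major) -> A1 allele count; 0b01 is missing.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


class IntegrityError(ValueError):
    """Raised when file dimensions or cross-references disagree."""


class ConfigError(ValueError):
    """Raised for invalid user-supplied configuration, naming the field."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with per-SNP metadata.

    Attributes
    ----------
    values : ndarray of int8, shape (n, m)
        Counts of the reference (A1) allele in {0, 1, 2}; -1 = missing.
    snp_meta : DataFrame
        Columns ``id, chrom, bp, allele_ref, allele_alt, freq``; sorted by
        (chrom, bp); ``freq`` is the observed A1 frequency ignoring missing
        calls (NaN for an all-missing SNP).
    sample_ids : ndarray of str
    """

    values: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise IntegrityError("genotype values must be 2-D (individuals x SNPs)")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise IntegrityError(
                f"{len(self.sample_ids)} sample ids for {n} genotype rows"
            )
        if len(self.snp_meta) != m:
            raise IntegrityError(f"{len(self.snp_meta)} SNP records for {m} columns")
        if self.snp_meta["id"].duplicated().any():
            raise IntegrityError("duplicate SNP ids")
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise IntegrityError("genotype codes outside {0,1,2,missing}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["id"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Observed A1 allele frequency per SNP, ignoring missing calls.

        An all-missing SNP gets NaN (frequency undefined)."""
        observed = self.values != MISSING
        counts = observed.sum(axis=0).astype(float)
        totals = np.where(observed, self.values, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, totals / (2.0 * counts), np.nan)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        """Return a new matrix restricted to ``snp_ids`` (genomic order kept)."""
        wanted = set(np.asarray(snp_ids, dtype=object))
        missing_ids = wanted - set(self.snp_meta["id"])
        if missing_ids:
            raise KeyError(f"SNP ids not in panel: {sorted(missing_ids)[:5]} ...")
        mask = self.snp_meta["id"].isin(wanted).to_numpy()
        return GenotypeMatrix(
            values=self.values[:, mask].copy(),
            snp_meta=self.snp_meta.loc[mask].reset_index(drop=True),
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            values=self.values[indices].copy(),
            snp_meta=self.snp_meta.copy(),
            sample_ids=self.sample_ids[indices],
        )

    def with_recomputed_freq(self) -> "GenotypeMatrix":
        meta = self.snp_meta.copy()
        meta["freq"] = self.allele_freq()
        return replace(self, snp_meta=meta)


@dataclass
class PhenotypeTable:
    """Per-sample trait values and categorical covariates."""

    data: pd.DataFrame
    trait_cols: list = field(default_factory=list)
    factor_cols: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if "id" not in self.data.columns:
            raise IntegrityError("phenotype table needs an 'id' column")
        if self.data["id"].duplicated().any():
            raise IntegrityError("duplicate sample ids in phenotype table")
        for t in self.trait_cols:
            if not np.issubdtype(self.data[t].dtype, np.number):
                raise IntegrityError(f"trait column {t!r} is not numeric")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["id"].to_numpy()


def _snp_meta(ids, chrom, bp, a1, a2, freq) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "bp": np.asarray(bp, dtype=np.int64),
            "allele_ref": np.asarray(a1, dtype=object),
            "allele_alt": np.asarray(a2, dtype=object),
            "freq": np.asarray(freq, dtype=float),
        }
    )
    order = np.lexsort((meta["bp"].to_numpy(), meta["chrom"].astype(str).to_numpy()))
    if not np.array_equal(order, np.arange(len(meta))):
        raise IntegrityError("snp_meta must be sorted by (chrom, bp)")
    return meta


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet (bed v1.0, SNP-major).

    Returns counts of the .bim A1 allele; sample order follows the .fam.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing {prefix.with_suffix(ext)}")

    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes {raw[:3].hex()} "
            f"(expected {_BED_MAGIC.hex()}: bed v1.0 SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise IntegrityError(
            f".bed payload is {body.size} bytes; expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    values = _BED_DECODE[codes].T  # individuals x SNPs

    gm = GenotypeMatrix(
        values=values,
        snp_meta=_snp_meta(
            bim["id"], bim["chrom"], bim["bp"], bim["a1"], bim["a2"],
            np.full(m, np.nan),
        ),
        sample_ids=fam["iid"].to_numpy(dtype=object),
    )
    return gm.with_recomputed_freq()


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a bit-exact PLINK bed v1.0 (SNP-major) triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.values.shape

    fam = pd.DataFrame(
        {
            "fid": g.sample_ids,
            "iid": g.sample_ids,
            "father": "0",
            "mother": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": g.snp_meta["chrom"],
            "id": g.snp_meta["id"],
            "cm": 0,
            "bp": g.snp_meta["bp"],
            "a1": g.snp_meta["allele_ref"],
            "a2": g.snp_meta["allele_alt"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    code_lut = np.zeros(4, dtype=np.uint8)
    for count, code in _BED_ENCODE.items():
        code_lut[count % 4] = code  # -1 % 4 == 3 slots missing at index 3
    codes = code_lut[g.values.T % 4].astype(np.uint8)  # SNP-major
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded.reshape(m, bytes_per_snp, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    ).sum(axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_phenotypes(path, trait_cols=None, factor_cols=None) -> PhenotypeTable:
    data = pd.read_csv(path, sep="\t", dtype={"id": str})
    trait_cols = list(trait_cols or [])
    factor_cols = list(factor_cols or [])
    return PhenotypeTable(data=data, trait_cols=trait_cols, factor_cols=factor_cols)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pheno.data.to_csv(path, sep="\t", index=False)


def hwe_exact_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Hardy-Weinberg exact test p-value per SNP (mid-less Levene-Haldane).

    Uses the exact conditional distribution of heterozygote counts given
    the minor-allele count; SNPs with no observed genotypes get NaN.
    """
    pvals = np.ones(g.n_snps)
    vals = g.values
    for j in range(g.n_snps):
        col = vals[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            pvals[j] = np.nan
            continue
        n_het = int(np.sum(obs == 1))
        n_hom1 = int(np.sum(obs == 2))
        n_hom2 = int(np.sum(obs == 0))
        pvals[j] = _hwe_exact(n_het, n_hom1, n_hom2)
    return pvals


def _hwe_exact(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Wigginton-Cutler-Abecasis exact HWE test on genotype counts."""
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0 or rare == 0:
        return 1.0
    # recurrence over possible heterozygote counts with the rare-allele total
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h <= rare - 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / total
    return min(1.0, sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)) / total)


@dataclass
class QcReport:
    n_snps_removed_maf: int = 0
    n_snps_removed_hwe: int = 0
    n_snps_removed_missing: int = 0
    n_samples_removed: int = 0


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing_per_sample: float = 0.05,
    hwe_p_min: float | None = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Quality-control filter: drop low-MAF / HWE-failing SNPs and
    high-missingness samples, then recompute allele frequencies.

    Defaults mirror common array-QC practice: MAF < 0.01, HWE exact
    p < 1e-6, samples with > 5% missing genotypes removed. Pass
    ``hwe_p_min=None`` to skip the HWE step.
    """
    if not (0 <= maf_min <= 1 and 0 <= max_missing_per_sample <= 1):
        raise ConfigError("maf_min and max_missing_per_sample must lie in [0,1]")
    report = QcReport()

    sample_missing = np.mean(g.values == MISSING, axis=1)
    keep_samples = sample_missing <= max_missing_per_sample
    report.n_samples_removed = int(np.sum(~keep_samples))
    if report.n_samples_removed:
        g = g.subset_samples(np.where(keep_samples)[0])

    freq = g.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    keep = np.isfinite(maf) & (maf >= maf_min) if maf_min > 0 else np.isfinite(maf)
    all_missing = ~np.isfinite(freq)
    keep = keep & ~all_missing
    report.n_snps_removed_missing = int(all_missing.sum())
    report.n_snps_removed_maf = int(np.sum(~keep) - all_missing.sum())

    if hwe_p_min is not None:
        hwe_p = hwe_exact_pvalues(g)
        fails = np.isfinite(hwe_p) & (hwe_p < hwe_p_min) & keep
        report.n_snps_removed_hwe = int(fails.sum())
        keep = keep & ~fails

    if not keep.any():
        raise ValueError("QC removed every SNP: empty panel")
    out = GenotypeMatrix(
        values=g.values[:, keep].copy(),
        snp_meta=g.snp_meta.loc[keep].reset_index(drop=True),
        sample_ids=g.sample_ids,
    ).with_recomputed_freq()
    logger.info(
        "QC: removed %d SNPs (MAF), %d (HWE), %d (all-missing), %d samples",
        report.n_snps_removed_maf,
        report.n_snps_removed_hwe,
        report.n_snps_removed_missing,
        report.n_samples_removed,
    )
    return out, report


def mean_impute(g: GenotypeMatrix) -> np.ndarray:
    """Float genotype matrix with missing calls replaced by 2p (per SNP).

    Imputation happens only at model entry (GRM / SNP regression); the
    stored integer matrix is never modified.
    """
    x = g.values.astype(np.float64)
    if (g.values == MISSING).any():
        fill = 2.0 * g.allele_freq()
        miss = g.values == MISSING
        x[miss] = np.broadcast_to(fill, x.shape)[miss]
    return x
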