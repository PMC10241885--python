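"""Reading, filtering and orienting genotype/phenotype data; file formats.

Formats handled here:

* genotype TSV — header row of SNP ids, first column the sample id,
  cells in {0, 1, 2, NA};
* VCF — biallelic sites only, genotype = number of ALT alleles from the
  GT field, missing or half calls treated as missing;
* phenotype TSV — two columns, sample id and 0/1 status (1 = case);
* counts TSV — columns snp_id, r0, r1, r2, s0, s1, s2, is_active;
* results TSV — ranked screening output (see :func:`write_results_tsv`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .screening import ScreeningResult
from .simulate import SimulatedDataset
from .stats import counts_matrix_from_genotypes, omega_matrix, nu_vector

__all__ = [
    "GenotypeDataset",
    "FilterReport",
    "read_genotypes",
    "read_genotype_tsv",
    "read_vcf",
    "read_phenotypes",
    "filter_snps",
    "orient_minor_allele",
    "write_genotype_tsv",
    "write_phenotype_tsv",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_results_tsv",
]

logger = logging.getLogger("snpscreen")


@dataclass
class GenotypeDataset:
    """Sample-level genotypes (samples x SNPs, NaN = missing) + phenotype."""

    snp_ids: List[str]
    sample_ids: List[str]
    genotypes: np.ndarray  # float64, entries in {0, 1, 2, NaN}
    phenotypes: np.ndarray  # int, {0, 1}

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n or len(self.phenotypes) != n:
            raise ValueError("sample ids / phenotypes must match genotype rows")
        if len(self.snp_ids) != m:
            raise ValueError("snp ids must match genotype columns")
        observed = self.genotypes[np.isfinite(self.genotypes)]
        if not np.isin(observed, (0, 1, 2)).all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        if not np.isin(self.phenotypes, (0, 1)).all():
            raise ValueError("phenotype entries must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def missing_counts(self) -> np.ndarray:
        return (~np.isfinite(self.genotypes)).sum(axis=0)

    def observed_class_counts(self) -> np.ndarray:
        """Number of distinct observed genotype values per SNP."""
        return sum(
            np.any(self.genotypes == g, axis=0).astype(int) for g in (0, 1, 2)
        )

    def count_tables(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-SNP (case, control) 2x3 count matrices, complete-case."""
        return counts_matrix_from_genotypes(self.genotypes, self.phenotypes)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    removed_missing: int
    removed_two_genotypes: int
    n_kept: int


def read_phenotypes(path) -> pd.Series:
    """Two-column TSV (sample id, 0/1 status); a header row is tolerated."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"phenotype file {path} must have exactly two columns")
    if not df.iloc[0, 1].strip() in ("0", "1"):  # header row
        df = df.iloc[1:]
    status = pd.to_numeric(df.iloc[:, 1], errors="raise").astype(int)
    if not status.isin((0, 1)).all():
        raise ValueError(f"phenotype status values in {path} must be 0 or 1")
    return pd.Series(status.values, index=df.iloc[:, 0].str.strip().values)


def read_genotype_tsv(path) -> Tuple[List[str], List[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    try:
        genotypes = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed genotype cell in {path}: {exc}") from None
    observed = genotypes[np.isfinite(genotypes)]
    if not np.isin(observed, (0, 1, 2)).all():
        bad = observed[~np.isin(observed, (0, 1, 2))][0]
        raise ValueError(f"malformed genotype cell in {path}: {bad!r}")
    return list(df.columns), [str(i) for i in df.index], genotypes


def read_vcf(path) -> Tuple[List[str], List[str], np.ndarray]:
    """Genotypes from a VCF via cyvcf2: ALT-allele count from the GT field.

    Multi-allelic records are skipped with a warning; missing and half
    calls become NaN.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%s", variant.CHROM, variant.POS
            )
            continue
        col = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue  # missing or half call
            col[i] = sum(1 for a in alleles if a == 1)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    vcf.close()
    genotypes = (
        np.stack(columns, axis=1) if columns else np.empty((len(sample_ids), 0))
    )
    return snp_ids, sample_ids, genotypes


def read_genotypes(path, fmt: str = "tsv", phenotype_path=None) -> GenotypeDataset:
    """Load a genotype matrix plus phenotypes joined by sample id."""
    if fmt == "tsv":
        snp_ids, sample_ids, genotypes = read_genotype_tsv(path)
    elif fmt == "vcf":
        snp_ids, sample_ids, genotypes = read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}; expected tsv or vcf")
    if phenotype_path is None:
        raise ValueError("a phenotype file is required")
    pheno = read_phenotypes(phenotype_path)
    unknown = set(pheno.index) - set(sample_ids)
    if unknown:
        raise ValueError(
            f"phenotype file lists sample ids absent from the genotype data: "
            f"{sorted(unknown)[:5]}"
        )
    keep = [i for i, sid in enumerate(sample_ids) if sid in pheno.index]
    if not keep:
        raise ValueError("no overlap between genotype and phenotype sample ids")
    if len(keep) < len(sample_ids):
        logger.warning(
            "dropping %d genotyped samples without phenotype", len(sample_ids) - len(keep)
        )
    kept_ids = [sample_ids[i] for i in keep]
    return GenotypeDataset(
        snp_ids,
        kept_ids,
        genotypes[keep],
        np.array([pheno[sid] for sid in kept_ids], dtype=np.int64),
    )


def filter_snps(
    data: GenotypeDataset, max_missing_ratio: float = 0.01
) -> Tuple[GenotypeDataset, FilterReport]:
    """Drop SNPs with missing fraction > threshold (strict), then SNPs with
    fewer than three distinct observed genotypes."""
    miss_frac = data.missing_counts() / data.n_samples
    keep1 = miss_frac <= max_missing_ratio
    removed_missing = int((~keep1).sum())
    classes = data.observed_class_counts()
    keep2 = keep1 & (classes >= 3)
    removed_two = int((keep1 & (classes < 3)).sum())
    kept_idx = np.flatnonzero(keep2)
    report = FilterReport(data.n_snps, removed_missing, removed_two, kept_idx.size)
    filtered = GenotypeDataset(
        [data.snp_ids[i] for i in kept_idx],
        data.sample_ids,
        data.genotypes[:, kept_idx],
        data.phenotypes,
    )
    return filtered, report


def orient_minor_allele(data: GenotypeDataset) -> GenotypeDataset:
    """Recode SNPs so that genotype 2 is homozygous for the minor allele.

    The coded-allele frequency is computed from observed genotypes pooled
    over all samples; SNPs with frequency > 0.5 are flipped (g -> 2 - g),
    an exact tie is left unchanged.  Screening statistics are invariant
    under this recoding up to sign, so nu is unaffected.
    """
    geno = data.genotypes.copy()
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(geno, axis=0) / 2.0
    flip = freq > 0.5
    geno[:, flip] = 2.0 - geno[:, flip]
    return GenotypeDataset(list(data.snp_ids), list(data.sample_ids), geno, data.phenotypes)


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_genotype_tsv(path, data: GenotypeDataset) -> None:
    df = pd.DataFrame(data.genotypes, index=data.sample_ids, columns=data.snp_ids)
    out = df.map(lambda v: "NA" if not math.isfinite(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_phenotype_tsv(path, sample_ids, phenotypes) -> None:
    pd.DataFrame({"sample_id": sample_ids, "status": np.asarray(phenotypes, int)}).to_csv(
        path, sep="\t", index=False, header=False
    )


def write_counts_tsv(path, dataset: SimulatedDataset) -> None:
    m = dataset.m
    is_active = np.zeros(m, dtype=int)
    is_active[dataset.active] = 1
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{k}" for k in range(m)],
            "r0": dataset.case_counts[:, 0],
            "r1": dataset.case_counts[:, 1],
            "r2": dataset.case_counts[:, 2],
            "s0": dataset.control_counts[:, 0],
            "s1": dataset.control_counts[:, 1],
            "s2": dataset.control_counts[:, 2],
            "is_active": is_active,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path):
    """Returns (snp_ids, case_counts, control_counts, is_active)."""
    df = pd.read_csv(path, sep="\t")
    required = ["snp_id", "r0", "r1", "r2", "s0", "s1", "s2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"counts file {path} lacks columns {missing}")
    case = df[["r0", "r1", "r2"]].to_numpy(dtype=np.int64)
    control = df[["s0", "s1", "s2"]].to_numpy(dtype=np.int64)
    is_active = (
        df["is_active"].to_numpy(dtype=np.int64)
        if "is_active" in df.columns
        else np.zeros(len(df), dtype=np.int64)
    )
    return list(df["snp_id"].astype(str)), case, control, is_active


def write_results_tsv(path, snp_ids, case_counts, control_counts,
                      result: ScreeningResult) -> None:
    """Ranked screening output exposing all four statistics per SNP."""
    case = np.asarray(case_counts)
    control = np.asarray(control_counts)
    om = omega_matrix(case, control)
    nu = nu_vector(case, control)
    m = len(snp_ids)
    rank = np.empty(m, dtype=int)
    rank[result.ranking] = np.arange(1, m + 1)
    selected = np.zeros(m, dtype=int)
    selected[result.selected] = 1
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "n_eff": (case + control).sum(axis=1),
            "omega_rec": om[:, 0],
            "omega_add": om[:, 1],
            "omega_dom": om[:, 2],
            "nu": nu,
            "method_stat": result.statistics,
            "rank": rank,
            "selected": selected,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
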