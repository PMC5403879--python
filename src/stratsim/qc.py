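"""Genotype quality control.

Filters are applied in a fixed order (removal counts depend on it):

1. drop SNPs with missingness above the lenient first-stage threshold;
2. drop individuals with high missingness, then SNPs above the strict
   second-stage threshold;
3. drop SNPs with minor allele frequency below ``maf_min``;
4. drop SNPs whose two-group Weir-Cockerham F_ST is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fst import fst_for_dataset
from .simulate import MISSING, GenotypeDataset


@dataclass
class QcThresholds:
    snp_missing_stage1: float = 0.2
    snp_missing_stage2: float = 0.05
    individual_missing: float = 0.05
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("snp_missing_stage1", "snp_missing_stage2",
                     "individual_missing", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.snp_missing_stage1 < self.snp_missing_stage2:
            raise ValueError("stage-1 SNP missingness threshold must be >= stage-2")


@dataclass
class QcReport:
    """Per-stage removal counts plus what survived."""

    snps_removed_stage1: int = 0
    individuals_removed: int = 0
    snps_removed_stage2: int = 0
    snps_removed_maf: int = 0
    snps_removed_undefined_fst: int = 0
    fst_stage_applied: bool = True
    n_samples_final: int = 0
    n_snps_final: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class EmptyDatasetError(ValueError):
    """Raised when quality control removes every SNP."""


def _snp_missingness(geno: np.ndarray) -> np.ndarray:
    return (geno == MISSING).mean(axis=0)


def apply_qc(dataset: GenotypeDataset,
             thresholds: QcThresholds = QcThresholds(),
             fst_grouping: Optional[Sequence] = None):
    """Apply the staged QC filters; returns (filtered dataset, QcReport).

    Stage 4 (undefined-F_ST removal) needs a two-group structure; when the
    dataset has only one population label and no explicit ``fst_grouping``
    is given, that stage is skipped and flagged in the report.
    """
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise ValueError("dataset is empty")
    report = QcReport()
    ds = dataset

    # stage 1: lenient SNP missingness
    keep = _snp_missingness(ds.genotypes) <= thresholds.snp_missing_stage1
    report.snps_removed_stage1 = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyDatasetError("all SNPs removed at stage 1 (missingness)")
    ds = ds.subset(snps=keep) if not keep.all() else ds

    # stage 2: individuals, then strict SNP missingness
    ind_keep = (ds.genotypes == MISSING).mean(axis=1) <= thresholds.individual_missing
    report.individuals_removed = int((~ind_keep).sum())
    if ind_keep.sum() == 0:
        raise EmptyDatasetError("all individuals removed (missingness)")
    if not ind_keep.all():
        ds = ds.subset(samples=ind_keep)
        if fst_grouping is not None:
            fst_grouping = np.asarray(fst_grouping, dtype=object)[ind_keep]
    keep = _snp_missingness(ds.genotypes) <= thresholds.snp_missing_stage2
    report.snps_removed_stage2 = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyDatasetError("all SNPs removed at stage 2 (missingness)")
    ds = ds.subset(snps=keep) if not keep.all() else ds

    # stage 3: minor allele frequency
    freq = ds.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~(np.isnan(maf) | (maf < thresholds.maf_min))
    report.snps_removed_maf = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyDatasetError("all SNPs removed at MAF stage")
    ds = ds.subset(snps=keep) if not keep.all() else ds

    # stage 4: well-defined F_ST
    labels = ds.sample_meta["population"].to_numpy()
    two_groups = fst_grouping is not None or len(np.unique(labels)) >= 2
    if two_groups:
        fst = fst_for_dataset(ds, grouping=fst_grouping)
        keep = fst.defined
        report.snps_removed_undefined_fst = int((~keep).sum())
        if keep.sum() == 0:
            raise EmptyDatasetError("all SNPs removed at F_ST stage")
        ds = ds.subset(snps=keep) if not keep.all() else ds
    else:
        report.fst_stage_applied = False

    report.n_samples_final = ds.n_samples
    report.n_snps_final = ds.n_snps
    return ds, report
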