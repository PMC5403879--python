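"""Weir-Cockerham F_ST estimation for two populations.

The unbiased estimator

    F_ST = (MSP - MSG) / (MSP + (n_c - 1) * MSG)

with MSP = sum_i n_i (p_i - p)^2, MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1),
n_c = sum n_i - sum n_i^2 / sum n_i, and p the sample-size-weighted mean
frequency.  n_i counts sampled *alleles* (2 x non-missing genotyped
individuals) — the Weir-Cockerham convention; an unweighted mean p and
individual counts are available as switches for sensitivity analyses.
Negative estimates are retained (no clipping at 0): the estimator scatters
around -1/(n_c - 1) under zero divergence, and clipping would bias
threshold-stratum membership near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeDataset

#: relative tolerance used to declare the estimator's denominator zero
_DENOM_TOL = 1e-12


@dataclass
class FstTable:
    """Per-SNP Weir-Cockerham estimates with their variance components."""

    table: pd.DataFrame  # columns: snp_id, chrom, pos_bp, fst, msp, msg, n_c, defined

    @property
    def fst(self) -> np.ndarray:
        return self.table["fst"].to_numpy()

    @property
    def defined(self) -> np.ndarray:
        return self.table["defined"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def weir_cockerham_fst(n1, n2, p1, p2, *, weighted_mean: bool = True):
    """Vectorized Weir-Cockerham F_ST from per-population allele counts.

    Parameters are the number of sampled alleles ``n_i`` and the allele
    frequency ``p_i`` for each of the two populations (scalars or equal-
    length arrays).  Returns ``(fst, msp, msg, n_c, defined)``; where the
    denominator vanishes the estimate is NaN and ``defined`` is False.
    Scalar inputs yield scalar outputs.
    """
    n1a = np.atleast_1d(np.asarray(n1, dtype=np.float64))
    n2a = np.atleast_1d(np.asarray(n2, dtype=np.float64))
    p1a = np.atleast_1d(np.asarray(p1, dtype=np.float64))
    p2a = np.atleast_1d(np.asarray(p2, dtype=np.float64))
    scalar = np.isscalar(n1) or np.ndim(n1) == 0

    if np.any(n1a < 2) or np.any(n2a < 2):
        raise ValueError("each population needs at least 2 sampled alleles (n_i >= 2)")

    tot = n1a + n2a
    if weighted_mean:
        pbar = (n1a * p1a + n2a * p2a) / tot
    else:
        pbar = 0.5 * (p1a + p2a)
    n_c = tot - (n1a**2 + n2a**2) / tot
    msp = n1a * (p1a - pbar) ** 2 + n2a * (p2a - pbar) ** 2
    msg = (n1a * p1a * (1.0 - p1a) + n2a * p2a * (1.0 - p2a)) / (tot - 2.0)
    denom = msp + (n_c - 1.0) * msg
    scale = np.maximum(msp + np.abs(n_c - 1.0) * msg, 1.0)
    defined = np.abs(denom) > _DENOM_TOL * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(defined, (msp - msg) / np.where(defined, denom, 1.0), np.nan)
    if scalar:
        return fst[0], msp[0], msg[0], n_c[0], bool(defined[0])
    return fst, msp, msg, n_c, defined


def fst_for_dataset(dataset: GenotypeDataset,
                    grouping: Optional[Sequence] = None,
                    *, weighted_mean: bool = True) -> FstTable:
    """Per-SNP F_ST between two groups of a genotype dataset.

    ``grouping`` is an array of group labels per sample (anything hashable;
    samples with label None/NaN are excluded).  By default the dataset's
    population labels are used: pop1 vs pop2 when both are present,
    otherwise the two labels present (e.g. pop1 vs admixed, matching the
    between-sample divergence actually observable in an admixed panel).
    Allele counts use observed non-missing genotypes, so n_i varies by SNP;
    SNPs where either group has fewer than 2 sampled alleles are flagged
    undefined rather than raising.
    """
    if grouping is None:
        labels = dataset.sample_meta["population"].to_numpy()
        present = pd.unique(labels)
        if {"pop1", "pop2"}.issubset(set(present)):
            keep = np.isin(labels, ["pop1", "pop2"])
        else:
            keep = np.ones(labels.shape[0], dtype=bool)
        grouping = np.where(keep, labels, None)
    grouping = np.asarray(grouping, dtype=object)
    mask = np.array([g is not None and g == g for g in grouping])
    groups = pd.unique(grouping[mask])
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {len(groups)}: {list(groups)}")

    out = {}
    for k, gname in enumerate(groups, start=1):
        rows = mask & (grouping == gname)
        g = dataset.genotypes[rows]
        valid = g != MISSING
        n_alleles = 2.0 * valid.sum(axis=0)
        counts = np.where(valid, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)
        out[f"n{k}"] = n_alleles
        out[f"p{k}"] = freq

    ok = (out["n1"] >= 2) & (out["n2"] >= 2)
    m = dataset.n_snps
    fst = np.full(m, np.nan)
    msp = np.full(m, np.nan)
    msg = np.full(m, np.nan)
    n_c = np.full(m, np.nan)
    defined = np.zeros(m, dtype=bool)
    if ok.any():
        f, sp, sg, nc, d = weir_cockerham_fst(
            out["n1"][ok], out["n2"][ok], out["p1"][ok], out["p2"][ok],
            weighted_mean=weighted_mean,
        )
        fst[ok], msp[ok], msg[ok], n_c[ok], defined[ok] = f, sp, sg, nc, d

    table = pd.DataFrame({
        "snp_id": dataset.snp_meta["snp_id"].to_numpy(),
        "chrom": dataset.snp_meta["chrom"].to_numpy(),
        "pos_bp": dataset.snp_meta["pos_bp"].to_numpy(),
        "fst": fst,
        "msp": msp,
        "msg": msg,
        "n_c": n_c,
        "defined": defined,
    })
    return FstTable(table)


def multilocus_fst(fst: FstTable) -> float:
    """Genome-wide ratio-of-sums Weir-Cockerham estimate.

    Numerators and denominators are summed over defined SNPs before the
    ratio is taken.  Unlike the mean of per-SNP estimates (a mean of
    ratios, biased toward zero by per-locus noise), this combined form
    recovers the generating divergence parameter of a panel simulated at
    fixed F.
    """
    t = fst.table[fst.table["defined"]]
    if len(t) == 0:
        raise ValueError("no defined SNPs")
    num = (t["msp"] - t["msg"]).sum()
    den = (t["msp"] + (t["n_c"] - 1.0) * t["msg"]).sum()
    return float(num / den)


def stratify_by_fst(fst: FstTable,
                    thresholds: Sequence[float] = (0.25, 0.50)) -> dict:
    """Cumulative exceedance strata over defined SNPs.

    Returns an ordered dict of boolean masks over the table's SNPs:
    ``"all"`` (every defined SNP) plus ``">t"`` for each threshold.
    Undefined SNPs are excluded from every stratum.
    """
    defined = fst.defined
    est = fst.fst
    masks = {"all": defined.copy()}
    for t in sorted(thresholds):
        with np.errstate(invalid="ignore"):
            masks[f">{t:g}"] = defined & (est > t)
    return masks
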