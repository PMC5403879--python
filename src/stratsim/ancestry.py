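"""Genome-wide sample-structure summaries.

Identity-by-state (IBS) distances, classical multidimensional scaling of
that distance matrix (the axes used as stratification covariates), genetic
relationship matrices from standardized dosages, and leave-one-chromosome-
out (LOCO) GRM variants for mixed-model association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .simulate import MISSING, GenotypeDataset

#: eigenvalues below this fraction of the largest are treated as zero
EIGEN_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Pairwise 1 - IBS proportions; ``overlap`` counts jointly typed SNPs."""

    values: np.ndarray
    overlap: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def zero_overlap_pairs(self) -> np.ndarray:
        """Boolean mask of pairs with no jointly non-missing SNP."""
        flagged = self.overlap == 0
        np.fill_diagonal(flagged, False)
        return flagged


@dataclass
class MdsComponents:
    """Classical-scaling sample coordinates, eigenvalue-ordered."""

    scores: np.ndarray        # (n, k)
    eigenvalues: np.ndarray   # all eigenvalues, descending

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def to_frame(self, sample_meta: pd.DataFrame) -> pd.DataFrame:
        """Covariate table in the conventional FID IID SOL C1..Ck layout."""
        df = pd.DataFrame({
            "FID": sample_meta["population"].to_numpy(),
            "IID": sample_meta["sample_id"].to_numpy(),
            "SOL": 0,
        })
        for j in range(self.k):
            df[f"C{j + 1}"] = self.scores[:, j]
        return df


@dataclass
class Grm:
    """Genetic relationship matrix from standardized dosages."""

    values: np.ndarray
    snp_count: int
    monomorphic_skipped: int = 0


def ibs_distance(dataset: GenotypeDataset) -> DistanceMatrix:
    """Pairwise distance(i, j) = 1 - shared alleles / (2 * joint SNPs).

    The allele-sharing count between dosages a and b at one SNP is
    2 - |a - b|, so with complete data the distance reduces to the mean
    absolute dosage difference over SNPs divided by 2.
    """
    if dataset.n_samples < 2:
        raise ValueError("at least 2 individuals required")
    g = dataset.genotypes
    miss = g == MISSING
    all_missing = miss.all(axis=1)
    if all_missing.any():
        who = dataset.sample_meta["sample_id"].iloc[int(np.argmax(all_missing))]
        raise ValueError(f"individual {who} has no called genotypes")

    n, m = g.shape
    if not miss.any():
        dist = squareform(pdist(g.astype(np.float64), metric="cityblock")) / (2.0 * m)
        overlap = np.full((n, n), m, dtype=np.int64)
        return DistanceMatrix(dist, overlap)

    valid = (~miss).astype(np.float64)
    gz = np.where(miss, 0, g).astype(np.float64)
    overlap = valid @ valid.T
    # sum over jointly valid SNPs of |a - b|, accumulated in chunks
    diff = np.zeros((n, n))
    for i in range(n):
        d = np.abs(gz[i] - gz) * (valid[i] * valid)
        diff[i] = d.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(overlap > 0, diff / (2.0 * np.maximum(overlap, 1)), np.nan)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, overlap.astype(np.int64))


def classical_mds(dist: DistanceMatrix, k: int) -> MdsComponents:
    """Torgerson classical scaling of a distance matrix.

    The squared-distance matrix is double-centered (B = -1/2 J D^2 J) and
    eigendecomposed; component scores are eigenvectors scaled by the square
    roots of their (positive) eigenvalues.  Deterministic up to column
    sign, which is fixed so each component's loading on the first
    individual is non-negative.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dist.values, dtype=np.float64)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries (zero-overlap pairs)")
    n = d.shape[0]
    d2 = d**2
    j_center = d2 - d2.mean(axis=0, keepdims=True) - d2.mean(axis=1, keepdims=True) + d2.mean()
    b = -0.5 * j_center
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]

    largest = max(vals[0], 0.0)
    n_pos = int(np.sum(vals > EIGEN_TOL * largest)) if largest > 0 else 0
    if n_pos == 0:
        # degenerate all-zero distances: every score is 0
        scores = np.zeros((n, k))
        return MdsComponents(scores, vals)
    if k > n_pos:
        raise ValueError(
            f"k={k} exceeds the number of positive eigenvalues; maximum usable k is {n_pos}"
        )
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    sign = np.where(scores[0] < 0, -1.0, 1.0)
    return MdsComponents(scores * sign, vals)


def compute_grm(dataset: GenotypeDataset, snp_mask: Optional[np.ndarray] = None) -> Grm:
    """GRM = mean over SNPs of standardized-dosage cross-products.

    Dosages are standardized per SNP by mean 2p and sd sqrt(2p(1-p)) using
    the observed allele frequency; missing dosages are mean-imputed (zero
    after centering).  Monomorphic SNPs in the mask are skipped and
    counted.
    """
    if snp_mask is None:
        snp_mask = np.ones(dataset.n_snps, dtype=bool)
    snp_mask = np.asarray(snp_mask)
    if snp_mask.dtype != bool:
        tmp = np.zeros(dataset.n_snps, dtype=bool)
        tmp[snp_mask] = True
        snp_mask = tmp
    if snp_mask.sum() == 0:
        raise ValueError("snp_mask selects no SNPs")

    g = dataset.genotypes[:, snp_mask].astype(np.float64)
    miss = dataset.genotypes[:, snp_mask] == MISSING
    g[miss] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    skipped = int((~poly).sum())
    if poly.sum() == 0:
        raise ValueError("no polymorphic SNPs in the mask")
    g = g[:, poly]
    p = p[poly]
    w = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    w = np.where(np.isnan(w), 0.0, w)
    m = w.shape[1]
    return Grm(values=(w @ w.T) / m, snp_count=m, monomorphic_skipped=skipped)


def loco_grms(dataset: GenotypeDataset) -> dict:
    """Per-chromosome leave-one-chromosome-out GRMs.

    For each chromosome c the GRM is built from every SNP *not* on c,
    avoiding proximal contamination when testing SNPs on c.
    """
    chroms = np.unique(dataset.snp_meta["chrom"].to_numpy())
    if chroms.size < 2:
        raise ValueError("LOCO requires at least 2 chromosomes")
    chrom_col = dataset.snp_meta["chrom"].to_numpy()
    return {int(c): compute_grm(dataset, snp_mask=(chrom_col != c)) for c in chroms}
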