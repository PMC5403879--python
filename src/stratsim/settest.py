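"""Gene-based association via the permutation set test.

SNPs are mapped to gene intervals (0-based half-open; SNPs falling in
more than one gene are excluded), small sets are filtered out, and each
remaining set is scored by the mean chi-square of a greedily selected
subset of approximately independent SNPs:

1. single-SNP covariate-adjusted statistics on the observed phenotype;
2. repeatedly take the remaining SNP with the smallest p-value while it is
   below ``p_entry``, discarding remaining SNPs whose dosage r^2 with any
   selected SNP exceeds ``r2_prune``, up to ``max_snps`` selections;
3. the set statistic is the mean chi-square of the selected SNPs;
4. the null distribution comes from phenotype permutations with the
   selection re-run per permutation (selection is part of the statistic);
   empirical p = (1 + #{perm stat >= observed}) / (1 + n_permutations).

The default permutation scheme is Freedman-Lane: the covariate-adjusted
residuals are permuted, so the permutation null preserves the covariate
structure instead of destroying it as raw phenotype shuffling would.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import design_matrix
from .simulate import GenotypeDataset, child_rng


@dataclass
class GeneIntervals:
    """Gene records (chrom, start, end, gene_id), 0-based half-open."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "start", "end", "gene_id"}
        if not required.issubset(t.columns):
            raise ValueError(f"gene intervals need columns {sorted(required)}")
        bad = np.where(t["start"].to_numpy() >= t["end"].to_numpy())[0]
        if bad.size:
            raise ValueError(f"malformed interval (start >= end) at record {int(bad[0])}")
        if t["gene_id"].duplicated().any():
            raise ValueError("gene_id values must be unique")

    def __len__(self) -> int:
        return len(self.table)


def read_bed(path) -> GeneIntervals:
    """Read gene intervals from a BED3+1 file (chrom, start, end, name)."""
    t = pd.read_csv(path, sep="\t", header=None, comment="#",
                    usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene_id"])
    return GeneIntervals(t)


@dataclass
class SetTestConfig:
    r2_prune: float = 0.1
    p_entry: float = 0.10
    max_snps: int = 10
    n_permutations: int = 10_000
    seed: int = 0
    permute: str = "residual"   # "residual" (Freedman-Lane) or "raw"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_prune <= 1.0:
            raise ValueError("r2_prune must lie in [0, 1]")
        if not 0.0 < self.p_entry <= 1.0:
            raise ValueError("p_entry must lie in (0, 1]")
        if self.max_snps < 1 or self.n_permutations < 1:
            raise ValueError("max_snps and n_permutations must be >= 1")
        if self.permute not in ("residual", "raw"):
            raise ValueError("permute must be 'residual' or 'raw'")


def map_snps_to_genes(snp_meta: pd.DataFrame, intervals: GeneIntervals) -> pd.Series:
    """Assign each SNP to the unique gene interval containing it.

    Uses base-pair positions (``pos_bp``) with the half-open convention:
    a SNP at ``end`` is outside.  SNPs contained in two or more genes are
    excluded (NaN, like SNPs in no gene); the number excluded that way is
    recorded in ``result.attrs['n_multi_gene']``.
    """
    chrom = snp_meta["chrom"].to_numpy()
    pos = snp_meta["pos_bp"].to_numpy()
    m = len(snp_meta)
    hits = np.zeros(m, dtype=np.int64)
    gene_of = np.full(m, None, dtype=object)
    for _, rec in intervals.table.iterrows():
        inside = (chrom == rec["chrom"]) & (pos >= rec["start"]) & (pos < rec["end"])
        hits += inside
        gene_of[inside] = rec["gene_id"]
    gene_of[hits != 1] = None
    out = pd.Series(gene_of, index=snp_meta.index, name="gene_id")
    out.attrs["n_multi_gene"] = int((hits > 1).sum())
    return out


def filter_sets(assignment: pd.Series, min_variants: int = 2) -> dict:
    """Gene -> list of SNP indices, keeping genes with >= min_variants SNPs."""
    if min_variants < 1:
        raise ValueError("min_variants must be >= 1")
    sets: dict = {}
    for idx, gene in assignment.items():
        if gene is not None and gene == gene:
            sets.setdefault(gene, []).append(idx)
    return {g: snps for g, snps in sets.items() if len(snps) >= min_variants}


def _dosage_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation between dosage columns.

    Computed over individuals complete for both SNPs of each pair; the
    complete-data path is a plain correlation matrix.
    """
    s = g.shape[1]
    if not np.isnan(g).any():
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(g, rowvar=False)
        c = np.atleast_2d(c)
        return np.nan_to_num(c**2, nan=0.0)
    r2 = np.zeros((s, s))
    for a in range(s):
        for b in range(a + 1, s):
            both = ~np.isnan(g[:, a]) & ~np.isnan(g[:, b])
            if both.sum() < 3:
                continue
            ga, gb = g[both, a], g[both, b]
            if ga.std() == 0 or gb.std() == 0:
                continue
            r = np.corrcoef(ga, gb)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    np.fill_diagonal(r2, 1.0)
    return r2


def _greedy_select(pvals: np.ndarray, r2: np.ndarray, config: SetTestConfig) -> list:
    """Greedy entry-and-prune selection; ties broken by lower SNP index.

    Non-finite p-values are never selected.  Returns positions within the
    set, in selection order.
    """
    order = np.lexsort((np.arange(pvals.size), pvals))
    selected: list = []
    excluded = np.zeros(pvals.size, dtype=bool)
    for pos in order:
        if len(selected) >= config.max_snps:
            break
        if excluded[pos] or not np.isfinite(pvals[pos]):
            continue
        if pvals[pos] >= config.p_entry:
            break
        selected.append(int(pos))
        excluded |= r2[pos] > config.r2_prune
    return selected


def permutation_set_test(dataset: GenotypeDataset, phenotype: np.ndarray,
                         covariates, sets: dict,
                         config: SetTestConfig = SetTestConfig()) -> pd.DataFrame:
    """Permutation set test over gene sets.

    ``sets`` maps gene_id -> SNP column indices (from :func:`filter_sets`).
    Missing dosages are mean-imputed for the within-set statistics so a
    single residualization serves observed and permuted phenotypes alike.
    Returns a table GENE, NSNP, NSEL, STAT, EMP_P; sets whose observed
    selection is empty get EMP_P exactly 1.  Each set uses an independent
    permutation stream derived from ``config.seed`` and the set's rank.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    n = dataset.n_samples
    m = dataset.n_snps
    for gene, snps in sets.items():
        if np.any((np.asarray(snps) < 0) | (np.asarray(snps) >= m)):
            raise ValueError(f"set {gene!r} references an unknown SNP index")

    x = design_matrix(covariates, n)
    q_cols = x.shape[1]
    df = n - q_cols - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    q, _ = np.linalg.qr(x)
    y_resid = y - q @ (q.T @ y)

    dosages = dataset.dosages(impute_mean=True)
    rows = []
    for rank, (gene, snps) in enumerate(sorted(sets.items(), key=lambda kv: str(kv[0]))):
        snps = list(snps)
        g = dosages[:, snps]
        r2 = _dosage_r2(np.where(np.isnan(g), np.nanmean(g, axis=0), g))
        g_resid = g - q @ (q.T @ g)
        gg = np.einsum("ij,ij->j", g_resid, g_resid)
        degenerate = gg <= 1e-10 * n

        def _stats_from(resid_pheno: np.ndarray) -> np.ndarray:
            """Chi-square stats for the set's SNPs; rows = phenotypes."""
            yy = np.einsum("ij,ij->i", resid_pheno, resid_pheno)
            num = resid_pheno @ g_resid
            with np.errstate(invalid="ignore", divide="ignore"):
                r2_gy = num**2 / (gg[None, :] * yy[:, None])
                stat = df * r2_gy / (1.0 - r2_gy)
            stat[:, degenerate] = np.nan
            return stat

        obs_stat_snp = _stats_from(y_resid[None, :])[0]
        obs_p = stats.chi2.sf(obs_stat_snp, df=1)
        sel = _greedy_select(obs_p, r2, config)
        if not sel:
            rows.append((gene, len(snps), 0, np.nan, 1.0))
            continue
        obs = float(np.mean(obs_stat_snp[sel]))

        rng = child_rng(config.seed, 4, rank)
        b = config.n_permutations
        base = y_resid if config.permute == "residual" else y
        perms = np.array([rng.permutation(n) for _ in range(b)])
        e = base[perms]
        e_resid = e - (e @ q) @ q.T
        perm_stats = _stats_from(e_resid)
        perm_p = stats.chi2.sf(perm_stats, df=1)

        exceed = 0
        for bi in range(b):
            sel_b = _greedy_select(perm_p[bi], r2, config)
            stat_b = float(np.mean(perm_stats[bi, sel_b])) if sel_b else 0.0
            if stat_b >= obs:
                exceed += 1
        emp_p = (1.0 + exceed) / (1.0 + b)
        rows.append((gene, len(snps), len(sel), obs, emp_p))

    return pd.DataFrame(rows, columns=["GENE", "NSNP", "NSEL", "STAT", "EMP_P"])


def synthetic_gene_intervals(snp_meta: pd.DataFrame, n_genes: int,
                             snps_per_gene: int = 40,
                             seed: Optional[int] = None) -> GeneIntervals:
    """Tile the SNP panel into synthetic, non-overlapping gene intervals.

    Consecutive blocks of ``snps_per_gene`` SNPs along each chromosome
    become one gene spanning [first SNP bp, last SNP bp + 1).  A stand-in
    for real gene annotations: interval structure only, no biology.
    """
    if n_genes < 1 or snps_per_gene < 1:
        raise ValueError("n_genes and snps_per_gene must be >= 1")
    records = []
    gene = 0
    for chrom, sub in snp_meta.groupby("chrom", sort=True):
        pos = np.sort(sub["pos_bp"].to_numpy())
        for start in range(0, len(pos) - snps_per_gene + 1, snps_per_gene):
            block = pos[start:start + snps_per_gene]
            records.append((chrom, int(block[0]), int(block[-1]) + 1, f"gene{gene:04d}"))
            gene += 1
            if gene >= n_genes:
                break
        if gene >= n_genes:
            break
    if gene < n_genes:
        raise ValueError(
            f"panel supports only {gene} genes of {snps_per_gene} SNPs; asked for {n_genes}"
        )
    return GeneIntervals(pd.DataFrame(records, columns=["chrom", "start", "end", "gene_id"]))
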