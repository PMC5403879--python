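"""Synthetic genotype and phenotype generation under population structure.

Two study designs are supported:

* a *distinct* design -- two homogeneous populations whose per-SNP allele
  frequencies diverge according to the Balding-Nichols model, with a
  per-SNP divergence parameter F drawn from a genome-wide distribution
  (a low-divergence bulk plus a heavy tail);
* an *admixed* design -- one homogeneous population plus admixed
  individuals whose chromosomes are mosaics of the two ancestral sources.
  Each admixed individual has a global ancestry fraction theta (the
  probability that any given locus derives from population 2) and local
  ancestry switches along each chromosome at Poisson-distributed points.

All linkage disequilibrium in the admixed design arises from local
ancestry; ancestral sites are drawn independently.  Phenotypes combine an
ancestry-proportional trait shift (theta * delta), an optional per-allele
causal effect, and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

Sampler = Callable[[np.random.Generator, int], np.ndarray]


def child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic independent RNG stream derived from a master seed.

    Streams are identified by a counter tuple; this is the seed-derivation
    scheme used throughout the experiment drivers.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def uniform_freq_sampler(low: float = 0.05, high: float = 0.95) -> Sampler:
    """Ancestral allele-frequency sampler, uniform on (low, high)."""
    if not (0.0 < low < high < 1.0):
        raise ValueError("frequency sampler bounds must satisfy 0 < low < high < 1")

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(low, high, size)

    return sample


@dataclass(frozen=True)
class FstMixture:
    """Two-component per-SNP divergence (F) distribution.

    A Beta low-divergence bulk plus a Beta heavy tail.  The default
    parameters were tuned once so that, for sample sizes 112/147 and a
    uniform(0.05, 0.95) ancestral frequency, the Weir-Cockerham estimates
    over a large panel exceed 0.25 for ~17% of SNPs and 0.50 for ~3%,
    mimicking the genome-wide European/African divergence profile.
    """

    tail_weight: float = 0.006
    bulk_a: float = 26.0
    bulk_b: float = 144.0
    tail_a: float = 8.0
    tail_b: float = 2.0

    def __call__(self, rng: np.random.Generator, size: int) -> np.ndarray:
        f = rng.beta(self.bulk_a, self.bulk_b, size)
        tail = rng.random(size) < self.tail_weight
        if tail.any():
            f[tail] = rng.beta(self.tail_a, self.tail_b, int(tail.sum()))
        return np.minimum(f, 0.995)


@dataclass
class AncestralModel:
    """Parameters of the ancestral SNP panel shared by both populations."""

    num_snps: int = 20_000
    num_chromosomes: int = 10
    map_length_morgans: float = 3.5
    ancestral_freq_sampler: Sampler = field(default_factory=uniform_freq_sampler)
    fst_sampler: Sampler = field(default_factory=FstMixture)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_snps < 1:
            raise ValueError("num_snps must be >= 1")
        if self.num_chromosomes < 1:
            raise ValueError("num_chromosomes must be >= 1")
        if self.map_length_morgans < 0:
            raise ValueError("map_length_morgans must be >= 0")


@dataclass
class PopulationPair:
    """Per-SNP allele frequencies of the two ancestral populations."""

    freq_pop1: np.ndarray
    freq_pop2: np.ndarray
    true_fst: np.ndarray
    snp_chrom: np.ndarray          # 1-based chromosome index per SNP
    snp_pos_morgan: np.ndarray     # genetic position within chromosome
    chrom_lengths: np.ndarray      # map length per chromosome (Morgans)

    @property
    def num_snps(self) -> int:
        return self.freq_pop1.shape[0]

    def __post_init__(self) -> None:
        m = self.num_snps
        for name in ("freq_pop2", "true_fst", "snp_chrom", "snp_pos_morgan"):
            if getattr(self, name).shape[0] != m:
                raise ValueError(f"{name} length does not match freq_pop1")
        for freqs in (self.freq_pop1, self.freq_pop2):
            if np.any((freqs < 0) | (freqs > 1)):
                raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class AdmixtureModel:
    """Global/local ancestry model for admixed individuals.

    ``ancestry_mean`` and ``ancestry_concentration`` parameterize the Beta
    distribution of the global population-2 ancestry fraction theta;
    ``generations`` G sets the Poisson density (per Morgan) of local
    ancestry switch points, i.e. tract lengths ~ Exp(G).
    """

    ancestry_mean: float = 0.8
    ancestry_concentration: float = 10.0
    generations: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.ancestry_mean < 1.0:
            raise ValueError("ancestry_mean must lie in (0, 1)")
        if self.ancestry_concentration <= 0:
            raise ValueError("ancestry_concentration must be > 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    def beta_params(self) -> tuple[float, float]:
        a = self.ancestry_mean * self.ancestry_concentration
        return a, self.ancestry_concentration - a


@dataclass
class LocalAncestryTracks:
    """Mosaic ancestry of each individual.

    ``segments[i][c]`` holds, for individual i and chromosome c (0-based),
    a pair of homologous copies; each copy is ``(breaks, sources)`` where
    ``breaks`` are the internal switch positions (Morgans, sorted) and
    ``sources`` (length ``len(breaks) + 1``) gives the ancestral source
    (1 or 2) of each tiled segment of [0, map_length].
    """

    thetas: np.ndarray
    chrom_lengths: np.ndarray
    segments: list  # [individual][chromosome] -> ((breaks, sources), (breaks, sources))

    @property
    def n_individuals(self) -> int:
        return self.thetas.shape[0]

    def sources_at(self, individual: int, chrom: int, copy: int,
                   positions: np.ndarray) -> np.ndarray:
        breaks, sources = self.segments[individual][chrom][copy]
        return sources[np.searchsorted(breaks, positions, side="right")]


@dataclass
class GenotypeDataset:
    """Additive genotype matrix with SNP and sample metadata.

    ``genotypes`` is an (n_samples, n_snps) int8 array of allele-A dosages
    {0, 1, 2}, with -1 coding missing.  ``snp_meta`` carries snp_id, chrom,
    pos_morgan, pos_bp and the generating true_fst; ``sample_meta`` carries
    sample_id, population label (pop1/pop2/admixed) and the global ancestry
    fraction theta (population-2 fraction; 0 and 1 for the homogeneous
    labels).
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta length does not match genotype rows")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match genotype columns")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype dosages must be in {0, 1, 2} or missing (-1)")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def dosages(self, impute_mean: bool = False) -> np.ndarray:
        """Float dosage matrix with missing as NaN or mean-imputed per SNP."""
        g = self.genotypes.astype(np.float64)
        miss = self.genotypes == MISSING
        if not miss.any():
            return g
        g[miss] = np.nan
        if impute_mean:
            col_mean = np.nanmean(g, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(miss)
            g[idx] = col_mean[idx[1]]
        return g

    def allele_freq(self) -> np.ndarray:
        """Pooled allele-A frequency per SNP over non-missing genotypes."""
        g = self.genotypes
        valid = g != MISSING
        counts = np.where(valid, g, 0).sum(axis=0)
        denom = 2 * valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    def subset(self, samples: Optional[np.ndarray] = None,
               snps: Optional[np.ndarray] = None) -> "GenotypeDataset":
        g = self.genotypes
        sm = self.sample_meta
        pm = self.snp_meta
        if samples is not None:
            g = g[samples]
            sm = sm.iloc[np.asarray(samples).nonzero()[0]] if np.asarray(samples).dtype == bool \
                else sm.iloc[samples]
            sm = sm.reset_index(drop=True)
        if snps is not None:
            g = g[:, snps]
            pm = pm.iloc[np.asarray(snps).nonzero()[0]] if np.asarray(snps).dtype == bool \
                else pm.iloc[snps]
            pm = pm.reset_index(drop=True)
        return GenotypeDataset(g.copy(), pm, sm)


@dataclass
class PhenotypeModel:
    """Quantitative trait model: y = theta*delta + snp_effect*dosage + noise.

    For homogeneous individuals theta is 0 (pop1) or 1 (pop2), so a delta
    of 3 reproduces two groups with trait means 0 and 3 and unit sd.
    """

    divergence_delta: float = 0.0
    residual_sd: float = 1.0
    causal_snp: Optional[int] = None
    snp_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


def draw_population_freqs(model: AncestralModel) -> PopulationPair:
    """Draw per-SNP allele frequencies for two diverged populations.

    For each SNP an ancestral frequency p and divergence F are sampled;
    each population's frequency is then an independent Balding-Nichols
    draw, Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
    F*p*(1-p).  F = 0 yields both frequencies equal to p.
    """
    rng = child_rng(model.seed, 0)
    m = model.num_snps
    p = np.asarray(model.ancestral_freq_sampler(rng, m), dtype=np.float64)
    if p.shape != (m,) or np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError(
            "ancestral_freq_sampler produced frequencies outside (0, 1); "
            "the Balding-Nichols parameterization requires 0 < p < 1"
        )
    f = np.asarray(model.fst_sampler(rng, m), dtype=np.float64)
    if f.shape != (m,) or np.any(f < 0.0) or np.any(f >= 1.0):
        raise ValueError("fst_sampler must produce divergence values in [0, 1)")

    freqs = np.empty((2, m))
    pos_f = f > 0
    for k in range(2):
        freqs[k, ~pos_f] = p[~pos_f]
        if pos_f.any():
            scale = (1.0 - f[pos_f]) / f[pos_f]
            freqs[k, pos_f] = rng.beta(p[pos_f] * scale, (1.0 - p[pos_f]) * scale)

    # SNPs are distributed over chromosomes in contiguous blocks with
    # sorted uniform genetic positions.
    per_chrom = np.full(model.num_chromosomes, m // model.num_chromosomes)
    per_chrom[: m % model.num_chromosomes] += 1
    chrom = np.repeat(np.arange(1, model.num_chromosomes + 1), per_chrom)
    pos = np.concatenate([
        np.sort(rng.uniform(0.0, model.map_length_morgans, c)) for c in per_chrom
    ])
    lengths = np.full(model.num_chromosomes, float(model.map_length_morgans))
    return PopulationPair(freqs[0], freqs[1], f, chrom, pos, lengths)


def simulate_local_ancestry(adm: AdmixtureModel, pair: PopulationPair,
                            n_individuals: int, seed: int,
                            thetas: Optional[np.ndarray] = None) -> LocalAncestryTracks:
    """Simulate mosaic local-ancestry tracks for admixed individuals.

    Per chromosome copy, switch points follow a Poisson process with rate
    ``generations`` per Morgan; at each switch point (and at the chromosome
    start) the segment source is drawn Bernoulli(theta) between population
    2 (probability theta) and population 1, so the stationary source
    probability equals the individual's global ancestry fraction.  With a
    zero map length each copy is a single whole-chromosome segment.

    ``thetas`` overrides the Beta(mean, concentration) draw — used to embed
    homogeneous individuals (theta 0 or 1) in the same representation.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = child_rng(seed, 1)
    if thetas is None:
        a, b = adm.beta_params()
        thetas = rng.beta(a, b, n_individuals)
    else:
        thetas = np.asarray(thetas, dtype=np.float64)
        if thetas.shape != (n_individuals,):
            raise ValueError("thetas must have length n_individuals")
        if np.any((thetas < 0) | (thetas > 1)):
            raise ValueError("thetas must lie in [0, 1]")

    rate = float(adm.generations)
    segments = []
    for i in range(n_individuals):
        th = thetas[i]
        per_chrom = []
        for length in pair.chrom_lengths:
            copies = []
            for _ in range(2):
                k = rng.poisson(rate * length) if length > 0 else 0
                breaks = np.sort(rng.uniform(0.0, length, k)) if k else np.empty(0)
                sources = np.where(rng.random(k + 1) < th, 2, 1).astype(np.int8)
                copies.append((breaks, sources))
            per_chrom.append(tuple(copies))
        segments.append(per_chrom)
    return LocalAncestryTracks(thetas, pair.chrom_lengths.copy(), segments)


def _simulate_distinct(pair: PopulationPair, labels: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    n = labels.shape[0]
    freq = np.empty((n, pair.num_snps))
    is2 = labels == "pop2"
    if not np.all(is2 | (labels == "pop1")):
        raise ValueError("distinct-design labels must be 'pop1' or 'pop2'")
    freq[~is2] = pair.freq_pop1
    freq[is2] = pair.freq_pop2
    geno = rng.binomial(2, freq).astype(np.int8)
    meta = pd.DataFrame({
        "sample_id": [f"ind{i:04d}" for i in range(n)],
        "population": labels,
        "theta": is2.astype(float),
    })
    return geno, meta


def _simulate_admixed(pair: PopulationPair, tracks: LocalAncestryTracks,
                      rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    n = tracks.n_individuals
    m = pair.num_snps
    geno = np.zeros((n, m), dtype=np.int8)
    chroms = np.unique(pair.snp_chrom)
    for c_idx, c in enumerate(chroms):
        snp_idx = np.where(pair.snp_chrom == c)[0]
        pos = pair.snp_pos_morgan[snp_idx]
        p1 = pair.freq_pop1[snp_idx]
        p2 = pair.freq_pop2[snp_idx]
        for i in range(n):
            for copy in range(2):
                src = tracks.sources_at(i, c_idx, copy, pos)
                f = np.where(src == 2, p2, p1)
                geno[i, snp_idx] += (rng.random(snp_idx.size) < f)
    theta = tracks.thetas
    population = np.where(theta == 0.0, "pop1",
                          np.where(theta == 1.0, "pop2", "admixed"))
    meta = pd.DataFrame({
        "sample_id": [f"ind{i:04d}" for i in range(n)],
        "population": population,
        "theta": theta,
    })
    return geno, meta


def simulate_genotypes(pair: PopulationPair,
                       design: Union[Sequence, np.ndarray, LocalAncestryTracks],
                       missing_rate: float = 0.0,
                       seed: int = 0) -> GenotypeDataset:
    """Draw genotypes for either study design.

    ``design`` is an array of population labels ('pop1'/'pop2') for the
    distinct design, or :class:`LocalAncestryTracks` for the admixed
    design (each allele is drawn from the frequency of its local ancestry
    source).  Entries are masked missing independently at ``missing_rate``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = child_rng(seed, 2)
    if isinstance(design, LocalAncestryTracks):
        geno, sample_meta = _simulate_admixed(pair, design, rng)
    else:
        labels = np.asarray(design, dtype=object).astype(str)
        geno, sample_meta = _simulate_distinct(pair, labels, rng)

    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING

    snp_meta = pd.DataFrame({
        "snp_id": [f"snp{j:06d}" for j in range(pair.num_snps)],
        "chrom": pair.snp_chrom.astype(int),
        "pos_morgan": pair.snp_pos_morgan,
        "pos_bp": np.round(pair.snp_pos_morgan * 1e6).astype(int),
        "true_fst": pair.true_fst,
    })
    return GenotypeDataset(geno, snp_meta, sample_meta)


def simulate_tagged_snps(n_individuals: int, n_tagged: int,
                         tag_prob: Sequence[float],
                         causal_freq: float = 0.5,
                         seed: int = 0) -> GenotypeDataset:
    """One causal SNP plus null SNPs in controlled linkage disequilibrium.

    SNP 0 is the causal variant with allele frequency ``causal_freq``;
    tagged SNP k copies each causal allele with probability ``tag_prob[k]``
    and otherwise draws a fresh allele at the same frequency, giving an
    expected allelic correlation of tag_prob (so r^2 ~ tag_prob^2).  Used
    to study how association statistics at null variants inflate with LD
    to a causal variant; realized r^2 should be measured from the returned
    dosages.
    """
    tag_prob = np.asarray(tag_prob, dtype=np.float64)
    if tag_prob.shape != (n_tagged,):
        raise ValueError("tag_prob must have length n_tagged")
    if np.any((tag_prob < 0) | (tag_prob > 1)):
        raise ValueError("tag probabilities must lie in [0, 1]")
    if not 0.0 < causal_freq < 1.0:
        raise ValueError("causal_freq must lie in (0, 1)")
    rng = child_rng(seed, 8)
    causal_alleles = rng.random((n_individuals, 2)) < causal_freq
    geno = np.empty((n_individuals, n_tagged + 1), dtype=np.int8)
    geno[:, 0] = causal_alleles.sum(axis=1)
    for k in range(n_tagged):
        copy = rng.random((n_individuals, 2)) < tag_prob[k]
        fresh = rng.random((n_individuals, 2)) < causal_freq
        alleles = np.where(copy, causal_alleles, fresh)
        geno[:, k + 1] = alleles.sum(axis=1)
    m = n_tagged + 1
    snp_meta = pd.DataFrame({
        "snp_id": [f"snp{j:06d}" for j in range(m)],
        "chrom": np.ones(m, dtype=int),
        "pos_morgan": np.linspace(0.0, 0.01 * (m - 1), m),
        "pos_bp": np.arange(m) * 10_000,
        "true_fst": np.zeros(m),
    })
    sample_meta = pd.DataFrame({
        "sample_id": [f"ind{i:04d}" for i in range(n_individuals)],
        "population": np.repeat("pop1", n_individuals),
        "theta": np.zeros(n_individuals),
    })
    return GenotypeDataset(geno, snp_meta, sample_meta)


def simulate_phenotype(dataset: GenotypeDataset, model: PhenotypeModel,
                       seed: int = 0) -> np.ndarray:
    """Draw a quantitative phenotype: y = theta*delta + effect*dosage + noise.

    Missing causal dosages are imputed to the per-SNP mean so no individual
    is dropped from phenotype generation.
    """
    rng = child_rng(seed, 3)
    n = dataset.n_samples
    y = dataset.sample_meta["theta"].to_numpy() * model.divergence_delta
    if model.causal_snp is not None:
        j = int(model.causal_snp)
        if not 0 <= j < dataset.n_snps:
            raise IndexError(f"causal_snp index {j} out of range for {dataset.n_snps} SNPs")
        g = dataset.genotypes[:, j].astype(np.float64)
        miss = dataset.genotypes[:, j] == MISSING
        if miss.any():
            g[miss] = g[~miss].mean() if (~miss).any() else 0.0
        y = y + model.snp_effect * g
    return y + rng.normal(0.0, model.residual_sd, n)
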