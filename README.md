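# stratsim

Simulation framework for studying how **population divergence (F_ST)**
drives residual type-I-error inflation and power loss in genome-wide
association studies (GWAS) of multi-ethnic and admixed samples that are
corrected with multidimensional-scaling (MDS) components.

## The problem

Association scans that mix ancestral populations confound genotype with
ancestry: if the two source populations differ both in allele frequencies
and in trait means, every frequency-differentiated SNP picks up a
spurious signal.  The standard remedy — including genotype-derived axes
(principal components or MDS components) as covariates — applies one
*uniform* correction to every SNP.  stratsim exists to ask, by
simulation, whether that uniform correction is adequate for the SNPs
where it matters most: those with unusually strong differentiation
between the source populations, and in samples where ancestry is not a
clean two-group split but a continuous admixture gradient.

The package targets researchers in statistical genetics who want a
controlled testbed: genotypes with known per-SNP divergence, phenotypes
with known confounding and known causal effects, and the full analysis
stack (QC, F_ST, MDS, single-SNP GWAS, mixed-model LOCO GWAS, gene-based
permutation tests, inflation diagnostics) in one place.

## Models and statistics

**Balding–Nichols genotypes.**  Each SNP has an ancestral frequency
*p* and a divergence parameter *F*; each population's frequency is an
independent draw from Beta(p(1−F)/F, (1−p)(1−F)/F), with mean *p* and
variance *F·p(1−p)*.  Per-SNP *F* follows a calibrated two-component
mixture (a low-divergence bulk and a heavy tail) so that the *estimated*
F_ST profile matches the genome-wide European/African one: about 17% of
SNPs above 0.25 and 3% above 0.5 at sample sizes 112/147.

**Admixture.**  Admixed individuals carry a global ancestry fraction
θ ~ Beta and mosaic chromosomes: local-ancestry switch points follow a
Poisson process (rate G per Morgan) and each segment's source is drawn
with probability θ, producing the long-range "admixture LD" that
correlates even unlinked divergent SNPs.

**Weir–Cockerham F_ST** for two populations,

    F_ST = (MSP − MSG) / (MSP + (n_c − 1)·MSG)

with MSP = Σᵢ nᵢ(pᵢ−p̄)², MSG = Σᵢ nᵢpᵢ(1−pᵢ) / Σᵢ(nᵢ−1),
n_c = Σnᵢ − Σnᵢ²/Σnᵢ, where nᵢ counts sampled alleles and p̄ is the
size-weighted mean frequency.

**Genomic inflation factor** λ = median(χ²)/0.4549 (or the mean χ²),
overall and within F_ST exceedance strata, plus the closed-form expected
mean χ² when null SNPs tag causal variants:
λ_mean = 1 + (1/L)·Σⱼ Σₖ N·h²ⱼ·r²ⱼₖ / (1 − h²ⱼ·r²ⱼₖ).

**Tests.**  Covariate-adjusted per-SNP OLS with 1-df χ² statistics; an
EMMAX-style mixed model with leave-one-chromosome-out (LOCO) genetic
relationship matrices; and gene-based permutation set tests (greedy
selection of up to 10 approximately independent SNPs with p < 0.10 and
pairwise r² ≤ 0.1, Freedman–Lane residual permutation).

## Worked example

`examples/03_power_and_bias.py` runs the three-condition power design on
a 30,000-SNP two-population panel (112 + 147 individuals) with a causal
SNP at estimated F_ST ≈ 0.74 carrying a 0.2 per-allele effect:

```
             condition  mds_k  causal_est_fst  mean_beta  power
  no_divergence_no_mds      0           0.739      0.199  0.798
no_divergence_with_mds     10           0.739      0.196  0.302
   divergence_with_mds     10           0.739      0.197  0.304
```

The effect estimates are unbiased (≈0.20) in every condition; the power
drop between the first and second rows is the cost of carrying 10 MDS
covariates at n = 259 — the correction, not the trait divergence, is
what reduces power here.  `examples/02_stratification_inflation.py`
shows the complementary type-I side on an admixed panel: with 20 MDS
components the genomic inflation factor stays near 1 in every F_ST
stratum, while the uncorrected scan inflates to λ ≈ 11 overall and
λ ≈ 170 for SNPs with F_ST > 0.5.  The other examples cover the
divergence profile, gene-based set tests, the closed-form inflation
formula, and PLINK bed/bim/fam round trips.

## Layout

- `src/stratsim/simulate.py` — genotype/phenotype generators
- `src/stratsim/qc.py`, `fst.py` — staged QC and F_ST estimation
- `src/stratsim/ancestry.py` — IBS distances, classical MDS, GRMs
- `src/stratsim/assoc.py` — linear and mixed-model (LOCO) scans
- `src/stratsim/inflation.py` — λ, QQ data, closed-form mean χ²
- `src/stratsim/settest.py` — gene intervals and permutation set tests
- `src/stratsim/plink.py` — PLINK bed/bim/fam codec
- `src/stratsim/experiments.py` — type-I and power experiment drivers
- `docs/methods.md` — modeling choices, defaults and limitations
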