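# Methods

This note records the models behind stratsim, the defaults and why they
were chosen, the numerical conventions, and what the simulations do and
do not establish about real data.

## Study designs

Two designs reproduce the two canonical forms of population
stratification:

* **distinct** — 112 individuals from population 1 and 147 from
  population 2, both homogeneous (the sizes of a CEU/YRI-style founder
  panel after QC);
* **admixed** — 85 homogeneous population-1 individuals plus 61 admixed
  individuals (a CEU/ASW-style panel) whose genomes are mosaics of the
  two ancestral sources.

Both designs fix one genotype panel and redraw phenotypes across
replicates, mirroring studies that simulate traits on fixed real
genotypes.

## Genotype model

Each SNP draws an ancestral frequency p ~ Uniform(0.05, 0.95) and a
divergence parameter F; population frequencies are independent
Balding–Nichols draws Beta(p(1−F)/F, (1−p)(1−F)/F) (mean p, variance
F·p(1−p)).  Genotypes are two Bernoulli alleles per individual.
Ancestral sites are drawn independently: there is **no background
haplotype LD**.  All LD in the admixed design arises from local
ancestry, which isolates the admixture-LD inflation mechanism; a
haplotype-block extension is out of scope.

**Per-SNP divergence distribution.**  F follows a two-component Beta
mixture: bulk Beta(26, 144) with weight 0.994 and tail Beta(8, 2) with
weight 0.006.  The parameters were tuned once, against the measured
response of the per-SNP Weir–Cockerham estimator at sample sizes
112/147, so that the *estimated* exceedance fractions match the
genome-wide European/African profile (≈17% of estimates above 0.25, ≈3%
above 0.5).  Two points matter here: (i) the single-locus estimator is
noisy (sd ≈ 0.1–0.3 depending on F) and approximately median-unbiased
only at low F, so matching *estimated* exceedances requires a tighter
true-F bulk than the raw percentages suggest; (ii) the mean of per-SNP
estimates does **not** recover F (a mean of ratios — empirically ≈0.31
at F = 0.5), while the genome-wide ratio-of-sums form (`multilocus_fst`)
does, which is why the recovery tests use the latter.

## Admixture model

Admixed individuals draw a global population-2 ancestry fraction
θ ~ Beta(mean 0.8, concentration 10) — a plausible ASW-like profile, not
an estimate from data.  Along each chromosome copy, switch points follow
a Poisson process with rate G = 6 per Morgan and each segment's source
is Bernoulli(θ), so tract lengths are Exp(G) and the stationary source
probability is θ.  G = 6 produces multi-centimorgan tracts, i.e. the
"long-range" admixture LD regime.  Chromosomes are 3.5 Morgans each and
panels span 10 chromosomes — 35 Morgans, the scale of the human
autosomal map (compressed into fewer, longer chromosomes); the genetic
length matters because the number of ancestry tracts (~2·G·L per copy
per chromosome) controls how closely an individual's realized
genome-wide ancestry tracks θ, and hence how much of the ancestry signal
genotype-derived axes can recover.

## Phenotype model

y = θ·δ + SNPeff·dosage + ε, ε ~ N(0, 1).  For homogeneous individuals
θ ∈ {0, 1}, so δ = 3 reproduces two groups with trait means 0 and 3 and
unit sd (the type-I experiments); the power experiments use δ = 4 and
SNPeff 0.2 (distinct) or 0.3 (admixed, compensating the smaller n).  The
linear θ·δ form interpolates the two-group model to admixed individuals.
Its important consequence: the confounder is θ itself, while genotypes
can at best reveal *realized* ancestry, which differs from θ by
~sd(θ(1−θ)/n_tracts)^½ ≈ 0.02 — an irreducible residual that no
genotype-derived correction removes.  Missing causal dosages are
mean-imputed for phenotype generation (no individuals dropped); the
experiments default to a missing rate of 0.

## Analysis stack

* **QC** in the fixed order: SNP missingness > 0.2; individual
  missingness > 0.05 then SNP missingness > 0.05; MAF < 0.01;
  undefined-F_ST removal.  Order matters for the removal counts and is
  part of the contract.
* **F_ST**: n_i counts sampled *alleles* (2 × non-missing individuals)
  and p̄ is size-weighted — the Weir–Cockerham convention; both are
  switchable (`weighted_mean`) since the convention is not universal.
  Negative estimates are retained: clipping at 0 would bias stratum
  membership near the null value −1/(n_c − 1).  In the admixed design
  F_ST is computed between the homogeneous and the admixed group — the
  divergence actually observable in such a panel (and the scale on which
  a causal SNP with estimated F_ST ≈ 0.65 is selected); admixture shrinks
  these estimates relative to the ancestral divergence.
* **MDS**: classical (Torgerson) scaling of the 1 − IBS distance matrix,
  all QC-passing SNPs, no LD pruning (none is part of the emulated
  procedure).  Eigenvalues below 10⁻⁹ × the largest count as zero;
  component signs are fixed by the first individual's loading.
* **Association**: per-SNP OLS via residualization against the covariate
  block (exact, by Frisch–Waugh–Lovell), per-SNP case deletion for
  missing dosages, p-values from the 1-df χ² of (β/se)² — the scale on
  which λ is defined; at n ≥ 146 the t-vs-χ² difference shifts λ by
  < 0.01.  SNPs collinear with the covariates are flagged, not fatal.
* **Mixed model (LOCO)**: one REML fit per chromosome under
  y = Xβ + u + ε, cov(u) = σ²_g·GRM_loco (EMMAX-style single fit, not
  per-SNP REML), by bounded scalar search on log(σ²_e/σ²_g) over three
  restart brackets, tolerance 10⁻⁸; SNPs are then tested by GLS in the
  rotated coordinates.  Missing dosages are mean-imputed so one
  covariance fit serves the chromosome.
* **Set test**: greedy entry-and-prune selection (smallest p first, ties
  to the lower SNP index; entry p < 0.10; prune r² > 0.1; at most 10
  SNPs), statistic = mean χ² of the selection, and a Freedman–Lane
  permutation null (covariate residuals permuted, selection re-run per
  permutation — the selection is part of the statistic).  Raw-phenotype
  permutation is available but not the default: it destroys the
  covariate-trait relation and would itself induce stratification
  artifacts.  Empirical p = (1 + #{perm ≥ obs})/(1 + B), so p ∈ (0, 1]
  with resolution 1/(B + 1).

## Experiment drivers and problem sizes

Type-I experiments use 20,000 SNPs over 10 chromosomes and 100
phenotype replicates — a desk-scale surrogate for the 1.3M/5.1M-SNP
panels the design emulates.  Consequences of the reduced panel: the
per-replicate spread of stratum λ is larger than genome-wide (the
median-λ sampling sd scales as m^−½ within a stratum, and high-F SNPs
fluctuate together through their shared loading on the ancestry axes),
so replicate *means* are the stable outputs.

Effect-size (power/bias) experiments use a 100,000-SNP panel: the
ancestry axes enter as covariates, and their estimation noise induces a
dataset-level bias at a high-F_ST causal SNP of order ±0.007 at 20k SNPs
(δ = 4), shrinking roughly with panel size.  At 100k SNPs the residual
bias in the distinct design is below the Monte-Carlo resolution of
10,000 replicates, emulating the precision of genome-wide axes.  In the
admixed design a bias of ±0.01–0.02 remains regardless of panel size —
the unobservable θ-vs-realized-ancestry residual described above — so
the unbiasedness check is run across independently simulated panels,
with the Monte-Carlo standard error taken from the between-panel spread
of mean estimates.  This marginalizes a genuine property of the design
(single-panel estimates at extreme-divergence SNPs are biased by their
panel's residual confounding, in either direction) rather than hiding
it; the single-panel spread is itself a finding worth inspecting.

The under-correction experiment runs the admixed design with no
covariates (mds_k = 0): the unambiguous "fewer axes than needed"
condition, for which the F_ST-ordering of residual inflation — the
design's central qualitative claim — is sharpest.

Synthetic gene intervals tile consecutive SNP blocks (default ~40 SNPs
per gene; the calibration runs tile the QC'd panel into 500 equal
blocks).  Set size is a real design constraint, not cosmetic: a set with
s SNPs has probability 0.9^s of selecting nothing under the null (its
empirical p is then exactly 1), so uniformity of set-level p-values is
only a meaningful diagnostic when that atom is small — ~1.5% at s = 40,
but 81% at s = 2.

All randomness descends from one master seed through labeled
SeedSequence streams (per-replicate counters for phenotypes); every
report is a pure function of (config, seed).

## Limitations

* No background LD, no mutation/recombination history, no sex
  chromosomes, exactly two ancestral populations.
* The trait model is a pure mean-shift plus one optional additive SNP;
  no polygenic background, no binary traits.
* The admixed design's F_ST strata are on the homogeneous-vs-admixed
  scale, which is compressed relative to ancestral divergence; absolute
  exceedance percentages in that design are not comparable to
  two-population panels.
* Desk-scale panels reproduce calibration properties, orderings and
  unbiasedness, not data-dependent absolutes (SNP counts, exact λ values
  of a particular real panel, absolute power levels, which depend on the
  real allele frequencies of specific causal SNPs).
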