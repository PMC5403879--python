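"""Effect-size estimates and power at a high-divergence causal SNP.

Reproduces the three-condition design of the power study on a reduced
panel: a causal SNP with estimated F_ST near 0.74 receives a 0.2
per-allele effect; phenotypes are redrawn 2,000 times per condition.  The
conditions separate the cost of the MDS correction itself from any
additional cost of correcting in the presence of trait divergence
(ancestral trait means 0 and 4).
"""

from stratsim import ExperimentConfig, power_design

cfg = ExperimentConfig(scenario="distinct", num_snps=30_000, delta=4.0,
                       snp_effect=0.2, replicates=2_000, seed=5)
table = power_design(cfg)
cols = ["condition", "mds_k", "causal_est_fst", "mean_beta", "power"]
print(table[cols].round(3).to_string(index=False))
print("\nmean_beta near 0.2 in every condition = unbiased estimates; the "
      "drop in power from the first row to the others is the price of "
      "the covariate correction at this sample size (n = 259).")
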