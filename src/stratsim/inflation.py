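"""Genomic inflation diagnostics.

Lambda (genomic inflation factor) estimation overall and within F_ST
strata, QQ-plot data, and the closed-form expected mean chi-square of an
association scan containing tagged causal variants:

    lambda_mean = 1 + (1/L) * sum_j sum_k  N h2_j r2_jk / (1 - h2_j r2_jk)

where L is the number of null SNPs, N the sample size, h2_j the
heritability of causal variant j and r2_jk its LD with tagged SNP k.  The
summand is the non-centrality parameter of the tagged SNP's 1-df test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class LambdaEstimate:
    value: float
    method: str          # "median" or "mean"
    snp_count: int


@dataclass
class TaggedCausal:
    """One causal variant: its heritability and LD with each tagged null SNP."""

    h2: float
    r2: Sequence[float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")
        r2 = np.asarray(self.r2, dtype=np.float64)
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValueError("r2 values must lie in [0, 1]")


@dataclass
class TheoreticalLambdaInputs:
    sample_size: int
    null_snp_count: int
    causals: Sequence[TaggedCausal] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_size < 1 or self.null_snp_count < 1:
            raise ValueError("sample_size and null_snp_count must be >= 1")


def genomic_inflation(statistics: np.ndarray, method: str = "median") -> LambdaEstimate:
    """Genomic inflation factor from 1-df chi-square statistics.

    ``median``: median(statistics) / 0.4549...  (the 1-df chi-square
    median) — the conventional genomic-control estimator, robust to true
    signal in the tail.  ``mean``: mean(statistics), the scale on which
    the closed-form expectation above is stated.
    """
    s = np.asarray(statistics, dtype=np.float64)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no finite statistics supplied")
    if method == "median":
        value = float(np.median(s)) / CHI2_1DF_MEDIAN
    elif method == "mean":
        value = float(np.mean(s))
    else:
        raise ValueError(f"unknown method {method!r}")
    return LambdaEstimate(value=value, method=method, snp_count=int(s.size))


def stratified_lambda(statistics: np.ndarray, masks: dict,
                      method: str = "median") -> dict:
    """Lambda per F_ST stratum; empty strata yield None rather than raising."""
    s = np.asarray(statistics, dtype=np.float64)
    out = {}
    for name, mask in masks.items():
        sub = s[np.asarray(mask, dtype=bool)]
        sub = sub[np.isfinite(sub)]
        out[name] = (genomic_inflation(sub, method=method) if sub.size else None)
    return out


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p under the uniform null.

    Observed p-values are sorted ascending and paired with expected
    quantiles rank/(n+1).  Zero p-values are clamped to the smallest
    positive representable value with a warning.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.maximum(p, 5e-324)
    obs = np.sort(p)
    n = obs.size
    exp = np.arange(1, n + 1) / (n + 1.0)
    return pd.DataFrame({
        "expected_neglog10": -np.log10(exp),
        "observed_neglog10": -np.log10(obs),
    })


def theoretical_lambda_mean(inputs: TheoreticalLambdaInputs) -> float:
    """Expected mean chi-square over the null SNPs of a scan with tagged causals."""
    total = 0.0
    n = inputs.sample_size
    for causal in inputs.causals:
        r2 = np.asarray(causal.r2, dtype=np.float64)
        prod = causal.h2 * r2
        if np.any(prod >= 1.0):
            raise ValueError("h2 * r2 >= 1: non-centrality parameter undefined")
        total += float(np.sum(n * prod / (1.0 - prod)))
    return 1.0 + total / inputs.null_snp_count


def qq_plot(qq: pd.DataFrame, path) -> None:
    """Render QQ data to PNG (requires matplotlib; not part of any analysis)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq["expected_neglog10"], qq["observed_neglog10"], s=4, alpha=0.5)
    lim = max(qq["expected_neglog10"].max(), qq["observed_neglog10"].max())
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
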