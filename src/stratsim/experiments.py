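"""Experiment drivers: type-I error and power/bias simulation studies.

Both experiments fix one genotype dataset (with its QC, F_ST table and
MDS axes) and redraw phenotypes across replicates, mirroring a design in
which real genotypes are fixed and traits are simulated.  Every source of
randomness derives from the master seed through a documented counter
scheme (stream ids in :func:`stratsim.simulate.child_rng`), so each
experiment's outputs are a pure function of (config, seed).

Default panel sizes are desk-scale surrogates for genome-wide data:
20,000 SNPs over 10 chromosomes.  With fewer SNPs the per-replicate
spread of the inflation factor is wider than it would be genome-wide
(the median-lambda sampling sd shrinks with SNP count); replicate means
are comparatively stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .ancestry import classical_mds, ibs_distance, loco_grms
from .assoc import linear_gwas, mlm_loco_gwas
from .fst import fst_for_dataset, stratify_by_fst
from .inflation import genomic_inflation, qq_data, stratified_lambda
from .qc import QcThresholds, apply_qc
from .simulate import (AdmixtureModel, AncestralModel, PhenotypeModel,
                       child_rng, draw_population_freqs, simulate_genotypes,
                       simulate_local_ancestry, simulate_phenotype)


@dataclass
class ExperimentConfig:
    """Settings for one simulation experiment.

    ``scenario`` is ``"distinct"`` (two homogeneous populations, default
    sizes 112/147) or ``"admixed"`` (one homogeneous population of 85 plus
    61 admixed individuals).  ``mds_k`` defaults to 10 for the distinct
    design and 20 for the admixed design (set explicitly to override,
    0 disables the correction).  ``causal_target_fst`` picks the causal
    SNP for the power experiment as the QC-passing SNP whose *estimated*
    F_ST is nearest the target (0.74 distinct / 0.65 admixed).
    """

    scenario: str = "distinct"
    n_pop1: Optional[int] = None
    n_pop2: Optional[int] = None          # admixed count in the admixed scenario
    num_snps: int = 20_000
    num_chromosomes: int = 10
    mds_k: Optional[int] = None
    delta: float = 3.0
    replicates: int = 100
    snp_effect: float = 0.0
    causal_target_fst: Optional[float] = None
    missing_rate: float = 0.0
    seed: int = 0
    use_mlm_loco: bool = False
    admixture: AdmixtureModel = field(default_factory=AdmixtureModel)
    qc: QcThresholds = field(default_factory=QcThresholds)

    def __post_init__(self) -> None:
        if self.scenario not in ("distinct", "admixed"):
            raise ValueError("scenario must be 'distinct' or 'admixed'")
        if self.n_pop1 is None:
            self.n_pop1 = 112 if self.scenario == "distinct" else 85
        if self.n_pop2 is None:
            self.n_pop2 = 147 if self.scenario == "distinct" else 61
        if self.mds_k is None:
            self.mds_k = 10 if self.scenario == "distinct" else 20
        if self.causal_target_fst is None:
            self.causal_target_fst = 0.74 if self.scenario == "distinct" else 0.65
        if min(self.n_pop1, self.n_pop2) < 2:
            raise ValueError("population sizes must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mds_k < 0:
            raise ValueError("mds_k must be >= 0")

    # -- plain key-value config file round trip ---------------------------
    def to_file(self, path) -> None:
        lines = []
        d = asdict(self)
        d["admixture"] = json.dumps(asdict(self.admixture))
        d["qc"] = json.dumps(asdict(self.qc))
        for key, value in d.items():
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "admixture":
                kwargs[key] = AdmixtureModel(**json.loads(value))
            elif key == "qc":
                kwargs[key] = QcThresholds(**json.loads(value))
            elif key in ("scenario",):
                kwargs[key] = value
            elif key in ("use_mlm_loco",):
                kwargs[key] = value == "True"
            elif key in ("delta", "snp_effect", "causal_target_fst", "missing_rate"):
                kwargs[key] = float(value)
            elif value == "None":
                kwargs[key] = None
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps({**asdict(self)}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PreparedData:
    """Dataset + QC + F_ST strata + MDS axes shared across replicates."""

    dataset: object
    qc_report: object
    fst: object
    strata: dict
    mds: object          # MdsComponents or None when mds_k == 0
    covariates: object   # ndarray or None


def prepare_dataset(config: ExperimentConfig) -> PreparedData:
    """Simulate one genotype panel and its structure summaries."""
    model = AncestralModel(num_snps=config.num_snps,
                           num_chromosomes=config.num_chromosomes,
                           seed=config.seed)
    pair = draw_population_freqs(model)
    if config.scenario == "distinct":
        labels = np.array(["pop1"] * config.n_pop1 + ["pop2"] * config.n_pop2)
        dataset = simulate_genotypes(pair, labels, config.missing_rate, seed=config.seed)
    else:
        n = config.n_pop1 + config.n_pop2
        rng = child_rng(config.seed, 5)
        a, b = config.admixture.beta_params()
        thetas = np.concatenate([
            np.zeros(config.n_pop1),
            rng.beta(a, b, config.n_pop2),
        ])
        tracks = simulate_local_ancestry(config.admixture, pair, n,
                                         seed=config.seed, thetas=thetas)
        dataset = simulate_genotypes(pair, tracks, config.missing_rate, seed=config.seed)

    dataset, qc_report = apply_qc(dataset, config.qc)
    fst = fst_for_dataset(dataset)
    strata = stratify_by_fst(fst)
    if config.mds_k > 0:
        mds = classical_mds(ibs_distance(dataset), config.mds_k)
        covariates = mds.scores
    else:
        mds, covariates = None, None
    return PreparedData(dataset, qc_report, fst, strata, mds, covariates)


@dataclass
class TypeIReport:
    """Replicate-level inflation summary for a null-phenotype experiment."""

    strata_summary: pd.DataFrame   # stratum, mean/sd/se of lambda, counts
    replicate_lambdas: pd.DataFrame
    qq: pd.DataFrame               # QQ data from the first replicate, all SNPs
    config: ExperimentConfig
    qc_report: object
    n_failures: int = 0

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.strata_summary.to_csv(outdir / "lambda_summary.tsv", sep="\t", index=False)
        self.replicate_lambdas.to_csv(outdir / "lambda_replicates.tsv", sep="\t", index=False)
        self.qq.to_csv(outdir / "qq_first_replicate.tsv", sep="\t", index=False)
        _write_manifest(outdir, self.config)


@dataclass
class PowerReport:
    """Effect-size and power summary for a causal-SNP experiment."""

    mean_beta: float
    sd_beta: float
    power: float
    alpha: float
    causal_snp: str
    causal_est_fst: float
    causal_true_fst: float
    replicates: int
    config: ExperimentConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "delta": self.config.delta,
            "snp_effect": self.config.snp_effect,
            "mds_k": self.config.mds_k,
            "causal_snp": self.causal_snp,
            "causal_est_fst": self.causal_est_fst,
            "mean_beta": self.mean_beta,
            "sd_beta": self.sd_beta,
            "power": self.power,
        }])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "power_report.tsv", sep="\t", index=False)
        _write_manifest(outdir, self.config)


def _write_manifest(outdir: Path, config: ExperimentConfig) -> None:
    manifest = {
        "package_version": _pkg_version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    config.to_file(outdir / "config.txt")


def run_type1_experiment(config: ExperimentConfig,
                         prepared: Optional[PreparedData] = None) -> TypeIReport:
    """Null-phenotype replicates over a fixed panel; lambda per F_ST stratum.

    Each replicate draws a fresh phenotype with the configured population
    trait divergence and no causal SNP, runs the covariate-adjusted scan
    (or the mixed-model LOCO scan when ``use_mlm_loco``), and records the
    median-based lambda in each stratum.  Failed replicates are counted
    and excluded.
    """
    prep = prepared if prepared is not None else prepare_dataset(config)
    loco = loco_grms(prep.dataset) if config.use_mlm_loco else None

    records = []
    qq = None
    n_failures = 0
    for r in range(config.replicates):
        # deterministic per-replicate stream: (seed, 6, replicate)
        y = _draw_null_phenotype(prep, config, r)
        try:
            if loco is None:
                res = linear_gwas(prep.dataset, y, prep.covariates)
            else:
                res = mlm_loco_gwas(prep.dataset, y, prep.covariates, loco)
            lambdas = stratified_lambda(res["STAT"].to_numpy(), prep.strata)
        except Exception:
            n_failures += 1
            continue
        row = {"replicate": r}
        for name, est in lambdas.items():
            row[name] = est.value if est is not None else np.nan
        records.append(row)
        if qq is None:
            pvals = res["P"].to_numpy()
            qq = qq_data(pvals[np.isfinite(pvals)])

    rep = pd.DataFrame(records)
    summary_rows = []
    for name, mask in prep.strata.items():
        vals = rep[name].to_numpy() if name in rep else np.array([])
        vals = vals[np.isfinite(vals)]
        summary_rows.append({
            "stratum": name,
            "snp_count": int(np.asarray(mask).sum()),
            "n_replicates": vals.size,
            "mean_lambda": float(vals.mean()) if vals.size else np.nan,
            "sd_lambda": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            "se_lambda": (float(vals.std(ddof=1) / np.sqrt(vals.size))
                          if vals.size > 1 else np.nan),
        })
    return TypeIReport(pd.DataFrame(summary_rows), rep, qq, config,
                       prep.qc_report, n_failures)


def _draw_null_phenotype(prep: PreparedData, config: ExperimentConfig,
                         replicate: int) -> np.ndarray:
    model = PhenotypeModel(divergence_delta=config.delta, residual_sd=1.0)
    sub_seed = int(np.random.SeedSequence(
        [config.seed, 6, replicate]).generate_state(1)[0] % (2**31))
    return simulate_phenotype(prep.dataset, model, seed=sub_seed)


def select_causal_snp(prep: PreparedData, target_fst: float,
                      max_distance: float = 0.1) -> int:
    """QC-passing SNP whose estimated F_ST is nearest the target."""
    est = prep.fst.fst
    with np.errstate(invalid="ignore"):
        dist = np.abs(est - target_fst)
    dist[~prep.fst.defined] = np.inf
    j = int(np.nanargmin(dist))
    if dist[j] > max_distance:
        raise ValueError(
            f"no SNP with estimated F_ST within {max_distance} of {target_fst}; "
            "regenerate with a larger panel or heavier divergence tail"
        )
    return j


def run_power_experiment(config: ExperimentConfig,
                         prepared: Optional[PreparedData] = None,
                         alpha: float = 0.05) -> PowerReport:
    """Replicate phenotypes at one high-divergence causal SNP.

    The panel and MDS axes are fixed once; each replicate draws
    y = theta*delta + snp_effect*dosage + N(0,1) and refits the
    covariate-adjusted linear model at the causal SNP only.  Power is the
    fraction of replicates with p < alpha; the report also carries the
    mean and sd of the estimated per-allele effect.
    """
    prep = prepared if prepared is not None else prepare_dataset(config)
    ds = prep.dataset
    j = select_causal_snp(prep, config.causal_target_fst)
    n = ds.n_samples
    theta = ds.sample_meta["theta"].to_numpy()
    g = ds.dosages(impute_mean=True)[:, j]

    from .assoc import design_matrix
    x = design_matrix(prep.covariates, n)
    q_cols = x.shape[1]
    df = n - q_cols - 1
    q, _ = np.linalg.qr(x)
    g_resid = g - q @ (q.T @ g)
    gg = float(g_resid @ g_resid)
    if gg <= 1e-10 * n:
        raise ValueError("causal SNP is collinear with the covariates")

    base = theta * config.delta + config.snp_effect * g
    r = config.replicates
    noise = np.empty((r, n))
    for rep_i in range(r):
        # per-replicate stream: (seed, 7, replicate)
        noise[rep_i] = child_rng(config.seed, 7, rep_i).normal(0.0, 1.0, n)
    y = base[None, :] + noise
    y_resid = y - (y @ q) @ q.T
    gy = y_resid @ g_resid
    yy = np.einsum("ij,ij->i", y_resid, y_resid)
    beta = gy / gg
    rss = np.maximum(yy - beta * gy, 0.0)
    se = np.sqrt(rss / df / gg)
    with np.errstate(divide="ignore"):
        stat = np.where(se > 0, (beta / se) ** 2, np.inf)
    from scipy import stats as _st
    pvals = _st.chi2.sf(stat, df=1)

    return PowerReport(
        mean_beta=float(beta.mean()),
        sd_beta=float(beta.std(ddof=1)),
        power=float((pvals < alpha).mean()),
        alpha=alpha,
        causal_snp=str(ds.snp_meta["snp_id"].iloc[j]),
        causal_est_fst=float(prep.fst.fst[j]),
        causal_true_fst=float(ds.snp_meta["true_fst"].iloc[j]),
        replicates=r,
        config=config,
    )


def power_design(config: ExperimentConfig,
                 prepared: Optional[PreparedData] = None) -> pd.DataFrame:
    """Three-condition power table for one scenario.

    Columns follow the standard design: no divergence / no correction,
    no divergence / with correction, divergence / with correction — all on
    the same fixed panel and causal SNP.
    """
    prep = prepared if prepared is not None else prepare_dataset(config)
    arms = [
        ("no_divergence_no_mds", replace(config, delta=0.0, mds_k=0)),
        ("no_divergence_with_mds", replace(config, delta=0.0)),
        ("divergence_with_mds", config),
    ]
    rows = []
    for name, arm_cfg in arms:
        arm_prep = prep
        if arm_cfg.mds_k != config.mds_k:
            arm_prep = PreparedData(prep.dataset, prep.qc_report, prep.fst,
                                    prep.strata, None, None)
        report = run_power_experiment(arm_cfg, prepared=arm_prep)
        row = report.to_frame()
        row.insert(0, "condition", name)
        rows.append(row)
    return pd.concat(rows, ignore_index=True)
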