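"""PLINK bed/bim/fam reading and writing.

SNP-major bed layout, 2-bit genotype codes (00 = two copies of allele 1,
10 = het, 11 = zero copies, 01 = missing).  The bim file stores the
genetic position in Morgans and a base-pair position of
round(morgans * 1e6); alleles are written as A/B with the stored dosage
counting allele A.  Writing then reading reproduces the dosage matrix,
SNP order and sample order exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeDataset

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = bytes([0x01])

# dosage (count of allele A) -> 2-bit code, and back
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    """Malformed bed payload (bad magic bytes, truncation, unknown mode)."""


class PlinkConsistencyError(ValueError):
    """bed/bim/fam triplet with inconsistent dimensions."""


def write_plink(dataset: GenotypeDataset, prefix) -> None:
    """Write the dataset as ``prefix``.bed/.bim/.fam."""
    prefix = Path(prefix)
    n, m = dataset.genotypes.shape

    codes = np.empty((m, n), dtype=np.uint8)
    g = dataset.genotypes.T  # SNP-major
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[g == dosage] = code
    n_pad = (-n) % 4
    if n_pad:
        codes = np.concatenate(
            [codes, np.zeros((m, n_pad), dtype=np.uint8)], axis=1)
    quads = codes.reshape(m, -1, 4)
    packed = (quads[:, :, 0] | (quads[:, :, 1] << 2)
              | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())

    bim = pd.DataFrame({
        "chrom": dataset.snp_meta["chrom"].to_numpy(),
        "snp_id": dataset.snp_meta["snp_id"].to_numpy(),
        "pos_morgan": dataset.snp_meta["pos_morgan"].to_numpy(),
        "pos_bp": dataset.snp_meta["pos_bp"].to_numpy(),
        "a1": "A",
        "a2": "B",
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame({
        "fid": dataset.sample_meta["population"].to_numpy(),
        "iid": dataset.sample_meta["sample_id"].to_numpy(),
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeDataset:
    """Read a bed/bim/fam triplet back into a :class:`GenotypeDataset`.

    Population labels are recovered from the fam FID column; quantities
    that PLINK files do not carry (true divergence, ancestry fractions)
    come back as NaN.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "pos_morgan", "pos_bp", "a1", "a2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise PlinkFormatError("bed file does not start with the PLINK magic bytes")
    if raw[2:3] != _SNP_MAJOR:
        raise PlinkFormatError("only SNP-major bed files are supported")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_snp:
        raise PlinkConsistencyError(
            f"bed payload holds {payload.size} bytes but bim/fam imply "
            f"{m} x {bytes_per_snp}"
        )
    packed = payload.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (packed >> (2 * shift)) & 0b11
    geno = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    snp_meta = pd.DataFrame({
        "snp_id": bim["snp_id"].astype(str),
        "chrom": bim["chrom"].astype(int),
        "pos_morgan": bim["pos_morgan"].astype(float),
        "pos_bp": bim["pos_bp"].astype(int),
        "true_fst": np.nan,
    })
    sample_meta = pd.DataFrame({
        "sample_id": fam["iid"].astype(str),
        "population": fam["fid"].astype(str),
        "theta": np.nan,
    })
    return GenotypeDataset(geno, snp_meta, sample_meta)


def write_phenotype(phenotype: np.ndarray, sample_meta: pd.DataFrame, path) -> None:
    """Phenotype table (FID IID PHENO), tab-separated with header."""
    pd.DataFrame({
        "FID": sample_meta["population"].to_numpy(),
        "IID": sample_meta["sample_id"].to_numpy(),
        "PHENO": np.asarray(phenotype, dtype=np.float64),
    }).to_csv(path, sep="\t", index=False)


def write_ancestry(sample_meta: pd.DataFrame, path) -> None:
    """Ancestry table (FID IID THETA), tab-separated with header."""
    pd.DataFrame({
        "FID": sample_meta["population"].to_numpy(),
        "IID": sample_meta["sample_id"].to_numpy(),
        "THETA": sample_meta["theta"].to_numpy(),
    }).to_csv(path, sep="\t", index=False)
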