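"""Minimal PLINK 1 binary (.bed/.bim/.fam) reader and writer.

The .bed file stores genotypes SNP-major, 2 bits per sample, 4 samples per
byte, low bits first.  Codes: 00 = two copies of allele 1, 10 = one copy,
11 = zero copies, 01 = missing.  Dosages returned here count allele 1 (the
A1/minor allele by PLINK convention), with NaN for missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PlinkReader", "read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# byte -> 4 dosages; -1 encodes missing
_DECODE = np.empty((256, 4), dtype=np.int8)
_CODE_TO_DOSE = {0b00: 2, 0b01: -1, 0b10: 1, 0b11: 0}
for _byte in range(256):
    for _k in range(4):
        _DECODE[_byte, _k] = _CODE_TO_DOSE[(_byte >> (2 * _k)) & 0b11]
_ENCODE_DOSE = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}

_FAM_COLS = ["fid", "iid", "father", "mother", "sex", "phenotype"]
_BIM_COLS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]


@dataclass
class PlinkReader:
    """Lazy per-SNP access to a PLINK 1 fileset."""

    fam: pd.DataFrame
    bim: pd.DataFrame
    _bed: np.ndarray  # raw bytes, m x bytes_per_snp

    @property
    def n_samples(self) -> int:
        return len(self.fam)

    @property
    def n_snps(self) -> int:
        return len(self.bim)

    def snp_dosages(self, index: int) -> np.ndarray:
        """Float dosages (allele-1 counts) for one SNP; NaN = missing."""
        raw = _DECODE[self._bed[index]].reshape(-1)[: self.n_samples]
        out = raw.astype(float)
        out[raw == -1] = np.nan
        return out

    def dosage_matrix(self, indices=None) -> np.ndarray:
        if indices is None:
            indices = range(self.n_snps)
        return np.column_stack([self.snp_dosages(i) for i in indices])

    def iter_snps(self, indices=None):
        if indices is None:
            indices = range(self.n_snps)
        for i in indices:
            yield i, self.snp_dosages(i)


def read_plink(prefix: str) -> PlinkReader:
    """Open ``prefix``.bed/.bim/.fam with format validation."""
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing {prefix + ext}")
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=_FAM_COLS, dtype={"fid": str, "iid": str})
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=_BIM_COLS, dtype={"chrom": str, "snp_id": str})
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes (not PLINK 1)")
        if header[2] != _SNP_MAJOR:
            raise ValueError(f"{prefix}.bed: not in SNP-major mode")
        body = fh.read()
    bytes_per_snp = (n + 3) // 4
    if len(body) != m * bytes_per_snp:
        raise ValueError(
            f"{prefix}.bed: expected {m * bytes_per_snp} data bytes for "
            f"{m} SNPs x {n} samples, found {len(body)} (truncated or "
            "sample-count mismatch)"
        )
    bed = np.frombuffer(body, dtype=np.uint8).reshape(m, bytes_per_snp)
    return PlinkReader(fam=fam, bim=bim, _bed=bed)


def write_plink(
    prefix: str,
    genotypes: np.ndarray,
    sample_ids=None,
    snp_ids=None,
    chroms=None,
    positions=None,
    a1: str = "A",
    a2: str = "B",
) -> None:
    """Write an n x m dosage matrix (allele-1 counts; NaN missing) as
    PLINK 1 .bed/.bim/.fam."""
    G = np.asarray(genotypes)
    n, m = G.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [f"snp{t + 1}" for t in range(m)]
    if chroms is None:
        chroms = ["1"] * m
    if positions is None:
        positions = np.arange(1, m + 1) * 1000

    fam = pd.DataFrame({
        "fid": sample_ids, "iid": sample_ids,
        "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        "chrom": chroms, "snp_id": snp_ids, "cm": 0,
        "pos": positions, "a1": a1, "a2": a2,
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    bytes_per_snp = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        buf = np.zeros(bytes_per_snp, dtype=np.uint8)
        for t in range(m):
            col = G[:, t]
            buf[:] = 0
            for j in range(n):
                v = col[j]
                code = _ENCODE_DOSE[-1 if not np.isfinite(float(v))
                                    else int(round(float(v)))]
                buf[j // 4] |= code << (2 * (j % 4))
            fh.write(buf.tobytes())
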