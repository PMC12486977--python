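"""PLINK 1 binary genotype I/O and the in-memory genotype container.

Genotypes are stored as counts of the A1 allele (the first allele column of
the BIM file), with ``-1`` marking a missing call.  The BED decoder follows
the PLINK 1 SNP-major 2-bit encoding: per SNP, four samples per byte, least
significant bits first, with ``00`` = homozygous A1, ``10`` = heterozygous,
``11`` = homozygous A2 and ``01`` = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BED_MAGIC = bytes([0x6C, 0x1B])
_MODE_SNP_MAJOR = 0x01
# 2-bit code -> A1 allele count (-1 = missing)
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """Malformed or inconsistent BED/BIM/FAM file set."""


@dataclass
class GenotypePanel:
    """SNP genotypes with map positions, sample metadata and breed labels.

    Attributes
    ----------
    genotypes
        ``(n_individuals, n_snps)`` int8 array of A1 allele counts in
        {0, 1, 2}, ``-1`` for missing.
    snp_map
        Per-SNP table with columns ``chrom, snp, cm, pos, a1, a2``;
        positions strictly increase within each chromosome.
    samples
        Per-individual table with at least ``fid`` and ``iid``.
    breed_label
        Per-individual breed assignment, aligned with ``samples``.
    phased_haplotypes
        Optional ``(2 * n_individuals, n_snps)`` binary array of A1
        indicators; row ``2i`` and ``2i+1`` are the two haplotypes of
        individual ``i`` and sum to the genotype row.
    """

    genotypes: np.ndarray
    snp_map: pd.DataFrame
    samples: pd.DataFrame
    breed_label: np.ndarray | None = None
    phased_haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise PlinkFormatError("genotypes must be 2-D (individuals x SNPs)")
        n, m = self.genotypes.shape
        if len(self.snp_map) != m:
            raise PlinkFormatError(
                f"snp_map has {len(self.snp_map)} rows for {m} SNP columns"
            )
        if len(self.samples) != n:
            raise PlinkFormatError(
                f"samples has {len(self.samples)} rows for {n} genotype rows"
            )
        if self.breed_label is not None:
            self.breed_label = np.asarray(self.breed_label)
            if self.breed_label.shape[0] != n:
                raise PlinkFormatError("breed_label length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP A1 allele frequency, ignoring missing calls."""
        g = self.genotypes
        valid = g >= 0
        with np.errstate(invalid="ignore"):
            return np.where(valid, g, 0).sum(axis=0) / (2.0 * valid.sum(axis=0))

    def dosages(self) -> np.ndarray:
        """Float genotype matrix with missing calls mean-imputed per SNP."""
        g = self.genotypes.astype(np.float64)
        missing = self.genotypes < 0
        if missing.any():
            mean = 2.0 * self.allele_freq()
            g[missing] = np.broadcast_to(mean, g.shape)[missing]
        return g

    def subset(self, individuals=None, snps=None) -> "GenotypePanel":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if snp.dtype == bool:
            snp = np.flatnonzero(snp)
        phased = None
        if self.phased_haplotypes is not None:
            hap_rows = np.column_stack([2 * ind, 2 * ind + 1]).ravel()
            phased = self.phased_haplotypes[np.ix_(hap_rows, snp)]
        return GenotypePanel(
            genotypes=self.genotypes[np.ix_(ind, snp)],
            snp_map=self.snp_map.iloc[snp].reset_index(drop=True),
            samples=self.samples.iloc[ind].reset_index(drop=True),
            breed_label=None if self.breed_label is None else self.breed_label[ind],
            phased_haplotypes=phased,
        )


def _decode_bed_bytes(data: np.ndarray, n_snps: int, n_ind: int) -> np.ndarray:
    """Decode SNP-major packed 2-bit genotypes into (n_ind, n_snps) counts."""
    bytes_per_snp = (n_ind + 3) // 4
    data = data.reshape(n_snps, bytes_per_snp)
    # expand each byte into 4 two-bit codes, least significant first
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    return _CODE_TO_COUNT[codes[:, :n_ind]].T.copy()


def _encode_bed_bytes(genotypes: np.ndarray) -> bytes:
    n_ind, n_snps = genotypes.shape
    bytes_per_snp = (n_ind + 3) // 4
    codes = np.full((n_snps, bytes_per_snp * 4), 0b01, dtype=np.uint8)
    gt = genotypes.T
    for count, code in _COUNT_TO_CODE.items():
        codes[:, :n_ind][gt == count] = code
    packed = np.zeros((n_snps, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    return packed.tobytes()


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 ``prefix.bed/.bim/.fam`` file set.

    Raises :class:`PlinkFormatError` on a bad magic number, a truncated BED
    payload, or BIM/FAM row counts inconsistent with the BED size.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None, names=BIM_COLUMNS,
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, names=FAM_COLUMNS,
        dtype={"fid": str, "iid": str},
    )
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad BED magic bytes at offset 0")
    if raw[2] != _MODE_SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only SNP-major BED (mode 0x01) is supported")
    n_ind, n_snps = len(fam), len(bim)
    expected = 3 + n_snps * ((n_ind + 3) // 4)
    if raw.size != expected:
        raise PlinkFormatError(
            f"{bed_path}: {raw.size} bytes, expected {expected} for "
            f"{n_snps} SNPs x {n_ind} individuals (BIM/FAM inconsistency or truncation)"
        )
    genotypes = _decode_bed_bytes(raw[3:], n_snps, n_ind)
    breed = fam["fid"].to_numpy() if fam["fid"].nunique() > 1 else None
    return GenotypePanel(genotypes=genotypes, snp_map=bim, samples=fam, breed_label=breed)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK 1 ``prefix.bed/.bim/.fam``.

    Breed labels, when present, are stored in the FAM family-ID column.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_MODE_SNP_MAJOR]))
        fh.write(_encode_bed_bytes(panel.genotypes))
    bim = panel.snp_map[BIM_COLUMNS]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = panel.samples.copy()
    for col, default in [("father", "0"), ("mother", "0"), ("sex", 0), ("phenotype", -9)]:
        if col not in fam.columns:
            fam[col] = default
    if panel.breed_label is not None:
        fam["fid"] = panel.breed_label
    fam[FAM_COLUMNS].to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
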