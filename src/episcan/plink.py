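"""PLINK 1 bed/bim/fam reader and writer (v1.00, SNP-major).

Genotypes are stored two bits per call, four calls per byte, LSB first:
00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2.
A1 is written as the minor allele, so the in-memory additive code (count
of minor alleles) maps 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11.

Gene labels are not part of the PLINK format; they are carried in an
optional ``<prefix>.snps.tsv`` sidecar written next to the triple and
read back when present.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = ["PlinkFormatError", "read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> additive minor-allele count (nan = missing)
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    pass


def write_plink(prefix: str | Path, geno: GenotypeMatrix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = geno.snp_meta
    n_ind = geno.n_individuals

    with open(prefix.with_suffix(".bim"), "w", encoding="utf-8") as fh:
        for _, row in meta.iterrows():
            a1 = row["minor_allele"]
            a2 = (
                row["other_allele"]
                if row["effect_allele"] == a1
                else row["effect_allele"]
            )
            fh.write(f"{row['chrom']}\t{row['rsid']}\t0\t{int(row['pos'])}\t{a1}\t{a2}\n")

    with open(prefix.with_suffix(".fam"), "w", encoding="utf-8") as fh:
        for iid in geno.individual_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")

    g = geno.genotypes.T  # SNP-major
    codes = np.full(g.shape, 1, dtype=np.uint8)  # missing
    codes[g == 2.0] = 0b00
    codes[g == 1.0] = 0b10
    codes[g == 0.0] = 0b11
    pad = (-n_ind) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((codes.shape[0], pad), dtype=np.uint8)], axis=1
        )
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())

    meta.to_csv(prefix.parent / (prefix.name + ".snps.tsv"), sep="\t", index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    bim_df = pd.read_csv(
        bim,
        sep="\t",
        header=None,
        names=["chrom", "rsid", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "rsid": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(
        fam,
        sep="\t",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n_snps, n_ind = len(bim_df), len(fam_df)
    if n_snps == 0 or n_ind == 0:
        raise PlinkFormatError("empty bim or fam file")

    raw = bed.read_bytes()
    if raw[:3] != _MAGIC:
        if len(raw) >= 2 and raw[:2] == _MAGIC[:2]:
            raise PlinkFormatError(
                "bed file is not in SNP-major mode (third magic byte != 0x01)"
            )
        raise PlinkFormatError("bad bed magic bytes; not a PLINK 1 bed file")
    bytes_per_snp = (n_ind + 3) // 4
    expected = 3 + n_snps * bytes_per_snp
    if len(raw) != expected:
        raise PlinkFormatError(
            f"bed length {len(raw)} != expected {expected} "
            f"({n_snps} SNPs x {bytes_per_snp} bytes + 3); truncated or "
            "fam/bim row counts disagree with bed"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    geno = _DECODE[codes[:, :n_ind]].T  # individuals x SNPs

    sidecar = prefix.parent / (prefix.name + ".snps.tsv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t", dtype={"rsid": str, "chrom": str})
    else:
        meta = pd.DataFrame(
            {
                "rsid": bim_df["rsid"],
                "gene": "",
                "chrom": bim_df["chrom"],
                "pos": bim_df["pos"],
                "effect_allele": bim_df["a1"],
                "other_allele": bim_df["a2"],
                "minor_allele": bim_df["a1"],
            }
        )
    return GenotypeMatrix(geno, meta, list(fam_df["iid"]))
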