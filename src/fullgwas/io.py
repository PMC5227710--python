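"""PLINK-format genotype I/O and the phenotype TSV.

Supported formats: text .ped/.map (whitespace-delimited, alleles as bases)
and binary .bed/.bim/.fam in SNP-major order.  The phenotype table is a TSV
with header columns ``iid, sex, ethnicity, exam, value``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PhenotypeTable, SNP_META_COLUMNS

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major


# ---------------------------------------------------------------------------
# .ped / .map


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    snps = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str, "id": str},
    )
    m = len(snps)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    alleles: list[list[dict]] = []  # per SNP: allele -> count, built lazily
    raw: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            samples.append(parts[1])
            raw.append(parts[6:])
    n = len(samples)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    major = []
    minor = []
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in (raw[i][2 * j], raw[i][2 * j + 1]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ValueError(f"SNP {snps['id'][j]!r} has more than two alleles")
        # major = most frequent (ties: lexicographic)
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        maj = ordered[0][0] if ordered else "A"
        mnr = ordered[1][0] if len(ordered) > 1 else ("G" if maj != "G" else "A")
        major.append(maj)
        minor.append(mnr)
        for i in range(n):
            a1, a2 = raw[i][2 * j], raw[i][2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == maj) + (a2 == maj)
    snps = snps.assign(major=major, minor=minor)[SNP_META_COLUMNS]
    return GenotypeMatrix(np.array(samples, dtype=object), snps, calls)


def write_ped_map(
    genotypes: GenotypeMatrix,
    prefix: str | Path,
    phenotypes: PhenotypeTable | None = None,
) -> None:
    """Write .ped/.map; sex (PLINK 1=male, 2=female) and the first-exam
    trait value are filled from ``phenotypes`` when given."""
    prefix = Path(prefix)
    snps = genotypes.snps
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, s in snps.iterrows():
            fh.write(f"{s['chrom']}\t{s['id']}\t0\t{s['pos']}\n")
    sex_of: dict = {}
    val_of: dict = {}
    if phenotypes is not None:
        first = phenotypes.records.drop_duplicates("iid")
        sex_of = dict(zip(first["iid"], first["sex"]))
        val_of = dict(zip(first["iid"], first["value"]))
    maj = snps["major"].to_numpy()
    mnr = snps["minor"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(genotypes.samples):
            sex = sex_of.get(iid)
            plink_sex = {1: "1", 0: "2"}.get(sex, "0")
            val = val_of.get(iid, -9)
            fields = [str(iid), str(iid), "0", "0", plink_sex, str(val)]
            row = genotypes.calls[i]
            for j, c in enumerate(row):
                if c == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [maj[j]] * int(c) + [mnr[j]] * int(2 - c)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# .bed / .bim / .fam

# 2-bit genotype codes in a .bed byte, A1 = minor allele:
#   00 hom A1 (minor)  -> 0 major alleles
#   01 missing
#   10 het             -> 1 major allele
#   11 hom A2 (major)  -> 2 major alleles
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_bed(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "minor", "major"],
        dtype={"chrom": str, "id": str, "minor": str, "major": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise ValueError("not a SNP-major .bed file")
    body = np.frombuffer(data[3:], dtype=np.uint8)
    stride = (n + 3) // 4
    if len(body) != stride * m:
        raise ValueError(".bed size does not match .bim/.fam dimensions")
    body = body.reshape(m, stride)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, stride * 4)[:, :n]
    calls = _BED_DECODE[codes].T.copy()
    snps = bim[["chrom", "id", "pos", "major", "minor"]].reset_index(drop=True)
    return GenotypeMatrix(fam["iid"].to_numpy(dtype=object), snps, calls)


def write_bed(
    genotypes: GenotypeMatrix,
    prefix: str | Path,
    phenotypes: PhenotypeTable | None = None,
) -> None:
    prefix = Path(prefix)
    snps = genotypes.snps
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, s in snps.iterrows():
            fh.write(f"{s['chrom']}\t{s['id']}\t0\t{s['pos']}\t{s['minor']}\t{s['major']}\n")
    sex_of: dict = {}
    val_of: dict = {}
    if phenotypes is not None:
        first = phenotypes.records.drop_duplicates("iid")
        sex_of = dict(zip(first["iid"], first["sex"]))
        val_of = dict(zip(first["iid"], first["value"]))
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in genotypes.samples:
            plink_sex = {1: "1", 0: "2"}.get(sex_of.get(iid), "0")
            fh.write(f"{iid} {iid} 0 0 {plink_sex} {val_of.get(iid, -9)}\n")
    n, m = genotypes.n_samples, genotypes.n_snps
    stride = (n + 3) // 4
    enc = np.array([_BED_ENCODE[c] for c in (0, 1, 2)], dtype=np.uint8)
    codes = np.full((m, stride * 4), _BED_ENCODE[MISSING], dtype=np.uint8)
    calls = genotypes.calls.T
    valid = calls != MISSING
    codes[:, :n] = np.where(valid, enc[np.clip(calls, 0, 2)], _BED_ENCODE[MISSING])
    codes[:, n:] = 0  # pad bits
    shifts = np.arange(4) * 2
    packed = (
        (codes.reshape(m, stride, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    """Read .bed/.bim/.fam if present, else .ped/.map."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return read_bed(prefix)
    return read_ped_map(prefix)


# ---------------------------------------------------------------------------
# phenotype TSV


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"iid": str, "exam": str})
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)
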