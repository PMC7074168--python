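"""PLINK genotype file formats: text PED/MAP and binary BED/BIM/FAM.

Dosages are coded as the count of the A1 allele. For BED/BIM/FAM the A1
allele is explicit in the BIM file; for PED/MAP (which carries no allele
metadata) the reader follows PLINK's convention and counts the minor allele
(ties broken by the lexicographically smaller allele), unless reference
alleles are supplied.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataFormatError
from .genotypes import GenotypeMatrix

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major


def _with_ext(prefix, ext: str) -> Path:
    """prefix + extension, robust to dots inside the prefix itself."""
    return Path(str(prefix) + ext)


# ---------------------------------------------------------------------------
# MAP / BIM / FAM
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "snp", "cm", "pos_bp"],
        dtype={"chrom": str},
    )
    if df.isna().any().any():
        raise DataFormatError(f"{path}: malformed MAP line")
    return df


def _read_bim(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "a1": str, "a2": str},
    )
    if df.isna().any().any():
        raise DataFormatError(f"{path}: malformed BIM line")
    return df


def _read_fam(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "iid", "sire", "dam", "sex", "phen"], dtype=str,
    )


def _to_genotype_matrix(ids, map_df: pd.DataFrame, dosages: np.ndarray) -> GenotypeMatrix:
    snp_map = map_df.copy()
    if "a1" not in snp_map.columns:
        snp_map["a1"] = "?"
        snp_map["a2"] = "?"
    snp_map["chrom"] = [_maybe_int(c) for c in snp_map["chrom"]]
    snp_map["pos_bp"] = snp_map["pos_bp"].astype(int)
    order = np.lexsort((snp_map["pos_bp"].to_numpy(),
                        np.array([str(c) for c in snp_map["chrom"]], dtype=object)))
    # preserve file order when already sorted; otherwise sort by (chrom, pos)
    key = snp_map[["chrom", "pos_bp"]]
    if not key.equals(key.sort_values(["chrom", "pos_bp"])):
        snp_map = snp_map.iloc[order].reset_index(drop=True)
        dosages = dosages[:, order]
    cols = ["snp", "chrom", "pos_bp", "cm", "a1", "a2"]
    return GenotypeMatrix(np.array(ids, dtype=object), snp_map[cols].reset_index(drop=True), dosages)


def _maybe_int(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return str(c)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped(prefix) -> GenotypeMatrix:
    """Read text PED/MAP; dosage counts the minor allele (A1)."""
    prefix = Path(prefix)
    map_df = _read_map(_with_ext(prefix, '.map'))
    m = len(map_df)
    ids = []
    allele_rows = []
    with open(_with_ext(prefix, '.ped')) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise DataFormatError(
                    f"{_with_ext(prefix, '.ped')}:{lineno}: expected "
                    f"{6 + 2 * m} fields for {m} MAP SNPs, got {len(parts)}"
                )
            ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), m, 2)
    dosages = np.full((len(ids), m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        seen = col[col != "0"]
        uniq, counts = np.unique(seen, return_counts=True)
        if len(uniq) > 2:
            raise DataFormatError(
                f"SNP {map_df['snp'][j]!r} has more than two alleles"
            )
        if len(uniq) == 0:
            a1, a2 = "?", "?"
        elif len(uniq) == 1:
            a1, a2 = uniq[0], "?"
        else:
            # A1 = minor allele, lexicographic tie-break
            order = np.lexsort((uniq, counts))
            a1, a2 = uniq[order[0]], uniq[order[1]]
        a1_list.append(a1)
        a2_list.append(a2)
        missing = (col == "0").any(axis=1)
        dosages[:, j] = np.where(missing, np.nan, (col == a1).sum(axis=1))
    map_df = map_df.assign(a1=a1_list, a2=a2_list)
    return _to_genotype_matrix(ids, map_df, dosages)


def write_ped(genotypes: GenotypeMatrix, prefix) -> None:
    """Write PED/MAP; dosage d becomes d copies of a1 and 2-d of a2."""
    prefix = Path(prefix)
    sm = genotypes.snp_map
    cm = sm["cm"] if "cm" in sm.columns else 0.0
    pd.DataFrame(
        {"chrom": sm["chrom"], "snp": sm["snp"], "cm": cm, "pos_bp": sm["pos_bp"]}
    ).to_csv(_with_ext(prefix, '.map'), sep="\t", header=False, index=False)
    a1 = sm["a1"].to_numpy()
    a2 = sm["a2"].to_numpy()
    with open(_with_ext(prefix, '.ped'), "w") as fh:
        for i, animal in enumerate(genotypes.animal_ids):
            fields = ["FAM", str(animal), "0", "0", "0", "-9"]
            for j, d in enumerate(genotypes.dosages[i]):
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM
# ---------------------------------------------------------------------------

#: 2-bit BED codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def read_bed(prefix) -> GenotypeMatrix:
    """Read binary BED/BIM/FAM (SNP-major); dosage counts the BIM A1 allele."""
    prefix = Path(prefix)
    bim = _read_bim(_with_ext(prefix, '.bim'))
    fam = _read_fam(_with_ext(prefix, '.fam'))
    n, m = len(fam), len(bim)
    data = Path(_with_ext(prefix, '.bed')).read_bytes()
    if data[:3] != BED_MAGIC:
        raise DataFormatError(
            f"{_with_ext(prefix, '.bed')}: bad magic bytes at offset 0: "
            f"{data[:3].hex()} (expected {BED_MAGIC.hex()}, SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(data) != expected:
        raise DataFormatError(
            f"{_with_ext(prefix, '.bed')}: truncated at byte {len(data)} "
            f"(expected {expected} for {n} samples x {m} SNPs)"
        )
    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within each byte (little-endian pairs)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T.copy()
    return _to_genotype_matrix(fam["iid"].to_list(), bim, dosages)


def write_bed(genotypes: GenotypeMatrix, prefix) -> None:
    """Write binary BED/BIM/FAM (SNP-major)."""
    prefix = Path(prefix)
    sm = genotypes.snp_map
    cm = sm["cm"] if "cm" in sm.columns else 0.0
    pd.DataFrame(
        {
            "chrom": sm["chrom"], "snp": sm["snp"], "cm": cm,
            "pos_bp": sm["pos_bp"], "a1": sm["a1"], "a2": sm["a2"],
        }
    ).to_csv(_with_ext(prefix, '.bim'), sep="\t", header=False, index=False)
    pd.DataFrame(
        {
            "fid": "FAM", "iid": genotypes.animal_ids, "sire": "0",
            "dam": "0", "sex": "0", "phen": "-9",
        }
    ).to_csv(_with_ext(prefix, '.fam'), sep="\t", header=False, index=False)
    n, m = genotypes.n_animals, genotypes.n_snps
    bytes_per_snp = (n + 3) // 4
    inv = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    out = bytearray(BED_MAGIC)
    for j in range(m):
        col = genotypes.dosages[:, j]
        codes = np.full(bytes_per_snp * 4, 0b01, dtype=np.uint8)  # pad = missing
        for dose, code in inv.items():
            codes[:n][col == dose] = code
        codes[:n][np.isnan(col)] = 0b01
        packed = (
            codes[0::4]
            | (codes[1::4] << 2)
            | (codes[2::4] << 4)
            | (codes[3::4] << 6)
        )
        out += packed.tobytes()
    Path(_with_ext(prefix, '.bed')).write_bytes(bytes(out))


def read_plink(prefix) -> GenotypeMatrix:
    """Read genotypes from PREFIX.{bed,bim,fam} or PREFIX.{ped,map}."""
    prefix = Path(prefix)
    if _with_ext(prefix, '.bed').exists():
        return read_bed(prefix)
    if _with_ext(prefix, '.ped').exists():
        return read_ped(prefix)
    raise DataFormatError(f"no PLINK files found at prefix {prefix}")
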