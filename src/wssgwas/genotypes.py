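"""Genotype matrix container: animals x SNPs allele dosages plus map metadata."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

#: snp_map columns required everywhere: SNP id, chromosome, bp position, alleles
MAP_COLUMNS = ["snp", "chrom", "pos_bp", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix with per-SNP map metadata.

    ``dosages`` is a float array of shape (n_animals, n_snps) holding counts of
    the a1 allele in {0, 1, 2} with NaN for missing calls. ``snp_map`` is a
    DataFrame with columns snp, chrom, pos_bp, a1, a2 (plus optional cm),
    sorted by (chrom, pos_bp).
    """

    animal_ids: np.ndarray
    snp_map: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ConfigurationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )
        for col in ("snp", "chrom", "pos_bp"):
            if col not in self.snp_map.columns:
                raise ConfigurationError(f"snp_map lacks required column {col!r}")
        key = self.snp_map[["chrom", "pos_bp"]]
        if not key.equals(key.sort_values(["chrom", "pos_bp"])):
            raise ConfigurationError("snp_map must be sorted by (chrom, position)")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Row/column subset; keeps map metadata aligned."""
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        s = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            self.animal_ids[a],
            self.snp_map.iloc[s].reset_index(drop=True),
            self.dosages[np.ix_(a, s)],
        )

    def select_animals(self, ids) -> "GenotypeMatrix":
        lookup = {x: i for i, x in enumerate(self.animal_ids)}
        try:
            idx = [lookup[x] for x in ids]
        except KeyError as exc:
            raise ConfigurationError(
                f"animal {exc.args[0]!r} has no genotype record"
            ) from None
        return self.subset(animal_idx=idx)
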