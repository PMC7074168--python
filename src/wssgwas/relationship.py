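"""Relationship matrices for single-step evaluation.

Builds the pedigree numerator relationship matrix A (tabular method), its
sparse inverse (Henderson's rules with Meuwissen-Luo inbreeding), the marker
based relationship matrix G (VanRaden, with per-SNP variance weights), and the
single-step inverse

    H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]

where the correction applies to the genotyped-by-genotyped block.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .exceptions import ConfigurationError, NumericalError
from .genotypes import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree


@dataclass
class AlleleFrequencies:
    """Per-SNP frequency of the counted (a1) allele, strictly inside (0, 1)."""

    p: np.ndarray
    source: str = "observed"  # "observed" | "supplied"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.size == 0:
            raise ConfigurationError("empty allele-frequency vector")
        if np.any((self.p <= 0.0) | (self.p >= 1.0)):
            bad = int(np.nonzero((self.p <= 0.0) | (self.p >= 1.0))[0][0])
            raise ConfigurationError(
                f"allele frequency out of (0,1) at SNP index {bad} "
                "(monomorphic SNPs should have been removed by the MAF filter)"
            )

    @property
    def het_variance(self) -> np.ndarray:
        """Per-SNP 2 p (1 - p)."""
        return 2.0 * self.p * (1.0 - self.p)


@dataclass
class SnpWeightVector:
    """Diagonal D of per-SNP variance weights; trace is kept at the SNP count."""

    d: np.ndarray
    iteration: int = 1

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if np.any(self.d < 0):
            raise ConfigurationError("SNP weights must be nonnegative")

    @classmethod
    def identity(cls, n_snps: int) -> "SnpWeightVector":
        return cls(np.ones(n_snps), iteration=1)

    @property
    def trace(self) -> float:
        return float(self.d.sum())


@dataclass
class RelationshipMatrix:
    """Square symmetric relationship matrix over an ordered id list."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # "A" | "A22" | "G" | "H_inverse_correction"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ConfigurationError("relationship matrix shape does not match ids")
        if n and not np.allclose(self.values, self.values.T, atol=1e-10):
            raise NumericalError(f"{self.kind} matrix is not symmetric to 1e-10")


def _kinship(i: int, j: int, sire: np.ndarray, dam: np.ndarray, memo: dict) -> float:
    """Recursive Malecot kinship phi(i, j), memoised, iterative (no deep recursion)."""
    pending = [(i, j)]
    while pending:
        a, b = pending[-1]
        if a > b:
            a, b = b, a
        if (a, b) in memo:
            pending.pop()
            continue
        if a == UNKNOWN or b == UNKNOWN:
            memo[(a, b)] = 0.0
            pending.pop()
            continue
        if a == b:
            need = [(sire[a], dam[a])]
        else:
            # b is the later animal in the parents-first ordering
            need = [(a, sire[b]), (a, dam[b])]
        need = [(min(x, y), max(x, y)) for x, y in need]
        unresolved = [k for k in need if k not in memo and UNKNOWN not in k]
        if unresolved:
            pending.extend(unresolved)
            continue
        def val(key):
            return 0.0 if UNKNOWN in key else memo[key]
        if a == b:
            memo[(a, b)] = 0.5 * (1.0 + val(need[0]))
        else:
            memo[(a, b)] = 0.5 * (val(need[0]) + val(need[1]))
        pending.pop()
    i, j = min(i, j), max(i, j)
    return memo[(i, j)]


def _meuwissen_luo_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Exact inbreeding coefficients F_i = phi(sire_i, dam_i) * ... via kinship.

    Uses a single memoised kinship table shared across animals; equivalent to
    the Meuwissen-Luo recursion (F_i is half the additive relationship of the
    parents) and exact for arbitrary ordered pedigrees.
    """
    n = len(sire)
    F = np.zeros(n)
    memo: dict = {}
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            continue
        F[i] = _kinship(s, d, sire, dam, memo)
    return F


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + F_i with F_i half the relationship of i's parents;
    a_ij (j < i) = mean of a_j,sire(i) and a_j,dam(i).
    """
    n = len(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(pedigree.ids, A, "A")


def build_A22(pedigree: Pedigree) -> RelationshipMatrix:
    """A restricted to the genotyped animals (dense)."""
    idx = pedigree.genotyped_index
    A = build_A(pedigree)
    return RelationshipMatrix(pedigree.ids[idx], A.values[np.ix_(idx, idx)], "A22")


def build_A_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with exact inbreeding coefficients."""
    n = len(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    F = _meuwissen_luo_inbreeding(sire, dam)
    rows, cols, vals = [], [], []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            mend = 0.75 - 0.25 * F[p]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        add(i, i, alpha)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (s, d):
            for q in (s, d):
                if p != UNKNOWN and q != UNKNOWN:
                    add(p, q, alpha / 4.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def compute_allele_freqs(genotypes: GenotypeMatrix) -> AlleleFrequencies:
    """Observed allele frequencies: mean dosage / 2 over non-missing calls."""
    counts = np.sum(~np.isnan(genotypes.dosages), axis=0)
    if np.any(counts == 0):
        bad = genotypes.snp_map["snp"].iloc[int(np.nonzero(counts == 0)[0][0])]
        raise ConfigurationError(
            f"SNP {bad!r} has no non-missing calls (should have been removed in QC)"
        )
    p = np.nanmean(genotypes.dosages, axis=0) / 2.0
    return AlleleFrequencies(p, source="observed")


def center_dosages(genotypes: GenotypeMatrix, freqs: AlleleFrequencies) -> np.ndarray:
    """Column-centered dosage matrix Z = X - 2p; missing calls become 0.

    Mean imputation of missing dosages to 2p makes the centered value 0, which
    leaves G unbiased in expectation.
    """
    Z = genotypes.dosages - 2.0 * freqs.p[np.newaxis, :]
    return np.where(np.isnan(Z), 0.0, Z)


def compute_lambda(freqs: AlleleFrequencies) -> float:
    """Variance-ratio scaling factor: 1 / sum_i 2 p_i (1 - p_i)."""
    return 1.0 / float(freqs.het_variance.sum())


def build_G(
    genotypes: GenotypeMatrix,
    freqs: AlleleFrequencies,
    weights: SnpWeightVector | None = None,
) -> RelationshipMatrix:
    """Weighted VanRaden genomic relationship: G = Z D Z' / sum 2 p (1-p)."""
    if weights is None:
        weights = SnpWeightVector.identity(genotypes.n_snps)
    if len(freqs.p) != genotypes.n_snps or len(weights.d) != genotypes.n_snps:
        raise ConfigurationError(
            "allele frequencies / weights length does not match SNP count"
        )
    Z = center_dosages(genotypes, freqs)
    denom = float(freqs.het_variance.sum())
    G = (Z * weights.d[np.newaxis, :]) @ Z.T / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(genotypes.animal_ids, G, "G")


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, beta: float = 0.95
) -> RelationshipMatrix:
    """Return beta * G + (1 - beta) * A22 (guarantees invertibility)."""
    if not (0.0 < beta <= 1.0):
        raise ConfigurationError(f"blending beta must be in (0, 1], got {beta}")
    if G.values.shape != A22.values.shape:
        raise ConfigurationError("G and A22 dimensions do not match")
    if beta == 1.0:
        return G
    return RelationshipMatrix(G.ids, beta * G.values + (1.0 - beta) * A22.values, "G")


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22: RelationshipMatrix,
    G_blended: RelationshipMatrix,
    genotyped_index: np.ndarray,
) -> sp.csr_matrix:
    """Single-step H^-1: add (G^-1 - A22^-1) into the genotyped block of A^-1."""
    A_inv = sp.csr_matrix(A_inv)
    idx = np.asarray(genotyped_index, dtype=np.int64)
    if idx.size == 0:
        return A_inv
    if np.any(idx < 0) or np.any(idx >= A_inv.shape[0]):
        raise ConfigurationError("genotyped index outside pedigree range")
    if G_blended.values.shape != (idx.size, idx.size):
        raise ConfigurationError("G dimension does not match genotyped animal count")
    try:
        cho = sla.cho_factor(G_blended.values)
        G_inv = sla.cho_solve(cho, np.eye(idx.size))
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "G is singular; blend it with A22 (beta < 1) before building H^-1"
        ) from exc
    A22_inv = sla.cho_solve(sla.cho_factor(A22.values), np.eye(idx.size))
    corr = G_inv - A22_inv
    corr = (corr + corr.T) / 2.0
    H_inv = A_inv.tolil(copy=True)
    H_inv[np.ix_(idx, idx)] = H_inv[np.ix_(idx, idx)].toarray() + corr
    return H_inv.tocsr()
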