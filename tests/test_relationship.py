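"""Relationship matrices: A, A^-1, G, blending, H^-1, lambda."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_pedigree, random_pedigree
from wssgwas.exceptions import ConfigurationError
from wssgwas.genotypes import GenotypeMatrix
from wssgwas.pedigree import UNKNOWN, Pedigree
from wssgwas.relationship import (
    AlleleFrequencies,
    SnpWeightVector,
    blend_G,
    build_A,
    build_A22,
    build_A_inverse,
    build_G,
    build_H_inverse,
    center_dosages,
    compute_allele_freqs,
    compute_lambda,
)


def A_oracle(ped):
    """Independent oracle: A_ij = 2 * phi(i, j) via naive recursive kinship."""

    def phi(a, b):
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        if a == b:
            return 0.5 * (1.0 + phi(ped.sire[a], ped.dam[a]))
        if b < a:
            a, b = b, a
        return 0.5 * (phi(a, ped.sire[b]) + phi(a, ped.dam[b]))

    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = 2.0 * phi(i, j)
    return A


def _geno(dosages, p=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_map = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": 1,
         "pos_bp": range(1, m + 1), "a1": "A", "a2": "B"}
    )
    return GenotypeMatrix(np.array([f"i{k}" for k in range(n)], dtype=object),
                          snp_map, dosages)


class TestBuildA:
    def test_unrelated_founders_identity(self):
        ped = make_pedigree([("a", None, None), ("b", None, None)])
        assert np.array_equal(build_A(ped).values, np.eye(2))

    def test_textbook_relationships(self):
        ped = make_pedigree(
            [
                ("s", None, None), ("d", None, None), ("d2", None, None),
                ("child", "s", "d"), ("fullsib", "s", "d"), ("halfsib", "s", "d2"),
            ]
        )
        A = build_A(ped).values
        i = {a: k for k, a in enumerate(ped.ids)}
        assert A[i["s"], i["child"]] == 0.5          # parent-offspring
        assert A[i["child"], i["fullsib"]] == 0.5    # full sibs
        assert A[i["child"], i["halfsib"]] == 0.25   # half sibs

    def test_offspring_of_full_sibs_is_inbred(self):
        ped = make_pedigree(
            [
                ("s", None, None), ("d", None, None),
                ("b1", "s", "d"), ("b2", "s", "d"),
                ("inbred", "b1", "b2"),
            ]
        )
        A = build_A(ped).values
        assert A[4, 4] == pytest.approx(1.25)  # F = 0.25

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_path_counting_oracle_small_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(12, rng)
        assert np.allclose(build_A(ped).values, A_oracle(ped), atol=1e-12)


class TestBuildAInverse:
    def test_single_founder(self):
        ped = make_pedigree([("x", None, None)])
        assert np.allclose(build_A_inverse(ped).toarray(), [[1.0]])

    def test_trio_closed_form(self):
        ped = make_pedigree([("s", None, None), ("d", None, None), ("o", "s", "d")])
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        assert np.allclose(build_A_inverse(ped).toarray(), expected)
        # cross-check: numerical inverse of the tabular A
        assert np.allclose(np.linalg.inv(build_A(ped).values), expected)

    def test_product_with_A_is_identity_random_200(self):
        rng = np.random.default_rng(7)
        ped = random_pedigree(200, rng)
        A = build_A(ped).values
        Ainv = build_A_inverse(ped).toarray()
        assert np.max(np.abs(Ainv @ A - np.eye(200))) < 1e-8


class TestAlleleFrequencies:
    def test_symmetric_three_animals(self):
        g = _geno([[0.0], [1.0], [2.0]])
        assert compute_allele_freqs(g).p[0] == 0.5

    def test_fixed_allele_rejected(self):
        g = _geno([[2.0], [2.0]])
        with pytest.raises(ConfigurationError):
            compute_allele_freqs(g)

    def test_missing_excluded_from_mean(self):
        g = _geno([[0.0], [0.0], [1.0], [2.0], [np.nan]])
        assert compute_allele_freqs(g).p[0] == pytest.approx(3 / 8)

    def test_all_missing_snp_raises(self):
        g = _geno([[np.nan], [np.nan]])
        with pytest.raises(ConfigurationError):
            compute_allele_freqs(g)


class TestBuildG:
    def test_single_snp_hand_example(self):
        g = _geno([[0.0], [1.0], [2.0]])
        freqs = AlleleFrequencies([0.5])
        G = build_G(g, freqs).values
        assert np.allclose(G, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])

    def test_weight_scale_invariance_after_normalization(self, small_dataset):
        g = small_dataset["genotypes"]
        freqs = compute_allele_freqs(g)
        w = SnpWeightVector(np.abs(np.random.default_rng(0).normal(1, 0.3, g.n_snps)))
        G1 = build_G(g, freqs, w).values
        w2 = SnpWeightVector(2.0 * w.d)
        G2 = build_G(g, freqs, w2).values
        assert np.allclose(2.0 * G1, G2)  # G linear in D; trace norm undoes it

    def test_mean_diagonal_near_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.5, 400)
        X = rng.binomial(2, p, size=(200, 400)).astype(float)
        g = _geno(X)
        freqs = compute_allele_freqs(g)
        G = build_G(g, freqs).values
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.1

    def test_allele_relabelling_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.3, size=(30, 15)).astype(float)
        G1 = build_G(_geno(X), compute_allele_freqs(_geno(X))).values
        Xf = 2.0 - X
        G2 = build_G(_geno(Xf), compute_allele_freqs(_geno(Xf))).values
        assert np.allclose(G1, G2, atol=1e-12)

    def test_missing_centered_to_zero(self):
        X = np.array([[0.0], [1.0], [2.0], [np.nan]])
        g = _geno(X)
        freqs = AlleleFrequencies([0.5])
        Z = center_dosages(g, freqs)
        assert Z[3, 0] == 0.0


class TestBlendG:
    def test_beta_one_is_identity(self, small_dataset):
        g = small_dataset["genotypes"]
        freqs = compute_allele_freqs(g)
        G = build_G(g, freqs)
        assert blend_G(G, G, 1.0) is G

    def test_identity_fixed_point(self):
        from wssgwas.relationship import RelationshipMatrix

        I3 = RelationshipMatrix(np.array(["a", "b", "c"], dtype=object), np.eye(3), "G")
        assert np.allclose(blend_G(I3, I3, 0.95).values, np.eye(3))

    def test_blending_makes_singular_G_invertible(self):
        # duplicate animals make G exactly singular
        X = np.array([[0.0, 1, 2, 1], [0.0, 1, 2, 1], [2.0, 1, 0, 1]])
        g = _geno(X)
        freqs = compute_allele_freqs(g)
        G = build_G(g, freqs)
        assert np.linalg.matrix_rank(G.values) < 3
        A22 = build_A22(
            Pedigree(np.array(["i0", "i1", "i2"], dtype=object),
                     np.full(3, UNKNOWN), np.full(3, UNKNOWN),
                     np.ones(3, dtype=bool))
        )
        Gb = blend_G(G, A22, 0.95)
        assert np.all(np.linalg.eigvalsh(Gb.values) > 1e-8)

    def test_beta_out_of_range(self, small_dataset):
        g = small_dataset["genotypes"]
        G = build_G(g, compute_allele_freqs(g))
        with pytest.raises(ConfigurationError):
            blend_G(G, G, 0.0)


class TestBuildHInverse:
    def test_no_genotypes_reduces_to_A_inverse(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(30, rng)
        Ainv = build_A_inverse(ped)
        Hinv = build_H_inverse(Ainv, None, None, np.array([], dtype=int))
        assert (Hinv != Ainv).nnz == 0

    def test_all_genotyped_reduces_to_G_inverse(self):
        rng = np.random.default_rng(2)
        ped = random_pedigree(15, rng)
        ped.genotyped = np.ones(len(ped), dtype=bool)
        X = rng.binomial(2, rng.uniform(0.2, 0.5, 40), size=(15, 40)).astype(float)
        g = _geno(X)
        g.animal_ids = ped.ids.copy()
        freqs = compute_allele_freqs(g)
        A22 = build_A22(ped)
        Gb = blend_G(build_G(g, freqs), A22, 0.95)
        Hinv = build_H_inverse(build_A_inverse(ped), A22, Gb, ped.genotyped_index)
        # A^-1 and A22^-1 cancel exactly when everyone is genotyped
        assert np.allclose(Hinv.toarray(), np.linalg.inv(Gb.values), atol=1e-8)

    def test_against_dense_closed_form_oracle(self):
        """20-animal pedigree, 8 genotyped: H^-1 equals the inverse of the
        textbook H built blockwise from A and G."""
        rng = np.random.default_rng(3)
        ped = random_pedigree(20, rng)
        gen_idx = np.sort(rng.choice(20, size=8, replace=False))
        ped.genotyped = np.zeros(20, dtype=bool)
        ped.genotyped[gen_idx] = True
        X = rng.binomial(2, rng.uniform(0.2, 0.5, 60), size=(8, 60)).astype(float)
        g = _geno(X)
        g.animal_ids = ped.ids[gen_idx].copy()
        freqs = compute_allele_freqs(g)
        A = build_A(ped).values
        A22 = build_A22(ped)
        Gb = blend_G(build_G(g, freqs), A22, 0.95)
        Hinv = build_H_inverse(build_A_inverse(ped), A22, Gb, gen_idx).toarray()

        # dense closed form: H = A + [[A12 K A21, A12 K G*],[...sym..., G* - A22]]
        # expressed via the standard identity H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21
        n1 = np.setdiff1d(np.arange(20), gen_idx)
        P = np.concatenate([n1, gen_idx])  # reorder: ungenotyped then genotyped
        Ap = A[np.ix_(P, P)]
        k = len(n1)
        A11, A12, A22b = Ap[:k, :k], Ap[:k, k:], Ap[k:, k:]
        A22i = np.linalg.inv(A22b)
        Gv = Gb.values
        H = np.zeros_like(Ap)
        H[:k, :k] = A11 + A12 @ A22i @ (Gv - A22b) @ A22i @ A12.T
        H[:k, k:] = A12 @ A22i @ Gv
        H[k:, :k] = H[:k, k:].T
        H[k:, k:] = Gv
        H_inv_oracle = np.linalg.inv(H)
        # undo the permutation
        inv_perm = np.argsort(P)
        assert np.max(np.abs(Hinv - H_inv_oracle[np.ix_(inv_perm, inv_perm)])) < 1e-6

    def test_singular_G_raises_with_advice(self):
        ped = make_pedigree([("a", None, None), ("b", None, None)])
        ped.genotyped = np.ones(2, dtype=bool)
        from wssgwas.relationship import RelationshipMatrix

        sing = RelationshipMatrix(ped.ids, np.ones((2, 2)), "G")
        A22 = build_A22(ped)
        from wssgwas.exceptions import NumericalError

        with pytest.raises(NumericalError, match="blend"):
            build_H_inverse(build_A_inverse(ped), A22, sing, np.array([0, 1]))


class TestComputeLambda:
    def test_single_snp_half(self):
        assert compute_lambda(AlleleFrequencies([0.5])) == pytest.approx(2.0)

    def test_m_snps_closed_form(self):
        m = 10
        assert compute_lambda(AlleleFrequencies([0.5] * m)) == pytest.approx(2.0 / m)

    def test_hand_arithmetic(self):
        lam = compute_lambda(AlleleFrequencies([0.1, 0.3]))
        assert lam == pytest.approx(1.0 / (0.18 + 0.42))

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            AlleleFrequencies([])
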