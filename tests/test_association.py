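"""wssGWAS core: backsolve, weight updates, windows, selection, union."""
import numpy as np
import pandas as pd
import pytest

from wssgwas.association import (
    SnpEffectVector,
    WindowResult,
    backsolve_snp_effects,
    nonredundant_union,
    normalize_weights,
    run_wssgwas,
    select_windows,
    top_snp,
    update_weights,
    window_variances,
)
from wssgwas.datasets import simmental_growth as pub
from wssgwas.exceptions import NumericalError
from wssgwas.genotypes import GenotypeMatrix
from wssgwas.mixed_model import ModelSpec, VarianceComponents
from wssgwas.relationship import (
    AlleleFrequencies,
    RelationshipMatrix,
    SnpWeightVector,
    build_G,
    compute_allele_freqs,
    compute_lambda,
    center_dosages,
)
from wssgwas.simulate import SimConfig, simulate_dataset

MEAN_ONLY = ModelSpec(factors=(), covariates=())


def _geno(X, chrom=None):
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    chrom = chrom if chrom is not None else [1] * m
    snp_map = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": chrom,
         "pos_bp": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "B"}
    )
    return GenotypeMatrix(np.array([f"i{k}" for k in range(n)], dtype=object),
                          snp_map, X)


def _random_panel(n, m, seed):
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, rng.uniform(0.2, 0.5, m), size=(n, m)).astype(float)
    g = _geno(X)
    freqs = compute_allele_freqs(g)
    return g, freqs, center_dosages(g, freqs)


class TestBacksolve:
    def test_identity_with_unblended_full_rank_G(self):
        # supplied (base-population) frequencies: columns are not exactly
        # centered, so G = lambda Z Z' has full rank and the algebraic
        # identity Z u = Z lambda D Z' G^-1 a = G G^-1 a = a is exact.
        # (With observed frequencies G always has the 1-vector in its null
        # space, which is why blending exists.)
        g, _, _ = _random_panel(10, 40, 1)
        freqs = AlleleFrequencies(np.full(40, 0.35), source="supplied")
        Z = center_dosages(g, freqs)
        G = build_G(g, freqs)
        lam = compute_lambda(freqs)
        D = SnpWeightVector.identity(40)
        a_g = np.random.default_rng(2).normal(0, 1, 10)
        u = backsolve_snp_effects(a_g, Z, D, G, lam)
        assert np.allclose(Z @ u.u, a_g, atol=1e-8)

    def test_zero_gebv_gives_zero_effects(self):
        g, freqs, Z = _random_panel(8, 20, 3)
        u = backsolve_snp_effects(np.zeros(8), Z, SnpWeightVector.identity(20),
                                  build_G(g, freqs), compute_lambda(freqs))
        assert np.all(u.u == 0.0)

    def test_matches_direct_dense_formula(self):
        g, freqs, Z = _random_panel(10, 5, 4)
        # 5 SNPs, 10 animals: G is singular (rank <= 5) -> use a weighted,
        # regularised G via explicit dense arithmetic on the formula
        rng = np.random.default_rng(5)
        d = rng.uniform(0.5, 2.0, 5)
        D = SnpWeightVector(d)
        lam = compute_lambda(freqs)
        Gv = (Z * d) @ Z.T * lam
        Gv = Gv + np.eye(10) * 0.01  # make invertible; same matrix both routes
        G = RelationshipMatrix(g.animal_ids, Gv, "G")
        a_g = rng.normal(0, 1, 10)
        u = backsolve_snp_effects(a_g, Z, D, G, lam)
        expected = lam * np.diag(d) @ Z.T @ np.linalg.inv(Gv) @ a_g
        assert np.allclose(u.u, expected, atol=1e-10)

    def test_singular_G_raises(self):
        g, freqs, Z = _random_panel(10, 2, 6)
        G = build_G(g, freqs)  # rank <= 2 < 10
        with pytest.raises(NumericalError):
            backsolve_snp_effects(np.ones(10), Z, SnpWeightVector.identity(2),
                                  G, compute_lambda(freqs))


class TestWeights:
    def test_update_formula(self):
        freqs = AlleleFrequencies([0.5, 0.1, 0.2])
        u = SnpEffectVector(np.array([0.0, 0.3, 1.0]))
        w = update_weights(u, freqs)
        assert w.d[0] == 0.0
        assert w.d[1] == pytest.approx(0.09 * 0.18)
        assert w.d[2] == pytest.approx(1.0 * 2 * 0.2 * 0.8)

    def test_unit_effect_half_frequency(self):
        w = update_weights(SnpEffectVector(np.array([1.0])), AlleleFrequencies([0.5]))
        assert w.d[0] == pytest.approx(0.5)

    def test_normalize_conserves_previous_trace(self):
        prev = SnpWeightVector.identity(4)
        raw = SnpWeightVector(np.array([2.0, 2, 2, 2]))
        out = normalize_weights(raw, prev)
        assert out.trace == pytest.approx(4.0)
        assert np.allclose(out.d, 1.0)

    def test_normalize_hand_example(self):
        prev = SnpWeightVector(np.array([1.0, 1.0]))  # trace 2
        out = normalize_weights(SnpWeightVector(np.array([1.0, 3.0])), prev)
        assert np.allclose(out.d, [0.5, 1.5])

    def test_normalized_weights_fixed_point(self):
        w = SnpWeightVector(np.array([0.5, 1.5]))
        out = normalize_weights(w, SnpWeightVector(np.array([1.0, 1.0])))
        assert np.allclose(out.d, w.d)

    def test_all_zero_weights_raise(self):
        with pytest.raises(NumericalError):
            normalize_weights(SnpWeightVector(np.zeros(3)),
                              SnpWeightVector.identity(3))


def brute_force_window_gvar(Z, u, sigma_a2, start, size):
    """Independent animal-level variance oracle with explicit loops."""
    n = Z.shape[0]
    vals = []
    for i in range(n):
        s = 0.0
        for j in range(start, start + size):
            s += Z[i, j] * u[j]
        vals.append(s)
    vals = np.array(vals)
    return vals.var(ddof=1) / sigma_a2 * 100.0


class TestWindowVariances:
    def test_zero_effects_zero_everywhere(self):
        g, freqs, Z = _random_panel(12, 30, 7)
        wins = window_variances(SnpEffectVector(np.zeros(30)), Z, g.snp_map, 1.0,
                                window_size=10)
        assert len(wins) == 21
        assert all(w.gvar_percent == 0.0 for w in wins)

    def test_single_nonzero_effect(self):
        g, freqs, Z = _random_panel(15, 30, 8)
        u = np.zeros(30)
        u[12] = 0.7
        sigma_a2 = 2.0
        wins = window_variances(SnpEffectVector(u), Z, g.snp_map, sigma_a2,
                                window_size=5)
        expected = np.var(Z[:, 12] * 0.7, ddof=1) / sigma_a2 * 100
        for w in wins:
            start = w.start_idx
            if start <= 12 < start + 5:
                assert w.gvar_percent == pytest.approx(expected, abs=1e-10)
            else:
                assert w.gvar_percent == 0.0

    def test_sixty_snp_toy_matches_brute_force(self):
        """41 sliding 20-SNP windows against the loop-level oracle."""
        g, freqs, Z = _random_panel(25, 60, 9)
        u = np.random.default_rng(10).normal(0, 0.1, 60)
        sigma_a2 = 1.7
        wins = window_variances(SnpEffectVector(u), Z, g.snp_map, sigma_a2)
        assert len(wins) == 41
        for w in wins:
            oracle = brute_force_window_gvar(Z, u, sigma_a2, w.start_idx, 20)
            assert w.gvar_percent == pytest.approx(oracle, abs=1e-6)

    def test_windows_never_cross_chromosomes(self):
        chrom = [1] * 25 + [2] * 25
        g = _geno(np.random.default_rng(11).binomial(2, 0.4, (10, 50)), chrom)
        freqs = compute_allele_freqs(g)
        Z = center_dosages(g, freqs)
        wins = window_variances(SnpEffectVector(np.ones(50)), Z, g.snp_map, 1.0)
        assert len(wins) == 2 * (25 - 20 + 1)
        for w in wins:
            assert w.start_idx + 20 <= 25 or w.start_idx >= 25

    def test_short_chromosome_skipped_with_warning(self):
        chrom = [1] * 25 + [2] * 5
        g = _geno(np.random.default_rng(12).binomial(2, 0.4, (10, 30)), chrom)
        Z = center_dosages(g, compute_allele_freqs(g))
        with pytest.warns(UserWarning, match="fewer than"):
            wins = window_variances(SnpEffectVector(np.ones(30)), Z, g.snp_map, 1.0)
        assert all(w.chrom == 1 for w in wins)

    def test_orthogonal_columns_additive(self):
        """For uncorrelated SNP columns, window gVar equals the sum of the
        per-SNP gVar values."""
        rng = np.random.default_rng(13)
        n = 32
        # orthogonal design: Hadamard-like +-1 columns are exactly uncorrelated
        from scipy.linalg import hadamard

        H = hadamard(32)[:, 1:21].astype(float)
        g = _geno(H + 1.0)  # dosage-like 0/2 values
        freqs = AlleleFrequencies(np.full(20, 0.5))
        Z = H  # centered at 2p = 1
        u = rng.normal(0, 1, 20)
        wins = window_variances(SnpEffectVector(u), Z, g.snp_map, 1.0)
        per_snp = np.array(
            [np.var(Z[:, j] * u[j], ddof=1) for j in range(20)]
        )
        assert len(wins) == 1
        assert wins[0].gvar_percent == pytest.approx(per_snp.sum() * 100, rel=1e-6)


class TestTopSnp:
    def _window(self, start=0, size=5):
        return WindowResult(1, 1000, 5000, start, size, 2.0)

    def test_single_nonzero_effect_wins(self):
        u = SnpEffectVector(np.array([0.0, 0, 0.4, 0, 0]))
        freqs = AlleleFrequencies(np.full(5, 0.3))
        g = _geno(np.zeros((2, 5)))
        assert top_snp(self._window(), u, freqs, g.snp_map) == "s2"

    def test_tie_broken_by_position(self):
        u = SnpEffectVector(np.array([0.5, 0, 0, 0, 0.5]))
        freqs = AlleleFrequencies(np.full(5, 0.3))
        g = _geno(np.zeros((2, 5)))
        assert top_snp(self._window(), u, freqs, g.snp_map) == "s0"

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(14)
        u = SnpEffectVector(rng.normal(0, 1, 20))
        freqs = AlleleFrequencies(rng.uniform(0.05, 0.5, 20))
        g = _geno(np.zeros((2, 20)))
        w = WindowResult(1, 1000, 20000, 0, 20, 1.0)
        contrib = u.u**2 * 2 * freqs.p * (1 - freqs.p)
        assert top_snp(w, u, freqs, g.snp_map) == f"s{int(np.argmax(contrib))}"


def _win(chrom, start, end, gvar, idx=0, trait=None):
    return WindowResult(chrom, start, end, idx, 20, gvar, trait=trait)


class TestSelectWindows:
    def test_all_below_threshold(self):
        wins = [_win(1, i * 10, i * 10 + 100, 0.5, i) for i in range(5)]
        assert select_windows(wins) == []

    def test_isolated_window_selected_alone(self):
        wins = [
            _win(1, 100, 200, 0.2, 0),
            _win(1, 1000, 1100, 7.89, 50),
            _win(1, 2000, 2100, 0.3, 100),
        ]
        out = select_windows(wins)
        assert len(out) == 1 and out[0].gvar_percent == 7.89

    def test_plateau_collapsed_to_local_max(self):
        wins = [
            _win(1, 100, 300, 1.2, 0),
            _win(1, 200, 400, 1.5, 1),
            _win(1, 300, 500, 1.3, 2),
        ]
        out = select_windows(wins)
        assert [w.gvar_percent for w in out] == [1.5]

    def test_two_separate_runs_kept(self):
        wins = [
            _win(1, 100, 300, 1.2, 0),
            _win(1, 200, 400, 1.5, 1),
            _win(1, 5000, 5200, 2.0, 40),
            _win(2, 100, 300, 1.1, 60),
        ]
        out = select_windows(wins)
        assert sorted(w.gvar_percent for w in out) == [1.1, 1.5, 2.0]
        assert [w.gvar_percent for w in out] == [2.0, 1.5, 1.1]  # sorted desc


class TestNonredundantUnion:
    def test_disjoint_counts_add(self):
        a = [_win(1, 100, 200, 2.0), _win(1, 500, 600, 1.5)]
        b = [_win(2, 100, 200, 3.0), _win(2, 500, 600, 1.2), _win(3, 1, 99, 1.1)]
        assert len(nonredundant_union([a, b])) == 5

    def test_published_tables_give_66_nonredundant_regions(self):
        """18 + 14 + 15 + 21 = 68 rows collapse to 66 distinct regions: the
        two regions shared identically between the yearling-weight and daily
        gain tables count once."""
        per_trait = []
        for trait, table in pub.WINDOW_TABLES.items():
            per_trait.append(
                [
                    _win(r.chrom, r.start_bp, r.end_bp, r.gvar_percent, trait=trait)
                    for r in table.itertuples()
                ]
            )
        assert sum(len(t) for t in per_trait) == 68
        union = nonredundant_union(per_trait)
        assert len(union) == 66

    def test_idempotent(self):
        a = [_win(1, 100, 200, 2.0), _win(1, 500, 600, 1.5)]
        assert len(nonredundant_union([a, a])) == len(a)


@pytest.fixture(scope="module")
def run_inputs():
    cfg = SimConfig(
        n_founders=60, n_generations=2, offspring_per_mating=4,
        n_chromosomes=2, snps_per_chromosome=50, n_qtl=2,
        qtl_variance_fraction=0.6, heritability=0.4,
        genotyped_fraction=0.6, seed=55,
    )
    ped, _, geno, phen, truth, _ = simulate_dataset(cfg)
    vc = VarianceComponents(truth.sigma_a2, truth.sigma_e2)
    return ped, geno, phen, vc


class TestRunWssGwas:
    def test_one_iteration_is_plain_ssgwas(self, run_inputs):
        ped, geno, phen, vc = run_inputs
        run = run_wssgwas(phen, ped, geno, vc, MEAN_ONLY, iterations=1)
        assert len(run.effects) == 1
        assert np.allclose(run.weights[0].d, 1.0)

    def test_three_iterations_recorded_and_trace_conserved(self, run_inputs):
        ped, geno, phen, vc = run_inputs
        run = run_wssgwas(phen, ped, geno, vc, MEAN_ONLY, iterations=3)
        assert len(run.effects) == len(run.weights) == len(run.window_profiles) == 3
        m = geno.n_snps
        for w in run.weights:
            assert w.trace == pytest.approx(m, abs=1e-8)

    def test_first_iteration_equals_single_backsolve(self, run_inputs):
        ped, geno, phen, vc = run_inputs
        r1 = run_wssgwas(phen, ped, geno, vc, MEAN_ONLY, iterations=1)
        r3 = run_wssgwas(phen, ped, geno, vc, MEAN_ONLY, iterations=3)
        assert np.allclose(r1.effects[0].u, r3.effects[0].u)

    def test_determinism(self, run_inputs):
        ped, geno, phen, vc = run_inputs
        a = run_wssgwas(phen, ped, geno, vc, MEAN_ONLY, iterations=2)
        b = run_wssgwas(phen, ped, geno, vc, MEAN_ONLY, iterations=2)
        assert np.array_equal(a.effects[-1].u, b.effects[-1].u)
        assert [w.gvar_percent for w in a.final_windows] == [
            w.gvar_percent for w in b.final_windows
        ]

    def test_backsolve_identity_reported_not_asserted(self, run_inputs):
        ped, geno, phen, vc = run_inputs
        run = run_wssgwas(phen, ped, geno, vc, MEAN_ONLY, iterations=1, beta=0.95)
        assert np.isfinite(run.backsolve_relative_deviation)
        # with blending the identity is only approximate
        assert run.backsolve_relative_deviation < 0.5
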