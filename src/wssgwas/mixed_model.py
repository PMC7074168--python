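"""Single-trait animal model on the single-step relationship structure.

The model is

    y = W b + Z a + e,     a ~ N(0, H sigma_a2),   e ~ N(0, I sigma_e2)

with W the fixed-effect design (categorical factors with drop-first reference
coding plus optional covariates), Z the incidence of phenotyped animals onto
the pedigree, and H the single-step relationship matrix (A when nobody is
genotyped). Variance components are estimated by EM-REML (optionally with an
average-information Newton step), breeding values by solving Henderson's
mixed-model equations.

Numerical engine
----------------
All REML quantities are computed from a one-time generalized spectral
decomposition of (Z'SZ, H^-1), S the projection orthogonal to W: with
Phi' H^-1 Phi = I and Phi' Z'S Z Phi = diag(lambda), every EM update, the
REML log-likelihood and the BLUP solutions are O(q) per iteration. Fits on
re-drawn phenotypes over a fixed design (``model.refit``) reuse the
decomposition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import ConfigurationError, NumericalError
from .pedigree import Pedigree


# ---------------------------------------------------------------------------
# summaries and variance components
# ---------------------------------------------------------------------------

@dataclass
class TraitSummary:
    """Descriptive statistics of one trait."""

    n: int
    mean: float
    sd: float
    min: float
    max: float

    @property
    def cv_percent(self) -> float:
        return self.sd / self.mean * 100.0


def summarize_trait(values) -> TraitSummary:
    """N, mean, sample SD (n-1), min, max, CV% of the non-missing values."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ConfigurationError("trait summary needs at least 2 non-missing values")
    mean = float(x.mean())
    if mean == 0.0:
        raise ConfigurationError("CV undefined: trait mean is zero")
    return TraitSummary(len(x), mean, float(x.std(ddof=1)), float(x.min()), float(x.max()))


@dataclass
class VarianceComponents:
    """Additive and residual variances with derived quantities."""

    sigma_a2: float
    sigma_e2: float
    se_sigma_a2: float | None = None
    se_sigma_e2: float | None = None
    se_h2: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ConfigurationError("variance components must be positive")

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_a2 / self.sigma_p2

    @property
    def ratio(self) -> float:
        """k = sigma_e2 / sigma_a2, the MME shrinkage ratio."""
        return self.sigma_e2 / self.sigma_a2


def heritability(vc: VarianceComponents) -> float:
    """h2 = sigma_a2 / (sigma_a2 + sigma_e2)."""
    return vc.h2


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Fixed-effect structure of a single-trait animal model.

    ``factors`` are categorical columns (reference coding, first level
    dropped); ``covariates`` enter as centered linear regressions. Growth
    trait convention: age in days is a covariate for every trait except
    birth weight.
    """

    trait: str = "trait"
    factors: tuple = ("sex", "year", "use_type", "farm")
    covariates: tuple = ("age_days",)
    id_column: str = "id"


def build_fixed_design(phenotypes: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list]:
    """Dense W with intercept, drop-first dummies per factor, centered covariates."""
    n = len(phenotypes)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f in spec.factors:
        if f not in phenotypes.columns:
            raise ConfigurationError(f"fixed-effect factor {f!r} missing from phenotype table")
        dummies = pd.get_dummies(phenotypes[f].astype(str), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for c in spec.covariates:
        if c not in phenotypes.columns:
            raise ConfigurationError(f"covariate {c!r} missing from phenotype table")
        x = phenotypes[c].to_numpy(dtype=float)
        cols.append(x - x.mean())
        names.append(c)
    return np.column_stack(cols), names


def build_incidence(phenotypes: pd.DataFrame, pedigree: Pedigree, spec: ModelSpec) -> sp.csr_matrix:
    """Sparse Z mapping phenotype records onto pedigree positions."""
    idx = pedigree.index_of(phenotypes[spec.id_column].astype(str))
    n = len(phenotypes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, len(pedigree))
    )


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class MmeSystem:
    """Assembled Henderson system C [b; a] = r."""

    C: sp.csr_matrix
    rhs: np.ndarray
    n_fixed: int
    fixed_names: list
    pedigree: Pedigree


@dataclass
class MmeSolution:
    """Solution of the mixed-model equations."""

    b_hat: np.ndarray
    a_hat: np.ndarray
    a_hat_genotyped: np.ndarray
    fixed_names: list
    residual_norm: float


def assemble_mme(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    H_inv: sp.spmatrix,
    vc: VarianceComponents,
) -> MmeSystem:
    """Henderson MME:  [[W'W, W'Z], [Z'W, Z'Z + H^-1 k]] [b; a] = [W'y; Z'y]."""
    q = len(pedigree)
    if H_inv.shape != (q, q):
        raise ConfigurationError("H^-1 dimension does not match pedigree size")
    missing = set(phenotypes[spec.id_column].astype(str)) - set(pedigree.ids.tolist())
    if missing:
        raise ConfigurationError(
            f"phenotyped animals absent from pedigree: {sorted(missing)[:5]}"
        )
    W, names = build_fixed_design(phenotypes, spec)
    Z = build_incidence(phenotypes, pedigree, spec)
    y = phenotypes[spec.trait].to_numpy(dtype=float)
    Ws = sp.csr_matrix(W)
    k = vc.ratio
    C = sp.bmat(
        [
            [Ws.T @ Ws, Ws.T @ Z],
            [Z.T @ Ws, Z.T @ Z + sp.csr_matrix(H_inv) * k],
        ],
        format="csr",
    )
    rhs = np.concatenate([W.T @ y, Z.T @ y])
    return MmeSystem(C, rhs, W.shape[1], names, pedigree)


def solve_mme(system: MmeSystem) -> MmeSolution:
    """Sparse direct solve of the MME; verifies the relative residual."""
    theta = spla.spsolve(system.C.tocsc(), system.rhs)
    resid = system.C @ theta - system.rhs
    denom = max(np.linalg.norm(system.rhs), 1e-300)
    rel = float(np.linalg.norm(resid) / denom)
    if not np.isfinite(rel) or rel > 1e-8:
        raise NumericalError(
            f"MME solve did not reach the required residual (relative norm {rel:.2e})"
        )
    p = system.n_fixed
    b_hat = theta[:p]
    a_hat = theta[p:]
    return MmeSolution(
        b_hat,
        a_hat,
        a_hat[system.pedigree.genotyped_index],
        system.fixed_names,
        rel,
    )


# ---------------------------------------------------------------------------
# REML via the generalized spectral decomposition
# ---------------------------------------------------------------------------

class _SpectralDesign:
    """Cached decomposition of one (W, Z, H^-1) design."""

    def __init__(self, W: np.ndarray, Z: sp.csr_matrix, H_inv) -> None:
        self.W = W
        self.Z = Z
        H_inv = np.asarray(
            H_inv.toarray() if sp.issparse(H_inv) else H_inv, dtype=float
        )
        self.H_inv = (H_inv + H_inv.T) / 2.0
        n, p = W.shape
        self.n, self.p = n, p
        self.rank_W = int(np.linalg.matrix_rank(W))
        if self.rank_W < p:
            raise NumericalError(
                "fixed-effect design is rank deficient after reference coding"
            )
        self.WtW_inv = np.linalg.inv(W.T @ W)
        ZtW = (Z.T @ W)  # q x p dense
        ZtZ = (Z.T @ Z).toarray()
        self.ZtSZ = ZtZ - ZtW @ self.WtW_inv @ ZtW.T
        self.ZtW = ZtW
        try:
            lam, Phi = sla.eigh(self.ZtSZ, self.H_inv)
        except sla.LinAlgError as exc:
            raise NumericalError("H^-1 is not positive definite") from exc
        self.lam = np.clip(lam, 0.0, None)
        self.Phi = Phi

    def project(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (v = Phi' Z' S y,  y'Sy)."""
        Wty = self.W.T @ y
        Sy = y - self.W @ (self.WtW_inv @ Wty)
        ZtSy = self.Z.T @ Sy
        return self.Phi.T @ ZtSy, float(y @ Sy)

    def solutions(self, y: np.ndarray, k: float) -> tuple[np.ndarray, np.ndarray]:
        """BLUE/BLUP (b_hat, a_hat) at variance ratio k."""
        v, _ = self.project(y)
        a_hat = self.Phi @ (v / (self.lam + k))
        b_hat = self.WtW_inv @ (self.W.T @ (y - self.Z @ a_hat))
        return b_hat, a_hat


def _reml_minus2_loglik(design: _SpectralDesign, v, ySy, sigma_a2, sigma_e2) -> float:
    """-2 residual log-likelihood up to an additive constant."""
    k = sigma_e2 / sigma_a2
    q = len(design.lam)
    n, p = design.n, design.rank_W
    rss = ySy - np.sum(v**2 / (design.lam + k))
    return (
        (n - p - q) * np.log(sigma_e2)
        + q * np.log(sigma_a2)
        + float(np.sum(np.log(design.lam + k)))
        + rss / sigma_e2
    )


@dataclass
class RemlDiagnostics:
    iterations: int
    converged: bool
    final_change: float
    method: str
    minus2_loglik: float = np.nan
    history: list = field(default_factory=list)


def _em_iterate(design, v, ySy, sigma_a2, sigma_e2, max_iter, tol, history):
    q = len(design.lam)
    dof_e = design.n - design.rank_W
    change = np.inf
    it = 0
    prev_ll = np.inf
    flat = 0
    for it in range(1, max_iter + 1):
        k = sigma_e2 / sigma_a2
        denom = design.lam + k
        tr_term = float(np.sum(1.0 / denom))
        a_Hinv_a = float(np.sum(v**2 / denom**2))
        rss = ySy - float(np.sum(v**2 / denom))
        new_a = (a_Hinv_a + sigma_e2 * tr_term) / q
        new_e = rss / dof_e
        if new_a <= 0 or new_e <= 0:
            raise NumericalError("EM-REML produced a non-positive variance update")
        # parameter change relative to the total variance: keeps the stopping
        # rule meaningful when one component collapses towards the boundary
        change = max(abs(new_a - sigma_a2), abs(new_e - sigma_e2)) / (
            sigma_a2 + sigma_e2
        )
        sigma_a2, sigma_e2 = new_a, new_e
        history.append((sigma_a2, sigma_e2))
        if change < tol:
            break
        # secondary rule: EM can crawl when the likelihood is nearly flat in
        # h2 (or a component sits at the boundary); once -2logL is stationary
        # to machine-level precision over several iterations, accept
        ll = _reml_minus2_loglik(design, v, ySy, sigma_a2, sigma_e2)
        flat = flat + 1 if abs(prev_ll - ll) < 1e-12 * (1.0 + abs(ll)) else 0
        prev_ll = ll
        if flat >= 5 and change < max(tol, 1e-8) ** 0.5:
            change = 0.0
            break
    return sigma_a2, sigma_e2, it, change


def _score(design, v, ySy, sigma_a2, sigma_e2):
    """Gradient of the REML log-likelihood wrt (sigma_a2, sigma_e2)."""
    k = sigma_e2 / sigma_a2
    q = len(design.lam)
    denom = design.lam + k
    tr_term = float(np.sum(1.0 / denom))
    a_Hinv_a = float(np.sum(v**2 / denom**2))
    rss = ySy - float(np.sum(v**2 / denom))
    d_a = -0.5 * ((q - k * tr_term) / sigma_a2 - a_Hinv_a / sigma_a2**2)
    d_e = -0.5 * (
        (design.n - design.rank_W - q) / sigma_e2
        + tr_term / sigma_a2
        - rss / sigma_e2**2
        + a_Hinv_a / (sigma_a2 * sigma_e2)
    )
    return np.array([d_a, d_e])


def _average_information(design, y, sigma_a2, sigma_e2):
    """2x2 average-information matrix AI_ij = 1/2 y'P Vdot_i P Vdot_j P y."""
    k = sigma_e2 / sigma_a2

    def P_apply(x: np.ndarray) -> np.ndarray:
        b, a = design.solutions(x, k)
        return (x - design.W @ b - design.Z @ a) / sigma_e2

    # H z via the cached factorization of H^-1
    cho = sla.cho_factor(design.H_inv)
    Py = P_apply(y)
    t_e = Py
    t_a = design.Z @ sla.cho_solve(cho, np.asarray(design.Z.T @ Py))
    Pt_a = P_apply(t_a)
    Pt_e = P_apply(t_e)
    ai = 0.5 * np.array(
        [[t_a @ Pt_a, t_a @ Pt_e], [t_a @ Pt_e, t_e @ Pt_e]]
    )
    return ai


def reml_estimate_from_design(
    design: _SpectralDesign,
    y: np.ndarray,
    start: VarianceComponents | None = None,
    method: str = "em",
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> tuple[VarianceComponents, RemlDiagnostics]:
    """EM-REML (method='em') or AI-accelerated REML (method='ai')."""
    if method not in ("em", "ai"):
        raise ConfigurationError(f"unknown REML method {method!r}")
    v, ySy = design.project(y)
    var_y = ySy / max(design.n - design.rank_W, 1)
    if start is None:
        sigma_a2 = 0.5 * var_y
        sigma_e2 = 0.5 * var_y
    else:
        sigma_a2, sigma_e2 = start.sigma_a2, start.sigma_e2
    history: list = []

    if method == "em":
        sigma_a2, sigma_e2, it, change = _em_iterate(
            design, v, ySy, sigma_a2, sigma_e2, max_iter, tol, history
        )
        # polish the EM fixed point by direct minimisation of the closed-form
        # -2logL (O(q) per evaluation); tightens the optimum when EM crawls on
        # a flat likelihood and is a no-op when EM has fully converged
        import scipy.optimize as opt

        res = opt.minimize(
            lambda t: _reml_minus2_loglik(design, v, ySy, *np.exp(t)),
            np.log([sigma_a2, sigma_e2]),
            method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-13, "maxiter": 5000, "maxfev": 10000},
        )
        if res.fun <= _reml_minus2_loglik(design, v, ySy, sigma_a2, sigma_e2):
            sigma_a2, sigma_e2 = (float(x) for x in np.exp(res.x))
        # scale-invariant stationarity: |d logL / d log(sigma2)| per observation
        grad = _score(design, v, ySy, sigma_a2, sigma_e2)
        stationary = (
            max(abs(grad[0]) * sigma_a2, abs(grad[1]) * sigma_e2) / design.n < 1e-6
        )
        converged = change < tol or res.success or stationary
        vc = VarianceComponents(sigma_a2, sigma_e2)
        diag = RemlDiagnostics(it, converged, change, "em")
    else:
        # a few EM warm-up steps, then AI Newton updates with step halving
        sigma_a2, sigma_e2, _, _ = _em_iterate(
            design, v, ySy, sigma_a2, sigma_e2, 3, 0.0, history
        )
        change = np.inf
        it = 3
        for it in range(4, max_iter + 1):
            grad = _score(design, v, ySy, sigma_a2, sigma_e2)
            ai = _average_information(design, y, sigma_a2, sigma_e2)
            try:
                step = np.linalg.solve(ai, grad)
            except np.linalg.LinAlgError as exc:
                raise NumericalError("average-information matrix is singular") from exc
            scale = 1.0
            for _ in range(30):
                new = np.array([sigma_a2, sigma_e2]) + scale * step
                if np.all(new > 0):
                    break
                scale /= 2.0
            else:
                raise NumericalError(
                    "AI-REML step-halving failed to find a positive update"
                )
            change = float(
                np.max(np.abs(new - [sigma_a2, sigma_e2]) / np.maximum([sigma_a2, sigma_e2], 1e-300))
            )
            sigma_a2, sigma_e2 = float(new[0]), float(new[1])
            history.append((sigma_a2, sigma_e2))
            if change < tol:
                break
        ai = _average_information(design, y, sigma_a2, sigma_e2)
        cov = np.linalg.inv(ai)
        se_a = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_e = float(np.sqrt(max(cov[1, 1], 0.0)))
        # delta method for h2 = sa / (sa + se)
        sp2 = sigma_a2 + sigma_e2
        grad_h2 = np.array([sigma_e2 / sp2**2, -sigma_a2 / sp2**2])
        se_h2 = float(np.sqrt(max(grad_h2 @ cov @ grad_h2, 0.0)))
        vc = VarianceComponents(sigma_a2, sigma_e2, se_a, se_e, se_h2)
        diag = RemlDiagnostics(it, change < tol, change, "ai")

    diag.history = history
    diag.minus2_loglik = _reml_minus2_loglik(design, v, ySy, vc.sigma_a2, vc.sigma_e2)
    if not diag.converged:
        raise NumericalError(
            f"REML did not converge in {max_iter} iterations "
            f"(last relative change {diag.final_change:.2e})"
        )
    return vc, diag


def reml_estimate(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    H_inv,
    start: VarianceComponents | None = None,
    method: str = "em",
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Functional wrapper: estimate (sigma_a2, sigma_e2) on the given design."""
    W, _ = build_fixed_design(phenotypes, spec)
    Z = build_incidence(phenotypes, pedigree, spec)
    design = _SpectralDesign(W, Z, H_inv)
    y = phenotypes[spec.trait].to_numpy(dtype=float)
    vc, _ = reml_estimate_from_design(design, y, start, method, max_iter, tol)
    return vc


# ---------------------------------------------------------------------------
# statsmodels-style model / results
# ---------------------------------------------------------------------------

class SingleStepGBLUP:
    """Single-trait animal model on the single-step H matrix.

    Parameters
    ----------
    phenotypes : DataFrame
        One row per record with the trait, fixed-effect columns and animal id.
    pedigree : Pedigree
        Ordered pedigree carrying the genotyped flags.
    H_inv : sparse or dense matrix
        Inverse relationship matrix over pedigree animals (A^-1 when no
        genotypes are available).
    spec : ModelSpec, optional
        Fixed-effect structure; defaults to the growth-trait model.
    """

    def __init__(self, phenotypes, pedigree, H_inv, spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else ModelSpec()
        self.phenotypes = phenotypes.reset_index(drop=True)
        self.pedigree = pedigree
        self.H_inv = H_inv
        missing = set(self.phenotypes[self.spec.id_column].astype(str)) - set(
            pedigree.ids.tolist()
        )
        if missing:
            raise ConfigurationError(
                f"phenotyped animals absent from pedigree: {sorted(missing)[:5]}"
            )
        self._design: _SpectralDesign | None = None

    @property
    def design(self) -> _SpectralDesign:
        if self._design is None:
            W, names = build_fixed_design(self.phenotypes, self.spec)
            Z = build_incidence(self.phenotypes, self.pedigree, self.spec)
            self._design = _SpectralDesign(W, Z, self.H_inv)
            self._fixed_names = names
        return self._design

    def refit(self, trait_values) -> "SingleStepGBLUP":
        """New model with re-drawn trait values, sharing the cached decomposition."""
        phen = self.phenotypes.copy()
        phen[self.spec.trait] = np.asarray(trait_values, dtype=float)
        new = SingleStepGBLUP.__new__(SingleStepGBLUP)
        new.spec = self.spec
        new.phenotypes = phen
        new.pedigree = self.pedigree
        new.H_inv = self.H_inv
        new._design = self.design
        new._fixed_names = self._fixed_names
        return new

    def fit(
        self,
        method: str = "em",
        start: VarianceComponents | None = None,
        max_iter: int = 2000,
        tol: float = 1e-8,
        vc: VarianceComponents | None = None,
    ) -> "SingleStepGBLUPResults":
        """Estimate variance components (unless ``vc`` is given) and BLUPs."""
        y = self.phenotypes[self.spec.trait].to_numpy(dtype=float)
        design = self.design
        if vc is None:
            vc, diag = reml_estimate_from_design(design, y, start, method, max_iter, tol)
        else:
            v, ySy = design.project(y)
            diag = RemlDiagnostics(0, True, 0.0, "fixed",
                                   _reml_minus2_loglik(design, v, ySy, vc.sigma_a2, vc.sigma_e2))
        b_hat, a_hat = design.solutions(y, vc.ratio)
        return SingleStepGBLUPResults(self, vc, b_hat, a_hat, diag)


class SingleStepGBLUPResults:
    """Fitted single-step animal model: variance components and BLUPs."""

    def __init__(self, model, vc, b_hat, a_hat, diagnostics):
        self.model = model
        self.vc = vc
        self.fe_estimates = b_hat
        self.gebv = a_hat
        self.diagnostics = diagnostics

    @property
    def h2(self) -> float:
        return self.vc.h2

    @property
    def gebv_genotyped(self) -> np.ndarray:
        return self.gebv[self.model.pedigree.genotyped_index]

    def trait_summary(self) -> TraitSummary:
        return summarize_trait(self.model.phenotypes[self.model.spec.trait])

    def summary(self) -> str:
        """Plain-text summary table (descriptives + variance components)."""
        s = self.trait_summary()
        vc = self.vc
        lines = [
            "Single-step GBLUP animal model",
            "=" * 58,
            f"trait: {self.model.spec.trait}   records: {s.n}   "
            f"pedigree animals: {len(self.model.pedigree)}   "
            f"genotyped: {self.model.pedigree.n_genotyped}",
            f"mean {s.mean:.3f}  SD {s.sd:.3f}  min {s.min:.3f}  max {s.max:.3f}  "
            f"CV% {s.cv_percent:.2f}",
            "-" * 58,
            f"sigma_a2 {vc.sigma_a2:.6g}"
            + (f" (SE {vc.se_sigma_a2:.3g})" if vc.se_sigma_a2 is not None else ""),
            f"sigma_e2 {vc.sigma_e2:.6g}"
            + (f" (SE {vc.se_sigma_e2:.3g})" if vc.se_sigma_e2 is not None else ""),
            f"sigma_p2 {vc.sigma_p2:.6g}",
            f"h2       {vc.h2:.4f}"
            + (f" (SE {vc.se_h2:.3g})" if vc.se_h2 is not None else "  (SE n/a under EM)"),
            f"REML: method={self.diagnostics.method} iterations={self.diagnostics.iterations} "
            f"converged={self.diagnostics.converged}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """GEBV table (id, genotyped flag, gebv)."""
        ped = self.model.pedigree
        return pd.DataFrame(
            {"id": ped.ids, "genotyped": ped.genotyped.astype(int), "gebv": self.gebv}
        )
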