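"""REML animal and reaction norm models on pedigree or single-step kinship.

The reaction norm model (RNM) for a fertility record y_i of animal j(i)
observed at environmental-gradient value x_i is

    y_i = x_f(i)'b + a0_{j(i)} + x_i * a1_{j(i)} + e_i

with fixed effects b (herd-year-month of first service, technician,
semen type, optionally a linear regression on the gradient), correlated
random intercepts and slopes

    [a0; a1] ~ N(0, Sigma (x) K),   Sigma = [[s00, s01], [s01, s11]],

K the pedigree (A) or single-step (H) relationship matrix, and i.i.d.
residuals e ~ N(0, I se) homogeneous across the gradient.  The plain
animal model is the special case with the slope term removed.

Estimation maximises the exact restricted log-likelihood, evaluated
through the mixed-model equations (one sparse or dense factorisation per
evaluation, with the determinant identity
log|V| + log|X'V^-1 X| = n log se + log|Sigma (x) K| + log|C|).
Updates are Newton steps using the exact average-information (AI) matrix
as curvature and a central-finite-difference score; a step that leaves
the parameter space or decreases the likelihood is repaired by
step-halving.  Standard errors of the (co)variance components come from
the inverse AI matrix at the optimum, and standard errors of derived
quantities (heritabilities, correlations) by first-order (delta-method /
Taylor-series) propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import norm

from .kinship import Kinship

__all__ = [
    "AnimalModel",
    "ReactionNormModel",
    "AnimalModelResults",
    "ReactionNormResults",
    "CovarianceStructure",
    "ConvergenceError",
    "IdentifiabilityError",
    "heritability",
    "coefficient_of_variation",
    "build_design",
]


class ConvergenceError(RuntimeError):
    """REML failed to converge within the allowed rounds."""


class IdentifiabilityError(ValueError):
    """The design cannot separate the requested variance components."""


def heritability(sigma_a_sq: float, sigma_e_sq: float) -> float:
    """Narrow-sense heritability sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    return sigma_a_sq / (sigma_a_sq + sigma_e_sq)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Phenotypic coefficient of variation SD / mean."""
    return sd / mean


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------

def build_design(
    df: pd.DataFrame,
    factors=("hym", "technician", "semen_type"),
    covariates=(),
) -> tuple[sp.csr_matrix, list[str]]:
    """Fixed-effect design: intercept, dummy-coded factors, covariates.

    Reference (first) levels are dropped; exactly collinear columns are
    removed by pivoted QR on the cross-product so the design is full rank.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        d = pd.get_dummies(df[f].astype("category"), prefix=f, drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
            names.append(str(c))
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(str(c))
    X = np.column_stack(cols)
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx, hermitian=True)
    if rank < X.shape[1]:
        _, _, piv = la.qr(xtx, pivoting=True)
        keep = np.sort(piv[:rank])
        X = X[:, keep]
        names = [names[i] for i in keep]
    return sp.csr_matrix(X), names


# ---------------------------------------------------------------------------
# covariance structure
# ---------------------------------------------------------------------------

@dataclass
class CovarianceStructure:
    """(Co)variance components of a reaction norm model with AI covariance.

    ``param_cov`` is ordered (sigma_a0_sq, sigma_a0a1, sigma_a1_sq,
    sigma_e_sq); for the plain animal model use ``sigma_a1_sq = 0`` and a
    2x2 ``param_cov`` over (sigma_a0_sq, sigma_e_sq).
    """

    sigma_a0_sq: float
    sigma_a1_sq: float
    sigma_a0a1: float
    sigma_e_sq: float
    param_cov: np.ndarray | None = None

    @property
    def sigma(self) -> np.ndarray:
        return np.array(
            [[self.sigma_a0_sq, self.sigma_a0a1], [self.sigma_a0a1, self.sigma_a1_sq]]
        )

    @property
    def se(self) -> dict:
        if self.param_cov is None:
            return {}
        d = np.sqrt(np.clip(np.diag(self.param_cov), 0, None))
        if len(d) == 4:
            keys = ("sigma_a0_sq", "sigma_a0a1", "sigma_a1_sq", "sigma_e_sq")
        else:
            keys = ("sigma_a0_sq", "sigma_e_sq")
        return dict(zip(keys, d))

    def as_dict(self) -> dict:
        out = {
            "sigma_a0_sq": self.sigma_a0_sq,
            "sigma_a1_sq": self.sigma_a1_sq,
            "sigma_a0a1": self.sigma_a0a1,
            "sigma_e_sq": self.sigma_e_sq,
        }
        out.update({f"se_{k}": v for k, v in self.se.items()})
        return out


def genetic_variance_at(x, cov: CovarianceStructure | tuple):
    """Genetic variance along the gradient: v(x) = s00 + 2 x s01 + x^2 s11."""
    if isinstance(cov, CovarianceStructure):
        s00, s01, s11 = cov.sigma_a0_sq, cov.sigma_a0a1, cov.sigma_a1_sq
    else:
        s00, s11, s01 = cov[0], cov[1], cov[2]
    x = np.asarray(x, dtype=float)
    return s00 + 2.0 * x * s01 + x**2 * s11


def genetic_correlation(x1, x2, cov: CovarianceStructure) -> float:
    """Genetic correlation between gradient levels x1 and x2."""
    v1 = genetic_variance_at(x1, cov)
    v2 = genetic_variance_at(x2, cov)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise ValueError("zero genetic variance at a gradient endpoint")
    c12 = cov.sigma_a0_sq + (np.asarray(x1) + np.asarray(x2)) * cov.sigma_a0a1 \
        + np.asarray(x1) * np.asarray(x2) * cov.sigma_a1_sq
    return c12 / np.sqrt(v1 * v2)


def intercept_slope_correlation(cov: CovarianceStructure):
    """Correlation between intercept and slope, with delta-method SE."""
    s00, s01, s11 = cov.sigma_a0_sq, cov.sigma_a0a1, cov.sigma_a1_sq
    denom = np.sqrt(s00 * s11)
    r = s01 / denom
    se = None
    if cov.param_cov is not None and len(cov.param_cov) == 4:
        grad = np.array([-r / (2 * s00), 1.0 / denom, -r / (2 * s11), 0.0])
        se = float(np.sqrt(max(grad @ cov.param_cov @ grad, 0.0)))
    return float(r), se


# ---------------------------------------------------------------------------
# model core
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))


class _MixedModel:
    """Shared REML machinery for 1-term (animal) and 2-term (RNM) models."""

    n_terms: int = 1

    def __init__(
        self,
        endog: np.ndarray,
        exog: sp.spmatrix,
        animal_pos: np.ndarray,
        kinship: Kinship,
        eg: np.ndarray | None = None,
        exog_names: list[str] | None = None,
        backend: str = "auto",
    ):
        self.y = np.asarray(endog, dtype=float)
        self.X = sp.csr_matrix(exog)
        self.codes = np.asarray(animal_pos, dtype=np.int64)
        self.kinship = kinship
        self.eg = None if eg is None else np.asarray(eg, dtype=float)
        self.exog_names = exog_names or [f"x{i}" for i in range(self.X.shape[1])]
        self.nobs = len(self.y)
        self.N = kinship.n
        if self.codes.min() < 0 or self.codes.max() >= self.N:
            raise ValueError("animal positions outside kinship")
        if self.n_terms == 2:
            if self.eg is None:
                raise ValueError("reaction norm model requires gradient values")
            if np.var(self.eg) < 1e-12 * (1.0 + np.mean(self.eg) ** 2):
                raise IdentifiabilityError(
                    "all gradient values equal: slope variance is unidentifiable"
                )
        self._prepare(backend)

    # -- precomputation ----------------------------------------------------
    def _prepare(self, backend):
        n, N = self.nobs, self.N
        # The optimiser works with the gradient centred at its mean: on raw
        # scales (e.g. THI units 15-75) the intercept is an extrapolation to
        # x = 0 and the likelihood has a badly conditioned curved ridge in
        # (s00, s01); centring is an exact reparametrisation and every
        # reported quantity is transformed back to the raw scale.
        self.center = float(np.mean(self.eg)) if self.n_terms == 2 else 0.0
        covs = [np.ones(n)] if self.n_terms == 1 else [np.ones(n), self.eg - self.center]
        self.covs = covs
        indptr = np.arange(n + 1)
        self.Z = [
            sp.csr_matrix((c, self.codes.copy(), indptr), shape=(n, N)) for c in covs
        ]
        self.XtX = (self.X.T @ self.X).tocsr()
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.XtZ = [(self.X.T @ Zj).tocsr() for Zj in self.Z]
        self.Zty = [Zj.T @ self.y for Zj in self.Z]
        self.D = {}
        for j in range(self.n_terms):
            for k in range(j, self.n_terms):
                self.D[(j, k)] = np.bincount(
                    self.codes, weights=covs[j] * covs[k], minlength=N
                )
        self.Kinv = self.kinship.inv.tocsc()
        self.p = self.X.shape[1]
        dim = self.p + self.n_terms * N
        nnz_est = self.XtX.nnz + 2 * sum(m.nnz for m in self.XtZ) + \
            self.n_terms**2 * self.Kinv.nnz + self.n_terms * N
        if backend == "auto":
            backend = "dense" if (dim <= 2000 or (dim <= 7000 and nnz_est / dim**2 > 0.05)) else "sparse"
        self.backend = backend
        self.dim = dim

    # -- theta handling ----------------------------------------------------
    @property
    def n_params(self) -> int:
        t = self.n_terms
        return t * (t + 1) // 2 + 1

    # raw <-> centred parameter transforms: with x* = x - c the intercept
    # becomes a0* = a0 + c a1, so Sigma* = B Sigma B' with B = [[1, c], [0, 1]]
    def _to_internal(self, theta):
        if self.n_terms == 1:
            return np.asarray(theta, dtype=float)
        c = self.center
        s00, s01, s11, se = theta
        return np.array([s00 + 2 * c * s01 + c * c * s11, s01 + c * s11, s11, se])

    def _to_raw(self, theta_c):
        if self.n_terms == 1:
            return np.asarray(theta_c, dtype=float)
        c = self.center
        s00, s01, s11, se = theta_c
        return np.array([s00 - 2 * c * s01 + c * c * s11, s01 - c * s11, s11, se])

    def _internal_jacobian(self):
        """d theta_centred / d theta_raw."""
        if self.n_terms == 1:
            return np.eye(2)
        c = self.center
        return np.array([
            [1.0, 2 * c, c * c, 0.0],
            [0.0, 1.0, c, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ])

    def _sigma(self, theta):
        if self.n_terms == 1:
            return np.array([[theta[0]]])
        return np.array([[theta[0], theta[1]], [theta[1], theta[2]]])

    def _valid(self, theta) -> bool:
        se = theta[-1]
        if not np.isfinite(theta).all() or se <= 0:
            return False
        sig = self._sigma(theta)
        try:
            ev = np.linalg.eigvalsh(sig)
        except np.linalg.LinAlgError:
            return False
        return bool(ev.min() > 1e-12 * max(ev.max(), 1e-300))

    # -- likelihood --------------------------------------------------------
    def _assemble(self, theta):
        se = theta[-1]
        sig = self._sigma(theta)
        sig_inv = np.linalg.inv(sig)
        t, N = self.n_terms, self.N
        blocks = [[None] * (t + 1) for _ in range(t + 1)]
        blocks[0][0] = self.XtX / se
        for j in range(t):
            blocks[0][j + 1] = self.XtZ[j] / se
            blocks[j + 1][0] = self.XtZ[j].T / se
        for j in range(t):
            for k in range(j, t):
                Djk = self.D[(j, k)]
                B = sp.diags(Djk / se) + sig_inv[j, k] * self.Kinv
                blocks[j + 1][k + 1] = B
                if k != j:
                    blocks[k + 1][j + 1] = B.T
        C = sp.bmat(blocks, format="csc")
        rhs = np.concatenate([self.Xty] + self.Zty) / se
        return C, rhs, sig, sig_inv

    def _factorize(self, C):
        if self.backend == "dense":
            Cd = C.toarray()
            cf = la.cho_factor(Cd, lower=True, check_finite=False)
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return ("dense", cf), logdet
        # symmetric-structure minimum-degree ordering: C is SPD and COLAMD
        # produces catastrophic fill on animal-model equations
        lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
        diag = lu.U.diagonal()
        logdet = float(np.sum(np.log(np.abs(diag))))
        return ("sparse", lu), logdet

    @staticmethod
    def _solve(factor, b):
        kind, f = factor
        if kind == "dense":
            return la.cho_solve(f, b, check_finite=False)
        return f.solve(np.asarray(b, dtype=float))

    def loglike(self, theta, _return_factor=False):
        """Exact restricted log-likelihood at raw-scale theta."""
        theta_c = self._to_internal(theta)
        return self._loglike_c(theta_c, _return_factor=_return_factor)

    def _loglike_c(self, theta, _return_factor=False):
        """Restricted logL at centred-parametrisation theta."""
        if not self._valid(theta):
            return (-np.inf, None, None) if _return_factor else -np.inf
        se = theta[-1]
        C, rhs, sig, _ = self._assemble(theta)
        try:
            factor, logdet_C = self._factorize(C)
        except (la.LinAlgError, RuntimeError):
            return (-np.inf, None, None) if _return_factor else -np.inf
        sol = self._solve(factor, rhs)
        ypy = self.yty / se - float(sol @ rhs)
        sign, logdet_sig = np.linalg.slogdet(sig)
        if sign <= 0:
            return (-np.inf, None, None) if _return_factor else -np.inf
        logdet_G = self.N * logdet_sig + self.n_terms * self.kinship.logdet
        m2ll = self.nobs * np.log(se) + logdet_G + logdet_C + ypy
        ll = -0.5 * (m2ll + (self.nobs - self.p) * _LOG2PI)
        if _return_factor:
            return ll, factor, sol
        return ll

    # -- average information ----------------------------------------------
    def _ai_matrix(self, theta, factor, sol):
        """Exact AI matrix: AI_ij = 0.5 f_i' P f_j with f_i = dV/dtheta_i P y."""
        se = theta[-1]
        t = self.n_terms
        b = sol[: self.p]
        u = [sol[self.p + j * self.N : self.p + (j + 1) * self.N] for j in range(t)]
        fitted = self.X @ b
        for j in range(t):
            fitted = fitted + self.Z[j] @ u[j]
        Py = (self.y - fitted) / se

        tvec = [self.kinship.dot(Zj.T @ Py) for Zj in self.Z]
        fs = []
        for j in range(t):
            for k in range(j, t):
                if j == k:
                    fs.append(self.Z[j] @ tvec[j])
                else:
                    fs.append(self.Z[j] @ tvec[k] + self.Z[k] @ tvec[j])
        fs.append(Py)

        Pfs = []
        for f in fs:
            rhs_f = np.concatenate([self.X.T @ f] + [Zj.T @ f for Zj in self.Z]) / se
            sol_f = self._solve(factor, rhs_f)
            bf = sol_f[: self.p]
            fit_f = self.X @ bf
            for j in range(t):
                fit_f = fit_f + self.Z[j] @ sol_f[self.p + j * self.N : self.p + (j + 1) * self.N]
            Pfs.append((f - fit_f) / se)
        q = len(fs)
        ai = np.empty((q, q))
        for i in range(q):
            for j in range(i, q):
                ai[i, j] = ai[j, i] = 0.5 * float(fs[i] @ Pfs[j])
        return ai

    # -- scores ------------------------------------------------------------
    def _fd_score(self, theta, ll0, ref, rel=1e-4):
        g = np.empty(len(theta))
        for k in range(len(theta)):
            h = rel * max(abs(theta[k]), 1e-3 * ref[k])
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            lp = self._loglike_c(tp)
            lm = self._loglike_c(tm)
            if np.isfinite(lp) and np.isfinite(lm):
                g[k] = (lp - lm) / (2 * h)
            elif np.isfinite(lp):
                g[k] = (lp - ll0) / h
            elif np.isfinite(lm):
                g[k] = (ll0 - lm) / h
            else:
                g[k] = 0.0
        return g

    def _start(self):
        # OLS residual variance partitioned between genetic and residual
        Xd = self.X.toarray()
        beta, *_ = np.linalg.lstsq(Xd, self.y, rcond=None)
        v = float(np.var(self.y - Xd @ beta, ddof=Xd.shape[1]))
        if self.n_terms == 1:
            return np.array([0.3 * v, 0.7 * v])
        # hierarchical warm start: a plain animal-model fit pins down the
        # genetic/residual split, and the genetic variance is then divided
        # evenly between the (centred) intercept and the slope term — the
        # reaction norm surface has low-slope-variance local basins that
        # capture the iteration when the slope starts too small
        xs = float(np.var(self.eg)) + 1e-12
        try:
            am = AnimalModel(self.y, self.X, self.codes, self.kinship,
                             backend=self.backend)
            am_res = am.fit(compute_se=False, maxiter=30)
            sa, se = am_res.sigma_a_sq, am_res.sigma_e_sq
            sa = max(sa, 1e-3 * v)
            return np.array([0.5 * sa, 0.0, 0.5 * sa / xs, se])
        except Exception:
            return np.array([0.3 * v, 0.0, 0.3 * v / xs, 0.7 * v])

    # -- fit ---------------------------------------------------------------
    def fit(
        self,
        start=None,
        maxiter: int = 60,
        tol_param: float = 1e-8,
        tol_logl: float = 1e-9,
        compute_se: bool = True,
        verbose: bool = False,
    ):
        # the optimiser runs in the centred parametrisation throughout
        theta = (self._to_internal(np.asarray(start, dtype=float))
                 if start is not None else self._start())
        if not self._valid(theta):
            raise ValueError("invalid starting values")
        ref = np.maximum(np.abs(theta), 1e-12)
        if self.n_terms == 2:
            ref[1] = max(ref[1], np.sqrt(ref[0] * ref[2]))
        ll, factor, sol = self._loglike_c(theta, _return_factor=True)
        if not np.isfinite(ll):
            raise ValueError("restricted likelihood undefined at start")
        trace = [(theta.copy(), ll)]
        converged = False
        n_iter = 0
        stalls = 0
        def _line_search(delta):
            step = 1.0
            for _ in range(40):
                cand = theta + step * delta
                if self._valid(cand):
                    ll_new, fac_new, sol_new = self._loglike_c(cand, _return_factor=True)
                    if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                        return cand, ll_new, fac_new, sol_new, step * delta
                step *= 0.5
            return None

        for n_iter in range(1, maxiter + 1):
            g = self._fd_score(theta, ll, ref)
            ai = self._ai_matrix(theta, factor, sol)
            # ridge for safety on ill-conditioned AI
            scale = np.abs(np.diag(ai)).max()
            try:
                delta = la.solve(ai + 1e-10 * scale * np.eye(len(ai)), g, assume_a="sym")
            except la.LinAlgError:
                delta = g / max(scale, 1e-300)
            hit = _line_search(delta)
            # far from the optimum the AI-Newton direction can point down a
            # side valley; a diagonally preconditioned gradient step is a
            # robust alternative — keep whichever climbs higher
            diag = np.maximum(np.abs(np.diag(ai)), 1e-12 * scale)
            hit_g = _line_search(g / diag)
            if hit_g is not None and (hit is None or hit_g[1] > hit[1]):
                hit = hit_g
            if hit is None:
                stalls += 1
                if stalls >= 2:
                    converged = True  # cannot improve beyond numerical noise
                    break
                continue
            cand, ll_new, fac_new, sol_new, dvec = hit
            rel_change = np.max(np.abs(dvec) / np.maximum(np.abs(theta), ref * 1e-3))
            dll = ll_new - ll
            theta, ll, factor, sol = cand, ll_new, fac_new, sol_new
            trace.append((theta.copy(), ll))
            if verbose:
                print(f"iter {n_iter}: logL={ll:.6f} theta={theta}")
            if rel_change < tol_param or abs(dll) < tol_logl:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {maxiter} rounds (logL={ll:.4f})"
            )
        # transform back to the raw parametrisation for reporting
        param_cov = None
        ai_c = self._ai_matrix(theta, factor, sol)
        J = self._internal_jacobian()       # d theta_c / d theta_raw
        ai_raw = J.T @ ai_c @ J
        if compute_se:
            try:
                Jinv = np.linalg.inv(J)
                param_cov = Jinv @ np.linalg.inv(ai_c) @ Jinv.T
            except np.linalg.LinAlgError:
                warnings.warn("singular AI matrix: no standard errors")
        theta_raw = self._to_raw(theta)
        trace = [(self._to_raw(t), llv) for t, llv in trace]
        return self._make_results(theta_raw, ll, factor, sol, ai_raw, param_cov,
                                  converged, n_iter, trace)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class _ResultsBase:
    def __init__(self, model, theta, ll, factor, sol, ai, param_cov, converged, n_iter, trace):
        self.model = model
        self.theta = theta
        self.loglike = float(ll)
        self._factor = factor
        self._sol = sol
        self.ai_matrix = ai
        self.param_cov = param_cov
        self.converged = converged
        self.n_iter = n_iter
        self.trace = trace
        self.k = model.n_params
        self._pev_cache: dict[int, np.ndarray] = {}
        p = model.p
        self.fe = pd.Series(sol[:p], index=model.exog_names)

    @property
    def aic(self) -> float:
        """-2 logL + 2 k with k the number of (co)variance parameters."""
        return -2.0 * self.loglike + 2.0 * self.k

    def _pev_block(self, animals):
        """Prediction-error (co)variances for the requested animal positions.

        Solves one MME column per animal-by-term; cached per animal.
        """
        model = self.model
        t = model.n_terms
        need = [a for a in np.atleast_1d(animals) if a not in self._pev_cache]
        if need:
            cols = []
            for a in need:
                for j in range(t):
                    e = np.zeros(model.dim)
                    e[model.p + j * model.N + a] = 1.0
                    cols.append(e)
            B = np.column_stack(cols)
            S = model._solve(self._factor, B)
            if t == 2:
                c = model.center
                Binv = np.array([[1.0, -c], [0.0, 1.0]])
            for i, a in enumerate(need):
                block = np.empty((t, t))
                for j in range(t):
                    col = S[:, i * t + j]
                    for m in range(t):
                        block[j, m] = col[model.p + m * model.N + a]
                block = 0.5 * (block + block.T)
                if t == 2:
                    # MME columns are in the centred basis; map back to raw
                    block = Binv @ block @ Binv.T
                self._pev_cache[a] = block
        return np.array([self._pev_cache[a] for a in np.atleast_1d(animals)])


class AnimalModelResults(_ResultsBase):
    """REML results for the single-trait animal model."""

    @property
    def sigma_a_sq(self) -> float:
        return float(self.theta[0])

    @property
    def sigma_e_sq(self) -> float:
        return float(self.theta[1])

    @property
    def se(self) -> dict:
        if self.param_cov is None:
            return {}
        d = np.sqrt(np.clip(np.diag(self.param_cov), 0, None))
        return {"sigma_a_sq": d[0], "sigma_e_sq": d[1]}

    @property
    def ebv(self) -> np.ndarray:
        return self._sol[self.model.p :]

    def heritability(self):
        """h^2 = sa/(sa+se) with delta-method SE from the AI matrix."""
        sa, se_ = self.sigma_a_sq, self.sigma_e_sq
        h2 = heritability(sa, se_)
        se_h2 = None
        if self.param_cov is not None:
            tot = sa + se_
            grad = np.array([se_ / tot**2, -sa / tot**2])
            se_h2 = float(np.sqrt(max(grad @ self.param_cov @ grad, 0.0)))
        return h2, se_h2

    def summary(self) -> str:
        h2, se_h2 = self.heritability()
        ses = self.se
        lines = [
            "Animal model (REML)",
            "=" * 46,
            f"records: {self.model.nobs}   animals: {self.model.N}   kinship: {self.model.kinship.label}",
            f"logL: {self.loglike:.4f}   AIC: {self.aic:.4f}   iterations: {self.n_iter}",
            f"sigma_a^2: {self.sigma_a_sq:.6g} ({ses.get('sigma_a_sq', float('nan')):.3g})",
            f"sigma_e^2: {self.sigma_e_sq:.6g} ({ses.get('sigma_e_sq', float('nan')):.3g})",
            f"h^2: {h2:.4f}" + (f" ({se_h2:.4f})" if se_h2 is not None else ""),
        ]
        return "\n".join(lines)


class ReactionNormResults(_ResultsBase):
    """REML results for the reaction norm model.

    Genomic breeding values are a function of the gradient,
    ``gEBV(x) = a0 + x a1``; heritability, genetic correlations and
    EBV accuracies are available at any gradient level.
    """

    @property
    def params(self) -> CovarianceStructure:
        return CovarianceStructure(
            sigma_a0_sq=float(self.theta[0]),
            sigma_a0a1=float(self.theta[1]),
            sigma_a1_sq=float(self.theta[2]),
            sigma_e_sq=float(self.theta[3]),
            param_cov=self.param_cov,
        )

    @property
    def a0(self) -> np.ndarray:
        # solutions are stored in the centred basis: a0_raw = a0_c - c a1
        a0_c = self._sol[self.model.p : self.model.p + self.model.N]
        return a0_c - self.model.center * self.a1

    @property
    def a1(self) -> np.ndarray:
        return self._sol[self.model.p + self.model.N :]

    # -- derived genetic parameters ---------------------------------------
    def genetic_variance_at(self, x):
        return genetic_variance_at(x, self.params)

    def heritability_at(self, x):
        """h^2(x) with Taylor-series SE from the AI parameter covariance."""
        cov = self.params
        x = np.asarray(x, dtype=float)
        v = genetic_variance_at(x, cov)
        tot = v + cov.sigma_e_sq
        h2 = np.where(tot > 0, v / tot, 0.0)
        se = None
        if self.param_cov is not None:
            w = cov.sigma_e_sq / tot**2
            grads = np.stack(
                [w, w * 2 * x, w * x**2, -v / tot**2], axis=-1
            )
            se = np.sqrt(np.clip(np.einsum("...i,ij,...j->...", grads, self.param_cov, grads), 0, None))
        return h2, se

    def genetic_correlation(self, x1, x2):
        return genetic_correlation(x1, x2, self.params)

    @property
    def intercept_slope_correlation(self):
        return intercept_slope_correlation(self.params)

    def slope_variance_test(self, alpha: float = 0.05):
        """One-tailed test of sigma_a1^2 > 0 (presence of G x E)."""
        ses = self.params.se
        se_s11 = ses.get("sigma_a1_sq")
        if se_s11 is None or se_s11 <= 0:
            raise ValueError("no standard error available for the slope variance")
        z = self.params.sigma_a1_sq / se_s11
        p = float(norm.sf(z))
        return SlopeVarianceTest(z=float(z), pvalue=p, significant=p < alpha)

    # -- breeding values and accuracy --------------------------------------
    def gebv_at(self, x, animals=None):
        """gEBV(x) = a0 + x a1 for the given animal positions (default all)."""
        a0, a1 = self.a0, self.a1
        if animals is not None:
            animals = np.asarray(animals)
            a0, a1 = a0[animals], a1[animals]
        return a0 + np.asarray(x, dtype=float) * a1

    def pev_at(self, x, animals):
        """PEV of gEBV(x): PEV(a0) + 2x PEVcov + x^2 PEV(a1)."""
        blocks = self._pev_block(animals)
        x = float(x)
        return blocks[:, 0, 0] + 2 * x * blocks[:, 0, 1] + x**2 * blocks[:, 1, 1]

    def accuracy_at(self, x, animals):
        """EBV accuracy sqrt(1 - PEV(x)/v(x)), clipped at zero."""
        v = float(self.genetic_variance_at(x))
        if v <= 0:
            raise ValueError("zero genetic variance at the requested gradient level")
        pev = self.pev_at(x, animals)
        return np.sqrt(np.clip(1.0 - pev / v, 0.0, None))

    # -- diagnostics -------------------------------------------------------
    def residuals(self) -> np.ndarray:
        m = self.model
        fitted = m.X @ self.fe.to_numpy()
        fitted = fitted + self.a0[m.codes] + m.eg * self.a1[m.codes]
        return m.y - fitted

    def residual_homogeneity(self, bounds=(0.10, 0.30), min_records: int = 200,
                             method: str = "refit"):
        """Residual variance across gradient-percentile subsets.

        Splits records at the given percentile ranks of the realized
        gradient (default three groups: bottom 10%, 10-30%, top 70%).
        With ``method="refit"`` each subset gets its own animal-model
        REML fit and its residual-variance estimate is reported; with
        ``method="residual"`` the cheap alternative — the variance of the
        full fit's residuals within the subset — is used (note that BLUP
        animal effects absorb part of any local variance inflation, so
        this variant is less sensitive).  Returns the per-subset table
        and the max/min variance ratio.
        """
        m = self.model
        ranks = pd.Series(m.eg).rank(pct=True, method="first").to_numpy()
        edges = [0.0, *bounds, 1.0]
        if method == "residual":
            r = self.residuals()
        rows = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (ranks > lo) & (ranks <= hi)
            n = int(mask.sum())
            if n < min_records:
                warnings.warn(f"gradient subset ({lo:.2f}, {hi:.2f}] has only {n} records")
            if method == "residual":
                var = float(np.var(r[mask], ddof=1)) if n > 1 else np.nan
            elif method == "refit":
                var = self._subset_residual_variance(mask)
            else:
                raise ValueError("method must be 'refit' or 'residual'")
            rows.append({"pct_lo": lo, "pct_hi": hi, "n": n, "residual_variance": var})
        out = pd.DataFrame(rows)
        v = out["residual_variance"].dropna()
        ratio = float(v.max() / v.min()) if len(v) > 1 and v.min() > 0 else np.nan
        return out, ratio

    def _subset_residual_variance(self, mask) -> float:
        """Profile REML residual variance of one gradient subset.

        The genetic covariance is held at the full fit's estimate (it is
        shared across subsets) and only the residual variance is
        re-estimated from the subset's records, which avoids the
        genetic/residual trade-off noise of a free refit on few records.
        """
        from scipy.optimize import minimize_scalar

        m = self.model
        Xs = m.X[mask].toarray()
        keep = Xs.std(axis=0) > 0
        keep[0] = True  # intercept
        Xs = Xs[:, keep]
        xtx = Xs.T @ Xs
        rank = np.linalg.matrix_rank(xtx, hermitian=True)
        if rank < Xs.shape[1]:
            _, _, piv = la.qr(xtx, pivoting=True)
            Xs = Xs[:, np.sort(piv[:rank])]
        sub = ReactionNormModel(m.y[mask], sp.csr_matrix(Xs), m.codes[mask],
                                m.kinship, eg=m.eg[mask], backend=m.backend) \
            if np.var(m.eg[mask]) > 1e-12 * (1 + np.mean(m.eg[mask]) ** 2) \
            else AnimalModel(m.y[mask], sp.csr_matrix(Xs), m.codes[mask],
                             m.kinship, backend=m.backend)
        se0 = float(self.theta[-1])
        if sub.n_terms == 2:
            genetic = list(self.theta[:3])
        else:
            genetic = [float(self.theta[0])]

        def negll(log_se):
            return -sub.loglike(np.array(genetic + [np.exp(log_se)]))

        opt = minimize_scalar(negll, bracket=(np.log(se0 / 4), np.log(se0)),
                              method="brent", options={"xtol": 1e-8})
        if not np.isfinite(opt.fun):
            return np.nan
        return float(np.exp(opt.x))

    def summary(self) -> str:
        cov = self.params
        ses = cov.se
        r, r_se = self.intercept_slope_correlation
        t = self.slope_variance_test() if ses.get("sigma_a1_sq") else None

        def fmt(v, s):
            return f"{v:.6g} ({s:.3g})" if s is not None else f"{v:.6g}"

        lines = [
            "Reaction norm model (AI-REML)",
            "=" * 58,
            f"records: {self.model.nobs}   animals: {self.model.N}   kinship: {self.model.kinship.label}",
            f"logL: {self.loglike:.4f}   AIC: {self.aic:.4f}   iterations: {self.n_iter}",
            f"sigma_a0^2:  {fmt(cov.sigma_a0_sq, ses.get('sigma_a0_sq'))}",
            f"sigma_a0a1:  {fmt(cov.sigma_a0a1, ses.get('sigma_a0a1'))}",
            f"sigma_a1^2:  {fmt(cov.sigma_a1_sq, ses.get('sigma_a1_sq'))}",
            f"sigma_e^2:   {fmt(cov.sigma_e_sq, ses.get('sigma_e_sq'))}",
            f"r(a0,a1):    {fmt(r, r_se)}",
        ]
        if t is not None:
            lines.append(
                f"G x E slope test: z = {t.z:.3f}, one-tailed p = {t.pvalue:.3g}"
                + ("  (significant)" if t.significant else "")
            )
        return "\n".join(lines)


@dataclass
class SlopeVarianceTest:
    z: float
    pvalue: float
    significant: bool


# ---------------------------------------------------------------------------
# public model classes
# ---------------------------------------------------------------------------

class AnimalModel(_MixedModel):
    """Single-trait animal model ``y = Xb + Za + e`` with a ~ N(0, K sa)."""

    n_terms = 1

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trait: str,
        kinship: Kinship,
        animal_col: str = "heifer_id",
        factors=("hym", "technician", "semen_type"),
        covariates=(),
        backend: str = "auto",
    ) -> "AnimalModel":
        X, names = build_design(df, factors=factors, covariates=covariates)
        id_pos = {a: i for i, a in enumerate(kinship.ids)}
        codes = np.asarray([id_pos[a] for a in df[animal_col]], dtype=np.int64)
        return cls(df[trait].to_numpy(dtype=float), X, codes, kinship,
                   exog_names=names, backend=backend)

    def _make_results(self, *args):
        return AnimalModelResults(self, *args)


class ReactionNormModel(_MixedModel):
    """Linear reaction norm model with correlated intercept and slope.

    By default the fixed part also carries a linear regression on the
    gradient, absorbing the mean environmental trend so the random slope
    captures only its genetic deviation (toggle with
    ``include_eg_fixed`` in :meth:`from_dataframe`).  Gradient values are
    used on their raw scale (proportion in [0, 1] or THI units).
    """

    n_terms = 2

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trait: str,
        eg_col: str,
        kinship: Kinship,
        animal_col: str = "heifer_id",
        factors=("hym", "technician", "semen_type"),
        include_eg_fixed: bool = True,
        backend: str = "auto",
    ) -> "ReactionNormModel":
        covariates = (eg_col,) if include_eg_fixed else ()
        X, names = build_design(df, factors=factors, covariates=covariates)
        id_pos = {a: i for i, a in enumerate(kinship.ids)}
        codes = np.asarray([id_pos[a] for a in df[animal_col]], dtype=np.int64)
        return cls(
            df[trait].to_numpy(dtype=float), X, codes, kinship,
            eg=df[eg_col].to_numpy(dtype=float), exog_names=names, backend=backend,
        )

    def _make_results(self, *args):
        return ReactionNormResults(self, *args)
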