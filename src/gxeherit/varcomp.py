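"""REML variance components for the model y = Xb + g + ge + e.

The phenotypic covariance is V = A_g * sg2 + A_ge * sge2 + I * se2,
where A_g is the SNP-derived relationship matrix and A_ge its
environment-masked counterpart.  Estimation is average-information REML
with an expectation-maximization first step and fallback; variance
components are constrained to a small positive floor, so the boundary
estimate prints as ~1e-6 of the phenotypic variance rather than a
negative value.

The significance of a variance component is assessed by a likelihood
ratio test whose null distribution is the 50:50 mixture of a point mass
at zero and chi-square(1), the standard reference for a parameter on the
boundary of its space.

The bivariate model treats the same trait measured in two environments
as two traits on disjoint individuals; the cross-environment genetic
covariance is identified through the between-environment blocks of the
GRM, and the genetic correlation is r_g = sg12 / sqrt(sg1^2 * sg2^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri
from scipy.stats import chi2

from .grm import GRMatrix

__all__ = [
    "ModelSpec",
    "VarCompResult",
    "LrtResult",
    "BivarResult",
    "reml_fit",
    "reml_loglik",
    "lrt",
    "boundary_lrt_pvalue",
    "bivar_reml",
    "test_rg",
    "design_matrix",
]

_FLOOR_FRAC = 1e-6  # component floor as a fraction of the phenotypic variance
_MAX_ITER = 100
_TOL_LL = 1e-8
_TOL_PAR = 1e-6


@dataclass
class ModelSpec:
    """Aligned inputs for a univariate variance-component fit.

    ``random_structures`` is an ordered list of (name, covariance matrix)
    pairs, e.g. [("G", A_g), ("GxE", A_ge)]; a residual identity
    component is always appended by the fitter.
    """

    y: np.ndarray
    X: np.ndarray
    random_structures: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effects design X is rank deficient")
        for name, M in self.random_structures:
            if np.asarray(M).shape != (n, n):
                raise ValueError(f"structure {name!r} is not n x n")


@dataclass
class VarCompResult:
    """Variance-component estimates and derived proportions."""

    names: list[str]  # component names, residual "e" last
    variances: np.ndarray
    ses: np.ndarray
    sigma_p2: float
    proportions: np.ndarray  # each component / sigma_p2
    prop_ses: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n: int
    message: str = ""
    cov_params: np.ndarray | None = field(default=None, repr=False)

    def proportion(self, name: str) -> float:
        return float(self.proportions[self.names.index(name)])

    def variance(self, name: str) -> float:
        return float(self.variances[self.names.index(name)])

    def to_hsq_text(self, lrt_result: "LrtResult | None" = None) -> str:
        """GCTA .hsq-style tab-separated summary."""
        rows = ["Source\tVariance\tSE"]
        for nm, v, s in zip(self.names, self.variances, self.ses):
            label = "V(e)" if nm == "e" else f"V({nm})"
            rows.append(f"{label}\t{v:.6f}\t{s:.6f}")
        rows.append(f"Vp\t{self.sigma_p2:.6f}\t")
        for nm, h, s in zip(self.names, self.proportions, self.prop_ses):
            if nm == "e":
                continue
            rows.append(f"V({nm})/Vp\t{h:.6f}\t{s:.6f}")
        rows.append(f"logL\t{self.loglik:.4f}\t")
        if lrt_result is not None:
            rows.append(f"LRT\t{lrt_result.statistic:.4f}\t")
            rows.append(f"Pval\t{lrt_result.p_value:.4g}\t")
        rows.append(f"n\t{self.n}\t")
        return "\n".join(rows) + "\n"


@dataclass
class LrtResult:
    statistic: float
    p_value: float
    df_note: str


@dataclass
class BivarResult:
    """Bivariate (two-environment) REML fit."""

    vg1: float
    vg2: float
    cov_g: float
    ve1: float
    ve2: float
    rg: float
    rg_se: float
    ses: np.ndarray  # SEs of (vg1, vg2, cov_g, ve1, ve2)
    loglik: float
    n_iter: int
    converged: bool
    n1: int
    n2: int
    message: str = ""
    _context: dict = field(default=None, repr=False)


def design_matrix(env_levels: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus treatment-coded indicators for an optional factor."""
    cols = [np.ones(n)]
    if env_levels is not None:
        env_levels = np.asarray(env_levels, dtype=object)
        uniq = list(dict.fromkeys(env_levels))
        for lev in uniq[1:]:
            cols.append((env_levels == lev).astype(float))
    return np.column_stack(cols)


def _sym_inv_logdet(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric positive definite matrix."""
    c, low = cho_factor(V, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv, info = dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, logdet


def reml_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """REML log-likelihood (up to an additive constant) at covariance V.

    Uses a single Cholesky factorization and triangular solves; no full
    inverse is formed.
    """
    try:
        c = cho_factor(V, lower=True, check_finite=False)
    except (np.linalg.LinAlgError, ValueError):
        return -np.inf
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    rhs = np.column_stack([X, y])
    sol = cho_solve(c, rhs, check_finite=False)
    W, Viy = sol[:, :-1], sol[:, -1]
    XtVX = X.T @ W
    sign, logdetX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    XtViy = X.T @ Viy
    ypy = float(y @ Viy) - float(XtViy @ np.linalg.solve(XtVX, XtViy))
    return -0.5 * (logdetV + logdetX + ypy)


def _airml(
    y: np.ndarray,
    X: np.ndarray,
    structures: list[np.ndarray],
    is_cov: list[bool],
    cov_pairs: dict[int, tuple[int, int]],
    theta0: np.ndarray,
    floor: float,
    max_iter: int = _MAX_ITER,
) -> dict:
    """Generic AI-REML over variance (and covariance) components.

    ``structures`` are the n x n covariance structures, one per
    parameter; ``is_cov[k]`` marks covariance parameters, which are not
    floored but projected into |c| <= sqrt(v_i * v_j) using
    ``cov_pairs[k] = (i, j)``.
    """
    n, p = X.shape
    K = len(structures)
    theta = theta0.copy()
    flags: list[str] = []
    ll_prev = -np.inf
    converged = False
    AI = np.eye(K)
    it = 0

    def project(th: np.ndarray) -> np.ndarray:
        th = th.copy()
        for k in range(K):
            if not is_cov[k]:
                th[k] = max(th[k], floor)
        for k, (i, j) in cov_pairs.items():
            bound = np.sqrt(th[i] * th[j])
            th[k] = np.clip(th[k], -bound, bound)
        return th

    last_change = np.inf
    for it in range(1, max_iter + 1):
        V = sum(t * S for t, S in zip(theta, structures))
        try:
            Vinv, logdetV = _sym_inv_logdet(V)
        except np.linalg.LinAlgError:
            # PSD-boundary covariance: retreat slightly and retry once
            for k in cov_pairs:
                theta[k] *= 1.0 - 1e-6
            V = sum(t * S for t, S in zip(theta, structures))
            Vinv, logdetV = _sym_inv_logdet(V + 1e-10 * np.eye(n))
        W = Vinv @ X
        XtVX = X.T @ W
        XtVX_inv = np.linalg.inv(XtVX)
        sign, logdetX = np.linalg.slogdet(XtVX)
        P = Vinv - W @ XtVX_inv @ W.T
        Py = P @ y
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))

        T = np.column_stack([S @ Py for S in structures])  # n x K
        q = T.T @ Py  # y' P S_k P y
        tr = np.array([float(np.vdot(P, S)) for S in structures])
        grad = -0.5 * (tr - q)
        U = P @ T
        AI = 0.5 * (T.T @ U)

        if it > 1:
            rel_ll = abs(ll - ll_prev) / max(1.0, abs(ll))
            if rel_ll < _TOL_LL and last_change < _TOL_PAR * theta.sum():
                converged = True
                break
        ll_prev = ll

        # candidate updates: active-set AI step with backtracking, then
        # EM; accept the first that does not decrease the likelihood.
        # Components pinned at the floor with an outward gradient are
        # held fixed so the Newton step is taken in the free directions.
        # A covariance pinned at its |c| <= sqrt(v_i v_j) bound with an
        # outward gradient is constrained onto the bound manifold and the
        # Newton step taken in the reduced parameterization.
        em_trial = project(theta + theta**2 * (q - tr) / n)
        candidates: list[np.ndarray] = []
        pinned: dict[int, tuple[int, int, float]] = {}
        for k, (i, j) in cov_pairs.items():
            bound = np.sqrt(theta[i] * theta[j])
            if (
                bound > 0
                and abs(abs(theta[k]) - bound) <= 1e-8 * bound
                and np.sign(theta[k]) * grad[k] > 0
            ):
                pinned[k] = (i, j, float(np.sign(theta[k])))
        if it > 1 and pinned:
            free_idx = [k for k in range(K) if k not in pinned]
            J = np.zeros((K, len(free_idx)))
            for col, k in enumerate(free_idx):
                J[k, col] = 1.0
            for k, (i, j, sgn) in pinned.items():
                J[k, free_idx.index(i)] = sgn * 0.5 * np.sqrt(theta[j] / theta[i])
                J[k, free_idx.index(j)] = sgn * 0.5 * np.sqrt(theta[i] / theta[j])
            g_red = J.T @ grad
            H_red = J.T @ AI @ J
            try:
                d_free = np.linalg.solve(H_red, g_red)
            except np.linalg.LinAlgError:
                d_free = np.linalg.lstsq(H_red, g_red, rcond=None)[0]
            for s in (1.0, 0.5, 0.25, 0.125):
                trial = theta.copy()
                trial[free_idx] = theta[free_idx] + s * d_free
                trial = project(trial)
                for k, (i, j, sgn) in pinned.items():
                    trial[k] = sgn * np.sqrt(trial[i] * trial[j])
                candidates.append(trial)
        elif it > 1:
            free = np.array(
                [
                    is_cov[k] or theta[k] > 1.5 * floor or grad[k] > 0
                    for k in range(K)
                ]
            )
            if not free.any():
                free[:] = True
            delta = np.zeros(K)
            sub = AI[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(sub, grad[free])
            except np.linalg.LinAlgError:
                delta[free] = np.linalg.lstsq(sub, grad[free], rcond=None)[0]
                flags.append("flat likelihood direction (singular AI matrix)")
            for s in (1.0, 0.5, 0.25, 0.125, 0.0625):
                candidates.append(project(theta + s * delta))
        candidates.append(em_trial)

        slack = 1e-10 * max(1.0, abs(ll))
        new = em_trial
        for trial in candidates:
            V_t = sum(t * S for t, S in zip(trial, structures))
            if reml_loglik(y, X, V_t) >= ll - slack:
                new = trial
                break
        last_change = float(np.max(np.abs(new - theta)))
        theta = new

    if not converged:
        flags.append(f"not converged after {it} iterations")
    cond = np.linalg.cond(AI)
    if cond > 1e10:
        flags.append("flat likelihood direction (ill-conditioned AI matrix)")
        cov_theta = np.linalg.pinv(AI)
    else:
        cov_theta = np.linalg.inv(AI)
    return {
        "theta": theta,
        "cov_theta": cov_theta,
        "loglik": ll,
        "n_iter": it,
        "converged": converged,
        "message": "; ".join(dict.fromkeys(flags)),
    }


def reml_fit(spec: ModelSpec, max_iter: int = _MAX_ITER) -> VarCompResult:
    """Fit the variance components of ``spec`` by AI-REML.

    A residual identity component is appended automatically.  Components
    are floored at 1e-6 of the observed phenotypic variance; standard
    errors come from the inverse average-information matrix and
    proportion SEs from the delta method.
    """
    y, X = spec.y, spec.X
    n = len(y)
    K = len(spec.random_structures) + 1
    if n < X.shape[1] + K + 1:
        raise ValueError("too few samples for the requested model")
    names = [nm for nm, _ in spec.random_structures] + ["e"]
    structures = [np.asarray(M, dtype=float) for _, M in spec.random_structures]
    structures.append(np.eye(n))
    sp2 = float(np.var(y, ddof=1))
    theta0 = np.full(K, sp2 / (K + 1))
    floor = _FLOOR_FRAC * sp2

    out = _airml(y, X, structures, [False] * K, {}, theta0, floor, max_iter)
    theta, cov_theta = out["theta"], out["cov_theta"]
    sigma_p2 = float(theta.sum())
    props = theta / sigma_p2
    # delta method for h_k = theta_k / sum(theta)
    J = (np.eye(K) * sigma_p2 - theta[:, None]) / sigma_p2**2
    cov_h = J @ cov_theta @ J.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ses = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))
        prop_ses = np.sqrt(np.maximum(np.diag(cov_h), 0.0))
    return VarCompResult(
        names=names,
        variances=theta,
        ses=ses,
        sigma_p2=sigma_p2,
        proportions=props,
        prop_ses=prop_ses,
        loglik=out["loglik"],
        n_iter=out["n_iter"],
        converged=out["converged"],
        n=n,
        message=out["message"],
        cov_params=cov_theta,
    )


def boundary_lrt_pvalue(statistic: float) -> float:
    """P-value under the 50:50 mixture of point mass at 0 and chi2(1).

    A statistic of exactly zero sits at the boundary and receives
    p = 0.5; otherwise p = 0.5 * P(chi2_1 >= statistic).
    """
    if statistic < 0:
        raise ValueError("LRT statistic must be nonnegative")
    if statistic == 0:
        return 0.5
    return float(0.5 * chi2.sf(statistic, df=1))


def lrt(full: VarCompResult, reduced: VarCompResult) -> LrtResult:
    """Boundary likelihood-ratio test of the component dropped in ``reduced``.

    The statistic is twice the log-likelihood difference, clamped to zero
    (with a warning) if the optimizer left it marginally negative.
    """
    if set(reduced.names) - set(full.names) or len(full.names) != len(reduced.names) + 1:
        raise ValueError("reduced model is not nested in the full model (one fewer component)")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < 0:
        warnings.warn(
            f"negative LRT statistic {stat:.3g} clamped to 0 "
            "(full fit did not dominate the reduced fit)",
            stacklevel=2,
        )
        stat = 0.0
    return LrtResult(
        statistic=stat,
        p_value=boundary_lrt_pvalue(stat),
        df_note="50:50 mixture of point mass at 0 and chi-square(1) (boundary null)",
    )


def _bivar_structures(
    A: np.ndarray, mask1: np.ndarray, mask2: np.ndarray
) -> list[np.ndarray]:
    n = A.shape[0]
    m1 = mask1.astype(float)
    m2 = mask2.astype(float)
    C_g1 = A * np.outer(m1, m1)
    C_g2 = A * np.outer(m2, m2)
    C_g12 = A * (np.outer(m1, m2) + np.outer(m2, m1))
    C_e1 = np.diag(m1)
    C_e2 = np.diag(m2)
    return [C_g1, C_g2, C_g12, C_e1, C_e2]


def bivar_reml(
    y1: pd.Series,
    y2: pd.Series,
    A: GRMatrix,
    max_iter: int = _MAX_ITER,
) -> BivarResult:
    """Bivariate REML for one trait measured in two disjoint sample sets.

    ``y1`` and ``y2`` are phenotype Series indexed by sample id, one per
    environment; ``A`` must cover their union.  Fits per-environment
    genetic variances, the cross-environment genetic covariance (through
    the between-set blocks of A), and per-environment residual variances;
    residual covariance is structurally absent since no individual is
    observed twice.
    """
    ids1, ids2 = list(y1.index), list(y2.index)
    if set(ids1) & set(ids2):
        raise ValueError("the two sample sets must be disjoint")
    if len(ids1) < 30 or len(ids2) < 30:
        raise ValueError("each environment needs at least 30 samples")
    missing = (set(ids1) | set(ids2)) - set(A.sample_ids)
    if missing:
        raise ValueError(f"GRM does not cover {len(missing)} sample(s)")

    order = ids1 + ids2
    sub = A.subset(order)
    n1, n2 = len(ids1), len(ids2)
    n = n1 + n2
    mask1 = np.zeros(n, dtype=bool)
    mask1[:n1] = True
    mask2 = ~mask1
    y = np.concatenate([y1.to_numpy(float), y2.to_numpy(float)])
    X = np.column_stack([mask1.astype(float), mask2.astype(float)])  # per-trait mean

    structures = _bivar_structures(sub.values, mask1, mask2)
    is_cov = [False, False, True, False, False]
    cov_pairs = {2: (0, 1)}
    v1 = float(np.var(y[:n1], ddof=1))
    v2 = float(np.var(y[n1:], ddof=1))
    theta0 = np.array([v1 / 3, v2 / 3, 0.0, 2 * v1 / 3, 2 * v2 / 3])
    floor = _FLOOR_FRAC * max(v1, v2)

    out = _airml(y, X, structures, is_cov, cov_pairs, theta0, floor, max_iter)
    vg1, vg2, cg, ve1, ve2 = out["theta"]
    rg = float(cg / np.sqrt(vg1 * vg2))
    rg = float(np.clip(rg, -1.0, 1.0))
    C = out["cov_theta"]
    # delta method for rg = c / sqrt(vg1 * vg2)
    grad = np.array(
        [-cg / (2 * vg1**1.5 * np.sqrt(vg2)), -cg / (2 * vg2**1.5 * np.sqrt(vg1)),
         1.0 / np.sqrt(vg1 * vg2), 0.0, 0.0]
    )
    rg_var = float(grad @ C @ grad)
    ses = np.sqrt(np.maximum(np.diag(C), 0.0))
    return BivarResult(
        vg1=float(vg1),
        vg2=float(vg2),
        cov_g=float(cg),
        ve1=float(ve1),
        ve2=float(ve2),
        rg=rg,
        rg_se=float(np.sqrt(max(rg_var, 0.0))),
        ses=ses,
        loglik=out["loglik"],
        n_iter=out["n_iter"],
        converged=out["converged"],
        n1=n1,
        n2=n2,
        message=out["message"],
        _context={
            "y": y,
            "X": X,
            "structures": structures,
            "floor": floor,
            "theta": out["theta"],
        },
    )


def _constrained_rg_loglik(result: BivarResult, r0: float) -> float:
    """Profile REML log-likelihood with r_g fixed at r0 (0 or +/-1)."""
    from scipy.optimize import minimize

    ctx = result._context
    y, X, S = ctx["y"], ctx["X"], ctx["structures"]
    C_g1, C_g2, C_g12, C_e1, C_e2 = S

    if r0 == 0.0:
        # drop the covariance structure and rerun AI-REML on 4 components
        out = _airml(
            y, X, [C_g1, C_g2, C_e1, C_e2], [False] * 4, {},
            np.array([ctx["theta"][0], ctx["theta"][1], ctx["theta"][3], ctx["theta"][4]]),
            ctx["floor"],
        )
        return out["loglik"]

    def negll(logpar: np.ndarray) -> float:
        vg1, vg2, ve1, ve2 = np.exp(logpar)
        cg = r0 * np.sqrt(vg1 * vg2)
        # V stays positive definite through the residual diagonal even at |r0| = 1
        V = vg1 * C_g1 + vg2 * C_g2 + cg * C_g12 + ve1 * C_e1 + ve2 * C_e2
        return -reml_loglik(y, X, V)

    th = np.maximum(ctx["theta"], ctx["floor"])
    x0 = np.log(np.array([th[0], th[1], th[3], th[4]]))
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 800})
    return -float(res.fun)


def test_rg(result: BivarResult, null_value: float) -> LrtResult:
    """Likelihood-ratio test of H0: r_g = ``null_value`` (0 or 1).

    Refits the bivariate model with the genetic covariance constrained to
    the null and compares 2*dlogL with chi-square(1).  For r_g = 1 the
    null sits on the boundary of the correlation space; the reference is
    noted as conservative in that case.
    """
    if null_value not in (0.0, 1.0, -1.0):
        raise ValueError("null_value must be 0 or +/-1")
    if result._context is None:
        raise ValueError("BivarResult lacks its fitting context")
    ll0 = _constrained_rg_loglik(result, float(null_value))
    stat = 2.0 * (result.loglik - ll0)
    if stat < 0:
        stat = 0.0
    note = "chi-square(1)"
    if abs(null_value) == 1.0:
        note += " (null on the correlation boundary; reference is conservative)"
    return LrtResult(statistic=stat, p_value=float(chi2.sf(stat, df=1)) if stat > 0 else 1.0,
                     df_note=note)
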