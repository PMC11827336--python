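"""Dense mixed-model machinery: REML variance components, BLUP and PEV.

The model is ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, sigma_k^2
K_k)`` for an arbitrary covariance kernel ``K_k`` (identity, a genomic
relationship matrix, or a kernel-by-environment block structure) and a
residual that is iid, heterogeneous by group, or spatially correlated as
AR1(col) x AR1(row) over field coordinates.

Variance components are estimated by average-information (AI) REML with
an expectation-maximisation fallback: whenever an AI step leaves the
parameter space or fails to improve the restricted likelihood, a step-
halved EM update (which is an ascent direction) is taken instead, so the
restricted log-likelihood is non-decreasing along fallback steps.  AR1
autocorrelation parameters are profiled by bounded derivative-free
optimisation of the restricted likelihood with inner variance-component
updates.

Everything is dense; the implementation targets desk-scale problems
(thousands of observations), not national evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, lapack
from scipy.optimize import minimize

__all__ = [
    "ar1_correlation",
    "RandomTerm",
    "term_from_labels",
    "Residual",
    "ModelSpec",
    "REMLOptions",
    "FitResult",
    "fit_reml",
    "solve_mixed",
    "restricted_loglik",
    "pev_to_accuracy",
    "pev_to_reliability",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """First-order autoregressive correlation matrix, entry (i, j) = rho^|i-j|."""
    if n < 1:
        raise ValueError("dimension must be >= 1")
    if not abs(rho) < 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(n)
    return np.asarray(rho, dtype=float) ** np.abs(idx[:, None] - idx[None, :])


# ----------------------------------------------------------------------
# model specification
# ----------------------------------------------------------------------
@dataclass
class RandomTerm:
    """One random effect: integer level codes per observation plus a kernel.

    ``K=None`` means an identity kernel.  When ``env`` codes are given the
    effective kernel is K-by-environment block diagonal (independent
    realisations of the kernel per environment), the structure used for
    genotype-by-environment interactions.
    """

    name: str
    levels: np.ndarray
    n_levels: int
    K: Optional[np.ndarray] = None
    level_ids: Optional[List] = None
    env: Optional[np.ndarray] = None
    n_env: int = 1
    env_ids: Optional[List] = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        if self.levels.min(initial=0) < 0 or (
            self.levels.size and self.levels.max() >= self.n_levels
        ):
            raise ValueError(f"term {self.name!r}: level codes out of range")
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.n_levels, self.n_levels):
                raise ValueError(f"term {self.name!r}: kernel shape mismatch")
        if self.env is not None:
            self.env = np.asarray(self.env, dtype=int)
            if self.env.shape != self.levels.shape:
                raise ValueError(f"term {self.name!r}: env codes shape mismatch")

    @property
    def q(self) -> int:
        return self.n_levels * (self.n_env if self.env is not None else 1)


def term_from_labels(
    name: str,
    labels: Sequence,
    K: Optional[np.ndarray] = None,
    kernel_ids: Optional[Sequence] = None,
    env_labels: Optional[Sequence] = None,
) -> RandomTerm:
    """Convenience constructor mapping observation labels to level codes."""
    if K is not None and kernel_ids is not None:
        index = {lab: i for i, lab in enumerate(kernel_ids)}
        try:
            levels = np.array([index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(
                f"term {name!r}: label {exc.args[0]!r} missing from kernel ids"
            ) from None
        n_levels = len(kernel_ids)
        level_ids = list(kernel_ids)
    else:
        codes, uniques = pd.factorize(np.asarray(labels, dtype=object), sort=True)
        levels, n_levels, level_ids = codes, len(uniques), list(uniques)
    env = env_ids = None
    n_env = 1
    if env_labels is not None:
        ecodes, euniq = pd.factorize(np.asarray(env_labels, dtype=object), sort=True)
        env, n_env, env_ids = ecodes, len(euniq), list(euniq)
    return RandomTerm(
        name=name,
        levels=levels,
        n_levels=n_levels,
        K=K,
        level_ids=level_ids,
        env=env,
        n_env=n_env,
        env_ids=env_ids,
    )


@dataclass
class Residual:
    """Residual covariance structure."""

    kind: str = "iid"  # iid | ar1_by_ar1 | heterogeneous_by_group
    groups: Optional[Sequence] = None
    rows: Optional[np.ndarray] = None
    cols: Optional[np.ndarray] = None
    rho_col: float = 0.0
    rho_row: float = 0.0
    estimate_rho: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("iid", "ar1_by_ar1", "heterogeneous_by_group"):
            raise ValueError(f"unknown residual kind {self.kind!r}")
        if self.kind == "ar1_by_ar1":
            if self.rows is None or self.cols is None:
                raise ValueError("ar1_by_ar1 residual needs row and col coordinates")
            self.rows = np.asarray(self.rows, dtype=int)
            self.cols = np.asarray(self.cols, dtype=int)
        if self.kind == "heterogeneous_by_group" and self.groups is None:
            raise ValueError("heterogeneous residual needs group labels")


@dataclass
class ModelSpec:
    y: np.ndarray
    X: np.ndarray
    random_terms: List[RandomTerm]
    residual: Residual = field(default_factory=Residual)
    fixed_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        for t in self.random_terms:
            if t.levels.shape[0] != n:
                raise ValueError(f"term {t.name!r} does not cover all observations")


@dataclass
class REMLOptions:
    init: Optional[Union[Dict[str, float], np.ndarray]] = None
    tol_loglik: float = 1e-8
    tol_param: float = 1e-6
    max_iter: int = 200
    algorithm: str = "ai"  # "ai" (with EM fallback) or "em"
    compute_pev: bool = True
    rho_xatol: float = 5e-3
    rho_bound: float = 0.99
    profile_max_iter: int = 60


@dataclass
class FitResult:
    variance_components: Dict[str, float]
    standard_errors: Dict[str, float]
    fixed_effects: np.ndarray
    fixed_names: Optional[List[str]]
    fixed_cov: np.ndarray
    random_effects: Dict[str, np.ndarray]
    random_effect_levels: Dict[str, List]
    pev: Dict[str, np.ndarray]
    loglik: float
    converged: bool
    n_iterations: int
    trace: List[float]
    rho: Optional[Tuple[float, float]] = None

    def component(self, name: str) -> float:
        return self.variance_components[name]

    def to_json_dict(self) -> Dict:
        """JSON-ready summary: components, s.e., likelihood, convergence trace."""
        return {
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "trace": [float(v) for v in self.trace],
            "rho": None if self.rho is None else [float(r) for r in self.rho],
        }

    def blups_frame(self) -> "pd.DataFrame":
        """Long-format BLUPs keyed by term and level identifier."""
        rows = []
        for name, u in self.random_effects.items():
            ids = self.random_effect_levels.get(name)
            u = np.atleast_2d(np.asarray(u))
            for e in range(u.shape[0]):
                for i, v in enumerate(u[e]):
                    level = ids[i] if ids is not None else i
                    rows.append((name, e if u.shape[0] > 1 else 0, level, float(v)))
        return pd.DataFrame(rows, columns=["term", "env", "level", "blup"])


# ----------------------------------------------------------------------
# covariance structure assembly
# ----------------------------------------------------------------------
def _term_Q(term: RandomTerm) -> np.ndarray:
    lev = term.levels
    if term.K is not None:
        Q = term.K[np.ix_(lev, lev)]
    else:
        Q = (lev[:, None] == lev[None, :]).astype(float)
    if term.env is not None:
        Q = Q * (term.env[:, None] == term.env[None, :])
    return Q


def _spatial_Q(rows: np.ndarray, cols: np.ndarray, rho_row: float, rho_col: float) -> np.ndarray:
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    return (float(rho_row) ** dr) * (float(rho_col) ** dc)


def _structure(
    spec: ModelSpec, rho_col: float, rho_row: float
) -> Tuple[List[str], List[np.ndarray], np.ndarray]:
    """Component names, obs-level covariance matrices Q_k, and level counts."""
    n = spec.y.size
    names: List[str] = []
    Qs: List[np.ndarray] = []
    qs: List[float] = []
    for t in spec.random_terms:
        names.append(t.name)
        Qs.append(_term_Q(t))
        qs.append(t.q)
    r = spec.residual
    if r.kind == "iid":
        names.append("residual")
        Qs.append(np.eye(n))
        qs.append(n)
    elif r.kind == "heterogeneous_by_group":
        codes, uniques = pd.factorize(np.asarray(r.groups, dtype=object), sort=True)
        for gi, g in enumerate(uniques):
            mask = (codes == gi).astype(float)
            names.append(f"residual_{g}")
            Qs.append(np.diag(mask))
            qs.append(float(mask.sum()))
    else:  # ar1_by_ar1
        names.append("residual_spatial")
        Qs.append(_spatial_Q(r.rows, r.cols, rho_row, rho_col))
        qs.append(n)
    if len(set(names)) != len(names):
        raise ValueError("duplicate component names in model specification")
    return names, Qs, np.asarray(qs, dtype=float)


def _check_fixed_rank(X: np.ndarray, fixed_names: Optional[List[str]]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        detail = ""
        if fixed_names:
            detail = f" (columns: {fixed_names})"
        raise ValueError(
            f"fixed design is rank deficient: rank {rank} < {X.shape[1]} columns; "
            f"remove confounded fixed effects{detail}"
        )


# ----------------------------------------------------------------------
# dense REML internals
# ----------------------------------------------------------------------
def _chol_lower(V: np.ndarray) -> Tuple[np.ndarray, float]:
    c, info = lapack.dpotrf(V, lower=1, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError("covariance matrix is not positive definite")
    return c, 2.0 * float(np.sum(np.log(np.diag(c))))


def _loglik_given_V(V: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    n, p = X.shape
    c, logdetV = _chol_lower(V)
    rhs = np.column_stack([X, y])
    sol = cho_solve((c, True), rhs)
    ViX, Viy = sol[:, :p], sol[:, p]
    XtViX = X.T @ ViX
    cx, lowx = cho_factor(XtViX, lower=True)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx))))
    XtViy = X.T @ Viy
    yPy = float(y @ Viy - XtViy @ cho_solve((cx, lowx), XtViy))
    return -0.5 * (logdetV + logdetX + yPy + (n - p) * _LOG2PI)


@dataclass
class _Decomposition:
    P: np.ndarray
    Py: np.ndarray
    beta: np.ndarray
    beta_cov: np.ndarray
    loglik: float


def _decompose(V: np.ndarray, X: np.ndarray, y: np.ndarray) -> _Decomposition:
    n, p = X.shape
    c, logdetV = _chol_lower(V)
    Vinv, info = lapack.dpotri(c, lower=1)
    if info != 0:  # pragma: no cover - LAPACK failure
        raise np.linalg.LinAlgError("inversion failed")
    Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    try:
        cx, lowx = cho_factor(XtViX, lower=True)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular fixed-effect coefficient matrix: a fixed effect is confounded"
        ) from None
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx))))
    XtViX_inv = cho_solve((cx, lowx), np.eye(p))
    B = XtViX_inv @ ViX.T
    P = Vinv - ViX @ B
    Py = P @ y
    beta = B @ y
    loglik = -0.5 * (logdetV + logdetX + float(y @ Py) + (n - p) * _LOG2PI)
    return _Decomposition(P=P, Py=Py, beta=beta, beta_cov=XtViX_inv, loglik=loglik)


def _build_V(Qs: List[np.ndarray], sigma: np.ndarray) -> np.ndarray:
    V = sigma[0] * Qs[0]
    for s, Q in zip(sigma[1:], Qs[1:]):
        V = V + s * Q
    return V


def _ai_reml(
    Qs: List[np.ndarray],
    qs: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray,
    opts: REMLOptions,
) -> Tuple[np.ndarray, _Decomposition, np.ndarray, List[float], bool, int]:
    m = len(Qs)
    floor = 1e-8 * max(float(np.var(y)), np.finfo(float).tiny)
    sigma = np.maximum(np.asarray(start, dtype=float), floor)
    dec = _decompose(_build_V(Qs, sigma), X, y)
    ll = dec.loglik
    trace = [ll]
    converged = False
    AI = np.eye(m)
    it = 0
    for it in range(1, opts.max_iter + 1):
        P, Py = dec.P, dec.Py
        W = np.column_stack([Q @ Py for Q in Qs])  # n x m
        quad = W.T @ Py
        tr = np.array([float(np.sum(P * Q)) for Q in Qs])
        score = 0.5 * (quad - tr)
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        AI = 0.5 * (AI + AI.T)

        new_sigma = None
        if opts.algorithm == "ai":
            # active-set AI: components pinned at the floor whose gradient
            # points outward are fixed there; the reduced AI system is
            # solved for the rest, with step halving and boundary clamping
            fixed = (sigma <= floor * (1.0 + 1e-6)) & (score < 0)
            free = np.where(~fixed)[0]
            delta = None
            if free.size:
                Af = AI[np.ix_(free, free)] + 1e-12 * np.eye(free.size)
                try:
                    df = np.linalg.solve(Af, score[free])
                    if np.all(np.isfinite(df)):
                        delta = np.zeros(m)
                        delta[free] = df
                except np.linalg.LinAlgError:
                    delta = None
            if delta is not None:
                lam = 1.0
                for _ in range(12):
                    prop = np.maximum(sigma + lam * delta, floor)
                    try:
                        ll_prop = _loglik_given_V(_build_V(Qs, prop), X, y)
                    except np.linalg.LinAlgError:
                        lam *= 0.5
                        continue
                    if ll_prop >= ll - 1e-10:
                        new_sigma, ll_new = prop, ll_prop
                        break
                    lam *= 0.5
        if new_sigma is None:
            # EM fallback: scaled-gradient ascent step with halving
            step = (sigma**2 / qs) * (quad - tr)
            lam, ll_prop, prop = 1.0, -np.inf, sigma
            for _ in range(50):
                prop = np.maximum(sigma + lam * step, floor)
                ll_prop = _loglik_given_V(_build_V(Qs, prop), X, y)
                if ll_prop >= ll - 1e-9:
                    break
                lam *= 0.5
            if ll_prop < ll - 1e-6:
                # cannot ascend further: treat the current point as the optimum
                converged = True
                break
            new_sigma, ll_new = prop, ll_prop

        rel_par = float(np.max(np.abs(new_sigma - sigma) / np.maximum(sigma, floor)))
        done = abs(ll_new - ll) < opts.tol_loglik * (1.0 + abs(ll_new)) and (
            rel_par < opts.tol_param
        )
        sigma, ll = new_sigma, ll_new
        trace.append(ll)
        dec = _decompose(_build_V(Qs, sigma), X, y)
        if done:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"REML did not converge in {opts.max_iter} iterations; returning last iterate",
            RuntimeWarning,
        )
    return sigma, dec, AI, trace, converged, it


# ----------------------------------------------------------------------
# BLUP and prediction error variance
# ----------------------------------------------------------------------
def _aggregate_rows(P: np.ndarray, lev: np.ndarray, q: int) -> np.ndarray:
    R = np.zeros((q, P.shape[1]))
    np.add.at(R, lev, P)
    return R


def _ZtPZ(P: np.ndarray, lev: np.ndarray, q: int) -> np.ndarray:
    R = _aggregate_rows(P, lev, q)  # q x n
    W = np.zeros((q, q))
    np.add.at(W, lev, R.T)  # aggregates columns; result is W' of what we want
    return W.T


def _term_blup_pev(
    term: RandomTerm, sigma_k: float, P: np.ndarray, Py: np.ndarray, compute_pev: bool
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """BLUP vector(s) and PEV diagonal for one random term.

    For environment-structured terms the outputs have shape
    ``(n_env, n_levels)``.
    """
    q = term.n_levels
    if term.env is None:
        s = np.bincount(term.levels, weights=Py, minlength=q)
        u = sigma_k * (term.K @ s if term.K is not None else s)
        pev = None
        if compute_pev:
            W = _ZtPZ(P, term.levels, q)
            if term.K is not None:
                kdiag = np.diag(term.K)
                pev = sigma_k * kdiag - sigma_k**2 * np.einsum(
                    "ij,jk,ki->i", term.K, W, term.K
                )
                cap = sigma_k * kdiag
            else:
                pev = sigma_k - sigma_k**2 * np.diag(W)
                cap = np.full(q, sigma_k)
            pev = np.clip(pev, 0.0, cap)
        return u, pev
    us = np.zeros((term.n_env, q))
    pevs = np.zeros((term.n_env, q)) if compute_pev else None
    for e in range(term.n_env):
        mask = term.env == e
        s = np.bincount(term.levels[mask], weights=Py[mask], minlength=q)
        us[e] = sigma_k * (term.K @ s if term.K is not None else s)
        if compute_pev:
            Pe = P[np.ix_(mask, mask)]
            W = _ZtPZ(Pe, term.levels[mask], q)
            if term.K is not None:
                kdiag = np.diag(term.K)
                pevs[e] = np.clip(
                    sigma_k * kdiag
                    - sigma_k**2 * np.einsum("ij,jk,ki->i", term.K, W, term.K),
                    0.0,
                    sigma_k * kdiag,
                )
            else:
                pevs[e] = np.clip(sigma_k - sigma_k**2 * np.diag(W), 0.0, sigma_k)
    return us, pevs


def _assemble_result(
    spec: ModelSpec,
    names: List[str],
    sigma: np.ndarray,
    dec: _Decomposition,
    AI: np.ndarray,
    trace: List[float],
    converged: bool,
    n_iter: int,
    opts: REMLOptions,
    rho: Optional[Tuple[float, float]] = None,
) -> FitResult:
    comp = dict(zip(names, (float(s) for s in sigma)))
    try:
        cov = np.linalg.pinv(AI)
        se = {n: float(np.sqrt(max(v, 0.0))) for n, v in zip(names, np.diag(cov))}
    except np.linalg.LinAlgError:  # pragma: no cover
        se = {n: float("nan") for n in names}
    blups: Dict[str, np.ndarray] = {}
    levels: Dict[str, List] = {}
    pevs: Dict[str, np.ndarray] = {}
    for term in spec.random_terms:
        u, pev = _term_blup_pev(
            term, comp[term.name], dec.P, dec.Py, opts.compute_pev
        )
        blups[term.name] = u
        if term.level_ids is not None:
            levels[term.name] = term.level_ids
        if pev is not None:
            pevs[term.name] = pev
    return FitResult(
        variance_components=comp,
        standard_errors=se,
        fixed_effects=dec.beta,
        fixed_names=spec.fixed_names,
        fixed_cov=dec.beta_cov,
        random_effects=blups,
        random_effect_levels=levels,
        pev=pevs,
        loglik=float(dec.loglik),
        converged=converged,
        n_iterations=n_iter,
        trace=trace,
        rho=rho,
    )


# ----------------------------------------------------------------------
# public entry points
# ----------------------------------------------------------------------
def _starting_values(
    spec: ModelSpec, names: List[str], opts: REMLOptions
) -> np.ndarray:
    vy = float(np.var(spec.y, ddof=1)) if spec.y.size > 1 else 1.0
    vy = max(vy, np.finfo(float).tiny)
    if opts.init is None:
        return np.full(len(names), vy / len(names))
    if isinstance(opts.init, dict):
        return np.array([opts.init.get(n, vy / len(names)) for n in names], dtype=float)
    init = np.asarray(opts.init, dtype=float)
    if init.shape != (len(names),):
        raise ValueError("init vector length does not match component count")
    return init


def _fit_at_rho(
    spec: ModelSpec,
    rho_col: float,
    rho_row: float,
    opts: REMLOptions,
    start: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, _Decomposition, np.ndarray, List[float], bool, int, List[str]]:
    names, Qs, qs = _structure(spec, rho_col, rho_row)
    s0 = start if start is not None else _starting_values(spec, names, opts)
    sigma, dec, AI, trace, converged, it = _ai_reml(Qs, qs, spec.X, spec.y, s0, opts)
    return sigma, dec, AI, trace, converged, it, names


def fit_reml(spec: ModelSpec, options: Optional[REMLOptions] = None) -> FitResult:
    """Estimate variance components by AI-REML (EM fallback) and solve for BLUP.

    AR1 autocorrelations, when present and not fixed, are profiled by
    Nelder-Mead over (rho_col, rho_row) with inner component updates.
    """
    opts = options or REMLOptions()
    _check_fixed_rank(spec.X, spec.fixed_names)
    r = spec.residual
    if r.kind == "ar1_by_ar1" and r.estimate_rho:
        bound = opts.rho_bound
        inner_opts = REMLOptions(
            init=opts.init,
            tol_loglik=max(opts.tol_loglik, 1e-7),
            tol_param=max(opts.tol_param, 1e-5),
            max_iter=opts.profile_max_iter,
            algorithm=opts.algorithm,
            compute_pev=False,
        )
        warm: Dict[str, Optional[np.ndarray]] = {"sigma": None}

        def negll(x: np.ndarray) -> float:
            rc = float(np.clip(x[0], -bound, bound))
            rr = float(np.clip(x[1], -bound, bound))
            penalty = 1e4 * (abs(x[0] - rc) + abs(x[1] - rr))
            sigma, dec, *_ = _fit_at_rho(spec, rc, rr, inner_opts, start=warm["sigma"])
            warm["sigma"] = sigma
            return -dec.loglik + penalty

        res = minimize(
            negll,
            x0=np.array([r.rho_col, r.rho_row], dtype=float),
            method="Nelder-Mead",
            options={"xatol": opts.rho_xatol, "fatol": 1e-7, "maxfev": 200},
        )
        rho_col = float(np.clip(res.x[0], -bound, bound))
        rho_row = float(np.clip(res.x[1], -bound, bound))
        sigma, dec, AI, trace, converged, it, names = _fit_at_rho(
            spec, rho_col, rho_row, opts, start=warm["sigma"]
        )
        return _assemble_result(
            spec, names, sigma, dec, AI, trace, converged, it, opts, (rho_col, rho_row)
        )
    rho = (r.rho_col, r.rho_row) if r.kind == "ar1_by_ar1" else None
    sigma, dec, AI, trace, converged, it, names = _fit_at_rho(
        spec, r.rho_col, r.rho_row, opts
    )
    return _assemble_result(spec, names, sigma, dec, AI, trace, converged, it, opts, rho)


def solve_mixed(
    spec: ModelSpec,
    components: Union[Dict[str, float], np.ndarray],
    options: Optional[REMLOptions] = None,
) -> FitResult:
    """BLUE/BLUP/PEV at fixed, user-supplied variance components."""
    opts = options or REMLOptions()
    _check_fixed_rank(spec.X, spec.fixed_names)
    r = spec.residual
    names, Qs, _ = _structure(spec, r.rho_col, r.rho_row)
    if isinstance(components, dict):
        missing = [n for n in names if n not in components]
        if missing:
            raise KeyError(f"missing variance components: {missing}")
        sigma = np.array([float(components[n]) for n in names])
    else:
        sigma = np.asarray(components, dtype=float)
        if sigma.shape != (len(names),):
            raise ValueError("component vector length mismatch")
    if np.any(sigma < 0):
        raise ValueError("variance components must be non-negative")
    sigma = np.maximum(sigma, 1e-12 * max(float(np.var(spec.y)), 1.0))
    dec = _decompose(_build_V(Qs, sigma), spec.X, spec.y)
    AI = np.eye(len(names))
    rho = (r.rho_col, r.rho_row) if r.kind == "ar1_by_ar1" else None
    return _assemble_result(
        spec, names, sigma, dec, AI, [dec.loglik], True, 0, opts, rho
    )


def restricted_loglik(
    spec: ModelSpec, components: Union[Dict[str, float], np.ndarray]
) -> float:
    """Restricted log-likelihood at fixed components (includes constants)."""
    r = spec.residual
    names, Qs, _ = _structure(spec, r.rho_col, r.rho_row)
    if isinstance(components, dict):
        sigma = np.array([float(components[n]) for n in names])
    else:
        sigma = np.asarray(components, dtype=float)
    return _loglik_given_V(_build_V(Qs, sigma), spec.X, spec.y)


# ----------------------------------------------------------------------
# accuracy / reliability
# ----------------------------------------------------------------------
def pev_to_accuracy(pev, sigma2: float) -> float:
    """Accuracy r = sqrt(1 - PEV/sigma^2) from the mean PEV diagonal."""
    if sigma2 <= 0:
        raise ValueError("term variance must be positive")
    mean_pev = float(np.mean(pev))
    if mean_pev < 0 or mean_pev > sigma2:
        warnings.warn("PEV outside [0, sigma^2]; clamping", RuntimeWarning)
        mean_pev = float(np.clip(mean_pev, 0.0, sigma2))
    return float(np.sqrt(1.0 - mean_pev / sigma2))


def pev_to_reliability(pev, sigma2: float) -> np.ndarray:
    """Per-level reliability 1 - PEV_i/sigma^2 (no square root)."""
    if sigma2 <= 0:
        raise ValueError("term variance must be positive")
    rel = 1.0 - np.asarray(pev, dtype=float) / sigma2
    return np.clip(rel, 0.0, 1.0)
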