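"""REML variance components and BLUP solving for GBLUP / PED-BLUP models.

The univariate model is y = X b + Z g + e with g ~ N(0, K sigma2_a) for a
pedigree (A) or genomic (G) relationship matrix K over all animals of
interest, and heterogeneous residuals e ~ N(0, diag(sigma2_e / w_i)).
Animals without records stay in K and are predicted purely through their
relationships (Henderson's mixed-model equations).

Variance components are estimated by REML: either classic EM-REML on the
mixed-model equations (monotone in the restricted likelihood, always
converging, slow near the boundary) or average-information (AI) updates on
the marginal covariance V = sum_k theta_k V_k with step halving against the
restricted likelihood (the default; quadratic convergence near the optimum).

The bivariate purebred/crossbred model treats the trait measured on
purebreds and on crossbreds as two traits with additive covariance
G0 (x) A (Kronecker).  Each animal carries at most one of the two records,
so the residual covariance between the traits is not estimable and is fixed
at zero; G0 is kept positive semidefinite by bending during the updates.
The purebred-crossbred genetic correlation is r_g = G0_12 /
sqrt(G0_11 * G0_22).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .genio import DataError
from .kinship import RelationshipMatrix, stabilize


# ---------------------------------------------------------------------------
# design helpers


def design_matrix(lines, levels=None):
    """Intercept + reference-coded line indicators (first level absorbed).

    Accuracy and slope downstream are invariant to the reference choice.
    Returns (X, levels) with X of shape (n, 1 + len(levels) - 1).
    """
    lines = np.asarray(lines, dtype=object)
    if levels is None:
        levels = list(dict.fromkeys(lines))
    X = np.ones((len(lines), 1))
    for lev in levels[1:]:
        X = np.column_stack([X, (lines == lev).astype(float)])
    return X, list(levels)


# ---------------------------------------------------------------------------
# BLUP


@dataclass
class BlupSolution:
    animal_ids: np.ndarray        # every animal in K, record carrier or not
    beta: np.ndarray              # fixed effects, beta[0] = intercept mu
    fixed_names: list
    g_hat: np.ndarray             # additive genetic values for all animals
    pev: np.ndarray               # prediction-error variance per animal
    reliability: np.ndarray       # 1 - PEV / (K_ii * sigma2_a)
    sigma2_a: float
    sigma2_e: float
    meta: dict = field(default_factory=dict)

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        return np.array([lookup[a] for a in ids], dtype=int)

    def genetic_value(self, ids) -> np.ndarray:
        return self.g_hat[self.index_of(ids)]

    def total_value(self, ids, X_pred=None) -> np.ndarray:
        """Fixed part + additive value (the GEBV/EBV used for validation)."""
        g = self.genetic_value(ids)
        if X_pred is None:
            return self.mu + g
        X_pred = np.asarray(X_pred, dtype=float)
        return X_pred @ self.beta + g


def solve_blup(
    y,
    K: RelationshipMatrix,
    record_ids,
    sigma2_a: float,
    sigma2_e: float,
    weights=None,
    X=None,
    fixed_names=None,
) -> BlupSolution:
    """Henderson's mixed-model equations with heterogeneous residuals.

    ``y`` (and ``weights``/``X`` rows) are indexed by ``record_ids``, a
    subset of K's animals; every animal in K receives a predicted additive
    value and a prediction-error variance from the inverse coefficient
    matrix.
    """
    y = np.asarray(y, dtype=float)
    record_ids = list(record_ids)
    n = len(y)
    if len(record_ids) != n:
        raise DataError("record_ids length must match y")
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise DataError("variances must be positive")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise DataError("weight vector mismatched to y")
        if (w <= 0).any():
            raise DataError("weights must be positive")
    if X is None:
        X = np.ones((n, 1))
        fixed_names = fixed_names or ["mu"]
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise DataError("fixed design row count must match y")
        fixed_names = fixed_names or [f"b{j}" for j in range(X.shape[1])]
    p = X.shape[1]
    q = K.n
    ridx = K.index_of(record_ids)

    Kv, eps = stabilize(K.values)
    try:
        cK = linalg.cho_factor(Kv, lower=True)
        Kinv = linalg.cho_solve(cK, np.eye(q))
    except linalg.LinAlgError:
        raise DataError("relationship matrix singular even after epsilon floor")

    # MME in the R^-1 parametrization: coefficient matrix is the information
    # matrix, so its inverse directly gives PEVs.
    Wy = w * y
    XtW = X.T * w
    C = np.zeros((p + q, p + q))
    C[:p, :p] = (XtW @ X) / sigma2_e
    ZtWZ = np.zeros(q)
    np.add.at(ZtWZ, ridx, w)
    C[p:, p:] = Kinv / sigma2_a
    C[p + ridx, p + ridx] += w / sigma2_e
    XtWZ = np.zeros((p, q))
    np.add.at(XtWZ.T, ridx, (XtW).T)
    C[:p, p:] = XtWZ / sigma2_e
    C[p:, :p] = C[:p, p:].T
    rhs = np.zeros(p + q)
    rhs[:p] = (X.T @ Wy) / sigma2_e
    np.add.at(rhs[p:], ridx, Wy / sigma2_e)
    try:
        Cinv = linalg.inv(C)
    except linalg.LinAlgError:
        raise DataError("singular mixed-model coefficient matrix")
    sol = Cinv @ rhs
    beta = sol[:p]
    g_hat = sol[p:]
    pev = np.diag(Cinv)[p:].copy()
    denom = np.diag(Kv) * sigma2_a
    reliability = np.clip(1.0 - pev / denom, 0.0, 1.0)
    return BlupSolution(
        animal_ids=K.animal_ids,
        beta=beta,
        fixed_names=list(fixed_names),
        g_hat=g_hat,
        pev=pev,
        reliability=reliability,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        meta={"kind": K.kind, "epsilon": eps, "lambda": sigma2_e / sigma2_a,
              "weighted": weights is not None},
    )


# ---------------------------------------------------------------------------
# restricted likelihood machinery


def _reml_loglik(y, X, V):
    n, p = X.shape
    cV, low = linalg.cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cV)))
    VinvX = linalg.cho_solve((cV, low), X)
    Vinvy = linalg.cho_solve((cV, low), y)
    XtVX = X.T @ VinvX
    cX = linalg.cho_factor(XtVX, lower=True)
    logdetX = 2.0 * np.sum(np.log(np.diag(cX[0])))
    Py = Vinvy - VinvX @ linalg.cho_solve(cX, X.T @ Vinvy)
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, Py, (cV, low), VinvX, cX


def _ai_reml(y, X, Vks, theta0, constrain, max_iter=100, tol=1e-8, floor_frac=1e-8):
    """Average-information REML for V(theta) = sum_k theta_k V_k.

    ``constrain(theta)`` projects a proposal back to the feasible set and
    reports whether it had to bend.  Step halving guards the restricted
    likelihood; convergence on relative parameter change or loglik change.
    Returns (theta, loglik, AI matrix at optimum, n_iter, converged, bends).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    theta = np.asarray(theta0, dtype=float).copy()
    floor = floor_frac * float(np.var(y))
    n_bend = 0
    ll = -np.inf
    AI = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = sum(t * Vk for t, Vk in zip(theta, Vks))
        try:
            ll, Py, cV, VinvX, cX = _reml_loglik(y, X, V)
        except linalg.LinAlgError:
            raise DataError("covariance matrix not positive definite during REML")
        Vinv = linalg.cho_solve(cV, np.eye(n))
        W_ = VinvX @ linalg.cho_solve(cX, VinvX.T)
        P = Vinv - W_
        grads = np.empty(len(Vks))
        tvecs = []
        for k, Vk in enumerate(Vks):
            tk = Vk @ Py
            tvecs.append(tk)
            grads[k] = -0.5 * (np.sum(P * Vk) - float(Py @ tk))
        AI = 0.5 * np.array([[float(tvecs[k] @ (P @ tvecs[l])) for l in range(len(Vks))]
                             for k in range(len(Vks))])
        AI = 0.5 * (AI + AI.T)
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(len(theta)) * np.trace(AI), grads)
        except np.linalg.LinAlgError:
            delta = grads / (np.diag(AI) + 1e-12)
        step = 1.0
        accepted = False
        for _ in range(30):
            prop = theta + step * delta
            prop, bent = constrain(prop, floor)
            V2 = sum(t * Vk for t, Vk in zip(prop, Vks))
            try:
                ll2 = _reml_loglik(y, X, V2)[0]
            except linalg.LinAlgError:
                step *= 0.5
                continue
            if ll2 >= ll - 1e-10:
                n_bend += int(bent)
                rel = np.max(np.abs(prop - theta) / np.maximum(np.abs(theta), floor))
                theta = prop
                accepted = True
                if rel < tol or abs(ll2 - ll) < 1e-10:
                    ll = ll2
                    converged = True
                ll = ll2
                break
            step *= 0.5
        if converged:
            break
        if not accepted:
            # likelihood cannot be improved along the AI direction: treat the
            # current point as (numerically) stationary
            converged = True
            break
    return theta, ll, AI, it, converged, n_bend


# ---------------------------------------------------------------------------
# univariate REML


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    se_sigma2_a: float
    se_sigma2_e: float
    loglik: float
    n_iterations: int
    converged: bool
    method: str
    loglik_trace: list = field(default_factory=list)


def reml_univariate(
    y,
    K: RelationshipMatrix,
    record_ids,
    weights=None,
    X=None,
    method: str = "ai",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Estimate (sigma2_a, sigma2_e) for y = Xb + g + e, g ~ N(0, K s2a).

    method="ai": average-information updates with step halving (default).
    method="em": EM-REML on the mixed-model equations; the restricted
    likelihood is non-decreasing across iterations.
    """
    y = np.asarray(y, dtype=float)
    record_ids = list(record_ids)
    n = len(y)
    if n < 2:
        raise DataError("need at least 2 records for REML")
    Ksub = K.subset(record_ids)
    Kv, _ = stabilize(Ksub.values)
    if weights is None:
        D = np.eye(n)
    else:
        w = np.asarray(weights, dtype=float)
        D = np.diag(1.0 / w)
    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)
    p = X.shape[1]
    vy = float(np.var(y))
    if method == "ai":
        def constrain(theta, floor):
            bent = (theta < floor).any()
            return np.maximum(theta, floor), bool(bent)

        theta, ll, AI, it, conv, _ = _ai_reml(
            y, X, [Kv, D], np.array([0.5 * vy, 0.5 * vy]), constrain,
            max_iter=min(max_iter, 200), tol=tol,
        )
        s2a, s2e = float(theta[0]), float(theta[1])
        try:
            cov = np.linalg.inv(AI)
            se_a, se_e = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se_a = se_e = np.nan
        return VarianceComponents(
            sigma2_a=s2a, sigma2_e=s2e, h2=s2a / (s2a + s2e),
            se_sigma2_a=float(se_a), se_sigma2_e=float(se_e),
            loglik=ll, n_iterations=it, converged=conv, method="ai",
        )
    if method != "em":
        raise DataError(f"unknown REML method {method!r}")

    # EM-REML on the MME; Kv plays Z K Z' because every record carrier is a
    # distinct animal of Ksub (Z = I after subsetting).
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    cK = linalg.cho_factor(Kv, lower=True)
    Kinv = linalg.cho_solve(cK, np.eye(n))
    s2a = s2e = 0.5 * vy if vy > 0 else 0.5
    trace = []
    converged = False
    it = 0
    XtW = X.T * w
    for it in range(1, max_iter + 1):
        C = np.zeros((p + n, p + n))
        C[:p, :p] = XtW @ X / s2e
        C[:p, p:] = XtW / s2e
        C[p:, :p] = C[:p, p:].T
        C[p:, p:] = np.diag(w) / s2e + Kinv / s2a
        rhs = np.concatenate([(XtW @ y) / s2e, w * y / s2e])
        Cinv = linalg.inv(C)
        sol = Cinv @ rhs
        b, u = sol[:p], sol[p:]
        Cuu = Cinv[p:, p:]
        s2a_new = float(u @ Kinv @ u + np.sum(Kinv * Cuu)) / n
        resid = y - X @ b - u
        s2e_new = float((w * resid) @ y) / (n - p)
        s2e_new = max(s2e_new, 1e-10 * max(vy, 1.0))
        s2a_new = max(s2a_new, 1e-10 * max(vy, 1.0))
        V = s2a_new * Kv + s2e_new * D
        trace.append(_reml_loglik(y, X, V)[0])
        rel = max(abs(s2a_new - s2a), abs(s2e_new - s2e)) / max(s2a + s2e, 1e-12)
        s2a, s2e = s2a_new, s2e_new
        if rel < tol or (len(trace) > 1 and abs(trace[-1] - trace[-2]) < 1e-10):
            converged = True
            break
    return VarianceComponents(
        sigma2_a=s2a, sigma2_e=s2e, h2=s2a / (s2a + s2e),
        se_sigma2_a=np.nan, se_sigma2_e=np.nan,
        loglik=trace[-1] if trace else np.nan,
        n_iterations=it, converged=converged, method="em",
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# bivariate purebred/crossbred REML


@dataclass
class BivariateComponents:
    G0: np.ndarray                # 2x2 additive (co)variance, PB then CB
    sigma2_e: tuple               # residual variances (PB, CB)
    r_g: float
    se_r_g: float
    loglik: float
    n_iterations: int
    converged: bool
    n_bends: int


def reml_bivariate(
    y_pb,
    y_cb,
    ids_pb,
    ids_cb,
    A: RelationshipMatrix,
    X_pb=None,
    X_cb=None,
    fix_cov: float | None = None,
    start: tuple | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    min_records: int = 30,
) -> BivariateComponents:
    """Bivariate REML for PB/CB records under var(g) = G0 (x) A.

    Each animal carries at most one record (PB animals trait 1, crossbreds
    trait 2), so the residual covariance is fixed at 0.  ``fix_cov``
    constrains G0_12 to a value instead of estimating it (0.0 gives the
    diagonal-G0 model, which reproduces per-trait univariate REML).
    """
    y_pb = np.asarray(y_pb, dtype=float)
    y_cb = np.asarray(y_cb, dtype=float)
    ids_pb, ids_cb = list(ids_pb), list(ids_cb)
    if len(y_pb) < min_records or len(y_cb) < min_records:
        raise DataError(f"each trait needs >= {min_records} records")
    if set(ids_pb) & set(ids_cb):
        raise DataError("an animal cannot carry both a PB and a CB record")
    ids = ids_pb + ids_cb
    Asub = A.subset(ids)  # raises if A does not cover both sets
    Av, _ = stabilize(Asub.values)
    n1, n2 = len(y_pb), len(y_cb)
    n = n1 + n2
    y = np.concatenate([y_pb, y_cb])
    X1 = np.ones((n1, 1)) if X_pb is None else np.asarray(X_pb, dtype=float)
    X2 = np.ones((n2, 1)) if X_cb is None else np.asarray(X_cb, dtype=float)
    X = np.zeros((n, X1.shape[1] + X2.shape[1]))
    X[:n1, : X1.shape[1]] = X1
    X[n1:, X1.shape[1]:] = X2

    m1 = np.zeros(n, dtype=bool)
    m1[:n1] = True
    V11 = np.where(np.outer(m1, m1), Av, 0.0)
    V22 = np.where(np.outer(~m1, ~m1), Av, 0.0)
    V12 = Av - V11 - V22
    E1 = np.diag(m1.astype(float))
    E2 = np.diag((~m1).astype(float))

    # starting values: supplied (g11, g22, e1, e2) or per-trait univariate fits
    if start is not None:
        g11, g22, e1, e2 = (max(float(v), 1e-6) for v in start)
    else:
        uni1 = reml_univariate(y_pb, A, ids_pb, method="ai", max_iter=50, tol=1e-6, X=X1)
        uni2 = reml_univariate(y_cb, A, ids_cb, method="ai", max_iter=50, tol=1e-6, X=X2)
        g11, e1 = max(uni1.sigma2_a, 1e-6), max(uni1.sigma2_e, 1e-6)
        g22, e2 = max(uni2.sigma2_a, 1e-6), max(uni2.sigma2_e, 1e-6)

    if fix_cov is None:
        Vks = [V11, V12, V22, E1, E2]
        theta0 = np.array([g11, 0.5 * np.sqrt(g11 * g22), g22, e1, e2])

        def constrain(theta, floor):
            th = theta.copy()
            bent = False
            for k in (0, 2, 3, 4):
                if th[k] < floor:
                    th[k] = floor
                    bent = True
            lim = 0.999 * np.sqrt(th[0] * th[2])
            if abs(th[1]) > lim:  # keep G0 positive semidefinite (bending)
                th[1] = np.sign(th[1]) * lim
                bent = True
            return th, bent

        theta, ll, AI, it, conv, n_bend = _ai_reml(
            y, X, Vks, theta0, constrain, max_iter=max_iter, tol=tol
        )
        g11, g12, g22, e1, e2 = theta
        cov_idx = (0, 1, 2)
    else:
        Vks = [V11, V22, E1, E2]
        offset = fix_cov * V12

        def constrain(theta, floor):
            return np.maximum(theta, floor), bool((theta < floor).any())

        theta, ll, AI, it, conv, n_bend = _ai_reml_fixed_offset(
            y, X, Vks, offset, np.array([g11, g22, e1, e2]), constrain,
            max_iter=max_iter, tol=tol,
        )
        g11, g22, e1, e2 = theta
        g12 = fix_cov
        cov_idx = None

    G0 = np.array([[g11, g12], [g12, g22]])
    r_g = float(g12 / np.sqrt(g11 * g22)) if g11 > 0 and g22 > 0 else np.nan
    se_rg = np.nan
    if cov_idx is not None and AI is not None:
        try:
            Cth = np.linalg.inv(AI)
            d = np.zeros(len(theta))
            d[0] = -r_g / (2 * g11)
            d[1] = 1.0 / np.sqrt(g11 * g22)
            d[2] = -r_g / (2 * g22)
            se_rg = float(np.sqrt(max(d @ Cth @ d, 0.0)))
        except np.linalg.LinAlgError:
            pass
    return BivariateComponents(
        G0=G0, sigma2_e=(float(e1), float(e2)), r_g=r_g, se_r_g=se_rg,
        loglik=ll, n_iterations=it, converged=conv, n_bends=n_bend,
    )


def _ai_reml_fixed_offset(y, X, Vks, V0, theta0, constrain, max_iter=100, tol=1e-8):
    """AI-REML where V(theta) = V0 + sum_k theta_k V_k with V0 fixed.

    Reuses the free-parameter machinery by appending V0 as a component whose
    coefficient the constraint pins at 1; step halving keeps the restricted
    likelihood monotone despite the clamped direction.
    """

    def constrain2(theta, floor):
        th, bent = constrain(theta[:-1], floor)
        return np.concatenate([th, [1.0]]), bent

    theta, ll, AI, it, conv, nb = _ai_reml(
        y, X, list(Vks) + [V0], np.concatenate([theta0, [1.0]]), constrain2,
        max_iter=max_iter, tol=tol,
    )
    return theta[:-1], ll, AI[:-1, :-1], it, conv, nb
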