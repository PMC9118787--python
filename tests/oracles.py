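"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity along a different route than the
package (brute-force loops, normal equations, generic numeric
optimization) so that agreement is meaningful.
"""

import numpy as np
from scipy import optimize, stats


def bh_oracle(p):
    """BH step-up by explicit sort / cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = min(prev, 1.0)
    return q


def ols_normal_equations(y, X_with_intercept):
    """Solve X'X beta = X'y directly; return (beta, se, df)."""
    X = np.asarray(X_with_intercept, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    return beta, se, df


def partial_corr_residual(x, y, z):
    """Partial correlation as the correlation of OLS residuals on z."""
    Z = np.column_stack([np.ones(len(z)), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def bray_curtis_pair(a, b):
    num = sum(abs(ai - bi) for ai, bi in zip(a, b))
    den = sum(ai + bi for ai, bi in zip(a, b))
    return num / den


def alpha_diversity_direct(p):
    """Direct-summation alpha indices for one renormalized sample."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    nz = p[p > 0]
    h = -sum(pi * np.log(pi) for pi in nz)
    simpson = 1.0 - sum(pi**2 for pi in nz)
    obs = len(nz)
    pielou = h / np.log(obs) if obs > 1 else 0.0
    return obs, h, simpson, pielou


# ---------------------------------------------------------------------------
# numeric ML SEM oracle for the cross-lag path model


def _sem_sigma(theta):
    phi11, phi21, phi22, b11, b12, b21, b22, psi1, psi2 = theta
    phi = np.array([[phi11, phi21], [phi21, phi22]])
    B = np.array([[b11, b12], [b21, b22]])
    U = np.vstack([np.eye(2), B])
    sigma = U @ phi @ U.T
    sigma[2, 2] += psi1
    sigma[3, 3] += psi2
    return sigma, phi, B, U


def _sem_objective(theta, S):
    sigma, *_ = _sem_sigma(theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e6
    _, logdet_s = np.linalg.slogdet(S)
    return logdet - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - 4.0


def _sem_gradient(theta, S):
    sigma, phi, B, U = _sem_sigma(theta)
    inv = np.linalg.inv(sigma)
    W = inv - inv @ S @ inv  # dF/dSigma
    grad = np.empty(9)
    # phi entries
    for k, (i, j) in enumerate([(0, 0), (1, 0), (1, 1)]):
        dphi = np.zeros((2, 2))
        dphi[i, j] = dphi[j, i] = 1.0
        dsigma = U @ dphi @ U.T
        grad[k] = np.sum(W * dsigma)
    # B entries
    for k, (i, j) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        dU = np.zeros((4, 2))
        dU[2 + i, j] = 1.0
        dsigma = dU @ phi @ U.T + U @ phi @ dU.T
        grad[3 + k] = np.sum(W * dsigma)
    # psi entries
    for k, i in enumerate([2, 3]):
        dsigma = np.zeros((4, 4))
        dsigma[i, i] = 1.0
        grad[7 + k] = np.sum(W * dsigma)
    return grad


def sem_ml_oracle(S, n):
    """Fit the df=1 path model by generic numeric ML optimization.

    Free parameters: exogenous covariance (3), the four paths, and two
    disturbance variances; the disturbance covariance is fixed at 0.
    Returns (T, srmr, cfi) computed from the optimizer's solution.
    """
    S = np.asarray(S, dtype=float)
    theta0 = np.array([S[0, 0], S[1, 0], S[1, 1], 0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
    res = optimize.minimize(
        _sem_objective,
        theta0,
        args=(S,),
        jac=_sem_gradient,
        method="BFGS",
        options={"gtol": 1e-14, "maxiter": 2000},
    )
    # polish with a second start from the solution
    res = optimize.minimize(
        _sem_objective,
        res.x,
        args=(S,),
        jac=_sem_gradient,
        method="BFGS",
        options={"gtol": 1e-14, "maxiter": 2000},
    )
    sigma, *_ = _sem_sigma(res.x)
    T = (n - 1) * res.fun
    iu = np.triu_indices(4)
    srmr = float(np.sqrt((((S - sigma)[iu]) ** 2).sum() / 10.0))
    # independence baseline
    T_b = (n - 1) * (
        np.linalg.slogdet(np.diag(np.diag(S)))[1]
        - np.linalg.slogdet(S)[1]
        + np.trace(S @ np.linalg.inv(np.diag(np.diag(S))))
        - 4.0
    )
    d = max(T - 1.0, 0.0)
    d_b = max(T_b - 6.0, d)
    cfi = 1.0 if d_b == 0 else 1.0 - d / d_b
    return float(T), srmr, float(cfi)


def dl_meta_oracle(betas, ses):
    """Hand-rolled DerSimonian-Laird pooling for cross-checks."""
    b = np.asarray(betas, float)
    se = np.asarray(ses, float)
    k = len(b)
    w = 1 / se**2
    mu_fe = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - mu_fe) ** 2))
    tau2 = max(0.0, (q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    ws = 1 / (se**2 + tau2)
    pooled = float(np.sum(ws * b) / np.sum(ws))
    se_pooled = float(np.sqrt(1 / np.sum(ws)))
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, k - 1))
    p_meta = float(2 * stats.norm.sf(abs(pooled / se_pooled)))
    return dict(
        pooled=pooled, se=se_pooled, q=q, tau2=tau2, i2=i2,
        p_het=p_het, p_meta=p_meta,
    )


def gls_fixed_effects(y, X, groups, tau2, sigma2):
    """GLS fixed effects at known random-intercept variance components."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n = len(y)
    V = sigma2 * np.eye(n)
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        V[np.ix_(idx, idx)] += tau2
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    return beta
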