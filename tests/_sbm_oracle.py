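"""Independent nonlinear-fraction oracle for the SBM programs.

Works on the reduced fractional problem in the intensity vector lambda
alone (the optimal slacks are then determined), solved by multistart SLSQP.
The SBM objective is a ratio of affine functions over a polyhedron, so a
local minimum is global; the super-efficiency objective is
convex-over-concave and is handled with several starts. Entirely
independent of the Charnes-Cooper linearization used by the package.
"""

import numpy as np
from scipy.optimize import minimize


def sbm_oracle(X, Yg, Yb, j, n_starts=8, seed=0):
    """Minimize the SBM fraction over feasible lambda directly."""
    X, Yg, Yb = (np.asarray(a, float) for a in (X, Yg, Yb))
    n, m = X.shape
    s1, s2 = Yg.shape[1], Yb.shape[1]
    x0, yg0, yb0 = X[j], Yg[j], Yb[j]

    def objective(lam):
        sm = x0 - X.T @ lam          # input slack
        sg = Yg.T @ lam - yg0        # good-output slack
        sb = yb0 - Yb.T @ lam        # bad-output slack
        num = 1.0 - (sm / x0).mean()
        den = 1.0 + (np.concatenate([sg / yg0, sb / yb0])).mean()
        return num / den

    cons = [
        {"type": "ineq", "fun": lambda lam: x0 - X.T @ lam},
        {"type": "ineq", "fun": lambda lam: Yg.T @ lam - yg0},
        {"type": "ineq", "fun": lambda lam: yb0 - Yb.T @ lam},
    ]
    bounds = [(0.0, None)] * n
    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.eye(n)[j]] + [np.eye(n)[j] * rng.uniform(0.5, 1.0)
                               + rng.uniform(0, 0.2, n)
                               for _ in range(n_starts - 1)]
    for lam0 in starts:
        res = minimize(objective, lam0, method="SLSQP", bounds=bounds,
                       constraints=cons,
                       options={"maxiter": 500, "ftol": 1e-12})
        if res.success:
            lam = np.clip(res.x, 0, None)
            feas = (np.all(X.T @ lam <= x0 * (1 + 1e-9) + 1e-12)
                    and np.all(Yg.T @ lam >= yg0 * (1 - 1e-9) - 1e-12)
                    and np.all(Yb.T @ lam <= yb0 * (1 + 1e-9) + 1e-12))
            if feas:
                best = min(best, objective(lam))
    return best


def super_sbm_oracle(X, Yg, Yb, j, n_starts=12, seed=0):
    """Minimize the super-efficiency fraction over peer intensities.

    For fixed lambda the optimal worsened point is determined elementwise:
    xbar = max(X'lam, x0), ybbar = max(Yb'lam, yb0), ygbar = min(Yg'lam, yg0),
    so the search runs over lambda >= 0 only.
    """
    X, Yg, Yb = (np.asarray(a, float) for a in (X, Yg, Yb))
    keep = [i for i in range(X.shape[0]) if i != j]
    Xr, Ygr, Ybr = X[keep], Yg[keep], Yb[keep]
    x0, yg0, yb0 = X[j], Yg[j], Yb[j]
    p = len(keep)

    def objective(lam):
        lam = np.clip(lam, 0, None)
        xbar = np.maximum(Xr.T @ lam, x0)
        ybbar = np.maximum(Ybr.T @ lam, yb0)
        ygbar = np.minimum(Ygr.T @ lam, yg0)
        num = np.concatenate([xbar / x0, ybbar / yb0]).mean()
        den = (ygbar / yg0).mean()
        if den <= 1e-12:
            return 1e9
        return num / den

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.full(p, 1.0 / p), np.ones(p)] + [
        rng.uniform(0, 2, p) for _ in range(n_starts - 2)
    ]
    for lam0 in starts:
        res = minimize(objective, lam0, method="SLSQP",
                       bounds=[(0.0, None)] * p,
                       options={"maxiter": 500, "ftol": 1e-12})
        if res.success:
            best = min(best, objective(res.x))
        best = min(best, objective(lam0))
    return best


def random_instance(rng, n=5, m=2, s1=1, s2=1):
    """A positive random DEA instance with mild scale correlation."""
    size = rng.lognormal(0, 0.3, n)
    X = size[:, None] * rng.uniform(0.5, 2.0, (n, m))
    Yg = size[:, None] * rng.uniform(0.5, 2.0, (n, s1))
    Yb = size[:, None] * rng.uniform(0.5, 2.0, (n, s2))
    return X, Yg, Yb
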