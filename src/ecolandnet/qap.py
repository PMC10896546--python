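"""QAP correlation and MRQAP regression with permutation inference.

Dyadic matrices violate the independence assumptions of ordinary tests, so
association between a tie matrix R and predictor matrices is tested by the
quadratic assignment procedure: statistics are computed on the vectorized
off-diagonal entries, and the null distribution is built by permuting node
labels — the same permutation applied simultaneously to rows and columns —
which preserves the dyadic dependence structure. MRQAP fits OLS on the
stacked off-diagonals; coefficient p-values come either from whole-matrix
Y-permutation (default) or from Dekker's double-semi-partialing, which
permutes the residualized predictor and is more robust under collinearity.

P-values use the add-one convention (1 + exceedances)/(1 + permutations),
so they are never exactly zero; both one- and two-tailed values are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QapDesign",
    "QapResult",
    "difference_matrix",
    "adjacency_matrix",
    "qap_correlation",
    "mrqap_regression",
]


def difference_matrix(values: Mapping[str, float] | Sequence[float],
                      cities: Sequence[str] | None = None) -> np.ndarray:
    """Symmetric |v_i - v_j| matrix with zero diagonal."""
    if isinstance(values, Mapping):
        if cities is None:
            cities = list(values.keys())
        missing = [c for c in cities if c not in values]
        if missing:
            raise KeyError(f"missing attribute values for cities {missing}")
        v = np.array([float(values[c]) for c in cities])
    else:
        v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("attribute values must be finite")
    return np.abs(v[:, None] - v[None, :])


def adjacency_matrix(pairs: Sequence[tuple[str, str]],
                     cities: Sequence[str]) -> np.ndarray:
    """Binary symmetric spatial-contiguity matrix from a pair list."""
    index = {c: i for i, c in enumerate(cities)}
    n = len(cities)
    S = np.zeros((n, n), dtype=int)
    for a, b in pairs:
        if a not in index or b not in index:
            unknown = [c for c in (a, b) if c not in index]
            raise KeyError(f"unknown city id(s) {unknown} in contiguity list")
        i, j = index[a], index[b]
        if i != j:
            S[i, j] = S[j, i] = 1
    return S


@dataclass(frozen=True)
class QapDesign:
    cities: Sequence[str]
    R: np.ndarray                       # dependent tie matrix
    predictors: dict[str, np.ndarray]   # name -> n x n matrix

    def __post_init__(self):
        n = len(self.cities)
        if self.R.shape != (n, n):
            raise ValueError("dependent matrix shape mismatch")
        for name, X in self.predictors.items():
            if X.shape != (n, n):
                raise ValueError(f"predictor {name!r} shape mismatch")


@dataclass(frozen=True)
class QapResult:
    table: pd.DataFrame      # per predictor: r, p_corr, beta, p_reg (+1-tailed)
    r_squared: float
    adj_r_squared: float
    intercept: float
    n_permutations: int
    seed: int
    method: str


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _vec(M: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.asarray(M, dtype=float)[mask]


def _perm_matrix(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    return M[np.ix_(p, p)]


def qap_correlation(R: np.ndarray, X: np.ndarray, n_perm: int = 5000,
                    seed: int = 0) -> dict:
    """Pearson correlation of off-diagonals with a joint-permutation null.

    Returns r with two-tailed and one-tailed (propensity toward the observed
    sign) add-one permutation p-values.
    """
    R = np.asarray(R, float)
    X = np.asarray(X, float)
    n = R.shape[0]
    mask = _offdiag_mask(n)
    r_vec, x_vec = _vec(R, mask), _vec(X, mask)
    if r_vec.std() == 0 or x_vec.std() == 0:
        raise ValueError("zero variance in off-diagonal entries; r undefined")
    r_obs = float(np.corrcoef(r_vec, x_vec)[0, 1])
    rng = np.random.default_rng(seed)
    rc = r_vec - r_vec.mean()
    denom_r = np.sqrt((rc ** 2).sum())
    count_two = 0
    count_one = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        xp = _vec(_perm_matrix(X, p), mask)
        xc = xp - xp.mean()
        r_perm = float(rc @ xc / (denom_r * np.sqrt((xc ** 2).sum())))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count_two += 1
        if (r_perm >= r_obs - 1e-12) if r_obs >= 0 else (r_perm <= r_obs + 1e-12):
            count_one += 1
    return {
        "r": r_obs,
        "p_two_tailed": (1 + count_two) / (1 + n_perm),
        "p_one_tailed": (1 + count_one) / (1 + n_perm),
        "n_permutations": n_perm,
        "seed": seed,
    }


def _ols(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return beta


def mrqap_regression(R: np.ndarray, predictors: Mapping[str, np.ndarray],
                     n_perm: int = 5000, seed: int = 0,
                     method: str = "y-permutation") -> QapResult:
    """OLS of the tie matrix on predictor matrices with permutation p-values.

    ``method`` is ``"y-permutation"`` (permute the dependent matrix's node
    labels, refit, compare coefficients) or ``"dsp"`` (double
    semi-partialing: permute the residual of each predictor on the others).
    Also reports the QAP correlation of each predictor (null from the same
    permutation budget). Deterministic given seed.
    """
    if method not in ("y-permutation", "dsp"):
        raise ValueError(f"unknown MRQAP method {method!r}")
    if not predictors:
        raise ValueError("need at least one predictor")
    R = np.asarray(R, float)
    n = R.shape[0]
    mask = _offdiag_mask(n)
    y = _vec(R, mask)
    if y.std() == 0:
        raise ValueError("zero variance in dependent matrix")
    names = list(predictors.keys())
    cols = [_vec(np.asarray(predictors[k], float), mask) for k in names]
    Xmat = np.column_stack(cols)
    # exact collinearity check
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            u, v = cols[a], cols[b]
            if u.std() == 0 or v.std() == 0:
                continue
            if abs(np.corrcoef(u, v)[0, 1]) > 1 - 1e-12:
                raise ValueError(
                    f"predictors {names[a]!r} and {names[b]!r} are collinear")
    Z = np.column_stack([np.ones_like(y), Xmat])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("predictor set is rank-deficient")
    beta = _ols(Z, y)
    fitted = Z @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    k = Xmat.shape[1]
    adj_r2 = 1.0 - (1.0 - r2) * (len(y) - 1) / (len(y) - k - 1)

    rng = np.random.default_rng(seed)
    ZtZinv_Zt = np.linalg.pinv(Z)
    exceed_two = np.zeros(k, dtype=int)
    exceed_one = np.zeros(k, dtype=int)
    obs = beta[1:]

    if method == "y-permutation":
        for _ in range(n_perm):
            p = rng.permutation(n)
            yp = _vec(_perm_matrix(R, p), mask)
            bp = (ZtZinv_Zt @ yp)[1:]
            exceed_two += np.abs(bp) >= np.abs(obs) - 1e-12
            exceed_one += np.where(obs >= 0, bp >= obs - 1e-12,
                                   bp <= obs + 1e-12)
    else:  # double semi-partialing
        for j in range(k):
            others = np.delete(np.arange(k), j)
            Zo = np.column_stack([np.ones_like(y), Xmat[:, others]])
            gamma = _ols(Zo, Xmat[:, j])
            resid = Xmat[:, j] - Zo @ gamma
            resid_mat = np.zeros((n, n))
            resid_mat[mask] = resid
            for _ in range(n_perm):
                p = rng.permutation(n)
                rp = _vec(_perm_matrix(resid_mat, p), mask)
                Zj = Z.copy()
                Zj[:, 1 + j] = rp
                bj = _ols(Zj, y)[1 + j]
                exceed_two[j] += abs(bj) >= abs(obs[j]) - 1e-12
                exceed_one[j] += ((bj >= obs[j] - 1e-12) if obs[j] >= 0
                                  else (bj <= obs[j] + 1e-12))

    rows = []
    for j, name in enumerate(names):
        corr = qap_correlation(R, predictors[name],
                               n_perm=min(n_perm, 2000),
                               seed=seed + 1 + j)
        rows.append({
            "predictor": name,
            "r": corr["r"],
            "p_corr": corr["p_two_tailed"],
            "p_corr_one_tailed": corr["p_one_tailed"],
            "beta": obs[j],
            "p_reg": (1 + exceed_two[j]) / (1 + n_perm),
            "p_reg_one_tailed": (1 + exceed_one[j]) / (1 + n_perm),
        })
    table = pd.DataFrame(rows)
    table["stars"] = table["p_reg"].map(
        lambda p: "***" if p < 0.01 else "**" if p < 0.05 else
        "*" if p < 0.1 else "")
    return QapResult(table=table, r_squared=r2, adj_r_squared=adj_r2,
                     intercept=float(beta[0]), n_permutations=n_perm,
                     seed=seed, method=method)
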