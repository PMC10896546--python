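"""Slacks-based measure (SBM) DEA with undesirable output, and super-efficiency.

Each decision-making unit (DMU; here a city within a year) consumes inputs
x, produces desirable outputs y^g and an undesirable output y^b (carbon).
The SBM score is the non-radial efficiency

    rho* = min  [1 - (1/m) sum_i s_i^-/x_i0]
                / [1 + 1/(s1+s2) (sum_r s_r^g/y_r0^g + sum_t s_t^b/y_t0^b)]
    s.t.  x0 = X'lam + s^-,  y0^g = Yg'lam - s^g,  y0^b = Yb'lam + s^b,
          lam, s >= 0   (constant returns; variable returns adds sum lam = 1)

solved by the standard Charnes–Cooper variable substitution: multiply every
variable by a scale t chosen so the denominator equals 1, giving a linear
program. rho* lies in (0, 1] and equals 1 iff all slacks vanish.

Frontier units (rho = 1) are re-scored by super-efficiency: the unit is
removed from the reference set and may be *worsened* — inputs and the
undesirable output expanded, desirable outputs retained — until it reaches
the residual frontier:

    delta* = min  [1/(m+s2) (sum_i xbar_i/x_i0 + sum_t ybbar_t/y_t0^b)]
                  / [(1/s1) sum_r ygbar_r/y_r0^g]
    s.t.  xbar >= X'lam, ygbar <= Yg'lam, ybbar >= Yb'lam   (peers only)
          xbar >= x0, 0 <= ygbar <= y0^g, ybbar >= y0^b, lam >= 0

with the undesirable output treated direction-wise like an input (one of
several published variants; selected here and stated in the score metadata).
delta* >= 1, and equals 1 when an identical peer remains in the reference set.

Both fractional programs are ratios of affine functions over a polyhedron,
so the linearized LP optimum is the global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .carbon import CarbonCoefficients, carbon_emissions
from .panel import INPUT_FIELDS, OUTPUT_FIELDS, Panel, classify_grade

__all__ = [
    "DeaDataset",
    "EfficiencyScore",
    "DeaError",
    "solve_sbm",
    "solve_super_sbm",
    "score_panel",
    "EFFICIENT_TOL",
]

#: rho within this distance of 1 classifies a unit as efficient
EFFICIENT_TOL = 1e-7
_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

Rts = Literal["crs", "vrs"]


class DeaError(RuntimeError):
    """LP failure or an undefined DEA program; carries the solver status."""

    def __init__(self, message: str, lp_status: str = "error"):
        super().__init__(message)
        self.lp_status = lp_status


@dataclass(frozen=True)
class DeaDataset:
    """Aligned input/output matrices for one frontier scope (rows = DMUs)."""

    dmu_ids: Sequence[str]
    X: np.ndarray   # (n, m) inputs
    Yg: np.ndarray  # (n, s1) desirable outputs
    Yb: np.ndarray  # (n, s2) undesirable outputs

    def __post_init__(self):
        X, Yg, Yb = (np.asarray(a, dtype=float) for a in (self.X, self.Yg, self.Yb))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Yg", Yg)
        object.__setattr__(self, "Yb", Yb)
        n = len(self.dmu_ids)
        for name, a in (("X", X), ("Yg", Yg), ("Yb", Yb)):
            if a.ndim != 2 or a.shape[0] != n:
                raise ValueError(f"{name} must be 2-D with one row per DMU")
            if not np.all(np.isfinite(a)) or np.any(a <= 0):
                raise ValueError(f"{name} entries must be finite and > 0")

    @property
    def n(self) -> int:
        return len(self.dmu_ids)


@dataclass(frozen=True)
class EfficiencyScore:
    dmu_id: str
    year: int | None
    rho: float
    delta: float | None      # super-efficiency, present only when rho = 1
    P: float                 # final score: rho if rho < 1 else delta
    input_slacks: np.ndarray
    good_slacks: np.ndarray
    bad_slacks: np.ndarray
    lp_status: str

    @property
    def efficient(self) -> bool:
        return self.rho >= 1.0 - EFFICIENT_TOL


def _run_lp(c, A_eq, b_eq, A_ub=None, b_ub=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs", options=_LP_OPTIONS)
    if not res.success:
        raise DeaError(f"LP failed: {res.message}", lp_status=res.status.__str__())
    return res


def solve_sbm(data: DeaDataset, dmu: int, rts: Rts = "crs") -> EfficiencyScore:
    """SBM efficiency of one DMU against the full reference set (itself included).

    Returns rho in (0, 1] with the de-scaled optimal slacks.
    """
    X, Yg, Yb = data.X, data.Yg, data.Yb
    n, m = X.shape
    s1, s2 = Yg.shape[1], Yb.shape[1]
    x0, yg0, yb0 = X[dmu], Yg[dmu], Yb[dmu]

    # variables: [t, lam*t (n), S- (m), Sg (s1), Sb (s2)]
    nv = 1 + n + m + s1 + s2
    iL, iSm, iSg, iSb = 1, 1 + n, 1 + n + m, 1 + n + m + s1

    c = np.zeros(nv)
    c[0] = 1.0
    c[iSm:iSm + m] = -1.0 / (m * x0)

    rows, rhs = [], []
    # denominator normalisation: t + (Sg/yg0 + Sb/yb0)/(s1+s2) = 1
    r = np.zeros(nv)
    r[0] = 1.0
    r[iSg:iSg + s1] = 1.0 / ((s1 + s2) * yg0)
    r[iSb:iSb + s2] = 1.0 / ((s1 + s2) * yb0)
    rows.append(r); rhs.append(1.0)
    for i in range(m):        # X'L + S- = t*x0
        r = np.zeros(nv)
        r[iL:iL + n] = X[:, i]
        r[iSm + i] = 1.0
        r[0] = -x0[i]
        rows.append(r); rhs.append(0.0)
    for j in range(s1):       # Yg'L - Sg = t*yg0
        r = np.zeros(nv)
        r[iL:iL + n] = Yg[:, j]
        r[iSg + j] = -1.0
        r[0] = -yg0[j]
        rows.append(r); rhs.append(0.0)
    for k in range(s2):       # Yb'L + Sb = t*yb0
        r = np.zeros(nv)
        r[iL:iL + n] = Yb[:, k]
        r[iSb + k] = 1.0
        r[0] = -yb0[k]
        rows.append(r); rhs.append(0.0)
    if rts == "vrs":          # sum lam = 1, scaled: sum L = t
        r = np.zeros(nv)
        r[iL:iL + n] = 1.0
        r[0] = -1.0
        rows.append(r); rhs.append(0.0)

    res = _run_lp(c, np.array(rows), np.array(rhs))
    t = res.x[0]
    if t <= 0:
        raise DeaError("degenerate SBM solution (t = 0)", lp_status="degenerate")
    rho = float(res.fun)
    return EfficiencyScore(
        dmu_id=str(data.dmu_ids[dmu]), year=None, rho=rho, delta=None, P=rho,
        input_slacks=res.x[iSm:iSm + m] / t,
        good_slacks=res.x[iSg:iSg + s1] / t,
        bad_slacks=res.x[iSb:iSb + s2] / t,
        lp_status="optimal",
    )


def solve_super_sbm(data: DeaDataset, dmu: int, rts: Rts = "crs") -> float:
    """Super-efficiency delta >= 1 of a frontier DMU against its peers.

    The evaluated point may be worsened (inputs and bads up, goods down) to
    reach the frontier formed without it; bads move direction-wise like
    inputs. Raises :class:`DeaError` if the DMU has no peers or the program
    is infeasible (possible under VRS).
    """
    if data.n < 2:
        raise DeaError("super-efficiency needs at least one peer DMU",
                       lp_status="no_peers")
    keep = [j for j in range(data.n) if j != dmu]
    Xr, Ygr, Ybr = data.X[keep], data.Yg[keep], data.Yb[keep]
    x0, yg0, yb0 = data.X[dmu], data.Yg[dmu], data.Yb[dmu]
    p = len(keep)
    m, s1, s2 = Xr.shape[1], Ygr.shape[1], Ybr.shape[1]

    # variables: [t, lam*t (p), P=t*xbar (m), G=t*ygbar (s1), B=t*ybbar (s2)]
    nv = 1 + p + m + s1 + s2
    iL, iP, iG, iB = 1, 1 + p, 1 + p + m, 1 + p + m + s1

    c = np.zeros(nv)
    c[iP:iP + m] = 1.0 / ((m + s2) * x0)
    c[iB:iB + s2] = 1.0 / ((m + s2) * yb0)

    eq_rows, eq_rhs = [], []
    r = np.zeros(nv)          # goods normalisation: (1/s1) sum G/yg0 = 1
    r[iG:iG + s1] = 1.0 / (s1 * yg0)
    eq_rows.append(r); eq_rhs.append(1.0)
    if rts == "vrs":
        r = np.zeros(nv)
        r[iL:iL + p] = 1.0
        r[0] = -1.0
        eq_rows.append(r); eq_rhs.append(0.0)

    ub_rows, ub_rhs = [], []

    def add_ub(row, b=0.0):
        ub_rows.append(row); ub_rhs.append(b)

    for i in range(m):        # X'L - P <= 0  and  t*x0 - P <= 0
        r = np.zeros(nv); r[iL:iL + p] = Xr[:, i]; r[iP + i] = -1.0; add_ub(r)
        r = np.zeros(nv); r[0] = x0[i]; r[iP + i] = -1.0; add_ub(r)
    for j in range(s1):       # G - Yg'L <= 0  and  G - t*yg0 <= 0
        r = np.zeros(nv); r[iG + j] = 1.0; r[iL:iL + p] = -Ygr[:, j]; add_ub(r)
        r = np.zeros(nv); r[iG + j] = 1.0; r[0] = -yg0[j]; add_ub(r)
    for k in range(s2):       # Yb'L - B <= 0  and  t*yb0 - B <= 0
        r = np.zeros(nv); r[iL:iL + p] = Ybr[:, k]; r[iB + k] = -1.0; add_ub(r)
        r = np.zeros(nv); r[0] = yb0[k]; r[iB + k] = -1.0; add_ub(r)

    res = _run_lp(c, np.array(eq_rows), np.array(eq_rhs),
                  np.array(ub_rows), np.array(ub_rhs))
    return float(res.fun)


def score_panel(panel: Panel, coef: CarbonCoefficients, *,
                scope: Literal["per-year", "pooled"] = "per-year",
                rts: Rts = "crs") -> pd.DataFrame:
    """Score every city-year; carbon emissions are the sole undesirable output.

    Per-year scope (default) builds one frontier per calendar year; pooled
    scope evaluates all city-years against a single frontier. Frontier units
    (rho = 1) get a super-efficiency delta; the final score P is rho below
    the frontier and delta on it. Deterministic given inputs and options.
    """
    groups: list[tuple[int | None, list]] = (
        [(y, [panel.record(c, y) for c in panel.cities]) for y in panel.years]
        if scope == "per-year"
        else [(None, list(panel.records))]
    )
    out = []
    for year, records in groups:
        emissions = np.array([carbon_emissions(r, coef) for r in records])
        if np.any(emissions <= 0):
            bad = [r.city_id for r, e in zip(records, emissions) if e <= 0]
            raise DeaError(f"non-positive carbon emissions for {bad}; "
                           "DEA needs strictly positive outputs")
        ds = DeaDataset(
            dmu_ids=[r.city_id for r in records],
            X=np.array([[getattr(r, f) for f in INPUT_FIELDS] for r in records]),
            Yg=np.array([[getattr(r, f) for f in OUTPUT_FIELDS] for r in records]),
            Yb=emissions[:, None],
        )
        for j, rec in enumerate(records):
            try:
                score = solve_sbm(ds, j, rts=rts)
                delta = (solve_super_sbm(ds, j, rts=rts)
                         if score.efficient else None)
            except DeaError as exc:
                raise DeaError(f"({rec.city_id}, {rec.year}): {exc}",
                               lp_status=exc.lp_status) from exc
            P = delta if delta is not None else score.rho
            out.append({
                "city_id": rec.city_id, "province": rec.province,
                "year": rec.year, "rho": score.rho, "delta": delta, "P": P,
                "grade": classify_grade(P), "lp_status": score.lp_status,
                "scope": scope, "rts": rts, "bad_direction": "input-like",
            })
    return pd.DataFrame(out)
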