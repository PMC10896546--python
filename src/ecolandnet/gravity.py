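"""Modified gravity model: directed association strengths and their binarization.

The association strength from city i to city j is

    S_ij = K_ij * M_i * M_j / D_ij^b,    K_ij = M_i / (M_i + M_j)

where the mass M_i is the city's eco-efficiency score, D_ij the great-circle
distance in km, and b the distance-attenuation exponent (2 by default). The
contribution rate K makes the matrix directed: K_ij + K_ji = 1, so
S_ij / S_ji = M_i / M_j. Ties are declared where S exceeds a threshold —
by default the mean of all off-diagonal strengths — giving a binary
directed network with zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .panel import AttributeTable

__all__ = [
    "EARTH_RADIUS_KM",
    "GravityMatrix",
    "TieNetwork",
    "distance_matrix",
    "gravity_matrix",
    "binarize",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GravityMatrix:
    cities: Sequence[str]
    S: np.ndarray      # directed strengths, zero diagonal
    K: np.ndarray      # contribution rates, K_ij + K_ji = 1 off-diagonal
    M: np.ndarray      # per-city mass (efficiency score)
    Dist: np.ndarray   # km
    b: float


@dataclass(frozen=True)
class TieNetwork:
    cities: Sequence[str]
    A: np.ndarray      # binary, zero diagonal
    threshold_used: float
    year: int | None = None

    def __post_init__(self):
        A = np.asarray(self.A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("tie matrix must be square")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("tie matrix entries must be 0/1")
        if np.diag(A).any():
            raise ValueError("tie matrix diagonal must be zero")
        object.__setattr__(self, "A", A.astype(int))

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def tie_count(self) -> int:
        return int(self.A.sum())


def distance_matrix(attrs: AttributeTable) -> np.ndarray:
    """Symmetric great-circle (haversine) distance matrix in km."""
    lat = np.radians(attrs.df["lat"].to_numpy(float))
    lon = np.radians(attrs.df["lon"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    D = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(D, 0.0)
    off = ~np.eye(len(lat), dtype=bool)
    if np.any(D[off] == 0):
        i, j = np.argwhere((D == 0) & off)[0]
        warnings.warn(
            f"coincident coordinates for distinct cities "
            f"{attrs.cities[i]!r} and {attrs.cities[j]!r}",
            stacklevel=2,
        )
    return D


def gravity_matrix(M: np.ndarray, Dist: np.ndarray, *, b: float = 2.0,
                   cities: Sequence[str] | None = None) -> GravityMatrix:
    """Directed gravity matrix from masses and pairwise distances."""
    M = np.asarray(M, dtype=float)
    Dist = np.asarray(Dist, dtype=float)
    n = M.size
    if cities is None:
        cities = [str(i) for i in range(n)]
    if Dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match mass vector")
    if np.any(M <= 0):
        bad = [cities[i] for i in np.where(M <= 0)[0]]
        raise ValueError(f"non-positive mass for cities {bad}")
    off = ~np.eye(n, dtype=bool)
    if np.any(Dist[off] <= 0) or not np.all(np.isfinite(Dist[off])):
        i, j = np.argwhere(off & ~((Dist > 0) & np.isfinite(Dist)))[0]
        raise ValueError(
            f"invalid distance between {cities[i]!r} and {cities[j]!r}"
        )
    K = M[:, None] / (M[:, None] + M[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        S = K * (M[:, None] * M[None, :]) / Dist ** b
    np.fill_diagonal(S, 0.0)
    np.fill_diagonal(K, 0.0)
    return GravityMatrix(cities=list(cities), S=S, K=K, M=M, Dist=Dist, b=b)


def binarize(G: GravityMatrix, rule: Literal["global-mean", "row-mean"]
             = "global-mean", year: int | None = None) -> TieNetwork:
    """Threshold the gravity matrix into a binary directed tie network.

    A tie i->j exists iff S_ij strictly exceeds the threshold: the mean of
    all off-diagonal strengths (default) or of row i (row-mean variant).
    A constant strength matrix yields the empty network (with a warning).
    """
    n = G.S.shape[0]
    off = ~np.eye(n, dtype=bool)
    if rule == "global-mean":
        threshold = float(G.S[off].mean())
        A = (G.S > threshold).astype(int)
    elif rule == "row-mean":
        row_thr = (G.S.sum(axis=1) / (n - 1))[:, None]
        A = (G.S > row_thr).astype(int)
        threshold = float(G.S[off].mean())  # recorded for reference
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    np.fill_diagonal(A, 0)
    if A[off].sum() == 0:
        warnings.warn("constant or sub-threshold strengths: empty tie network",
                      stacklevel=2)
    return TieNetwork(cities=list(G.cities), A=A,
                      threshold_used=threshold, year=year)
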