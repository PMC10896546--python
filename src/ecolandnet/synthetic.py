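"""Synthetic yearbook generator: panels, attributes, geography and planted networks.

Emulates the statistical structure the analysis assumes without imitating
any real region: city sizes are log-normal, the four production inputs are
proportional to size with multiplicative noise, outputs carry a
province-specific productivity multiplier (so provinces form an efficiency
gradient with some systematically nearer the frontier) plus a mild common
yearly productivity growth, and carbon-source quantities scale with
fertilizer, machinery and sown area. Geography is a jittered grid whose
4-neighborhood supplies the contiguity list, keeping coordinates, distances
and adjacency internally consistent without any polygon processing.

For driver-recovery experiments, :func:`generate_tie_network` samples a
directed network from a logistic tie model with known (planted)
coefficients on standardized predictor matrices; the intercept is solved so
the expected density matches the configured target (default 0.19, the
density regime the analysis is meant to operate in).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gravity import TieNetwork
from .panel import AttributeTable, CityYearRecord, Panel

__all__ = ["SyntheticConfig", "generate_panel", "generate_tie_network"]


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_cities: int = 47
    years: Sequence[int] = tuple(range(2010, 2021))
    n_provinces: int = 4
    #: per-province output multipliers; higher means nearer the frontier
    efficiency_gradient: Sequence[float] = (1.35, 1.15, 0.95, 0.85)
    #: coefficient of variation of the multiplicative log-normal noise
    noise_cv: float = 0.15
    #: yearly productivity growth common to all provinces
    growth_rate: float = 0.02
    #: planted tie-model effects on standardized predictors
    planted_beta: Mapping[str, float] = field(default_factory=lambda: {
        "adjacency": 2.0,
        "agri_economy_diff": -1.0,
        "mechanization_diff": -1.0,
    })
    #: expected tie density the logistic intercept is solved for
    target_density: float = 0.19

    def __post_init__(self):
        if self.n_cities < 4:
            raise ValueError("need at least 4 cities")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if len(self.efficiency_gradient) != self.n_provinces:
            raise ValueError("one efficiency multiplier per province")
        if not self.years:
            raise ValueError("empty year list")
        if not 0 < self.target_density < 1:
            raise ValueError("target_density must be in (0, 1)")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


# base per-unit-size levels of the yearbook indicators
_BASE = {
    "sown_area": 300.0,        # thousand hectares
    "labor": 50.0,             # 10^4 persons
    "machinery_power": 200.0,  # 10^4 kW
    "fertilizer": 20.0,        # 10^4 t
    "grain_output": 150.0,     # 10^4 t
    "agri_output_value": 80.0,  # 10^8 yuan
}


def generate_panel(config: SyntheticConfig
                   ) -> tuple[Panel, AttributeTable, list[tuple[str, str]]]:
    """Generate a complete panel, attribute table and contiguity list."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cities
    years = list(config.years)
    cities = [f"C{i + 1:02d}" for i in range(n)]
    ncols = math.ceil(math.sqrt(n))
    rows = np.arange(n) // ncols
    cols = np.arange(n) % ncols
    # contiguous provinces: consecutive index blocks = horizontal grid bands
    bounds = np.linspace(0, n, config.n_provinces + 1).astype(int)
    province_of = np.zeros(n, dtype=int)
    for p in range(config.n_provinces):
        province_of[bounds[p]:bounds[p + 1]] = p
    prov_names = [f"P{p + 1}" for p in range(config.n_provinces)]
    mult = np.asarray(config.efficiency_gradient, dtype=float)[province_of]

    size = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    lon = 100.0 + cols * 0.8 + rng.uniform(-0.15, 0.15, n)
    lat = 26.0 + rows * 0.8 + rng.uniform(-0.15, 0.15, n)

    records: list[CityYearRecord] = []
    last_year_vals: dict[str, dict[str, float]] = {}
    for year in years:
        growth = (1.0 + config.growth_rate) ** (year - years[0])
        noise = {k: _lognormal_noise(rng, config.noise_cv, n) for k in _BASE}
        for i, city in enumerate(cities):
            inputs = {k: _BASE[k] * size[i] * noise[k][i]
                      for k in ("sown_area", "labor", "machinery_power",
                                "fertilizer")}
            composite = math.prod(inputs[k] / _BASE[k] for k in inputs) ** 0.25
            outputs = {k: _BASE[k] * composite * mult[i] * growth * noise[k][i]
                       for k in ("grain_output", "agri_output_value")}
            carbon = {
                "fertilizer": inputs["fertilizer"] * 1e7,        # kg applied
                "diesel": inputs["machinery_power"] * 4e4,       # kg consumed
                "pesticide": inputs["sown_area"] * 1.2e3,        # kg applied
                "agri_film": inputs["sown_area"] * 2.0e3,        # kg used
                "plowing": inputs["sown_area"] * 10.0,           # km^2
                "irrigation": inputs["sown_area"] * 1e3 * 0.4,   # ha
            }
            records.append(CityYearRecord(
                city_id=city, province=prov_names[province_of[i]], year=year,
                carbon_sources=carbon, **inputs, **outputs))
            if year == years[-1]:
                last_year_vals[city] = {**inputs, **outputs}

    attr_rows = []
    for i, city in enumerate(cities):
        v = last_year_vals[city]
        attr_rows.append({
            "city_id": city,
            "agri_gdp_share": float(np.clip(
                0.10 + 0.12 * mult[i] + rng.normal(0, 0.03), 0.02, 0.6)),
            "urbanization_rate": float(np.clip(
                0.65 - 0.15 * mult[i] + rng.normal(0, 0.05), 0.1, 0.9)),
            "rural_income": float(6000 + 6000 * mult[i]
                                  + rng.normal(0, 500)),
            "fertilizer_intensity": v["fertilizer"] * 1e4
            / (v["sown_area"] * 1e3),          # t per sown ha
            "mechanization_intensity": v["machinery_power"] * 1e4
            / (v["sown_area"] * 1e3),          # kW per sown ha
            "population": float(80 * size[i]
                                * _lognormal_noise(rng, config.noise_cv, 1)[0]),
            "lon": lon[i],
            "lat": lat[i],
        })
    attrs = AttributeTable(pd.DataFrame(attr_rows).set_index("city_id"))

    contiguity: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if (abs(rows[i] - rows[j]) + abs(cols[i] - cols[j])) == 1:
                contiguity.append((cities[i], cities[j]))

    return Panel(records, years=years), attrs, contiguity


def _standardize_offdiag(M: np.ndarray) -> np.ndarray:
    mask = ~np.eye(M.shape[0], dtype=bool)
    mu, sd = M[mask].mean(), M[mask].std()
    Z = np.zeros_like(M, dtype=float)
    Z[mask] = (M[mask] - mu) / sd if sd > 0 else 0.0
    return Z


def generate_tie_network(config: SyntheticConfig,
                         predictors: Mapping[str, np.ndarray],
                         cities: Sequence[str] | None = None
                         ) -> tuple[TieNetwork, dict[str, float]]:
    """Sample a directed tie network from a logistic model with known betas.

    Tie probability is logistic(beta0 + sum_k beta_k * Z_k) with Z_k the
    off-diagonal-standardized predictor named in ``planted_beta``;
    predictors without a planted beta are ignored. beta0 is solved by
    bisection so the *expected* density equals ``target_density``. Returns
    the sampled network and the planted coefficient mapping (including the
    solved intercept under key ``"_intercept"``).
    """
    names = list(config.planted_beta.keys())
    missing = [k for k in names if k not in predictors]
    if missing:
        raise KeyError(f"planted_beta refers to unknown predictors {missing}")
    n = next(iter(predictors.values())).shape[0]
    if cities is None:
        cities = [f"C{i + 1:02d}" for i in range(n)]
    mask = ~np.eye(n, dtype=bool)
    eta = np.zeros((n, n))
    for k in names:
        eta += config.planted_beta[k] * _standardize_offdiag(
            np.asarray(predictors[k], dtype=float))

    def mean_p(b0: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(b0 + eta[mask]))).mean())

    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = (lo + hi) / 2
        if mean_p(mid) < config.target_density:
            lo = mid
        else:
            hi = mid
    beta0 = (lo + hi) / 2

    rng = np.random.default_rng(config.seed)
    prob = 1.0 / (1.0 + np.exp(-(beta0 + eta)))
    A = (rng.random((n, n)) < prob).astype(int)
    np.fill_diagonal(A, 0)
    net = TieNetwork(cities=list(cities), A=A,
                     threshold_used=float("nan"), year=None)
    planted = dict(config.planted_beta)
    planted["_intercept"] = beta0
    return net, planted
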