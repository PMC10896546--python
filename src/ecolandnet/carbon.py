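"""Carbon accounting: the undesirable output as a coefficient-weighted sum.

Emissions for a city-year are E = sum_k coef_k * quantity_k over the carbon
sources recorded in the panel, converted to the panel's output unit
(10^4 tonnes C). Coefficients and their unit conversions live in a plain
table so they can be replaced wholesale; the shipped defaults follow the
six-source convention of the agricultural carbon-accounting literature
(fertilizer, pesticide, plastic film, diesel, plowing, irrigation) and are
provenance-annotated, not ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .panel import CityYearRecord, Panel

__all__ = [
    "CarbonCoefficients",
    "default_coefficients",
    "carbon_emissions",
    "panel_emissions",
    "read_coefficients",
    "write_coefficients",
]

# kg C per quantity unit; output_scale converts kg C to 10^4 t C (1e-7),
# folded with any per-source quantity-unit mass factor.
_DEFAULTS = [
    # source, factor (kg C per unit), unit, output_scale, provenance
    ("fertilizer", 0.8956, "kg applied", 1e-7,
     "synthesis coefficient, agricultural carbon literature (replaceable)"),
    ("pesticide", 4.9341, "kg applied", 1e-7,
     "synthesis coefficient, agricultural carbon literature (replaceable)"),
    ("agri_film", 5.18, "kg used", 1e-7,
     "synthesis coefficient, agricultural carbon literature (replaceable)"),
    ("diesel", 0.5927, "kg consumed", 1e-7,
     "synthesis coefficient, agricultural carbon literature (replaceable)"),
    ("plowing", 312.6, "km^2 plowed", 1e-7,
     "synthesis coefficient, agricultural carbon literature (replaceable)"),
    ("irrigation", 266.48, "ha irrigated", 1e-7,
     "synthesis coefficient, agricultural carbon literature (replaceable)"),
]


@dataclass(frozen=True)
class CarbonCoefficients:
    """Emission factors per source with explicit unit conversion.

    ``factor`` is kg C per source quantity unit; ``output_scale`` multiplies
    factor * quantity into the panel's emission unit (10^4 t).
    """

    table: pd.DataFrame  # index: source; columns: factor, unit, output_scale, provenance

    def __post_init__(self) -> None:
        for col in ("factor", "output_scale"):
            if col not in self.table.columns:
                raise ValueError(f"coefficient table missing column {col!r}")
            if (self.table[col] <= 0).any():
                bad = list(self.table.index[self.table[col] <= 0])
                raise ValueError(f"non-positive {col} for sources {bad}")

    def factor_for(self, source: str) -> tuple[float, float]:
        row = self.table.loc[source]
        return float(row["factor"]), float(row["output_scale"])

    @property
    def sources(self) -> list[str]:
        return list(self.table.index)


def default_coefficients() -> CarbonCoefficients:
    df = pd.DataFrame(
        _DEFAULTS,
        columns=["source", "factor", "unit", "output_scale", "provenance"],
    ).set_index("source")
    return CarbonCoefficients(df)


def carbon_emissions(record: CityYearRecord, coef: CarbonCoefficients) -> float:
    """Total emissions of one city-year in 10^4 t C.

    Linear and additive in the source quantities; every source present in
    the record must have a coefficient.
    """
    missing = [s for s in record.carbon_sources if s not in coef.table.index]
    if missing:
        raise KeyError(
            f"{record.city_id}/{record.year}: no emission coefficient for "
            f"sources {missing}"
        )
    total = 0.0
    for source, qty in record.carbon_sources.items():
        factor, scale = coef.factor_for(source)
        total += factor * qty * scale
    return total


def panel_emissions(panel: Panel, coef: CarbonCoefficients) -> pd.DataFrame:
    """Emissions table (city_id, year, emissions) for a whole panel."""
    rows = [
        {"city_id": r.city_id, "year": r.year,
         "emissions": carbon_emissions(r, coef)}
        for r in panel.records
    ]
    return pd.DataFrame(rows)


def read_coefficients(path) -> CarbonCoefficients:
    return CarbonCoefficients(pd.read_csv(path).set_index("source"))


def write_coefficients(coef: CarbonCoefficients, path) -> None:
    coef.table.to_csv(path, index=True, index_label="source")


def merge_quantities(a: Mapping[str, float], b: Mapping[str, float]) -> dict:
    """Disjoint union of two carbon-source quantity mappings."""
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"overlapping carbon sources {sorted(overlap)}")
    out = dict(a)
    out.update(b)
    return out
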