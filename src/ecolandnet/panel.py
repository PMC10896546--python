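"""City-year input–output panel: data model, validation, I/O and reporting.

The panel holds the yearbook-style observations behind the eco-efficiency
analysis: four production inputs (crop sown area, primary-industry labor,
agricultural machinery power, chemical fertilizer), two desirable outputs
(grain output, gross agricultural output value) and the raw carbon-source
quantities from which the undesirable output (carbon emissions) is computed.

Units follow the yearbook conventions: sown area in thousand hectares,
labor in 10^4 persons, machinery power in 10^4 kW, fertilizer in 10^4 t,
grain output in 10^4 t, agricultural output value in 10^8 yuan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CARBON_PREFIX",
    "INPUT_FIELDS",
    "OUTPUT_FIELDS",
    "GRADE_LABELS",
    "PanelValidationError",
    "CityYearRecord",
    "Panel",
    "AttributeTable",
    "classify_grade",
    "grade_bounds",
    "provincial_means",
    "grade_share",
    "read_panel",
    "write_panel",
    "read_attributes",
    "write_attributes",
    "read_contiguity",
    "write_contiguity",
    "read_square_matrix",
    "write_square_matrix",
]

INPUT_FIELDS = ("sown_area", "labor", "machinery_power", "fertilizer")
OUTPUT_FIELDS = ("grain_output", "agri_output_value")
#: panel-file columns holding carbon-source quantities are prefixed with this
CARBON_PREFIX = "carbon_"

_SCALAR_FIELDS = INPUT_FIELDS + OUTPUT_FIELDS


class PanelValidationError(ValueError):
    """A panel file or record violates a structural or positivity invariant."""


@dataclass(frozen=True)
class CityYearRecord:
    """One city's yearbook observation for one year."""

    city_id: str
    province: str
    year: int
    sown_area: float
    labor: float
    machinery_power: float
    fertilizer: float
    grain_output: float
    agri_output_value: float
    carbon_sources: Mapping[str, float] = field(default_factory=dict)

    def validate(self, years: Sequence[int] | None = None) -> None:
        for name in _SCALAR_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise PanelValidationError(
                    f"{self.city_id}/{self.year}: field {name!r} is not finite"
                )
            if v <= 0:
                # DEA ratio terms are undefined at zero; reject, never impute.
                raise PanelValidationError(
                    f"{self.city_id}/{self.year}: field {name!r} must be > 0, got {v}"
                )
        for src, q in self.carbon_sources.items():
            if not math.isfinite(q) or q < 0:
                raise PanelValidationError(
                    f"{self.city_id}/{self.year}: carbon source {src!r} "
                    f"must be finite and >= 0, got {q}"
                )
        if years is not None and self.year not in years:
            raise PanelValidationError(
                f"{self.city_id}: year {self.year} outside study window "
                f"{min(years)}..{max(years)}"
            )


class Panel:
    """A complete rectangle of :class:`CityYearRecord`, one per (city, year).

    City order is fixed at construction and shared by every downstream
    matrix (gravity, tie, difference), so all matrices stay aligned.
    """

    def __init__(self, records: Iterable[CityYearRecord],
                 years: Sequence[int] | None = None):
        records = list(records)
        if not records:
            raise PanelValidationError("empty panel")
        cities: list[str] = []
        provinces: dict[str, str] = {}
        for r in records:
            if r.city_id not in provinces:
                cities.append(r.city_id)
                provinces[r.city_id] = r.province
            elif provinces[r.city_id] != r.province:
                raise PanelValidationError(
                    f"city {r.city_id!r} assigned to two provinces"
                )
        yrs = sorted({r.year for r in records}) if years is None else list(years)
        seen: set[tuple[str, int]] = set()
        for r in records:
            r.validate(yrs)
            key = (r.city_id, r.year)
            if key in seen:
                raise PanelValidationError(f"duplicate record for {key}")
            seen.add(key)
        missing = [(c, y) for c in cities for y in yrs if (c, y) not in seen]
        if missing:
            raise PanelValidationError(
                f"panel is not a complete city x year rectangle; "
                f"missing {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        self.records = records
        self.cities = cities
        self.years = yrs
        self.provinces = provinces
        self._by_key = {(r.city_id, r.year): r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def record(self, city_id: str, year: int) -> CityYearRecord:
        return self._by_key[(city_id, year)]

    @property
    def carbon_source_names(self) -> list[str]:
        names: list[str] = []
        for r in self.records:
            for s in r.carbon_sources:
                if s not in names:
                    names.append(s)
        return names

    def to_frame(self) -> pd.DataFrame:
        sources = self.carbon_source_names
        rows = []
        for r in self.records:
            row = {"city_id": r.city_id, "province": r.province, "year": r.year}
            row.update({f: getattr(r, f) for f in _SCALAR_FIELDS})
            row.update({CARBON_PREFIX + s: r.carbon_sources.get(s, 0.0)
                        for s in sources})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AttributeTable:
    """Per-city attributes used as gravity coordinates and QAP predictors."""

    df: pd.DataFrame  # indexed by city_id

    _REQUIRED = ("agri_gdp_share", "urbanization_rate", "rural_income",
                 "fertilizer_intensity", "mechanization_intensity",
                 "population", "lon", "lat")

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self._REQUIRED if c not in df.columns]
        if missing:
            raise PanelValidationError(f"attribute table missing columns {missing}")
        if df.index.has_duplicates:
            raise PanelValidationError("duplicate city_id in attribute table")
        for col in ("agri_gdp_share", "urbanization_rate"):
            bad = df.index[(df[col] < 0) | (df[col] > 1)]
            if len(bad):
                raise PanelValidationError(
                    f"{col} outside [0, 1] for cities {list(bad[:3])}"
                )
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            raise PanelValidationError("coordinates outside valid lon/lat range")

    def aligned_to(self, cities: Sequence[str]) -> "AttributeTable":
        missing = [c for c in cities if c not in self.df.index]
        if missing:
            raise PanelValidationError(f"attribute table missing cities {missing}")
        return AttributeTable(self.df.loc[list(cities)])

    @property
    def cities(self) -> list[str]:
        return list(self.df.index)


# ---------------------------------------------------------------------------
# Efficiency grades and report aggregation
# ---------------------------------------------------------------------------

#: five efficiency bands, highest first; boundary scores fall in the upper band
GRADE_LABELS = ("high", "relatively_high", "medium", "low", "lowest")
_GRADE_EDGES = (1.0, 0.8, 0.6, 0.4, 0.0)


def grade_bounds(label: str) -> tuple[float, float]:
    """Return the [lower, upper) score interval of a grade band."""
    i = GRADE_LABELS.index(label)
    upper = math.inf if i == 0 else _GRADE_EDGES[i - 1]
    return _GRADE_EDGES[i], upper


def classify_grade(score: float) -> str:
    """Map an efficiency score P to its band.

    Bands partition [0, inf): high P>=1, relatively_high 0.8<=P<1, medium
    0.6<=P<0.8, low 0.4<=P<0.6, lowest P<0.4.
    """
    if not math.isfinite(score) or score < 0:
        raise ValueError(f"efficiency score must be finite and >= 0, got {score}")
    for label, lower in zip(GRADE_LABELS, _GRADE_EDGES):
        if score >= lower:
            return label
    return GRADE_LABELS[-1]  # unreachable: lowest band starts at 0


def provincial_means(scores: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Province x year mean-efficiency report.

    ``scores`` needs columns ``city_id``, ``province``, ``year`` and ``P``.
    Each (province, year) cell is the unweighted mean over that province's
    cities; the per-year ``average`` column is the unweighted mean of the
    provincial cells (not of all cities); the ``Average`` row is the mean
    over years of each column. All cells rounded to ``decimals``.
    """
    required = {"city_id", "province", "year", "P"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    counts = scores.groupby(["province", "year"])["P"].count()
    if (counts == 0).any():  # pragma: no cover - groupby drops empty groups
        raise ValueError("empty province group")
    table = scores.pivot_table(index="year", columns="province", values="P",
                               aggfunc="mean", sort=False)
    if table.isna().any().any():
        gaps = [(p, y) for (y, p) in zip(*np.where(table.isna()))]
        raise ValueError(f"missing province/year cells in scores: {gaps}")
    table["average"] = table.mean(axis=1)
    table.loc["Average"] = table.mean(axis=0)
    return table.round(decimals)


def grade_share(scores: Sequence[float], bands: Iterable[str]) -> float:
    """Percentage (1 decimal) of scores falling in the given grade bands."""
    scores = list(scores)
    if not scores:
        raise ValueError("empty score list")
    bands = set(bands)
    unknown = bands - set(GRADE_LABELS)
    if unknown:
        raise ValueError(f"unknown grade labels {sorted(unknown)}")
    hits = sum(classify_grade(s) in bands for s in scores)
    return round(100.0 * hits / len(scores), 1)


# ---------------------------------------------------------------------------
# File I/O (delimited text, UTF-8, header row)
# ---------------------------------------------------------------------------

def read_panel(path, years: Sequence[int] | None = None,
               column_map: Mapping[str, str] | None = None) -> Panel:
    """Read and validate a panel CSV.

    Columns: ``city_id``, ``province``, ``year``, the six indicator fields,
    plus any number of ``carbon_<source>`` quantity columns. ``column_map``
    renames file headers onto these names first. City order is file order.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    needed = ["city_id", "province", "year", *_SCALAR_FIELDS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path}: missing columns {missing}")
    carbon_cols = [c for c in df.columns if c.startswith(CARBON_PREFIX)]
    records = []
    for idx, row in df.iterrows():
        try:
            rec = CityYearRecord(
                city_id=str(row["city_id"]),
                province=str(row["province"]),
                year=int(row["year"]),
                carbon_sources={c[len(CARBON_PREFIX):]: float(row[c])
                                for c in carbon_cols},
                **{f: float(row[f]) for f in _SCALAR_FIELDS},
            )
            rec.validate()
        except (PanelValidationError, ValueError) as exc:
            raise PanelValidationError(f"{path}, row {idx + 2}: {exc}") from exc
        records.append(rec)
    return Panel(records, years=years)


def write_panel(panel: Panel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def read_attributes(path) -> AttributeTable:
    df = pd.read_csv(path).set_index("city_id")
    return AttributeTable(df)


def write_attributes(attrs: AttributeTable, path) -> None:
    attrs.df.to_csv(path, index=True, index_label="city_id")


def read_contiguity(path) -> list[tuple[str, str]]:
    """Read a two-column city-pair list; pairs are interpreted symmetrically."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise PanelValidationError(f"{path}: contiguity file needs two columns")
    a, b = df.columns[:2]
    return [(str(r[a]), str(r[b])) for _, r in df.iterrows()]


def write_contiguity(pairs: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["city_a", "city_b"]).to_csv(path, index=False)


def read_square_matrix(path, cities: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a square city x city matrix with city_id header row and column."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise PanelValidationError(f"{path}: row and column city orders differ")
    if cities is not None and list(df.index) != list(cities):
        raise PanelValidationError(f"{path}: city order does not match panel")
    return df


def write_square_matrix(matrix: np.ndarray, cities: Sequence[str], path) -> None:
    pd.DataFrame(np.asarray(matrix), index=list(cities),
                 columns=list(cities)).to_csv(path, index=True,
                                              index_label="city_id")
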