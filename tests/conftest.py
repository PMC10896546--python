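import numpy as np
import pandas as pd
import pytest

from ecolandnet.panel import AttributeTable, CityYearRecord, Panel


def make_record(city="C01", province="P1", year=2010, scale=1.0, mult=1.0,
                carbon=None, **overrides):
    """A valid city-year record with all fields proportional to `scale`."""
    fields = dict(
        sown_area=300.0 * scale,
        labor=50.0 * scale,
        machinery_power=200.0 * scale,
        fertilizer=20.0 * scale,
        grain_output=150.0 * scale * mult,
        agri_output_value=80.0 * scale * mult,
    )
    fields.update(overrides)
    if carbon is None:
        carbon = {"fertilizer": fields["fertilizer"] * 1e7,
                  "diesel": fields["machinery_power"] * 4e4}
    return CityYearRecord(city_id=city, province=province, year=year,
                          carbon_sources=carbon, **fields)


@pytest.fixture
def small_panel():
    """2 cities x 2 years, different sizes and productivities."""
    recs = [
        make_record("C01", "P1", y, scale=1.0, mult=1.2)
        for y in (2010, 2011)
    ] + [
        make_record("C02", "P2", y, scale=1.6, mult=0.8)
        for y in (2010, 2011)
    ]
    return Panel(recs, years=[2010, 2011])


def make_attributes(cities, rng=None, lons=None, lats=None):
    rng = rng or np.random.default_rng(0)
    n = len(cities)
    df = pd.DataFrame({
        "agri_gdp_share": rng.uniform(0.1, 0.4, n),
        "urbanization_rate": rng.uniform(0.3, 0.7, n),
        "rural_income": rng.uniform(8000, 18000, n),
        "fertilizer_intensity": rng.uniform(0.3, 0.9, n),
        "mechanization_intensity": rng.uniform(4, 9, n),
        "population": rng.uniform(30, 300, n),
        "lon": lons if lons is not None else 100 + rng.uniform(0, 5, n),
        "lat": lats if lats is not None else 26 + rng.uniform(0, 5, n),
    }, index=pd.Index(cities, name="city_id"))
    return AttributeTable(df)
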