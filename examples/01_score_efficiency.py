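"""Score a tiny city panel by SBM / super-SBM with carbon as the bad output.

Three cities over one year: C1 is the most productive (highest output per
unit input), C2 is mid-sized, C3 is small and unproductive. The frontier
city earns a super-efficiency score above 1; the others score in (0, 1).
"""

from ecolandnet import CityYearRecord, Panel, default_coefficients, score_panel


def record(city, province, scale, mult):
    return CityYearRecord(
        city_id=city, province=province, year=2020,
        sown_area=300 * scale, labor=50 * scale,
        machinery_power=200 * scale, fertilizer=20 * scale,
        grain_output=150 * scale * mult, agri_output_value=80 * scale * mult,
        carbon_sources={"fertilizer": 20 * scale * 1e7,
                        "diesel": 200 * scale * 4e4},
    )


panel = Panel([
    record("C1", "North", scale=1.0, mult=1.3),
    record("C2", "North", scale=1.5, mult=1.0),
    record("C3", "South", scale=0.7, mult=0.7),
], years=[2020])

scores = score_panel(panel, default_coefficients())
print(scores[["city_id", "rho", "delta", "P", "grade"]].to_string(index=False))
print()
print("P is the final efficiency: rho (<1) off the frontier, the")
print("super-efficiency delta (>=1) on it; grades band P at 1/0.8/0.6/0.4.")
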