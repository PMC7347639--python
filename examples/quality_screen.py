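"""Apply the station-year inclusion rules to a synthetic panel.

A station-year is excluded when more than 60% of the year is missing, when
a gap of more than 4 consecutive missing days touches the 10 days around
the first high-pollen day (>= 200 grains/m3), or when the early-season
analysis window holds no data at all.
"""

from pollenproxy import MissingnessParams, PanelSpec, apply_inclusion, generate_panel

# Exaggerated missingness so that several site-years breach the rules.
spec = PanelSpec(
    n_site_years=8,
    seed=7,
    missingness=MissingnessParams(
        weekend_missing_prob=0.9,
        edge_gap_days=(30, 60),
        random_gap_rate=12.0,
        random_gap_length_mean=4.0,
    ),
)

print(f"{'site-year':<12} {'%missing':>8} {'gap@high':>8}  verdict")
for station, _ in generate_panel(spec):
    report = apply_inclusion(station.series, site_year_id=station.site_year_id)
    verdict = "included" if report.included else \
        "excluded: " + ", ".join(report.exclusion_reasons)
    print(
        f"{report.site_year_id:<12} {report.pct_missing_days:8.1f} "
        f"{report.gap_near_first_high_days:8d}  {verdict}"
    )
print("\n'%missing' is over the calendar year; 'gap@high' is the longest")
print("missing run touching the +-10-day window around the first high day.")
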