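"""Generate a small synthetic pollen/search panel and write it to CSV.

Each site-year couples a station's daily pollen concentrations (bimodal
season, weekend/edge missingness) with a search-market's 10 download
replicates (lagged power-law response, zero-censored, rescaled to 0-100).
"""

import numpy as np

from pollenproxy import PanelSpec, generate_panel
from pollenproxy.io import write_metadata_csv, write_series_csv

spec = PanelSpec(n_site_years=5, year=2015, seed=42)
panel = generate_panel(spec)

for station, region in panel:
    pollen = station.series
    search = region.averaged
    print(
        f"{station.station_id} @ ({station.latitude:.2f}, {station.longitude:.2f})"
        f"  pollen: {pollen.n_observed}/365 days observed,"
        f" peak {np.nanmax(pollen.values):7.1f} grains/m3"
        f" | {region.dma_id}: {region.tv_homes:,.0f} TV-homes,"
        f" {int(np.sum(search.values == 0))} zero-censored days"
    )

write_series_csv([s for s, _ in panel], "scratch_pollen.csv")
write_series_csv([r for _, r in panel], "scratch_search.csv")
write_metadata_csv([s for s, _ in panel], "scratch_stations_meta.csv")
write_metadata_csv([r for _, r in panel], "scratch_regions_meta.csv")
print("\nwrote scratch_pollen.csv / scratch_search.csv (+ metadata);")
print("re-running with the same seed reproduces them byte-for-byte.")
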