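"""Merge geocode candidates by source priority, project, and round to 10 m.

Priority: gold-standard local engine > commercial point service >
commercial street-segment service > the delivery's own coordinates.
"""

from bizscape import GeocodeCandidate, GeocodeSource, Precision, merge_geocodes
from bizscape.geoprocessing import project_and_round

cands = [
    GeocodeCandidate("123456789", "most_recent", GeocodeSource.VENDOR_SUPPLIED,
                     40.7130, -74.0060, Precision.ZIP),
    GeocodeCandidate("123456789", "most_recent", GeocodeSource.COMMERCIAL_STREET,
                     40.7129, -74.0061, Precision.STREET_SEGMENT),
    GeocodeCandidate("123456789", "most_recent", GeocodeSource.GOLD_LOCAL,
                     40.7128, -74.0060, Precision.POINT),
]
best = merge_geocodes(cands)
print(f"winning source: {best.source.value} at precision {best.precision.value}")

x, y = project_and_round(best.lat, best.lon)
print(f"UTM 18N (NAD83), rounded to 10 m: easting {x:.0f}, northing {y:.0f}")
# identical rounded coordinates define 'same location' for deduplication:
x2, y2 = project_and_round(best.lat + 2e-5, best.lon)  # ~2 m away
print(f"a point ~2 m north rounds to:     easting {x2:.0f}, northing {y2:.0f}")
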