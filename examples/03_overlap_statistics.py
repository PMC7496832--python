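"""Geodesic buffers, depth-band masks and percent-overlap statistics.

The kind of numbers these support: what fraction of a ridge region falls
inside a fisheries-management area, and what fraction of the seafloor lies
in the trawlable 1,000-2,500 m depth band.
"""

import numpy as np
from shapely.geometry import Point

import deepsea_exposure as dse
from deepsea_exposure._geo import haversine_m

grid = dse.regular_grid(24, 24, lat_range=(-12, 11), lon_range=(-150, -127))
regions, truth = dse.gen_regions(grid)

ridge = dse.mask_from_regions(regions, grid, name="ridge_axis")
rfmo = dse.mask_from_regions(regions, grid, name="rfmo_managed")
pct = dse.overlap_percent(ridge, rfmo)
print(f"ridge cells inside the RFMO-managed area: {pct:.1f}% "
      f"(of {ridge.count()} ridge cells)")

bathy = dse.gen_bathymetry(grid, seed=0)
band = dse.depth_band_mask(bathy, grid, (1000.0, 2500.0))
everywhere = dse.CellMask(grid=grid, member=np.ones(grid.shape, bool))
print(f"seafloor in the trawlable 1,000-2,500 m band: "
      f"{dse.overlap_percent(everywhere, band):.1f}% of the domain")

# a 150-nautical-mile buffer around a ridge point; boundary vertices sit
# 277.8 km (150 nm) from the centre on the sphere
centre = Point(-140.0, 0.0)
buf = dse.buffer_region(centre, 150.0, unit="nautical_mile")
bx, by = np.array(buf.exterior.coords).T
d_km = haversine_m(bx, by, centre.x, centre.y) / 1000.0
print(f"150-nm buffer boundary distance: {d_km.mean():.1f} km "
      f"(spread {d_km.min():.1f}-{d_km.max():.1f} km)")
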