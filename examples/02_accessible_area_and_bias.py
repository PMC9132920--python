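"""Build an accessible area (M) from ecoregions and a sampling-bias surface.

The M-area is the union of ecoregions at least 20% covered by a concave hull
of a species' records; the bias surface is a kernel density of all pooled
records used to down-weight over-collected background cells.
"""
import numpy as np

from enmpipe import bias_raster, build_m_area, concave_hull, make_world
from enmpipe.geometry import equal_area_km2

world = make_world(seed=1)
species = world.species[0]
recs = world.records[(world.records.genus + " " + world.records.species) == species]
print(f"{species}: {len(recs)} records")

hull = concave_hull(list(zip(recs.lon, recs.lat)))
m_area = build_m_area(hull, world.ecoregions, min_coverage=0.20)
n_regions = sum(1 for r in world.ecoregions if m_area.covers(r.polygon.buffer(-1e-9)))
print(f"hull area {equal_area_km2(hull):,.0f} km^2 -> M-area "
      f"{equal_area_km2(m_area):,.0f} km^2 from {n_regions} ecoregions")

bias = bias_raster(world.records.lon.to_numpy(), world.records.lat.to_numpy(),
                   world.env.spec)
r, c = np.unravel_index(np.argmax(bias), bias.shape)
lon, lat = world.env.spec.cell_center(r, c)
print(f"bias surface: max {bias.max():.3f} at ({lon:.2f}, {lat:.2f}), "
      f"values rounded to 3 decimals, integral ~ {bias.sum() * world.env.spec.cellsize**2 / 1000:.3f}")
# the integral of density * cell area / 1000 should be close to 1
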