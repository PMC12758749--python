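"""Simulate a synthetic study region set: station temperatures and posts.

Builds a 3-region world with a 3-week peak-summer window, aggregates
station daily maxima to regional values, and draws heat-related posts whose
expected daily volume follows each region's quadratic attention law.
"""
import datetime as dt

from heatlens import region_daily_tmax, simulate_posts, simulate_temperatures
from heatlens.synthetic import default_world, station_region_map

world = default_world(seed=7, n_regions=3)
world.date_end = dt.date(2023, 7, 21)

stations = simulate_temperatures(world)
temps = region_daily_tmax(stations, station_region_map(world))
posts = simulate_posts(world, temps)

print(f"{len(stations)} station-days from {world.n_regions * world.stations_per_region} stations")
print(f"{len(temps)} region-day temperatures, e.g. {temps[0].region} "
      f"{temps[0].date} {temps[0].tmax_c:.1f} °C from {temps[0].n_stations} stations")
print(f"{len(posts)} posts; first: {posts[0].post_id!r}: {posts[0].raw_text!r}")
# Hotter days in a region yield more posts: the generative attention law is
# a convex quadratic in daily maximum temperature, scaled by per-capita GDP.
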