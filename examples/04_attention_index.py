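"""The heat attention index and its association with temperature.

Attention = heat-related posts / per-capita GDP (ten-thousand-yuan units).
On a world where warmer regions genuinely talk more about heat, the period
index correlates positively with period-mean daily maximum temperature.
"""
import datetime as dt

import numpy as np

from heatlens import attention_index, region_daily_tmax, spearman_assoc
from heatlens.synthetic import WorldConfig, simulate_post_counts, simulate_temperatures, station_region_map

n = 8
a2, vertex = 0.05, 10.0  # attention rises over the whole summer range
world = WorldConfig(
    n_regions=n, stations_per_region=2,
    date_start=dt.date(2023, 7, 1), date_end=dt.date(2023, 8, 31),
    gdp_per_capita=tuple(float(g) for g in np.linspace(3, 12, n)),
    temp_mean=tuple(float(m) for m in np.linspace(25, 33, n)),
    temp_amplitude=0.0, temp_ar1=0.4, temp_noise_sd=1.5,
    attention_params=((a2 * vertex**2 + 0.5, -2 * a2 * vertex, a2),) * n,
    seed=11,
)
stations = simulate_temperatures(world)
temps = region_daily_tmax(stations, station_region_map(world))
counts = simulate_post_counts(world, temps)

mean_t, idx = [], []
for ri, region in enumerate(world.regions):
    mean_t.append(np.mean([t.tmax_c for t in temps if t.region == region]))
    total = sum(counts[(region, d)] for d in world.dates)
    idx.append(attention_index(total, world.gdp_per_capita[ri]))
    print(f"{region}: mean tmax {mean_t[-1]:5.2f} °C, posts {total:5d}, "
          f"attention index {idx[-1]:7.2f}")

rho, p = spearman_assoc(mean_t, idx)
print(f"Spearman rho = {rho:.3f} (p = {p:.2g})")
# A rho near 1 says hotter regions show systematically higher normalised
# heat attention, which is what the index is designed to capture.
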