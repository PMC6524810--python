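"""Per-cell seasonal structure: SI, peak month and dominant gear.

The seasonality index SI measures how unevenly a cell's climatological
effort spreads over the year (0 even, 1.83 all in one month).  The peak
month is taken from the first principal component of the year-by-month
matrix, reported only where a clear cycle exists.
"""

import numpy as np

import effortseason as es
from effortseason import ingest, local_metrics as lm

scenario = es.Scenario(lon_min=100, lon_max=124, lat_min=0, lat_max=24,
                       mean_total_effort=600, seed=42)
data = es.generate_parametric(scenario)
vessels = es.split_purse_seiners(ingest.read_vessel_table(data.vessels))
grid = es.GridSpec(1.0)
effort = es.monthly_aggregate(es.rasterize_daily(data.records, grid,
                                                 vessels=vessels), grid)

clim = lm.climatology(effort)
si = lm.seasonality_index(clim)
print(f"SI over {int(np.isfinite(si.values).sum())} cells: "
      f"median {float(si.median()):.2f}, "
      f"p90 {float(si.quantile(0.9)):.2f} (scale 0 .. 1.83)")

peak = lm.peak_month(effort)
ok = np.isfinite(peak.peak_month.values)
print(f"peak month defined in {ok.mean():.0%} of cells "
      f"(zero-year filter + 2/3-variance filter)")
truth = np.asarray(data.truth["peak_month_field"])
delta = (peak.peak_month.values[ok] - truth[ok]) % 12
exact = (delta == 0).mean()
within1 = np.isin(delta, [0, 1, 11]).mean()
print(f"injected peak month recovered exactly in {exact:.0%} of those, "
      f"within one month in {within1:.0%}")

for thr in (0.75, 0.5):
    dom, legend = lm.dominant_gear(effort, threshold=thr)
    labels, counts = np.unique(dom.values, return_counts=True)
    found = {legend[int(c)]: int(n) for c, n in zip(labels, counts)}
    print(f"dominant gear at >{thr:.0%} of cell effort: {found}")
# The default gear mixture (trawlers at 53%) dominates no cell at the
# strict 75% threshold; at 50% the trawler-led coastal band appears.
# With the mixture's modest all-gear amplitude and Poisson sampling the
# recovered peak often lands on a neighboring month — the cosine is flat
# near its maximum — so exact recovery is much lower than the
# within-one-month rate.  Strongly seasonal cells (amplitude >= 0.5)
# recover exactly; see the test suite.
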