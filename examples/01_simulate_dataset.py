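"""Generate a synthetic AIS-like dataset and inspect its ground truth.

The parametric generator draws daily vessel-day counts from per-cell
expected intensities (spatial base field x seasonal cosine x holiday and
moratorium factors) and assigns them to a synthetic fleet.  Everything
injected is stored in a truth record for later recovery checks.
"""

import effortseason as es

scenario = es.Scenario(lon_min=100, lon_max=124, lat_min=0, lat_max=24,
                       mean_total_effort=200, seed=42)
data = es.generate_parametric(scenario)

print(f"records:         {len(data.records):,} daily fishing positions")
print(f"vessels:         {len(data.vessels)} across "
      f"{data.vessels['gear_class'].nunique()} reported gear classes")
print(f"moratorium mask: {len(data.mask.cells)} cells")
print("injected gear shares (% of expected vessel-days):")
for gear, share in data.truth["expected_shares_pct"].items():
    print(f"  {gear:20s} {share:5.1f}")
print("injected holiday deficits (days):",
      {int(k): v for k, v in data.truth["holiday_days"].items()})
# The shares are what the ingest + global-metrics stages should recover;
# the holiday deficits are what the winter-deficit estimator should return.
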