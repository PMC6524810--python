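# Methods

## Effort unit and gridding

The atomic unit is the fishing-vessel-day: a vessel counted once per
grid cell per calendar day however many fishing positions it reports
there.  A vessel fishing in k distinct cells on one day contributes one
vessel-day in each cell; counting is per cell, with no cross-cell
deduplication, so per-cell counts are independent of what the vessel
does elsewhere that day.  Consequently the total vessel-day count at a
fine resolution is ≥ the total at a coarser one (merging cells can only
merge duplicates), and aggregated fine-grid counts do not exactly equal
native coarse-grid rasterization — the resolution harness treats the
two as separate measurements and reports their rank agreement.

Grids are global and regular, addressed by lower-left corner on
half-open intervals with lon ∈ [−180, 180); longitude 180 wraps to
−180 and latitude 90 joins the northernmost row, so every point maps to
exactly one cell.  The analysis set is 0.5°, 1.0° and 4.0°; `GridSpec`
accepts any resolution dividing 360 and 180 exactly, and the pipeline
config restricts to the analysis set.  Monthly effort is the vessel-day
sum divided by the days of the month (29 in a leap February), in
fishing-vessel-days per day.

Vessel filters: only vessels with at least one fishing record in every
calendar year of the window (default 2015–2017) are retained — the
weakest reading of "continually active" implementable from effort
records alone; stricter readings can be expressed by the caller.  Purse
seiners split into high-seas (length > 40 m AND mean fishing distance
from shore > 50 nm, 1 nm = 1.852 km) versus coastal; a purse seiner
with unknown length is classified coastal (the majority class) with a
warning, which avoids silently inflating high-seas effort.

Region masks (e.g. an EEZ hosting a moratorium) contain the cells whose
centers fall inside the polygon — deterministic and
resolution-consistent; fractional-overlap weighting was considered and
rejected as over-engineering for 1° analysis.  Remove- and keep-mode
outputs partition the grid exactly.

## Global metrics

Per gear, the relative cycle is E_g/Ē_g with Ē_g the full-window mean;
its standard deviation (sample convention, n−1, used throughout the
package) measures cycle intensity.  Gear shares are percentages of the
window-summed monthly series.  The implied-holiday estimator compares
each winter month's pooled (climatological) mean against the pooled
March–November baseline and multiplies the relative deficit by the
month's mean calendar length over the window; on a single non-leap year
this reduces to (1 − E_m/baseline) · d_m exactly.  Estimates are
signed — a busier-than-baseline month yields negative days — so
generator or pipeline errors cannot hide behind clipping.  The
estimator uses total effort over all gears; it is computed on the
mask-excluded series, mirroring the removal of the moratorium region
before interpreting winter dips.

## Local metrics

The climatology averages each calendar month across years (whole years
required).  The seasonality index is evaluated on the climatological
months, with ē_a the annual **total** of the 12 climatological values;
this convention makes the attainable range exactly [0, 22/12 ≈ 1.83],
and effort spread equally over k months gives SI = 2(12−k)/12 in closed
form.  Cells with zero annual effort are flagged invalid rather than
raising.  The local relative sd is sd(e/ē) over the monthly series,
computed as sd(e)/ē; both statistics are invariant under positive
rescaling of a cell's series.

Peak month: per cell, on all-gear summed effort, the Y×12 year-by-month
matrix is centered by its grand mean and decomposed by SVD; explained
variance is σ₁²/Σσ_k².  Cells failing either filter — nonzero annual
effort in every year, or explained variance < 2/3 — carry no peak and
record the reason.  The first right-singular 12-vector is sign-aligned
to correlate positively with the cell's mean monthly profile, and the
peak is its argmax with ties broken to the earliest month.  This
variant (grand-mean centering, variance ratio over all components, sign
by profile correlation) was chosen because it is deterministic,
testable, and gives explained variance exactly 1 for identical years; a
defensible alternative — the fraction of 36-month variance explained by
repeating the climatology (an R²) — would pass the same synthetic
recovery checks.  A matrix that is all-zero after centering fails the
variance filter as degenerate.

Dominant gear uses a strict inequality (> 75% of window-summed cell
effort); exactly 75% is "none".

## Distance-to-port profiles

Distances are interpolated bilinearly at cell centers from a fine
raster; invalid (land) nodes are handled by renormalizing over valid
neighbors, and a center with no valid neighbor, or outside the raster,
is excluded.  Bins are contiguous 75 km half-open intervals from zero.
Per bin the cells' local relative sds are averaged with mean-effort
weights; bins carrying less than 0.1% of the gear's total effort are
flagged discarded (values still computed) — the threshold is applied
per gear because profiles are per gear.  Both the weights and the
threshold scale with effort, so profiles are invariant under uniform
rescaling.  Two rasters (port and shore) are accepted because the purse
split needs shore distance while profiles need port distance; if only
one is supplied the pipeline uses it for both with a warning.

## Synthetic generator

The parametric mode defines, per gear, a spatial base field — coastal
(exponential decay away from a synthetic coastline meridian, band width
in km) or basin-wide — normalized so the gear's expected domain total
matches its share of the scenario's mean total effort.  The default
scenario is a 60°×60° western-Pacific-like domain at 1.0°, 600
vessel-days per day, with shares 53/15/13/7/4/4/4 (trawlers, fixed,
longlines, coastal purse, high-seas purse, jiggers, other — the 11%
purse share split 7/4), coastal bands of 150–300 km, and per-gear
seasonal amplitudes of 0.2 (demersal gears) to 0.8 (jiggers), following
the observed pattern that pelagic gears cycle hardest.  These defaults
are study conditions, not tuning knobs.

Seasonality is a per-cell cosine in calendar month, 1 + A·cos(2π(m −
p)/12): single-parameter and analytically invertible, so recovery tests
know the injected peak p and amplitude A exactly.  The default peak
field assigns p cyclically along latitude rows; because the coastal
base fields vary only with longitude, every longitude column carries
all twelve phases with equal weight and the seasonal term cancels in
the domain sum, leaving the global series flat except for holidays and
the moratorium — which is what makes the holiday estimator's target
unambiguous.  The default moratorium region spans exactly 12° of
latitude so that removing it preserves this balance.  Holiday deficits
(default 4.0/4.0/2.5 days for Dec/Jan/Feb) scale each day of the month
by 1 − h/d_m; the moratorium multiplies member-cell intensity by 0.1
inside its windows (mid-May to mid-September, starting two weeks
earlier in the third year).

Vessel-day counts are drawn per cell-day either Poisson (default) or
deterministically.  The deterministic mode integerizes each month's
expected totals by error diffusion across cells (cumulative floor along
the cell axis), so realized global monthly totals match expectation to
within one vessel-day, then spreads each cell's monthly integer over
days proportionally to the daily intensity.  Counts are assigned to
vessels by tiling a per-day random permutation of the gear's pool over
the day's cell slots: vessels within a cell-day are distinct whenever
no cell-day count exceeds the pool size (validated; a hard error
otherwise), a vessel may legitimately fish several cells in one day,
and every pool vessel is active each year (repaired by label swap in
the rare miss, so the continuity filter keeps the pool by
construction).  Dropout vessels — active in a single year — can be
injected to exercise the filter.  Identical scenario and seed give
byte-identical outputs.

Distance rasters are exact great-circle (haversine, R = 6371.0 km)
distances to the nearest synthetic port and to the coastline meridian,
on a 0.1° grid (fine enough that bilinear interpolation at 1° cell
centers is exact to meters; the 1/100° resolution of the real product
would add nothing at analysis scale).  Nodes west of the coastline are
land and invalid.

The bioeconomic mode integrates dE/dt = κ_e(pqB − c)E − R with harvest
H = qEB by a daily Euler step, clipping E at zero.  The
profit-per-unit-effort form is used: the growth term is the profit
margin per unit effort, p·q·B − c, times effort, with the
proportionality constant absorbed into κ_e — the standard bioeconomic
reading of an effort dynamic that is stated conceptually rather than
dimensionally in its source.  Zero effort is absorbing (growth is
proportional to E and re-entry is out of scope).  Catchability, biomass
and the regulatory removal R may be constants, per-cell fields or
functions of time; a strong R inside a closure window empties the
region, reproducing a moratorium trough.

## What the generator does and does not emulate

It emulates: gear-specific coastal/basin spatial structure, controlled
per-cell seasonal cycles, a regionally confined seasonal closure,
whole-day winter holiday deficits, Poisson count noise, and vessel
metadata sufficient for the purse split and continuity filter.  It does
not emulate vessel kinematics, AIS message loss or coverage bias,
fleet entry/exit, multi-peak seasonality, or spatially correlated
noise.  Passing recovery tests therefore demonstrates that the pipeline
measures what it claims on data whose generating process is known; it
does not certify the ecological interpretation of any real-data map,
nor reproduce real-data retention percentages, which depend on the
actual satellite dataset.

## Numerical choices and problem sizes

Standard deviations use ddof = 1 everywhere.  SVDs are batched over
cells; explained variance of an all-zero centered matrix is defined as
0 (fails the filter).  Peak-month ties break to the earliest month.
Bilinear interpolation renormalizes over valid raster neighbors.  The
test and acceptance suites run on 24°–30° square domains at 150–600
vessel-days per day — large enough that Poisson relative errors on
monthly totals are well under the tolerances being asserted, and small
enough to keep the full suite under a minute per multi-seed criterion;
the multi-seed recovery checks use 20 seeds.

## Known limitations

The per-cell counting convention (no cross-cell dedup) is a documented
choice, not asserted as the source datasets'; "continually active" is
likewise implemented in its weakest defensible reading.  The holiday
estimator attributes winter deficits wholly to non-fishing days and
cannot distinguish holidays from weather or market effects.  The peak
detector reports a single month and cannot represent bimodal seasons.
The cosine seasonal model has a flat maximum, so under weak amplitude
and strong sampling noise the recovered peak frequently lands on a
neighboring month; exact recovery statistics are therefore quoted for
amplitude ≥ 0.5.
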