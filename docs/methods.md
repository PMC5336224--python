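# Methods

This note documents the models behind `firenet`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a user should know before trusting the output.

## Coordinate and area conventions

All rasters are row-major with 0-based indices. Cell centers sit at
`x = x₀ + (col + 0.5)·Δ`, `y = y₀ + (row + 0.5)·Δ` with `+x` east and
`+y` north; a cell is `Δ²/10⁴` ha, so the default Δ = 100 m makes one
cell one hectare. These conventions are stated once here and used by
every module.

## Synthetic landscape

The tenure map is built by seeded multi-source region growing: parcel
seeds are dropped uniformly, each tenure class owns at least one parcel,
and parcels flood outward in random order, producing contiguous,
irregular ownership blocks. Tenure classes alternate between two fuel
archetypes — forested (base spread rate 4–10 m/min, fireline-intensity
scale 900–2,200 kW/m) and grass/shrub (15–35 m/min, 120–500 kW/m) — so
the landscape reproduces the qualitative contrast between slow-spreading
high-intensity forest fuels and fast-spreading low-intensity rangeland
fuels. Within a tenure, rates get mild lognormal jitter.

Communities are compact core blobs with 1–3 concentric WUI rings;
structure counts are allocated across communities by Dirichlet weights
and within a community core-heavily (60% core), conserving the requested
total exactly. Community cells are relabelled to a dedicated `Community`
tenure on the companion grid used for simulation and accounting.

Daily weather is a seasonal ERC sinusoid (midline 45, amplitude 30,
peak at day 196) plus AR(1) noise (marginal sd 10, lag-1 correlation
0.8), clipped to [0, 100]; gust speeds are lognormal (median 18 km/h,
log-sd 0.5) with uniform direction; dead fuel moisture declines linearly
in ERC (1-h class 0.25 − 0.0022·ERC, floored at 0.03; 10-h and 100-h
offset +0.02/+0.04).

Ignition catalogues are inhomogeneous Poisson draws. Human intensity is
an exponential distance-decay kernel around community cells (e-folding
1,500 m) times a bimodal seasonal weight (spring and fall bumps at days
120 and 290); natural intensity is a smoothed Gaussian random field
times a mid-summer seasonal weight (center day 200, sd 35 d) times an
increasing ERC response `exp(γ·ERC)` with γ = 0.03. Defaults are 291
human and 354 natural ignitions per year — the historical record's
annual counts — and lognormal final sizes with means 26 ha (human) and
22 ha (natural), σ_log = 1. Daily weights are normalized against the
supplied weather series, so configured annual rates are exact expected
counts and realized/expected → 1 as the sample grows.

What the generators do **not** emulate: topography and slope effects,
real fuel-model semantics, spatially varying wind fields, suppression,
and the year-to-year trend structure of a real fire record. Passing
tests therefore demonstrate that the *method* is implemented correctly
and internally consistent under known conditions — not that any
particular real landscape behaves like the synthetic one.

## Ignition prediction system

Occurrence is a logistic GLM of the daily per-pixel fire indicator on a
quadratic tensor basis in grid-normalized (x, y), two periodic
harmonics of day-of-year (continuous across the year boundary), and a
linear ERC term, fitted per cause. Because fire pixel-days are ~10⁻⁶ of
the universe, the model is fitted on all fire pixel-days plus a seeded
10:1 random subsample of non-fire pixel-days; sampling controls with
fraction f shifts the logit by −log f, so the intercept is corrected by
+log f to restore the pixel-day probability scale. The logit separates
into spatial and daily parts, which makes integrated daily intensities
and spatial sampling weights cheap. Newton-Raphson is used (the raw
0–100 ERC scale stalls quasi-Newton solvers); non-convergence raises,
with diagnostics, rather than returning a half-fitted model.

Fire size is OLS of log size on ERC and the spatial basis, restricted
to fires above the 10 ha minimum modelled size; predictions are
lognormal draws around the fitted mean with the residual scale. The
occurrence/size pair is implemented as a two-stage hurdle (fit
occurrence, then size given occurrence) rather than a single joint
model; this is the simplest family consistent with "probability of a
fire" plus "expected size where a fire occurs", and the two stages are
independently testable by parameter recovery.

The burn-period curve is calibrated by controlled simulations: fires are
grown at fixed durations (default 60–960 min) from random burnable
ignitions under sampled weather; the median size per duration is fitted
by log-log least squares to `size = a·Tᵇ` (medians because size
outcomes are right-skewed). The inverse `(S/a)^{1/b}` is strictly
increasing, and on a uniform landscape reproduces the analytic
`T = √(10⁴·S/π)/r` within lattice error.

Fire lists resample one library weather year per season; ignition counts
are Poisson with the model's daily intensity, locations follow the
spatial weights, fuel moisture comes from the ERC-conditional mean
table, and wind comes from the gust subset observed on days with fires
above 500 ha (falling back to the top ERC decile when the catalogue has
too few large-fire days, as small synthetic catalogues usually do).
Sampled sizes below 10 ha are discarded before listing.

## Fire growth

Fire growth is minimum travel time on a lattice graph: Dijkstra from the
ignition cell, edge traversal time = center distance ÷ the mean of the
two endpoint cells' directional rates. The directional rate is an
elliptical wind kernel

    R(θ) = R₀ · m · LB · (1 − ε) / (1 − ε·cos θ),

with length-to-breadth `LB = 1 + 0.25·U` (U in m/s, capped at 8),
eccentricity `ε = √(1 − 1/LB²)`, moisture damping
`m = clip(1 − fm₁/0.35, 0.05, 1)`, and θ the angle between the edge
bearing and the wind vector; the head rate is `R₀·m·LB` and the no-wind
limit is isotropic. Wind direction is the direction the wind blows
*toward*.

Connectivity is 16-neighbor by default: the 8 compass offsets plus the 8
half-step bearings, i.e. the (±2, ±1)-type offsets, which cut the
worst-case angular error of the lattice metric from 22.5° to ~13° (the
no-wind "circle" is recovered within ~3% instead of ~8% at 8-neighbor).
A two-cell edge is traversable only if at least one of the two cells it
straddles is burnable, so a one-cell fuel break still blocks spread.
Ties break on (time, cell index) for determinism; cells with zero base
rate are non-burnable, and an ignition on one yields a flagged
single-cell perimeter. On every small instance the arrival field equals
a brute-force shortest-path oracle to machine precision (a standing
test).

Flame length uses Byram's relation `FL = 0.0775·I^0.46` with
`I = intensity_coeff · (achieved directional rate / base rate)`, i.e.
head runs burn hotter than flanking spread. Burn probability is
reported with two normalizations: the headline annual BP is
(seasons in which the cell burned)/(seasons simulated), which has yr⁻¹
units; the per-fire ratio (burn count)/(fires simulated) is also kept
because both denominators appear in practice. Conditional flame-length
probabilities use twenty 0.5 m bins, bin 20 open-ended above 9.5 m with
its midpoint pinned at 9.75 m; CFL is the probability-weighted midpoint
sum.

## Transmission accounting

Every burned cell is attributed to its tenure (community cells both to
the aggregate `Community` class and to their community id); the fire's
source is its ignition cell's tenure. A hectare is counted once as
incoming to its destination and once as outgoing from its source —
the only reading under which `TotalFire = NonTF + TF-IN` per tenure and
`Σ TF-IN = Σ TF-OUT` hold exactly, and both identities are enforced by
tests at machine precision. Cause (human/natural) is carried through
every tally. At community scale, individual communities replace the
aggregate class to avoid double counting. Structure exposure per
polygon is (fraction of polygon burned) × (polygon structure count),
summed by community; one fire can expose several communities.

## Networks

Edges are strict threshold exceedances (`M[i][j] > min_edge`, defaults
20 ha/yr at tenure scale, 10 at community scale, with a 1 ha/yr
"dashed" band available); self-loops are excluded — non-transmitted
fire is reported separately, not as an edge. Density is `E/(N(N−1))`
over the full node set including isolates. Centrality is exposed as
weighted out-strength, the simplest weight-sum index, and labelled as
such.

## Firesheds

The exposure indicator (fire exposed ≥1 structure in community c) is
kriged by ordinary kriging of the 0/1 outcome with predictions clipped
to [0, 1]. "Logistic/indicator" kriging variants differ mainly in link
machinery; clipped ordinary kriging reproduces the required behaviour
(values in [0, 1], exact interpolation at zero nugget) without extra
assumptions. Variograms (exponential by default, spherical available)
are fitted to binned empirical semivariances by least squares weighted
by pair counts; γ(0) = 0 exactly, the nugget being the jump just above
zero lag. Degenerate inputs (constant indicators, failed fits) fall
back to a flagged pure-nugget model, and the kriged surface then
degenerates to the indicator mean. Kriging uses the 16 nearest points
per cell; a singular system falls back to inverse-distance weights for
that cell and logs it.

Firesheds are `surface ≥ 0.1` masked by ignition density
≥ 1.5×10⁻⁴ km⁻² (both comparisons inclusive), with the density
estimated by Gaussian kernel smoothing of per-cell ignition counts
(bandwidth = 5 cells). The mask is applied after kriging/thresholding;
whether the original procedure masked before or after is not decisive
for any identity we compute, and masking last keeps the surface itself
threshold-free. The combined fireshed is the union of per-community
masks; composition, overlap fraction (share of union cells in ≥2
firesheds), ratio to developed area, and transmission efficiency
(structures/yr per 1,000 ha of fireshed in a tenure) are computed from
the masks and the tenure map.

## Pipeline scale and defaults

The end-to-end default is a 100×100-cell (10⁴ ha) landscape, 18 years of
catalogue weather, and 200 simulated fire seasons — a deliberately
scaled-down study area that a laptop runs in about a minute. At that
extent the historical annual ignition counts (291 human/354 natural,
which belong to a ~3.3 Mha region) would saturate the grid, so the
pipeline default scales them to 12/15 per year: enough records over 18
years to fit both occurrence models (≥100 per cause) while keeping fire
density plausible. The catalogue generator itself keeps the full
historical defaults, since it emulates the historical record; the
historical record also prints a total (16,061 ha/yr) that disagrees
slightly with its own components (7,877 + 7,184 ha/yr) — the generators
target the component values.

## Known limitations

Fire behaviour is a stylized elliptical-kernel MTT, not a fuel-model
fire behaviour system: crown fire, spotting, slope and suppression are
out of scope, and `intensity_coeff` is a free per-cell scale rather
than a fuel-model output. The occurrence model's quadratic spatial
basis cannot represent fine spatial structure in ignition risk; with a
rough true field the integrated intensity can be mildly biased (a few
percent in tests). Single-realization variogram estimation is noisy
when the range is not small relative to the domain — parameter-recovery
tolerances reflect that. GeoTIFF output carries georeferencing in a
JSON sidecar rather than embedded tags.
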