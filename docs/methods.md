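# Methods

This note documents the model, the synthetic study conditions, the
numerical choices, and the known limitations of `branchcarbon`. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Carbon-balance model

The pipeline estimates the carbon cost-benefit balance of individual
branches from four ingredients: a photosynthetic light-response curve
(LRC), a continuous light record at the branch, an air-temperature record,
and the branch's morphology and chemistry.

**Light response.** Net photosynthesis is modelled as a saturating
exponential in PPFD,

    P_N(I) = Pgmax (1 − e^(−ϕ(I0) I / Pgmax)) − Rd,

which is linear with slope ϕ(I0) near darkness and approaches
`Pgmax − Rd` under saturating light. `Rd` is stored as a positive
magnitude and subtracted, which removes a family of sign-convention bugs.
Units throughout: µmol CO₂ m⁻² s⁻¹ for rates, µmol photons m⁻² s⁻¹ for
light.

**Fitting.** Each curve is fitted on its own (no pooling across curves;
aggregation happens later on derived series). The optimizer is scipy's
trust-region-reflective nonlinear least squares with analytic residuals,
tolerances 1e-12, and bounds Pgmax ∈ (0, 100], Rd ∈ [0, 20],
ϕ(I0) ∈ (0, 0.2] — a generous physiological envelope that keeps the search
away from degenerate regions. Starting values: Rd₀ = −min(P_N),
Pgmax₀ = max(P_N) + Rd₀, ϕ₀ = slope of the two lowest-light points. Fits
with fewer than 3 observations, or all observations at one light level, are
rejected; optimizer non-convergence is reported via a `converged` flag on
the result, never silently. A scale equivariance holds by construction
(multiplying all P_N by c scales all three parameters by c) and is tested.

Under observation noise, the information content of a standard 8-level
curve design bounds how well each parameter can be recovered: the
asymptote (Pgmax) is pinned by several saturated levels, while Rd is
essentially an intercept seen by only the few lowest levels. The
Monte-Carlo recovery study in the acceptance script quantifies this
(median relative errors per parameter at noise sd 0.3).

**Temperature corrections.** Photosynthesis is multiplied by a
piecewise-linear factor: 0 at and below −2 °C, rising to 1 at 10 °C, flat
to 30 °C, falling to 0 at 42 °C. Respiration is corrected independently by
the exponential Q10 law with Q10 = 2. The reference temperature for Rd is
25 °C — the cuvette setpoint of the gas-exchange measurements, which is
the only defensible anchor; it is configurable. The same temperature
series is used for both crown positions (vertical temperature gradients
within a crown are small relative to the light gradient). Hourly
temperature is applied as a step function to the four 15-min light steps
of each hour; interpolation would change sub-daily values slightly but
cannot change any of the structural identities (and alternative
temperature responses alter A_N without touching the amortisation/RCC
machinery).

**Daily integration.** Net 15-min rates are summed per calendar day as
Σ net × 900 s × 12e-6 g µmol⁻¹, giving A_N in g C m⁻² d⁻¹; winter days are
legitimately negative. Only complete days enter: partial days at series
edges, or days invalidated by logger gaps longer than 2 consecutive steps
(shorter gaps are linearly infilled), are dropped with a warning —
amortisation counts whole days, so fabricating partial-day sums would bias
day counts. Per species and crown position, the daily series of every
fitted curve × light logger are averaged pointwise into one mean A_N.

**Costs, amortisation, RCC.** Carbon cost = dry mass × C fraction, for
foliage (C_F) and current-year twig wood+bark (C_T). Respiration costs of
biosynthesis are deliberately excluded (bulk carbon is tightly proportional
to construction cost, and the comparison of interest is sun vs shade).
Amortisation starts at 50% budbreak with day 1 = the budbreak date, and is
the smallest whole-day count whose cumulative A_Branch meets the cost — no
sub-day interpolation, matching the integer-day convention of the
measurement design. Evergreen series may loop from 31 December back to
1 January of the same annual series, at most `max_loops` (10) times;
branches that never amortise are flagged rather than looped forever. RCC =
100 × cost / lifetime uptake, where the deciduous lifetime window is
budbreak → discoloration *inclusive of both endpoints* (documented
convention, tested), and the evergreen window is `lifespan_years` annual
cycles of the looped series starting at budbreak. For a periodic annual
series this denominator is exactly lifespan × annual sum — one consequence,
worth knowing, is that evergreen RCC is invariant to the budbreak date, so
the season-length sensitivity factor is exactly zero for evergreens under
this convention. The alternative (loop only the post-budbreak remainder in
year 1) was considered and rejected as it makes the final partial year
ill-defined.

**Sensitivity analysis.** Eight factors are replaced one at a time with
sun-crown values and the whole pipeline is re-run (no shortcut formulas):
incident light (series swap), Pgmax / Rd / ϕ(I0) (single-parameter swaps),
SLA, LA:BDW, tissue C (both fractions), season length (phenology window;
evergreens swap only budbreak since they have no season end). The two
morphology ratios need a convention for what is held fixed, which the
measurement alone does not dictate: SLA replacement holds *leaf dry mass*
fixed and rescales leaf area (area = mass × SLA_sun), leaving twig mass
untouched; LA:BDW replacement holds *leaf area* fixed and rescales twig
mass (mass = area / LA:BDW_sun). Replacements operate on species ×
position mean inputs, consistent with the averaging used by the RCC
calculation itself.

**Starch build-up.** Build-up carbon = seasonal concentration amplitude
(minimum-to-maximum, g starch g⁻¹ dry mass) × tissue dry mass × 0.4 (the C
fraction of starch). Conifers store in 1-year-old needles (their mass and
area are carried separately on the records for exactly this purpose);
broadleaves store in 3–5-year-old wood, so the measured current-year twig
mass is upscaled by Biomass₅ = Biomass₁ × Σ_{i=1..5} i/2^(i−1) =
3.5625 × Biomass₁, assuming constant annual biomass increment and on
average two new shoots per parent shoot. Both the years (5) and the
shoots-per-parent (2) generalize as configuration knobs (Σ i/s^(i−1)); the
same branching structure is assumed for sun and shade branches. The
relative cost divides build-up carbon by branch uptake over the build-up
window (endpoints inclusive); a window with non-positive uptake is flagged
and reported with its sign, not clipped. For the conifer pre-budbreak
window the assimilating leaf area is that of the 1-year-old needles, and
the annual series is treated as the previous-year equivalent (the window
lies within the same calendar year, before budbreak).

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes, not
any particular site's weather. All defaults were chosen once, from the
study conditions, and define the scenario every test and the acceptance
script runs on.

* **Light** — deterministic clear-sky envelope: half-sine diurnal course
  with day length varying sinusoidally over the year (amplitude from the
  sunrise equation at the configured latitude, default 47.4° N), seasonal
  peak PPFD 350 → 1800 µmol m⁻² s⁻¹, times a random daily cloud
  transmission exp(−τ), τ ~ Exponential(1) (mean transmission 0.5 —
  realistic for a temperate, moderately cloudy site; scale 0 disables
  clouds). Shade = RI × sun × log-normal mean-one step noise (σ = 0.1
  default, 0 gives an exact ratio). Night values are exactly zero; series
  have exactly 35,040 (35,136 in leap years) 15-min steps.
* **Temperature** — hourly; mean 9.6 °C (the site climatology the analysis
  is anchored to), seasonal amplitude 9.5 °C (coldest late January),
  diurnal amplitude 4 °C peaking at 15:00, AR(1) noise (ρ = 0.9,
  stationary sd 1.2 °C).
* **Gas exchange** — 2 curves per species × position, 8 light levels
  0–1500, Gaussian noise sd 0.3 µmol m⁻² s⁻¹; true parameters are retained
  for recovery tests.
* **Crown contrasts** (demo scenario): broadleaf RI 0.30 with sun/shade
  Pgmax 11/8, Rd 1.2/0.6, ϕ(I0) 0.045/0.055, SLA 0.009/0.020 m² g⁻¹
  (LMA ≈ 110/50 g m⁻²), season days 115–291 with the shade season 6 days
  shorter; conifer RI 0.25, 5-year needle lifespan, Pgmax 6.5/4.5,
  SLA 0.004/0.007, budbreak day 130 (shade +4). Starch amplitudes
  0.02 g g⁻¹ (broadleaf wood, build-up in the 60 days after budbreak) and
  0.12 g g⁻¹ (conifer needles, build-up in the 50 days before budbreak).
* **Branch records** — 3 trees per species; tree-level log-normal size
  factors (σ = 0.15) are *shared* between the paired sun and shade records
  of a tree, so a zero-contrast configuration yields exactly identical
  pairs (the null the sensitivity analysis is tested against).

All randomness flows from the single scenario seed through named
`SeedSequence` streams (cloud, shade noise, temperature, gas exchange,
branches), so each generator is individually reproducible, regeneration is
bit-identical, and pipeline outputs are byte-identical across reruns.

What the generator does **not** emulate: sunflecks and sub-15-min light
variability, radiative-transfer canopy structure, VPD or drought limitation
of photosynthesis, between-tree trait variance beyond the size factors, and
inter-annual transfer (starch and assimilation are always computed within
one scenario year). Passing tests therefore demonstrate the correctness of
the accounting on data with the assumed structure — not that real crowns
obey those assumptions.

## Numerical choices and degenerate inputs

* Day counting is integer and conservative: costs landing exactly on a
  cumulative day boundary are met on that day; any positive increment
  pushes to the next day.
* The amortisation and looping scans are vectorized cumulative sums,
  checked integer-exactly against an independent day-by-day oracle over
  randomized scenarios (including negative winter days and year wraps).
* RCC and starch percentages with non-positive denominators return NaN
  plus a flag; they are never clipped or silently dropped.
* CSV round-trips are exact: floats are written at shortest-repr precision
  and read with round-trip parsing; timestamps are ISO-8601.
* Temperature multiplier and Q10 law are evaluated in closed form; anchor
  values at −2, 10, 30, 42 °C are exact by construction.
* The problem sizes used by the test suite and acceptance script — one
  scenario year at 15-min resolution, 2 species × 2 positions × 3 trees,
  200 Monte-Carlo fit replicates, 100 randomized amortisation scenarios —
  were chosen so a full run completes in seconds while every code path
  (looping, flags, averaging, all eight factors) is exercised.

## Known limitations

* The carbon cost is bulk tissue carbon; biosynthesis respiration
  (≈ 25% of accumulated carbon) is excluded by design, so absolute RCCs
  are underestimates while sun/shade *differences* are preserved.
* Evergreen RCC is insensitive to phenology under the periodic-lifespan
  convention (see above); conclusions about the season-length factor apply
  only to deciduous species.
* The sensitivity analysis reports point responses of mean inputs;
  confidence intervals would require resampling over trees, which the
  synthetic scenario's 3 trees per species cannot meaningfully support.
* Needle lifespans enter as fixed integers per species; position-dependent
  lifespans (shade needles often live longer) are not modelled.
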