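# branchcarbon

Branch-level carbon balance of sun and shade branches in tree crowns.

Within a tree crown, light drops steeply from top to bottom — shaded lower
branches typically receive only 5–40% of the irradiance of the upper crown.
Whether that energy gradient translates into a worse carbon economy for
shade branches depends on how far shade acclimation (thinner leaves, lower
respiration, higher quantum yield, later phenology) compensates for the
lower light. `branchcarbon` implements the full accounting needed to answer
that question at the branch level: it turns continuous light records and
gas-exchange measurements into daily carbon assimilation, relates the
carbon invested in a year's new leaves and twigs to that assimilation, and
quantifies which traits matter via a factor-replacement sensitivity
analysis. A synthetic-data module generates complete study scenarios with
known ground truth, so every stage of the pipeline is testable end to end.

Intended users: plant ecophysiologists and carbon-balance modellers working
with canopy light gradients, leaf economics, or branch autonomy.

## The model

**Light response.** Net photosynthesis follows a saturating exponential
light-response curve (LRC):

    P_N(I) = Pgmax · (1 − exp(−ϕ(I0) · I / Pgmax)) − Rd

with `I` the photosynthetic photon flux density (PPFD, µmol photons
m⁻² s⁻¹), `Pgmax` the maximum gross assimilation rate, `Rd` the dark
respiration rate, and `ϕ(I0)` the quantum yield at zero light. Each
measured curve is fitted individually by nonlinear least squares.
Logger illuminance converts as PPFD = lux / 120.

**Temperature correction.** Gross photosynthesis `Pg = P_N + Rd` is scaled
by a piecewise-linear factor with a broad optimum (1.0 between 10 and
30 °C, falling to zero at −2 and +42 °C); respiration follows a Q10 law
with Q10 = 2 about the 25 °C measurement reference.

**Daily assimilation.** Corrected 15-min net rates are summed over each day
and converted with the molar mass of carbon (12 g mol⁻¹) to daily net
assimilation per unit leaf area, `A_N` (g C m⁻² d⁻¹); multiplying by branch
leaf area gives whole-branch assimilation `A_Branch`.

**Costs and pay-back.** The carbon cost of a tissue is dry mass × carbon
fraction (foliage `C_F`, current-year twig `C_T`). The *amortisation time*
is the number of days from 50% budbreak until cumulative `A_Branch` reaches
the cost (evergreen series loop past 31 December). The *relative carbon
cost* (RCC) expresses a cost as a percentage of cumulative `A_Branch` over
the foliage lifespan — budbreak to 50% discoloration for deciduous species,
or `lifespan_years` annual cycles for evergreen conifers.

**Sensitivity.** Eight factors of the shade-branch RCC calculation
(incident light, Pgmax, Rd, ϕ(I0), SLA, LA:BDW, tissue C, season length)
are replaced one at a time by their sun-crown values and the pipeline is
re-run, reporting the relative RCC change per factor.

**Starch build-up.** The carbon bound in the seasonal starch build-up is
amplitude × tissue mass × 0.4 (the C fraction of starch); for broadleaves
the current-year twig mass is upscaled to the 5-year-old storing branch by
the branching-structure factor Σᵢ i/2^(i−1) = 3.5625. The build-up carbon is
expressed as a percentage of branch assimilation during the build-up window
(pre-budbreak for conifers, early season for broadleaves).

## Worked example

```bash
branchcarbon run-all --seed 1 --out demo
```

```
run complete: 12 branches evaluated -> demo
                    total_amortisation_days  total_rcc_pct
species   position
broadleaf shade                       16.67          11.45
          sun                         21.33          13.54
conifer   shade                       68.33           6.92
          sun                         70.33           6.57
```

The demo scenario pairs a beech-like deciduous broadleaf (relative
irradiance 0.30 in the shade crown, ~176-day season) with a spruce-like
evergreen conifer (RI 0.25, 5-year needle lifespan). A sun broadleaf branch
pays back its full construction cost (leaves + twig) in about three weeks
of assimilation and invests ~14% of its lifetime uptake in construction;
its shade counterpart, despite receiving 30% of the light, lands at ~11% —
the classic result that shade acclimation (here mainly doubled SLA and
halved Rd) keeps the *relative* carbon economy of shade branches on par
with sun branches. The conifer amortises more slowly (needles are heavier
per unit area) but spreads the cost over a 5-year needle lifespan, giving
the lowest RCC of all.

The same run writes all stage tables to `demo/`: fitted LRC parameters
(`lrc_params.csv`), daily assimilation (`a_n_daily.csv`), per-branch costs
(`branch_costs.csv`), the sensitivity analysis (`sensitivity.csv`), starch
costs (`starch_costs.csv`) and a reproducibility manifest
(`manifest.yaml`). The library API mirrors the CLI:

```python
from branchcarbon import demo_scenario, run_pipeline
result = run_pipeline(demo_scenario(seed=1), "demo")
print(result["sensitivity"].head(3))
```

```
     species          factor  rcc_initial  rcc_replaced  rel_change
0  broadleaf  incident_light    11.446499      7.211464   -0.369985
1  broadleaf           pgmax    11.446499      9.644054   -0.157468
2  broadleaf              rd    11.446499     13.479962    0.177659
```

Replacing the shade branch's incident light with the sun series lowers its
RCC by 37%; replacing its (low) dark respiration with the sun value raises
RCC by 18% — light is the dominant driver, and low-light traits are the
main compensators.

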