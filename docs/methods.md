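# Methods

## The two analyses

**Static cascades.** The food web is a directed graph with consumer→resource
edges; basal species (benthic producers and the plankton node) have no
resources of their own. The cascade rule is purely bottom-up: after a
primary removal, a non-basal species with no surviving resource is extinct,
iterated to the least fixed point. Basal species obtain energy from outside
the trophic links (photosynthesis, or advected subsidy for plankton) and
never starve; the fisheries node is bookkeeping, never removable and never a
cascade victim. `run_static_sequence` replays an entire deletion order
incrementally — each link is visited once over the whole sequence — and the
unit suite checks it against the `cascade` operator applied from scratch to
every prefix, which is itself checked against an independent
greatest-fixpoint oracle on a thousand random webs.

**R50.** The robustness of a deletion order is the fraction of species that
must be primarily removed before total losses (primary + secondary) reach
half the web. The crossing threshold is floor(S/2), at least one, which
makes the theoretical bounds exact for every web size: a cascade-free web
scores floor(S/2)/S ≤ 0.5, and a single catastrophic removal scores 1/S.
If a sequence ends before the crossing (the landings-ordered sequence stops
after the harvested species), R50 is reported as undefined rather than
extrapolated.

**Bioenergetic dynamics.** Biomasses follow the allometric trophic-network
equations. Producers: dB_i/dt = r_i B_i G_i(B) − Σ_j x_j y_j B_j F_ji/e_ji −
F_max,i B_i, with logistic term G_i = 1 − (Σ_{j∈producers} c_ij B_j)/K;
consumers: dB_i/dt = f_a x_i y_i B_i Σ_j F_ij − f_m x_i B_i − predation −
F_max,i B_i; the plankton node obeys the producer equation plus a constant
inflow *s*. The functional response is Hill-type with exponent q = 1.2
(between type II and III) and Beddington–DeAngelis-style intraspecific
interference d_i in the denominator. Mass-specific rates scale as M^−1/4 and
are normalised by the growth rate of the reference producer (the smallest,
hence fastest-growing, producer), so one time unit is a day on that
producer's timescale; ten simulated years = 3650 days. Competition among
producers is fully shared (c ≡ 1): K is a community-level carrying capacity,
so the plankton standing stock competes with the benthic producers for it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| a_x/a_r | 0.314 | metabolic/growth allometric ratio (invertebrate-dominated webs) |
| y = a_y/a_x | 8 | maximum consumption relative to metabolism, identical for all consumers |
| q | 1.2 | Hill exponent of the functional response |
| e | 0.85 / 0.45 | assimilation efficiency, carnivory / herbivory |
| f_a, f_m | 0.4, 0.1 | assimilated fraction of intake; maintenance fraction |
| B0 | 0.5 | half-saturation biomass per link |
| d | 0 (library), 1 (generator) | consumer interference |
| K | one biomass unit per producer | shared producer carrying capacity |
| extinction threshold | 10⁻⁶ | biomass below which a species is removed |

All are overridable per run (YAML parameter file) and per link
(`consumer,resource,field,value` CSV).

## Numerical choices

Integration uses `scipy.solve_ivp` with LSODA at rtol 1e-7 / atol 1e-10.
The subsidised system is stiff — plankton turns over in days while apex
predators have metabolic rates of order 10⁻²/day — and the
Adams/BDF-switching integrator is an order of magnitude faster than
explicit Runge–Kutta 4(5) at indistinguishable trajectories (both remain
available through the `method` argument; the small-fixture oracles agree to
better than 10⁻⁶). The 10⁻⁶ extinction threshold is enforced by a terminal
event: integration stops at the crossing, the species is clamped to zero
and excluded from the dynamics, and the run resumes. Clamping without event
detection would make extinction times step-size dependent. If an event
fires without any species at the threshold (numerical grazing), the minimum
species is retired to guarantee progress. `equilibrate` reports, but does
not enforce, stationarity (max |dB/dt|/B < 10⁻⁶/day): apex predators relax
on timescales longer than one ten-year window, which is why a null
perturbation cell can still show residual drifts of a few percent.

**Fishing calibration.** The F_max vector that reduces every harvested
species by a target percentage is a coupled 22-dimensional root-finding
problem: fishing a consumer releases its prey, and fishing a basal species
releases its competitors, so per-species root finders working independently
stall. `calibrate_fmax` solves it as a damped proportional fixed point:
one whole-web equilibration per iteration, after which every rate is scaled
by (achieved/target)^0.6 — biomass still above target means fish harder —
with the exponent halved whenever the worst error grows (strong fishing can
overshoot into a flipped community state and oscillate). Tolerance is 1%
relative on each species' equilibrium biomass; on the one-producer fixture
the result matches the logistic-harvest closed form F = rρ. A −100% target
means reduction to 1% of baseline, not extinction: fishing removes a
fraction of the biomass produced each day, so a fully exploited stock can
persist at low abundance.

Scenario protocol: relax ten years to the unperturbed equilibrium
("before"), switch on F_max and/or rescale the subsidy as a step change,
relax ten further years ("after"), report per-species percentage changes
(−100 exactly for extinctions) and biomass-weighted totals per trophic
category split by harvested status. The factorial design calibrates F_max
once per fishing level at the unperturbed subsidy — a fishery whose effort
is set under present-day productivity — and reuses it across that row.

## The synthetic generator

`synth.generate_web` emulates the studied system's architecture so the
full pipeline is testable without external data: niche-model topology
(interval diets, realistic omnivory and generalism) at a target
connectance, then structural edits — 44% of species made basal, one basal
node designated plankton whose only consumers are a clique of specialist
filter-feeders, strict-carnivore and apex guilds at the top of the niche
axis with basal diet items pruned, strict herbivores just above the basal
level, body masses increasing ~100× per trophic level with lognormal
scatter, a stratified harvested set (macroalgae through carnivores, catch
ranks permuted), and a fisheries node linked to every harvested species.
The default spec lands on 107 nodes and 1381 links including the fisheries
node's 22.

The generator's dynamic defaults are chosen so that every species is
viable at the unperturbed equilibrium, as in the studied system: consumer
interference d = 1 (sessile space competition and predator interference are
strong in rocky-shore communities, and without interference the web is
top-heavy and unstable), filter-feeder half-saturation on plankton 0.05
(suspension feeders capture dilute prey), and subsidy s = 5 per day, an
order of magnitude above one producer's share of local production —
benthic communities under upwelling are heavily subsidised. Two structural
guarantees matter dynamically: every filter-feeder has at least one
predator (otherwise an invulnerable filter-feeder monopolises the entire
subsidy flux), and every consumer has a food chain to the basal level.

**What the emulation does and does not show.** It reproduces the
architecture (counts, guild structure, degree of the fisheries node) and
the qualitative dynamic regime: zero secondary extinctions from removing
all harvested species, the plankton node as the single most damaging
deletion, subsidy removal starving the filter-feeder guild, fishing
releasing non-harvested species. Quantitative percentages (category-level
biomass responses, extinction thresholds per unit extraction) depend on
the per-link coefficients of the original study system and are reported
as this package computes them, not as estimates of the empirical values.
Passing tests therefore validate the machinery and the mechanism, not the
field-measured magnitudes.

## Known limitations

- No prey switching or rewiring: preferences ω are fixed; a consumer whose
  preferred resources die does not re-normalise onto survivors.
- No temperature dependence, recruitment, spatial structure or non-trophic
  interactions (facilitation, habitat provision).
- Shared carrying capacity with c ≡ 1 admits slow competitive exclusion
  among producers; on some generated webs a producer is still declining
  after ten years, which shows up as small drifts in null scenarios.
- The supporting-basal deletion score (degree × (1 + summed consumer
  degree), basal-first on ties) yields the fastest collapse among the
  implemented sequences but is one operationalisation of "connected
  species that support connected species"; dominator-tree formulations
  would rank differently.
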