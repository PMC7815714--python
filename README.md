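# coastweb

Robustness and dynamics of a harvested, subsidised coastal food web.

Artisanal fisheries act on rocky-shore communities as a top-down force,
removing biomass from species at every trophic level, while climate-driven
changes in nearshore plankton productivity alter the bottom-up energy
supply that sessile filter-feeders pump into the benthos. `coastweb`
implements the two complementary analyses used to study how these forces
interact in a ~107-node intertidal food web:

1. **Static extinction cascades.** The web is a directed consumer→resource
   graph. After removing a set of species, any non-basal species whose
   resources are all gone starves (a *secondary extinction*); the rule is
   iterated to a fixed point. Ordered deletion sequences (by landings, at
   random, most-connected-first, supporting-basal-first) are summarised by
   the robustness index **R50** — the fraction of species that must be
   removed before half the web is lost, bounded by 1/S and 0.5.

2. **Bioenergetic (ATN) dynamics.** Each species carries a biomass B_i
   governed by allometrically scaled rates (r, x, y ∝ M^−1/4, normalised to
   the fastest-growing producer): producers grow logistically under a shared
   community carrying capacity K; consumers feed through a Hill-type
   functional response F_ij = ω_ij B_j^q / (B0_ij^q + d_i B_i B0_ij +
   Σ_l ω_il B_l^q) with q = 1.2; the plankton node receives a constant
   external subsidy *s*; harvested species suffer a fisheries mortality
   F_max,i B_i. A species whose biomass drops below 10⁻⁶ is extinct and
   removed from the dynamics. Fishing levels are expressed as target biomass
   reductions (−50 / −80 / −100%) and the F_max vector achieving them is
   calibrated against the model itself; subsidy scenarios rescale *s* by
   ±50/80/100%; a full fishing × subsidy factorial crosses both.

A niche-model-based generator (`coastweb.synth`) reproduces the studied
architecture — 44% basal species, one plankton node consumed only by a
clique of 15 specialist filter-feeders, 22 harvested species with catch
ranks, a fisheries node linked to all of them — so the entire pipeline runs
without any external data.

## Worked example

```python
from coastweb import *
from coastweb.synth import SynthSpec, generate_web

web, params = generate_web(SynthSpec(seed=1))
m = structural_metrics(web)
print(m.S, m.L, m.degree[web.fisheries])   # 107 1381 22

# static: the plankton node is the most damaging single deletion
print(len(cascade(web, {"plankton"})))     # 15  (every filter-feeder starves)
print(run_static_sequence(web, harvesting_order(web)).cumulative_secondary[-1])  # 0

# dynamic: relax ten years, then remove the subsidy entirely
baseline = equilibrate(params, default_initial_biomass(params, seed=1))
res = run_scenario(web, params, ScenarioSpec(0.0, -100.0, seed=1), baseline=baseline)
print(len(res.extinct))                    # 16  (all 15 filter-feeders + plankton)
```

Removing all 22 harvested species costs 43.7% of the web's links — about 89
more than expected from deleting 22 random species — yet triggers **zero**
secondary extinctions in either approach: the harvested species sit in
highly redundant trophic positions. The same web is far more sensitive to
the bottom-up channel: cutting the plankton subsidy starves the specialist
filter-feeder guild outright.

The same pipeline is scriptable from the shell:

```sh
coastweb synth --s 106 --seed 1 --out web/
coastweb robustness --edges web/edges.csv --nodes web/nodes.csv \
    --mode static --sequence most-connected --seed 1 --out out/
coastweb scenario --edges web/edges.csv --nodes web/nodes.csv \
    --fishing 50 --subsidy -80 --params web/params.yaml \
    --overrides web/overrides.csv --seed 1 --out out/
```

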