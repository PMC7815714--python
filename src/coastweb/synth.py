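"""Synthetic food webs emulating a subsidised coastal intertidal system.

Topology comes from the niche model (interval diets, realistic omnivory
and generalism), then is edited to reproduce the architecture of the
study system: a large basal level (~44% of species), a single plankton
node whose only consumers are a clique of specialist filter-feeders, a
set of harvested species spanning macroalgae to carnivores with catch
ranks, and a highly omnivorous fisheries node linked to every harvested
species.  Body masses increase with trophic level, so allometric rates
decrease up the web.  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atn import ATNParams, params_from_web
from .foodweb import FoodWeb, short_weighted_trophic_level


@dataclass
class SynthSpec:
    """Generator settings.

    ``S`` counts ecological species (the fisheries node is added on
    top); ``C`` is the target connectance of the ecological web;
    ``mass_ratio`` is the mean consumer/resource body-mass ratio per
    trophic level.  Defaults emulate the studied intertidal web: ~107
    nodes including fisheries, connectance ~0.12, 15 filter-feeders and
    22 harvested species.
    """

    S: int = 106
    C: float = 0.12095  # ~1359 ecological links; 1381 in total with the fisheries node
    n_filter_feeders: int = 15
    n_harvested: int = 22
    n_carnivores: int = 8
    n_top_predators: int = 7
    n_herbivores: int = 8
    mass_ratio: float = 100.0
    producer_fraction: float = 0.44
    subsidy: float = 5.0  # plankton inflow per day, ~an order above benthic production
    interference: float = 1.0  # Beddington–DeAngelis consumer interference
    b0_plankton: float = 0.05  # filter-feeders capture dilute suspended plankton
    seed: int = 0

    @classmethod
    def scaled(cls, S: int = 106, C: float = 0.12095, seed: int = 0, **kw) -> "SynthSpec":
        """Spec with guild quotas scaled proportionally from the default architecture."""
        f = S / 106

        def n(x: int) -> int:
            return max(1, int(round(x * f)))

        return cls(
            S=S,
            C=C,
            seed=seed,
            n_filter_feeders=n(15),
            n_harvested=min(n(22), S - 1),
            n_carnivores=n(8),
            n_top_predators=n(7),
            n_herbivores=n(8),
            **kw,
        )

    def validate(self) -> None:
        if self.S < 5:
            raise ValueError("S must be at least 5")
        if not 0 < self.C < 0.5:
            raise ValueError("C must lie in (0, 0.5)")
        if self.n_filter_feeders < 1:
            raise ValueError("need at least one filter-feeder")
        if self.n_harvested >= self.S:
            raise ValueError("n_harvested must be smaller than S")
        n_basal = int(round(self.producer_fraction * self.S))
        n_special = (
            self.n_filter_feeders
            + self.n_carnivores
            + self.n_top_predators
            + self.n_herbivores
        )
        if n_special > self.S - n_basal - 1:
            raise ValueError("filter-feeder/carnivore quotas exceed the consumer pool")
        if round(self.C * self.S**2) < self.S - n_basal:
            raise ValueError(f"connectance C={self.C} unreachable at S={self.S}")


# stratification of the harvested set over categories, mirroring the
# studied fishery's landings: macroalgae 7, filter-feeders 2, herbivores 1,
# omnivores 10, carnivores 2 (of 22)
_HARVEST_WEIGHTS = {
    "producer": 7,
    "filter-feeder": 2,
    "herbivore": 1,
    "omnivore": 10,
    "carnivore": 2,
}


def _niche_model(S: int, C: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Classic niche-model directed web; edge (i, j) means i eats j."""
    beta = 1.0 / (2.0 * C) - 1.0
    n = np.sort(rng.uniform(0, 1, size=S))
    ranges = n * rng.beta(1.0, beta, size=S)
    ranges[0] = 0.0  # smallest-niche species is basal
    centers = np.array([rng.uniform(r / 2, min(ni, 1 - r / 2)) for ni, r in zip(n, ranges)])
    edges = []
    for i in range(S):
        lo, hi = centers[i] - ranges[i] / 2, centers[i] + ranges[i] / 2
        for j in range(S):
            if lo <= n[j] <= hi:
                edges.append((i, j))
    return edges


def generate_web(spec: SynthSpec) -> tuple[FoodWeb, ATNParams]:
    """Generate a food web plus default ATN parameters from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    S = spec.S
    n_basal = int(round(spec.producer_fraction * S))
    target_L = int(round(spec.C * S**2))

    edges = set(_niche_model(S, spec.C, rng))
    # role reassignment: the lowest-niche block is the basal level
    basal = set(range(n_basal))
    edges = {(c, r) for c, r in edges if c not in basal}
    plankton = 0

    # filter-feeders: specialist consumers of the plankton node only,
    # drawn from the low-niche half of the consumer pool (sessile grazers
    # of suspended matter sit low in the web)
    consumers = [i for i in range(S) if i not in basal]
    low_half = consumers[: max(len(consumers) * 2 // 3, spec.n_filter_feeders)]
    ff = set(rng.choice(low_half, size=spec.n_filter_feeders, replace=False).tolist())
    edges = {(c, r) for c, r in edges if c not in ff and r != plankton}
    edges |= {(f, plankton) for f in ff}

    # strict carnivores and apex predators occupy the top of the niche
    # axis: their basal diet items are pruned (they eat animals only),
    # and nothing eats an apex predator
    upper = [c for c in reversed(consumers) if c not in ff]
    top_pred = set(upper[: spec.n_top_predators])
    carnivore = set(upper[spec.n_top_predators : spec.n_top_predators + spec.n_carnivores])
    strict = top_pred | carnivore
    edges = {(c, r) for c, r in edges if not (c in strict and r in basal)}
    edges = {(c, r) for c, r in edges if r not in top_pred}

    # strict herbivores graze the benthic producers just above the basal level
    lower = [c for c in consumers if c not in ff and c not in strict]
    herb = set(lower[: spec.n_herbivores])
    edges = {(c, r) for c, r in edges if not (c in herb and r not in basal)}

    def _resources(e):
        res = {i: set() for i in range(S)}
        for c, r in e:
            res[c].add(r)
        return res

    # every consumer needs a resource: herbivores/omnivores fall back on a
    # benthic producer, strict carnivores on a filter-feeder
    res = _resources(edges)
    benthic = sorted(basal - {plankton})
    ff_list = sorted(ff)
    for c in consumers:
        if c not in ff and not (res[c] - {c}):
            pool = ff_list if c in strict else benthic
            edges.add((c, int(rng.choice(pool))))

    # guarantee a food chain to the basal level (break consumer-only cycles)
    def _reaches_basal(e):
        res = _resources(e)
        reach = set(basal)
        changed = True
        while changed:
            changed = False
            for c in consumers:
                if c not in reach and res[c] & reach:
                    reach.add(c)
                    changed = True
        return reach

    reach = _reaches_basal(edges)
    for c in consumers:
        if c not in reach:
            pool = ff_list if c in strict else benthic
            edges.add((c, int(rng.choice(pool))))

    # nudge the ecological link count onto the target connectance,
    # respecting filter-feeder specialism, strict carnivory and apexhood
    non_ff = [c for c in consumers if c not in ff]
    res = _resources(edges)
    guard = 0
    while len(edges) != target_L and guard < 20 * target_L:
        guard += 1
        if len(edges) < target_L:
            c = int(rng.choice(non_ff))
            r = int(rng.integers(0, S))
            if (
                r != plankton
                and r not in top_pred
                and r not in res[c]
                and (r in basal or r < c)
                and not (c in strict and r in basal)
                and not (c in herb and r not in basal)
            ):
                edges.add((c, r))
                res[c].add(r)
        else:
            c = int(rng.choice(non_ff))
            if len(res[c]) > 1:
                r = int(rng.choice(sorted(res[c])))
                edges.discard((c, r))
                res[c].discard(r)

    # link pruning may have cut a basal path; re-repair (tiny overshoot of
    # the link target is acceptable)
    reach = _reaches_basal(edges)
    for c in consumers:
        if c not in reach:
            pool = ff_list if c in strict else benthic
            edges.add((c, int(rng.choice(pool))))

    # every filter-feeder supports at least one predator, as sessile prey
    # guilds do; borrow predators from the strict carnivores
    cons_now = {i: set() for i in range(S)}
    for c, r in edges:
        cons_now[r].add(c)
    pred_pool = sorted(strict) or non_ff
    for f in sorted(ff):
        if not cons_now[f]:
            for c in rng.choice(pred_pool, size=min(2, len(pred_pool)), replace=False):
                edges.add((int(c), f))

    names = [f"sp{i:03d}" for i in range(S)]
    names[plankton] = "plankton"
    str_edges = {(names[c], names[r]) for c, r in edges}

    # provisional web for trophic levels (masses filled afterwards)
    provisional = FoodWeb(
        species=names,
        links=set(str_edges),
        body_mass={s: 1.0 for s in names},
        category={s: "producer" for s in names},
    )
    swtl = short_weighted_trophic_level(provisional, strict=True)

    # body masses grow with trophic level at the requested mean ratio
    masses = {}
    for i, s in enumerate(names):
        noise = float(np.exp(rng.normal(0.0, 0.4)))
        masses[s] = spec.mass_ratio ** (swtl[s] - 1.0) * noise
    masses["plankton"] = 0.1 * min(
        masses[names[i]] for i in benthic
    )  # plankton is the smallest, fastest-growing producer

    # trophic categories: designated roles first, the rest by diet
    res = _resources(edges)
    category = {}
    for i, s in enumerate(names):
        if i == plankton:
            category[s] = "plankton"
        elif i in basal:
            category[s] = "producer"
        elif i in ff:
            category[s] = "filter-feeder"
        elif i in top_pred:
            category[s] = "top-predator"
        elif i in carnivore:
            category[s] = "carnivore"
        elif i in herb:
            category[s] = "herbivore"
        else:
            diet_animal = sum(1 for r in res[i] if r not in basal)
            category[s] = "herbivore" if diet_animal == 0 else "omnivore"

    # harvested species, stratified across categories like the landings
    pools = {
        cat: [names[i] for i in range(S) if category[names[i]] == cat]
        for cat in _HARVEST_WEIGHTS
    }
    pools["carnivore"] += [s for s in names if category[s] == "top-predator"]
    weights = np.array([_HARVEST_WEIGHTS[c] for c in _HARVEST_WEIGHTS], dtype=float)
    quota = np.floor(spec.n_harvested * weights / weights.sum()).astype(int)
    while quota.sum() < spec.n_harvested:
        quota[int(rng.integers(0, len(quota)))] += 1
    harvested: list[str] = []
    for cat, q in zip(_HARVEST_WEIGHTS, quota):
        pool = [s for s in pools[cat] if s not in harvested and s != "plankton"]
        take = min(q, len(pool))
        if take:
            harvested += rng.choice(pool, size=take, replace=False).tolist()
    shortfall = spec.n_harvested - len(harvested)
    if shortfall > 0:
        rest = [s for s in names if s not in harvested and s != "plankton"]
        harvested += rng.choice(rest, size=shortfall, replace=False).tolist()
    ranks = rng.permutation(len(harvested)) + 1
    catch_rank = {s: int(k) for s, k in zip(harvested, ranks)}

    # the fisheries node consumes every harvested species, nothing eats it
    fishery = "fishery"
    species = names + [fishery]
    links = set(str_edges) | {(fishery, s) for s in harvested}
    category[fishery] = "fisheries"
    web = FoodWeb(
        species=species,
        links=links,
        body_mass=masses,
        category=category,
        harvested={s: s in set(harvested) for s in species},
        catch_rank=catch_rank,
    )
    params = params_from_web(
        web,
        d=spec.interference,
        s=spec.subsidy,
        link_overrides=[
            (names[f], "plankton", "B0", spec.b0_plankton) for f in sorted(ff)
        ],
    )
    return web, params


# ---------------------------------------------------------------------------
# hand-built micro-webs used across the test-suite
# ---------------------------------------------------------------------------


def small_fixture_suite() -> dict[str, FoodWeb]:
    """Deterministic micro-webs with closed-form or oracle-checkable behaviour.

    - ``chain``: producer → herbivore → carnivore; removing the producer
      collapses the chain.
    - ``star``: one generalist hub eating four producers; the hub leads
      any most-connected deletion order.
    - ``two_channel``: benthic channel (producer → herbivore) and pelagic
      channel (plankton → filter-feeder) joined by a shared predator.
    - ``competition_pair``: two producers under a shared carrying
      capacity, one harvested; harvesting one releases the other.
    """
    webs = {}
    webs["chain"] = FoodWeb(
        species=["P", "H", "C"],
        links={("H", "P"), ("C", "H")},
        body_mass={"P": 1.0, "H": 10.0, "C": 100.0},
        category={"P": "producer", "H": "herbivore", "C": "carnivore"},
    )
    webs["star"] = FoodWeb(
        species=["hub", "p1", "p2", "p3", "p4"],
        links={("hub", p) for p in ("p1", "p2", "p3", "p4")},
        body_mass={"hub": 50.0, "p1": 1.0, "p2": 1.0, "p3": 1.0, "p4": 1.0},
        category={
            "hub": "herbivore",
            "p1": "producer",
            "p2": "producer",
            "p3": "producer",
            "p4": "producer",
        },
    )
    webs["two_channel"] = FoodWeb(
        species=["plankton", "algae", "FF", "H", "pred"],
        links={("FF", "plankton"), ("H", "algae"), ("pred", "FF"), ("pred", "H")},
        body_mass={"plankton": 0.01, "algae": 1.0, "FF": 5.0, "H": 8.0, "pred": 200.0},
        category={
            "plankton": "plankton",
            "algae": "producer",
            "FF": "filter-feeder",
            "H": "herbivore",
            "pred": "top-predator",
        },
    )
    webs["competition_pair"] = FoodWeb(
        species=["A", "B"],
        links=set(),
        body_mass={"A": 2.0, "B": 1.0},
        category={"A": "producer", "B": "producer"},
        harvested={"A": True, "B": False},
        catch_rank={"A": 1},
    )
    return webs
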