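"""Shared fixtures: micro-webs, random-web factory, a small synthetic system.

The expensive shared objects (a 30-species synthetic web with its
unperturbed equilibrium) are session-scoped so dynamic-model tests pay
the relaxation cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

from coastweb import (
    FoodWeb,
    default_initial_biomass,
    equilibrate,
)
from coastweb.synth import SynthSpec, generate_web, small_fixture_suite


@pytest.fixture(scope="session")
def fixtures() -> dict[str, FoodWeb]:
    return small_fixture_suite()


@pytest.fixture()
def chain(fixtures):
    return fixtures["chain"]


@pytest.fixture()
def star(fixtures):
    return fixtures["star"]


@pytest.fixture()
def two_channel(fixtures):
    return fixtures["two_channel"]


def random_web(rng: np.random.Generator, S: int | None = None) -> FoodWeb:
    """A random directed web with at least one basal species.

    Used to exercise the cascade engine against the brute-force oracle;
    makes no attempt at ecological realism beyond 'consumers eat
    something'.
    """
    if S is None:
        S = int(rng.integers(3, 13))
    n_basal = int(rng.integers(1, max(2, S // 2)))
    names = [f"n{i}" for i in range(S)]
    links = set()
    for i in range(n_basal, S):
        # each consumer eats 1..4 random species (self-loops allowed)
        k = int(rng.integers(1, min(5, S + 1)))
        for j in rng.choice(S, size=k, replace=False):
            links.add((names[i], names[int(j)]))
    basal_like = {names[i] for i in range(S) if not any(c == names[i] for c, _ in links)}
    return FoodWeb(
        species=names,
        links=links,
        body_mass={s: 1.0 for s in names},
        category={s: ("producer" if s in basal_like else "omnivore") for s in names},
    )


def cascade_oracle(web: FoodWeb, removed: set[str]) -> set[str]:
    """Greatest-fixpoint survivor computation, independent of the engine.

    Starts from 'everything not removed survives' and repeatedly strips
    non-basal species with no surviving resource; the complement of the
    survivors (minus the primaries) is the secondary-extinction set.
    The production engine computes the same set from below.
    """
    fisheries = web.fisheries
    survivors = set(web.species) - set(removed)
    while True:
        keep = {
            s
            for s in survivors
            if web.is_basal(s)
            or s == fisheries
            or any(r in survivors for r in web.resources_of(s))
        }
        if keep == survivors:
            break
        survivors = keep
    return set(web.species) - survivors - set(removed)


@pytest.fixture(scope="session")
def small_synth():
    """30-species synthetic web with params: the workhorse dynamic system."""
    spec = SynthSpec(
        S=30,
        C=0.12,
        n_filter_feeders=4,
        n_harvested=6,
        n_carnivores=3,
        n_top_predators=2,
        n_herbivores=3,
        seed=42,
    )
    return generate_web(spec)


@pytest.fixture(scope="session")
def small_synth_baseline(small_synth):
    web, params = small_synth
    eq = equilibrate(params, default_initial_biomass(params, seed=42))
    return eq
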