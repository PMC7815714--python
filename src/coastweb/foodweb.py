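"""Directed food-web container, structural metrics and CSV I/O.

Edges are stored consumer→resource: an edge ``(i, j)`` means species *i*
eats species *j*.  A *basal* species is one with no resources of its own
(benthic primary producers and the plankton node).  Two special nodes may
be present: a single plankton node (basal, externally subsidised in the
dynamic model) and a single fisheries node, which consumes harvested
species but is itself never consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

CATEGORIES = (
    "producer",
    "plankton",
    "filter-feeder",
    "herbivore",
    "omnivore",
    "carnivore",
    "top-predator",
    "fisheries",
)

NODE_COLUMNS = (
    "species",
    "body_mass",
    "category",
    "harvested",
    "catch_rank",
    "is_plankton",
    "is_fisheries",
)


class FoodWebError(ValueError):
    """Raised when a food web violates its structural invariants."""


@dataclass
class FoodWeb:
    """A directed trophic network with per-species attributes.

    Parameters
    ----------
    species:
        Ordered node identifiers (opaque strings).
    links:
        Set of directed consumer→resource pairs.  Self-loops encode
        cannibalism and are legal.
    body_mass:
        Positive body mass per node (arbitrary consistent units).  The
        fisheries node may lack a mass (``nan``).
    category:
        Trophic category label per node, one of :data:`CATEGORIES`.
    harvested:
        Whether the species is taken by the artisanal fishery.
    catch_rank:
        Optional landings rank per harvested node (1 = largest catch).
    """

    species: list[str]
    links: set[tuple[str, str]]
    body_mass: dict[str, float]
    category: dict[str, str]
    harvested: dict[str, bool] = field(default_factory=dict)
    catch_rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.links = set(tuple(l) for l in self.links)
        self.harvested = {s: bool(self.harvested.get(s, False)) for s in self.species}
        self._resources: dict[str, list[str]] | None = None
        self._consumers: dict[str, list[str]] | None = None
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        known = set(self.species)
        if len(known) != len(self.species):
            raise FoodWebError("duplicate species identifiers")
        for c, r in self.links:
            if c not in known or r not in known:
                missing = c if c not in known else r
                raise FoodWebError(f"link endpoint {missing!r} not in species table")
        plank = [s for s in self.species if self.category.get(s) == "plankton"]
        fish = [s for s in self.species if self.category.get(s) == "fisheries"]
        if len(plank) > 1:
            raise FoodWebError(f"more than one plankton node: {plank}")
        if len(fish) > 1:
            raise FoodWebError(f"more than one fisheries node: {fish}")
        for s in self.species:
            m = self.body_mass.get(s, np.nan)
            if s not in fish and not (np.isfinite(m) and m > 0):
                raise FoodWebError(f"species {s!r} lacks a positive body mass")
        if fish:
            f = fish[0]
            if self.consumers_of(f):
                raise FoodWebError("fisheries node must have no consumers")
            res = set(self.resources_of(f))
            for s in self.species:
                if self.harvested.get(s) and s not in res:
                    raise FoodWebError(
                        f"harvested species {s!r} not linked from the fisheries node"
                    )

    # -- adjacency -------------------------------------------------------

    def _build_adjacency(self) -> None:
        res: dict[str, list[str]] = {s: [] for s in self.species}
        cons: dict[str, list[str]] = {s: [] for s in self.species}
        for c, r in sorted(self.links):
            res[c].append(r)
            cons[r].append(c)
        self._resources, self._consumers = res, cons

    def resources_of(self, node: str) -> list[str]:
        """Species that `node` eats (out-neighbours)."""
        if self._resources is None:
            self._build_adjacency()
        return self._resources[node]

    def consumers_of(self, node: str) -> list[str]:
        """Species that eat `node` (in-neighbours)."""
        if self._consumers is None:
            self._build_adjacency()
        return self._consumers[node]

    def is_basal(self, node: str) -> bool:
        """True when the node has no resources (producers and plankton)."""
        return len(self.resources_of(node)) == 0

    def degree(self, node: str) -> int:
        """Number of trophic links the node takes part in (a self-loop counts once)."""
        return sum(1 for c, r in self.links if c == node or r == node)

    # -- derived node sets ----------------------------------------------

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def L(self) -> int:
        return len(self.links)

    @property
    def plankton(self) -> str | None:
        for s in self.species:
            if self.category.get(s) == "plankton":
                return s
        return None

    @property
    def fisheries(self) -> str | None:
        for s in self.species:
            if self.category.get(s) == "fisheries":
                return s
        return None

    @property
    def harvested_species(self) -> list[str]:
        return [s for s in self.species if self.harvested.get(s)]

    @property
    def basal_species(self) -> list[str]:
        return [s for s in self.species if self.is_basal(s)]

    def removable_species(self) -> list[str]:
        """All species eligible for primary deletion (the fisheries node is not)."""
        f = self.fisheries
        return [s for s in self.species if s != f]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        g.add_edges_from(self.links)
        return g


# ---------------------------------------------------------------------------
# structural metrics
# ---------------------------------------------------------------------------


@dataclass
class StructuralMetrics:
    """Whole-web and per-node structural summary."""

    S: int
    L: int
    connectance: float
    degree: dict[str, int]
    swtl: dict[str, float]
    mean_swtl: float

    def to_frame(self) -> pd.DataFrame:
        """One row per node plus a ``__summary__`` row."""
        rows = [
            {"species": s, "degree": self.degree[s], "swtl": self.swtl[s]}
            for s in self.degree
        ]
        rows.append(
            {
                "species": "__summary__",
                "degree": self.L,
                "swtl": self.mean_swtl,
            }
        )
        df = pd.DataFrame(rows)
        df.attrs.update(S=self.S, L=self.L, connectance=self.connectance)
        return df


def _shortest_chain_tl(web: FoodWeb) -> dict[str, float]:
    """1 + length of the shortest food chain down to a basal node; basal = 1."""
    tl = {s: np.inf for s in web.species}
    frontier = [s for s in web.species if web.is_basal(s)]
    for s in frontier:
        tl[s] = 1.0
    level = 1.0
    while frontier:
        level += 1.0
        nxt = []
        for r in frontier:
            for c in web.consumers_of(r):
                if tl[c] == np.inf:
                    tl[c] = level
                    nxt.append(c)
        frontier = nxt
    return tl


def _prey_averaged_tl(web: FoodWeb, reachable: dict[str, float]) -> dict[str, float]:
    """Solve TL_i = 1 + mean over resources of TL_j as a linear system."""
    nodes = [s for s in web.species if np.isfinite(reachable[s])]
    idx = {s: k for k, s in enumerate(nodes)}
    n = len(nodes)
    a = np.eye(n)
    for s in nodes:
        res = [r for r in web.resources_of(s) if r in idx]
        if res:
            w = 1.0 / len(res)
            for r in res:
                a[idx[s], idx[r]] -= w
    tl = np.linalg.solve(a, np.ones(n))
    out = {s: np.nan for s in web.species}
    out.update({s: float(tl[idx[s]]) for s in nodes})
    return out


def short_weighted_trophic_level(web: FoodWeb, strict: bool = True) -> dict[str, float]:
    """Short-weighted trophic level per node.

    SWTL averages the shortest-chain trophic level with the prey-averaged
    trophic level (1 + mean resource SWTL solved as a linear system), the
    standard definition in the food-web literature.  Basal species sit at
    exactly 1.  A node caught in a consumer-only cycle with no food chain
    to the basal level has no defined trophic level: ``strict`` raises,
    otherwise its SWTL is ``nan``.
    """
    short = _shortest_chain_tl(web)
    orphans = [s for s in web.species if not np.isfinite(short[s])]
    if orphans and strict:
        raise FoodWebError(
            f"trophic level undefined: no path to a basal node from {orphans}"
        )
    prey = _prey_averaged_tl(web, short)
    return {
        s: 0.5 * short[s] + 0.5 * prey[s] if np.isfinite(short[s]) else np.nan
        for s in web.species
    }


def structural_metrics(web: FoodWeb, strict: bool = True) -> StructuralMetrics:
    """Compute S, L, connectance ``L/S**2``, per-node degree and SWTL."""
    swtl = short_weighted_trophic_level(web, strict=strict)
    degree = {s: web.degree(s) for s in web.species}
    finite = [v for v in swtl.values() if np.isfinite(v)]
    return StructuralMetrics(
        S=web.S,
        L=web.L,
        connectance=web.L / web.S**2 if web.S else np.nan,
        degree=degree,
        swtl=swtl,
        mean_swtl=float(np.mean(finite)) if finite else np.nan,
    )


# ---------------------------------------------------------------------------
# node removal and the random-removal structural null
# ---------------------------------------------------------------------------


def remove_nodes(web: FoodWeb, nodes: Iterable[str]) -> FoodWeb:
    """Induced subweb after deleting `nodes`; incident links drop, attributes persist."""
    drop = set(nodes)
    unknown = drop - set(web.species)
    if unknown:
        raise FoodWebError(f"cannot remove unknown species {sorted(unknown)}")
    keep = [s for s in web.species if s not in drop]
    keepset = set(keep)
    return FoodWeb(
        species=keep,
        links={(c, r) for c, r in web.links if c in keepset and r in keepset},
        body_mass={s: web.body_mass[s] for s in keep if s in web.body_mass},
        category={s: web.category[s] for s in keep},
        harvested={s: web.harvested[s] for s in keep},
        catch_rank={s: web.catch_rank[s] for s in keep if s in web.catch_rank},
    )


def random_removal_null(
    web: FoodWeb, k: int, reps: int, seed: int
) -> list[StructuralMetrics]:
    """Null distribution of structural metrics under random species loss.

    Each replicate removes ``k`` species drawn uniformly (without
    replacement) from all species except the fisheries node, and records
    the surviving web's structural metrics.  Reproducible under ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pool = web.removable_species()
    if k > len(pool):
        raise FoodWebError(f"cannot remove k={k} from {len(pool)} removable species")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        drop = rng.choice(pool, size=k, replace=False)
        out.append(structural_metrics(remove_nodes(web, drop), strict=False))
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_foodweb(edge_table: str | Path, node_table: str | Path) -> FoodWeb:
    """Read a web from an edge-list CSV (``consumer,resource``) and a node CSV.

    The node table carries columns ``species, body_mass, category,
    harvested, catch_rank, is_plankton, is_fisheries``.  Unknown edge
    endpoints and missing body masses are hard errors; duplicate edges
    are deduplicated with a warning.  Loading is order-stable.
    """
    edges = pd.read_csv(edge_table, dtype=str)
    nodes = pd.read_csv(node_table)
    missing_cols = {"consumer", "resource"} - set(edges.columns)
    if missing_cols:
        raise FoodWebError(f"edge table lacks columns {sorted(missing_cols)}")
    nodes["species"] = nodes["species"].astype(str)
    known = set(nodes["species"])
    pairs = list(zip(edges["consumer"], edges["resource"]))
    for c, r in pairs:
        if c not in known:
            raise FoodWebError(f"edge list names unknown node {c!r}")
        if r not in known:
            raise FoodWebError(f"edge list names unknown node {r!r}")
    if len(set(pairs)) < len(pairs):
        warnings.warn("duplicate edges in edge table; deduplicated", stacklevel=2)

    category = dict(zip(nodes["species"], nodes["category"]))
    if "is_plankton" in nodes:
        for s, flag in zip(nodes["species"], nodes["is_plankton"]):
            if bool(flag) and category.get(s) != "plankton":
                category[s] = "plankton"
    if "is_fisheries" in nodes:
        for s, flag in zip(nodes["species"], nodes["is_fisheries"]):
            if bool(flag) and category.get(s) != "fisheries":
                category[s] = "fisheries"

    catch_rank = {}
    if "catch_rank" in nodes:
        for s, v in zip(nodes["species"], nodes["catch_rank"]):
            if pd.notna(v):
                catch_rank[s] = int(v)

    return FoodWeb(
        species=list(nodes["species"]),
        links=set(pairs),
        body_mass=dict(zip(nodes["species"], nodes["body_mass"].astype(float))),
        category=category,
        harvested={
            s: bool(v) for s, v in zip(nodes["species"], nodes.get("harvested", False))
        },
        catch_rank=catch_rank,
    )


def save_foodweb(web: FoodWeb, edge_table: str | Path, node_table: str | Path) -> None:
    """Write the two-CSV representation read back by :func:`load_foodweb`."""
    pd.DataFrame(sorted(web.links), columns=["consumer", "resource"]).to_csv(
        edge_table, index=False
    )
    rows = []
    for s in web.species:
        rows.append(
            {
                "species": s,
                "body_mass": web.body_mass.get(s, np.nan),
                "category": web.category[s],
                "harvested": web.harvested.get(s, False),
                "catch_rank": web.catch_rank.get(s, ""),
                "is_plankton": web.category[s] == "plankton",
                "is_fisheries": web.category[s] == "fisheries",
            }
        )
    pd.DataFrame(rows, columns=list(NODE_COLUMNS)).to_csv(node_table, index=False)
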