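"""Allometric trophic network (ATN) bioenergetic dynamics.

Biomass dynamics of every species in the web follow the classic
producer/consumer ATN equations, extended here with two terms: a
constant external subsidy ``s`` flowing into the plankton node
(pelagic production advected into the benthic system, independent of
local consumption), and a per-species fisheries mortality ``F_max``
removing a fixed fraction of standing biomass per day.

Producers (index *i*)::

    dB_i/dt = r_i B_i G_i(B) - sum_j x_j y_j B_j F_ji / e_ji - Fmax_i B_i
    G_i(B)  = 1 - (sum_{j in producers} c_ij B_j) / K

Consumers::

    dB_i/dt = f_a x_i B_i y_i sum_j F_ij - f_m x_i B_i
              - sum_j x_j y_j B_j F_ji / e_ji - Fmax_i B_i

with the Hill-type functional response::

    F_ij = w_ij B_j^q / (B0_ij^q + d_i B_i B0_ij + sum_l w_il B_l^q)

The plankton node obeys the producer equation plus ``s``.  All rates are
normalised allometrically: time is measured in units of the inverse
mass-specific growth rate of the reference producer (the producer with
the smallest body mass), one time step = one day, 3650 steps = 10 years.

A species whose biomass falls below 1e-6 is extinct: its biomass is
clamped to zero and it is excluded from all further dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .foodweb import FoodWeb
from .static_robustness import EXTINCTION_THRESHOLD


class ATNError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ATNParams:
    """Every rate and coefficient of the bioenergetic model, per species/link.

    Species are the *dynamic* nodes of the web: the fisheries node is
    not a state variable — harvesting enters only through ``F_max``.
    Matrices are indexed ``[consumer, resource]`` and are zero off the
    trophic links.
    """

    species: list[str]
    is_producer: np.ndarray  # bool, includes plankton
    plankton: int | None  # index or None
    masses: np.ndarray
    link: np.ndarray  # bool adjacency [consumer, resource]
    r: np.ndarray  # producer intrinsic growth (0 for consumers)
    x: np.ndarray  # consumer metabolic rate (0 for producers)
    y: np.ndarray  # max consumption ratio a_y/a_x (0 for producers)
    e: np.ndarray  # assimilation efficiency per link
    omega: np.ndarray  # consumer preference, rows sum to 1 over resources
    B0: np.ndarray  # half-saturation biomass per link
    d: np.ndarray  # consumer intraspecific interference
    q: float  # Hill exponent of the functional response
    c: np.ndarray  # producer competition coefficients
    K: float  # shared producer carrying capacity
    f_a: float  # assimilated fraction of ingested biomass
    f_m: float  # maintenance (respiration) fraction
    F_max: np.ndarray  # fisheries mortality per species (0 if not harvested)
    s: float  # plankton subsidy per day
    a_r: float = 1.0
    a_x: float = 0.314
    a_y: float = 2.512
    M_Pref: float = 1.0

    @property
    def n(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def validate(self) -> None:
        n = self.n
        for name in ("masses", "r", "x", "y", "d", "F_max"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ATNError(f"{name} has shape {arr.shape}, expected ({n},)")
        for name in ("link", "e", "omega", "B0", "c"):
            arr = getattr(self, name)
            if arr.shape != (n, n):
                raise ATNError(f"{name} has shape {arr.shape}, expected ({n},{n})")
        if np.any(self.masses <= 0):
            raise ATNError("body masses must be positive")
        if self.K <= 0 or self.q <= 0:
            raise ATNError("K and q must be positive")
        if not (0 <= self.f_a <= 1 and 0 <= self.f_m <= 1):
            raise ATNError("f_a and f_m must lie in [0, 1]")
        on_link = self.link
        if np.any((self.e[on_link] <= 0) | (self.e[on_link] > 1)):
            raise ATNError("assimilation efficiencies must lie in (0, 1]")
        consumers = ~self.is_producer
        rowsum = self.omega.sum(axis=1)
        if not np.allclose(rowsum[consumers], 1.0):
            raise ATNError("consumer preferences must sum to 1 over resources")
        if np.any(self.r < 0) or np.any(self.x < 0) or np.any(self.F_max < 0):
            raise ATNError("rates must be non-negative")

    def with_fishing(self, F_max: np.ndarray) -> "ATNParams":
        return replace(self, F_max=np.asarray(F_max, dtype=float))

    def with_subsidy(self, s: float) -> "ATNParams":
        return replace(self, s=float(s))


def build_rates(
    masses: Sequence[float],
    is_producer: Sequence[bool],
    a_r: float = 1.0,
    a_x: float = 0.314,
    a_y: float = 2.512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Allometric rates from body masses.

    Rates scale with body mass as ``M**-0.25``.  Growth and metabolic
    rates are normalised by the growth rate of the *reference producer*
    — the producer with the smallest body mass, hence the highest
    mass-specific growth rate — whose normalised ``r`` is exactly 1; the
    maximum consumption rate is normalised by each consumer's own
    metabolism, making ``y = a_y/a_x`` the same for every consumer.

    Returns ``(r, x, y, M_Pref)``.
    """
    masses = np.asarray(masses, dtype=float)
    is_producer = np.asarray(is_producer, dtype=bool)
    if np.any(masses <= 0):
        raise ATNError("body masses must be positive")
    if not is_producer.any():
        raise ATNError("at least one producer is required")
    if min(a_r, a_x, a_y) <= 0:
        raise ATNError("allometric constants must be positive")
    m_pref = float(masses[is_producer].min())
    ratio = (masses / m_pref) ** -0.25
    r = np.where(is_producer, ratio, 0.0)
    x = np.where(~is_producer, (a_x / a_r) * ratio, 0.0)
    y = np.where(~is_producer, a_y / a_x, 0.0)
    return r, x, y, m_pref


def params_from_web(
    web: FoodWeb,
    *,
    a_r: float = 1.0,
    a_x: float = 0.314,
    a_y: float = 2.512,
    q: float = 1.2,
    e_carnivory: float = 0.85,
    e_herbivory: float = 0.45,
    d: float = 0.0,
    B0: float = 0.5,
    f_a: float = 0.4,
    f_m: float = 0.1,
    K: float | None = None,
    s: float | None = None,
    link_overrides: Sequence[tuple[str, str, str, float]] = (),
) -> ATNParams:
    """Default-parameterised ATN model for a food web.

    The fisheries node is dropped (harvesting is the ``F_max`` term, not
    a species).  Preferences are uniform over each consumer's resources;
    assimilation is ``e_herbivory`` on producer resources and
    ``e_carnivory`` otherwise; producer competition is fully shared
    (``c == 1``), so ``K`` is the community-level carrying capacity,
    defaulting to one unit of biomass per producer.  The plankton
    subsidy defaults to half the reference-scale production of one
    producer's share of ``K``.  ``link_overrides`` rows
    ``(consumer, resource, field, value)`` patch ``e``/``omega``/``B0``
    per link; ``omega`` overrides are renormalised to sum to one.
    """
    dyn = [sp for sp in web.species if web.category.get(sp) != "fisheries"]
    idx = {sp: i for i, sp in enumerate(dyn)}
    n = len(dyn)
    link = np.zeros((n, n), dtype=bool)
    for c, r_ in web.links:
        if c in idx and r_ in idx:
            link[idx[c], idx[r_]] = True
    is_producer = np.array([not link[i].any() for i in range(n)])
    masses = np.array([web.body_mass[sp] for sp in dyn], dtype=float)
    r, x, y, m_pref = build_rates(masses, is_producer, a_r, a_x, a_y)

    omega = np.zeros((n, n))
    counts = link.sum(axis=1)
    rows = counts > 0
    omega[rows] = link[rows] / counts[rows, None]
    e = np.where(link & is_producer[None, :], e_herbivory, 0.0) + np.where(
        link & ~is_producer[None, :], e_carnivory, 0.0
    )
    B0m = np.where(link, B0, 0.0)
    c_mat = np.zeros((n, n))
    prod_idx = np.where(is_producer)[0]
    c_mat[np.ix_(prod_idx, prod_idx)] = 1.0

    n_prod = int(is_producer.sum())
    if K is None:
        K = float(n_prod)
    plank = web.plankton
    plank_i = idx[plank] if plank in idx else None
    if s is None:
        if plank_i is not None:
            s = 0.5 * float(r[plank_i]) * K / n_prod
        else:
            s = 0.0

    for cons, res, fname, value in link_overrides:
        i, j = idx[cons], idx[res]
        if not link[i, j]:
            raise ATNError(f"override on non-link ({cons!r}, {res!r})")
        if fname == "e":
            e[i, j] = value
        elif fname == "omega":
            omega[i, j] = value
        elif fname == "B0":
            B0m[i, j] = value
        else:
            raise ATNError(f"unknown per-link field {fname!r}")
    rowsum = omega.sum(axis=1)
    omega[rowsum > 0] /= rowsum[rowsum > 0, None]

    p = ATNParams(
        species=dyn,
        is_producer=is_producer,
        plankton=plank_i,
        masses=masses,
        link=link,
        r=r,
        x=x,
        y=y,
        e=e,
        omega=omega,
        B0=B0m,
        d=np.full(n, d, dtype=float),
        q=q,
        c=c_mat,
        K=float(K),
        f_a=f_a,
        f_m=f_m,
        F_max=np.zeros(n),
        s=float(s),
        a_r=a_r,
        a_x=a_x,
        a_y=a_y,
        M_Pref=m_pref,
    )
    p.validate()
    return p


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def functional_response(B: np.ndarray, params: ATNParams) -> np.ndarray:
    """Hill-type consumption fraction F[i, j] of consumer *i* on resource *j*.

    Zero off-link and whenever the resource biomass is zero; equals 1/2
    for a lone resource at its half-saturation biomass with no
    interference.
    """
    B = np.maximum(np.asarray(B, dtype=float), 0.0)
    Bq = B**params.q
    denom = (
        np.where(params.link, params.B0, 0.0) ** params.q
        + (params.d * B)[:, None] * params.B0
        + (params.omega @ Bq)[:, None]
    )
    F = np.zeros_like(denom)
    on = params.link & (denom > 0)
    F[on] = (params.omega * Bq[None, :])[on] / denom[on]
    return F


def derivatives(
    B: np.ndarray, params: ATNParams, alive: np.ndarray | None = None
) -> np.ndarray:
    """dB/dt of every species; extinct (non-alive) species are frozen at zero."""
    B = np.asarray(B, dtype=float)
    if B.shape != (params.n,):
        raise ATNError(f"biomass vector has shape {B.shape}, expected ({params.n},)")
    if alive is None:
        alive = np.ones(params.n, dtype=bool)
    Bm = np.where(alive, np.maximum(B, 0.0), 0.0)

    F = functional_response(Bm, params)
    # per-consumer intake x_i * y_i * B_i * sum_j F_ij
    intake = params.x * params.y * Bm * F.sum(axis=1)
    # predation loss on each resource j: sum_i x_i y_i B_i F_ij / e_ij
    with np.errstate(divide="ignore", invalid="ignore"):
        per_link = np.where(
            params.link, (params.x * params.y * Bm)[:, None] * F / params.e, 0.0
        )
    predation = per_link.sum(axis=0)

    G = 1.0 - (params.c @ np.where(params.is_producer, Bm, 0.0)) / params.K
    dB = np.where(
        params.is_producer,
        params.r * Bm * G,
        params.f_a * intake - params.f_m * params.x * Bm,
    )
    dB -= predation + params.F_max * Bm
    if params.plankton is not None and alive[params.plankton]:
        dB[params.plankton] += params.s
    return np.where(alive, dB, 0.0)


@dataclass
class StateTrajectory:
    """Daily biomass trajectory with an extinction log."""

    times: np.ndarray
    B: np.ndarray  # (len(times), n)
    species: list[str]
    extinct_log: list[tuple[str, float]] = field(default_factory=list)

    @property
    def final(self) -> np.ndarray:
        return self.B[-1]

    def to_frame(self) -> "object":
        import pandas as pd

        n = len(self.species)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "species": np.tile(self.species, len(self.times)),
                "biomass": self.B.ravel(),
            }
        )


def integrate(
    params: ATNParams,
    B_init: Sequence[float],
    T: float,
    *,
    alive: np.ndarray | None = None,
    t0: float = 0.0,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> StateTrajectory:
    """Integrate the ATN equations over ``[t0, t0+T]`` with daily output.

    The default integrator is LSODA (adaptive, switching between
    Adams and BDF): subsidised webs couple day-scale plankton turnover
    to near-inert apex predators, which makes the system stiff.  Any
    ``solve_ivp`` method works; adaptive Runge–Kutta 4(5) gives the
    same trajectories more slowly.  The 1e-6 extinction threshold is
    enforced by event detection: integration stops at the crossing, the
    species is clamped to zero, logged, and excluded from the dynamics
    before the run resumes.  Deterministic given its inputs.
    """
    if T <= 0:
        raise ATNError("T must be positive")
    B = np.array(B_init, dtype=float)
    if B.shape != (params.n,):
        raise ATNError(f"B_init has shape {B.shape}, expected ({params.n},)")
    if np.any(B < 0):
        raise ATNError("initial biomasses must be non-negative")
    alive = np.ones(params.n, dtype=bool) if alive is None else alive.copy()
    extinct_log: list[tuple[str, float]] = []

    # initial states already at or under threshold are extinct at t0
    dying = alive & (B <= EXTINCTION_THRESHOLD)
    for i in np.where(dying)[0]:
        extinct_log.append((params.species[i], t0))
    alive &= ~dying
    B[~alive] = 0.0

    t_end = t0 + T
    grid = t0 + np.arange(0.0, np.floor(T) + 1.0)
    if grid[-1] < t_end:
        grid = np.append(grid, t_end)
    times_out: list[np.ndarray] = []
    B_out: list[np.ndarray] = []
    t = t0
    while t < t_end - 1e-12:
        mask = alive.copy()

        def rhs(tt, bb, mask=mask):
            return derivatives(bb, params, mask)

        def extinction_event(tt, bb, mask=mask):
            living = bb[mask]
            return (living.min() if living.size else 1.0) - EXTINCTION_THRESHOLD

        extinction_event.terminal = True
        extinction_event.direction = -1.0
        t_eval = grid[(grid >= t - 1e-9) & (grid <= t_end + 1e-9)]
        sol = solve_ivp(
            rhs,
            (t, t_end),
            B,
            method=method,
            t_eval=t_eval if len(t_eval) else None,
            events=extinction_event,
            rtol=rtol,
            atol=atol,
        )
        sol_t = np.asarray(sol.t, dtype=float)
        if sol.status == -1:
            raise ATNError(f"integrator failed near t={t:.3f}: {sol.message}")
        if sol_t.size:
            times_out.append(sol_t)
            B_out.append(np.clip(np.asarray(sol.y).T.reshape(-1, params.n), 0.0, None))
        if sol.status == 1:  # extinction crossing
            t = float(sol.t_events[0][0])
            B = np.clip(sol.y_events[0][0], 0.0, None)
            just_died = alive & (B <= EXTINCTION_THRESHOLD * (1 + 1e-9))
            if not just_died.any():
                # numerical grazing of the threshold: retire the minimum to
                # guarantee progress rather than loop on the same crossing
                living = np.where(alive)[0]
                just_died[living[np.argmin(B[living])]] = True
            for i in np.where(just_died)[0]:
                extinct_log.append((params.species[i], t))
            alive &= ~just_died
            B[~alive] = 0.0
            grid = grid[grid > t + 1e-9]  # avoid duplicating the event time
        else:
            B = np.clip(sol.y[:, -1], 0.0, None)
            t = t_end

    if times_out:
        times = np.concatenate(times_out)
        traj = np.concatenate(B_out, axis=0)
    else:
        times = np.array([t0])
        traj = B[None, :]
    dead = ~alive
    traj[:, dead] = np.where(
        times[:, None] >= np.array(
            [dict(extinct_log).get(s, -np.inf) for s in params.species]
        )[None, dead],
        0.0,
        traj[:, dead],
    )
    return StateTrajectory(
        times=times, B=traj, species=list(params.species), extinct_log=extinct_log
    )


@dataclass
class Equilibrium:
    """Endpoint of a long relaxation run."""

    B: np.ndarray
    species: list[str]
    stationary: bool
    max_rel_derivative: float
    extinct: set[str]
    trajectory: StateTrajectory | None = None

    def biomass_of(self, name: str) -> float:
        return float(self.B[self.species.index(name)])


def equilibrate(
    params: ATNParams,
    B_init: Sequence[float],
    T: float = 3650.0,
    *,
    alive: np.ndarray | None = None,
    stationarity_tol: float = 1e-6,
    keep_trajectory: bool = False,
    **kwargs,
) -> Equilibrium:
    """Relax the system for ``T`` days (default ten years) and report the end state.

    Stationarity — max |dB/dt|/B over surviving species below
    ``stationarity_tol`` per day — is reported, not enforced: slow
    drifts and limit cycles are flagged but never rejected.
    """
    traj = integrate(params, B_init, T, alive=alive, **kwargs)
    B = traj.final
    survivors = B > 0
    if alive is not None:
        survivors &= alive
    dB = derivatives(B, params, survivors)
    rel = np.abs(dB[survivors]) / np.maximum(B[survivors], EXTINCTION_THRESHOLD)
    max_rel = float(rel.max()) if rel.size else 0.0
    return Equilibrium(
        B=B,
        species=list(params.species),
        stationary=max_rel < stationarity_tol,
        max_rel_derivative=max_rel,
        extinct={name for name, _ in traj.extinct_log},
        trajectory=traj if keep_trajectory else None,
    )


def default_initial_biomass(
    params: ATNParams, seed: int | None = None, jitter: float = 0.5
) -> np.ndarray:
    """Per-category starting biomasses, uniformly jittered in [1-jitter, 1+jitter].

    Producers start at an equal share of the carrying capacity;
    consumers at a tenth of that share, reflecting trophic biomass
    pyramids.  Seeded for reproducibility.
    """
    rng = np.random.default_rng(seed)
    n_prod = max(int(params.is_producer.sum()), 1)
    base = np.where(params.is_producer, params.K / n_prod, 0.1 * params.K / n_prod)
    factors = rng.uniform(1 - jitter, 1 + jitter, size=params.n) if jitter else 1.0
    return base * factors
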