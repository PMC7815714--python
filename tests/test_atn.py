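"""Bioenergetic model: rates, functional response, derivatives, integration."""

import numpy as np
import pytest
from scipy.optimize import brentq, minimize_scalar

from coastweb import (
    ATNError,
    FoodWeb,
    build_rates,
    default_initial_biomass,
    derivatives,
    equilibrate,
    functional_response,
    integrate,
    params_from_web,
)
from coastweb.synth import SynthSpec, generate_web


def lone_producer(K=1.0, s=0.0, category="producer", mass=1.0):
    name = "plankton" if category == "plankton" else "P"
    web = FoodWeb(
        species=[name],
        links=set(),
        body_mass={name: mass},
        category={name: category},
    )
    return params_from_web(web, K=K, s=s)


class TestAllometricRates:
    def test_reference_producer_growth_is_unity(self):
        r, x, y, m_pref = build_rates([2.0, 8.0, 32.0], [True, True, False])
        assert r[0] == 1.0 and m_pref == 2.0
        assert r[1] == pytest.approx(8.0**-0.25 * 2.0**0.25)

    def test_quarter_power_scaling(self):
        # a producer 16x heavier than the reference grows at half the rate
        r, *_ = build_rates([1.0, 16.0], [True, True])
        assert r[1] == pytest.approx(0.5)

    def test_consumer_at_reference_mass_metabolises_at_ax_over_ar(self):
        r, x, y, _ = build_rates([1.0, 1.0], [True, False], a_r=1.0, a_x=0.314)
        assert x[1] == pytest.approx(0.314)

    def test_max_consumption_ratio_is_species_independent(self, small_synth):
        _, params = small_synth
        consumers = ~params.is_producer
        assert np.allclose(params.y[consumers], params.a_y / params.a_x)

    def test_errors(self):
        with pytest.raises(ATNError, match="producer"):
            build_rates([1.0, 2.0], [False, False])
        with pytest.raises(ATNError, match="mass"):
            build_rates([1.0, -2.0], [True, True])


class TestFunctionalResponse:
    def make_params(self, n_resources, d=0.0, B0=0.5, q=1.2):
        names = ["c"] + [f"r{k}" for k in range(n_resources)]
        web = FoodWeb(
            species=names,
            links={("c", f"r{k}") for k in range(n_resources)},
            body_mass={s: 1.0 for s in names},
            category={"c": "herbivore", **{f"r{k}": "producer" for k in range(n_resources)}},
        )
        return params_from_web(web, d=d, B0=B0, q=q)

    def test_zero_resource_means_zero_consumption(self):
        p = self.make_params(1)
        F = functional_response(np.array([1.0, 0.0]), p)
        assert F[0, 1] == 0.0

    @pytest.mark.parametrize("q", [0.8, 1.0, 1.2, 2.0])
    def test_half_saturation_identity(self, q):
        # a lone resource at its half-saturation biomass is consumed at
        # exactly half the maximum rate, whatever the Hill exponent
        p = self.make_params(1, q=q, B0=0.5)
        F = functional_response(np.array([1.0, 0.5]), p)
        assert F[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_two_resources_hand_evaluation(self):
        # ω = 1/2 each, q = 1.2, B0 = 0.5, d = 0, B = (Bc, 0.5, 0.25):
        # denom = 0.5^1.2 + 0.5*0.5^1.2 + 0.5*0.25^1.2
        p = self.make_params(2)
        B = np.array([1.0, 0.5, 0.25])
        denom = 0.5**1.2 + 0.5 * 0.5**1.2 + 0.5 * 0.25**1.2
        expect_1 = 0.5 * 0.5**1.2 / denom
        expect_2 = 0.5 * 0.25**1.2 / denom
        F = functional_response(B, p)
        assert F[0, 1] == pytest.approx(expect_1, abs=1e-12)
        assert F[0, 2] == pytest.approx(expect_2, abs=1e-12)

    def test_interference_depresses_consumption(self):
        lazy = self.make_params(1, d=0.0)
        busy = self.make_params(1, d=2.0)
        B = np.array([1.0, 0.5])
        assert functional_response(B, busy)[0, 1] < functional_response(B, lazy)[0, 1]

    def test_response_stays_below_one(self, small_synth):
        _, params = small_synth
        rng = np.random.default_rng(0)
        for _ in range(20):
            B = rng.uniform(0, 5, size=params.n)
            F = functional_response(B, params)
            assert np.all(F >= 0) and np.all(F < 1)


class TestDerivatives:
    def test_producer_at_carrying_capacity_is_stationary(self):
        p = lone_producer(K=2.0)
        assert derivatives(np.array([2.0]), p)[0] == pytest.approx(0.0)

    def test_subsidy_is_the_only_flux_in_a_dead_web(self, small_synth):
        _, params = small_synth
        dB = derivatives(np.zeros(params.n), params)
        expect = np.zeros(params.n)
        expect[params.plankton] = params.s
        assert np.allclose(dB, expect)

    def test_three_species_chain_term_by_term(self):
        # hand evaluation of producer/consumer balances on a P->H->C chain
        web = FoodWeb(
            species=["P", "H", "C"],
            links={("H", "P"), ("C", "H")},
            body_mass={"P": 1.0, "H": 1.0, "C": 1.0},
            category={"P": "producer", "H": "herbivore", "C": "carnivore"},
        )
        p = params_from_web(web, K=1.0, B0=0.5, q=1.2, d=0.0, f_a=0.4, f_m=0.1)
        B = np.array([0.6, 0.3, 0.1])
        x, y = p.x[1], p.y[1]  # equal masses: same rates for H and C
        FH = 0.6**1.2 / (0.5**1.2 + 0.6**1.2)  # H on P
        FC = 0.3**1.2 / (0.5**1.2 + 0.3**1.2)  # C on H
        dP = 1.0 * 0.6 * (1 - 0.6 / 1.0) - x * y * 0.3 * FH / 0.45
        dH = 0.4 * x * y * 0.3 * FH - 0.1 * x * 0.3 - x * y * 0.1 * FC / 0.85
        dC = 0.4 * x * y * 0.1 * FC - 0.1 * x * 0.1
        got = derivatives(B, p)
        assert got == pytest.approx([dP, dH, dC], rel=1e-12)

    def test_dimension_mismatch_is_an_error(self, small_synth):
        _, params = small_synth
        with pytest.raises(ATNError):
            derivatives(np.ones(3), params)


class TestIntegration:
    def test_logistic_growth_reaches_carrying_capacity(self):
        p = lone_producer(K=1.0)
        traj = integrate(p, [0.05], 200.0)
        assert abs(traj.final[0] - 1.0) < 1e-4
        # monotone approach from below
        assert np.all(np.diff(traj.B[:, 0]) > -1e-9)

    def test_starving_consumer_is_logged_and_clamped(self):
        web = FoodWeb(
            species=["P", "H"],
            links={("H", "P")},
            body_mass={"P": 1.0, "H": 2.0},
            category={"P": "producer", "H": "herbivore"},
        )
        p = params_from_web(web, K=1.0)
        B0 = np.array([0.0, 0.5])  # no food at all
        traj = integrate(p, B0, 3650.0, alive=np.array([False, True]))
        dead = {name for name, _ in traj.extinct_log}
        assert "H" in dead
        assert traj.final[1] == 0.0

    def test_subsidised_plankton_matches_root_finding_oracle(self):
        p = lone_producer(K=1.0, s=0.3, category="plankton", mass=0.01)
        traj = integrate(p, [0.5], 800.0)
        r = p.r[0]
        root = brentq(lambda b: r * b * (1 - b / 1.0) + 0.3, 1.0, 50.0)
        assert traj.final[0] == pytest.approx(root, abs=1e-6)

    def test_biomass_never_negative(self, small_synth):
        _, params = small_synth
        traj = integrate(params, default_initial_biomass(params, seed=3), 400.0)
        assert np.all(traj.B >= 0)

    def test_extinct_species_stay_at_zero(self, small_synth):
        _, params = small_synth
        B0 = default_initial_biomass(params, seed=3)
        B0[5] = 0.0
        traj = integrate(params, B0, 200.0)
        assert np.all(traj.B[:, 5] == 0.0)

    def test_nonpositive_horizon_rejected(self, small_synth):
        _, params = small_synth
        with pytest.raises(ATNError):
            integrate(params, np.ones(params.n), 0.0)


class TestEquilibrate:
    def test_equilibrium_input_stays_put(self):
        p = lone_producer(K=1.5)
        eq = equilibrate(p, [1.5], T=100.0)
        assert eq.B[0] == pytest.approx(1.5, rel=1e-9)
        assert eq.stationary

    def test_extinctions_reported_with_zero_biomass(self, small_synth):
        # without the subsidy the heavily grazed plankton is competitively
        # excluded and the specialist filter-feeders starve
        web, params = small_synth
        p0 = params.with_subsidy(0.0)
        eq = equilibrate(p0, default_initial_biomass(p0, seed=42))
        ff = {s for s in web.species if web.category[s] == "filter-feeder"}
        assert ff <= eq.extinct
        for s in eq.extinct:
            assert eq.biomass_of(s) == 0.0

    def test_dynamic_collapse_includes_static_starvation(self, chain):
        # bottom-up starvation (static rule) implies dynamic extinction
        p = params_from_web(chain, K=1.0)
        alive = np.array([False, True, True])  # producer removed
        eq = equilibrate(p, np.array([0.0, 0.5, 0.1]), alive=alive)
        assert {"H", "C"} <= eq.extinct


class TestParameterRecovery:
    def test_producer_growth_rate_identifiable_from_trajectory(self):
        # simulate a 10-species web, perturb one producer's r, refit by
        # least squares on the daily trajectory: a sanity check that the
        # simulator is informative about its own rate parameters
        web, params = generate_web(
            SynthSpec(
                S=10,
                C=0.2,
                n_filter_feeders=1,
                n_harvested=2,
                n_carnivores=1,
                n_top_predators=1,
                n_herbivores=1,
                producer_fraction=0.4,
                seed=7,
            )
        )
        i = int(np.where(params.is_producer)[0][1])
        B0 = default_initial_biomass(params, seed=7)
        target = integrate(params, B0, 120.0).B

        true_r = params.r[i]

        def loss(r_val):
            trial = params.r.copy()
            trial[i] = r_val
            import dataclasses

            p2 = dataclasses.replace(params, r=trial)
            return np.sum((integrate(p2, B0, 120.0).B - target) ** 2)

        fit = minimize_scalar(
            loss, bounds=(0.25 * true_r, 4 * true_r), method="bounded",
            options={"xatol": 1e-3 * true_r},
        )
        assert abs(fit.x - true_r) / true_r < 0.05
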