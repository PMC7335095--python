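"""Assembly dynamics: eligibility, competition, risk, cascades, the
Gillespie loop, and trajectory replay."""

import math

import numpy as np
import pytest

from ecoassembly import (
    AssemblyParams,
    PoolParams,
    apply_colonization,
    apply_modifier_loss,
    apply_primary_extinction,
    at_risk,
    at_risk_species,
    colonization_eligible,
    competitive_strength,
    empty_community,
    event_rates,
    generate_pool,
    resolve_cascade,
    run_assembly,
)
from ecoassembly.engine import COLONIZATION, MODIFIER_LOSS, PRIMARY, SECONDARY

from conftest import build_pool


def _colonize(state, pool, *species):
    for s in species:
        apply_colonization(state, pool, s)
    return state


class TestEligibility:
    def test_basal_feeder_eligible_in_empty_community(self, small_pool):
        state = empty_community(small_pool)
        assert colonization_eligible(state, small_pool, 1)

    def test_needs_block_colonization_even_with_food(self, small_pool):
        # species 4 eats 1 and 3 but needs modifier 5
        state = empty_community(small_pool)
        state.present[[1, 3]] = True
        assert not colonization_eligible(state, small_pool, 4)
        state.present[5] = True
        assert colonization_eligible(state, small_pool, 4)

    def test_one_of_several_resources_suffices(self, small_pool):
        state = empty_community(small_pool)
        state.present[[1, 5]] = True  # D eats A or C; only A present
        assert colonization_eligible(state, small_pool, 4)

    def test_present_species_query_is_contract_violation(self, small_pool):
        state = empty_community(small_pool)
        state.present[1] = True
        with pytest.raises(ValueError):
            colonization_eligible(state, small_pool, 1)


class TestCompetitiveStrength:
    @pytest.mark.parametrize(
        "n,e,v,expected",
        [
            (0, 0, 0, 0.0),
            (2, 3, 1, 2 * math.pi - 3 * math.sqrt(2) - 1),   # ~1.0405
            (1, 1, 0, math.pi - math.sqrt(2)),                # ~1.7274
        ],
    )
    def test_hand_evaluations(self, n, e, v, expected):
        # build a community realizing exactly (n, e, v) for species 1
        S = 2 + n + e + v
        eat = {(1, 0)} | {(1, 1 + i) for i in range(1, e + 1)}
        eat |= {(1 + e + i, 1) for i in range(1, v + 1)}
        # predators and resources need their own diet to be present
        eat |= {(s, 0) for s in range(2, S + 1)}
        need = {(1, 1 + e + v + i) for i in range(1, n + 1)}
        pool = build_pool(S, 0, eat=eat, need=need)
        params = AssemblyParams(competition_scope="realized")
        state = empty_community(pool)
        state.present[1 : S + 1] = True
        got = competitive_strength(1, state, pool, params)
        # e counts realized resources other than basal, plus basal when e == 0
        expected_adj = (
            params.c_n * n - params.c_e * (e + 1) - params.c_v * v
        )
        assert got == pytest.approx(expected_adj)
        assert expected == pytest.approx(
            params.c_n * n - params.c_e * e - params.c_v * v
        )

    def test_pool_scope_counts_unrealized_resources(self):
        pool = build_pool(3, 0, eat={(1, 0), (1, 2), (1, 3), (2, 0), (3, 0)})
        state = empty_community(pool)
        state.present[[1, 2]] = True
        realized = competitive_strength(
            1, state, pool, AssemblyParams(competition_scope="realized")
        )
        potential = competitive_strength(
            1, state, pool, AssemblyParams(competition_scope="pool")
        )
        assert potential == pytest.approx(realized - math.sqrt(2))


class TestAtRisk:
    def _two_consumer_pool(self):
        # X(2) and Y(3) share resource R(1); Y has a need (4) boosting sigma
        return build_pool(
            4,
            0,
            eat={(1, 0), (2, 1), (3, 1), (4, 0)},
            need={(3, 4)},
        )

    def test_weaker_consumer_at_risk_stronger_not(self):
        pool = self._two_consumer_pool()
        params = AssemblyParams(basal_competition=False)
        state = empty_community(pool)
        state.present[[1, 2, 3, 4]] = True
        risky = set(at_risk_species(state, pool, params))
        assert 2 in risky and 3 not in risky

    def test_sole_consumer_never_at_risk(self, small_pool):
        state = empty_community(small_pool)
        _colonize(state, small_pool, 1, 2)
        assert not at_risk(2, state, small_pool, AssemblyParams())

    def test_rule_variants_differ_on_partial_dominance(self):
        # two resources: focal species wins on R1, loses on R2
        pool = build_pool(
            5,
            0,
            eat={(1, 0), (2, 0), (3, 1), (3, 2), (4, 2), (5, 3)},
            need={(4, 5)},
        )
        state = empty_community(pool)
        state.present[1:6] = True
        any_rule = AssemblyParams(risk_rule="outcompeted_on_any")
        all_rule = AssemblyParams(risk_rule="outcompeted_on_all")
        # species 4 (needs -> high sigma) beats 3 on resource 2;
        # species 3 is sole consumer of resource 1 so it tops it
        assert at_risk(3, state, pool, any_rule)
        assert not at_risk(3, state, pool, all_rule)

    def test_sigma_ties_are_safe_by_default(self):
        pool = build_pool(3, 0, eat={(1, 0), (2, 1), (3, 1)})
        state = empty_community(pool)
        state.present[1:4] = True
        assert at_risk_species(state, pool, AssemblyParams()).size == 0
        risky = at_risk_species(state, pool, AssemblyParams(tie_risk=True))
        assert set(risky) == {2, 3}

    def test_risk_monotone_in_needs_and_predators(self):
        # more needs (higher sigma) weakly removes risk; more predators adds it
        pool = build_pool(
            6,
            0,
            eat={(1, 0), (2, 1), (3, 1), (4, 2), (5, 0), (6, 0)},
            need={(2, 5), (2, 6)},
        )
        params = AssemblyParams()
        state = empty_community(pool)
        state.present[1:7] = True
        base_risky = set(at_risk_species(state, pool, params))
        assert 3 in base_risky and 2 not in base_risky  # needs protect 2
        pool.eat[4, 2] = False  # drop 2's predator: still safe
        assert 2 not in set(at_risk_species(state, pool, params))


class TestRiskKernelAgreement:
    @pytest.mark.parametrize(
        "scope,rule,tie,basal",
        [
            ("pool", "outcompeted_on_all", False, False),
            ("realized", "outcompeted_on_any", False, False),
            ("pool", "outcompeted_on_any", True, True),
            ("realized", "outcompeted_on_all", True, False),
        ],
    )
    def test_fast_kernel_matches_reference(self, rng, scope, rule, tie, basal):
        """The sparse arena-scan used inside the run loop must agree
        with the dense reference at_risk_species on random states."""
        from ecoassembly.engine import (
            _arena_risk_kernel,
            _consumer_csr,
            strengths,
        )

        params = AssemblyParams(
            competition_scope=scope, risk_rule=rule, tie_risk=tie,
            basal_competition=basal,
        )
        for seed in range(10):
            pool = generate_pool(
                PoolParams(n_species=30, p_e=0.12, p_n=0.03, eta=0.8, seed=seed)
            )
            state = empty_community(pool)
            mask = rng.random(30) < 0.5
            state.present[1:31] = mask
            # random modifiers present too
            for m in pool.modifier_ids:
                state.present[m] = rng.random() < 0.5
            reference = set(at_risk_species(state, pool, params))
            sigma = strengths(state, pool, params)
            indptr, indices = _consumer_csr(pool)
            seen = np.zeros(pool.n_entities, dtype=np.bool_)
            flag = np.zeros(pool.n_entities, dtype=np.bool_)
            _arena_risk_kernel(
                indptr, indices, state.present, sigma,
                rule == "outcompeted_on_any", tie, basal, seen, flag,
            )
            if rule == "outcompeted_on_any":
                fast = set(np.flatnonzero(flag))
            else:
                fast = set(np.flatnonzero(seen & ~flag))
            assert fast == reference


class TestEventRates:
    def test_rate_table_composition(self, small_pool):
        params = AssemblyParams(r_c=2.0, r_e=1.0, r_m=0.5)
        state = empty_community(small_pool)
        table = event_rates(state, small_pool, params)
        assert set(table.colonizers) == {1}
        assert table.total == pytest.approx(2.0)

    def test_density_scaled_modifier_decay(self, small_pool):
        params = AssemblyParams(modifier_decay="density_scaled")
        state = empty_community(small_pool)
        _colonize(state, small_pool, 1)
        state.present[1] = False
        state.disconnected[5] = True
        table = event_rates(state, small_pool, params)
        assert table.rate_m == pytest.approx(params.r_m * 1)

    def test_selection_probability_proportional_to_rate(self):
        from ecoassembly import gillespie_draw

        rng = np.random.default_rng(0)
        rates = np.array([2.0, 1.0])
        picks = np.array([gillespie_draw(rates, rng)[1] for _ in range(3000)])
        frac = (picks == 0).mean()
        se = math.sqrt(2 / 3 * 1 / 3 / 3000)
        assert abs(frac - 2 / 3) < 3 * se


class TestApplyEvents:
    def test_engineer_brings_modifiers(self, small_pool):
        state = empty_community(small_pool)
        apply_colonization(state, small_pool, 1)
        assert state.present[5]
        assert not state.disconnected[5]

    def test_colonization_rescues_disconnected_modifier(self, small_pool):
        state = empty_community(small_pool)
        apply_colonization(state, small_pool, 1)
        state.present[1] = False
        resolve_cascade(state, small_pool)
        assert state.disconnected[5]
        apply_colonization(state, small_pool, 1)
        assert not state.disconnected[5]
        assert state.present[5]

    def test_chain_cascade(self, small_pool):
        # basal <- A(1) <- B(2) <- C(3): removing A removes B and C
        state = empty_community(small_pool)
        _colonize(state, small_pool, 1, 2, 3)
        state.present[1] = False
        _, events = resolve_cascade(state, small_pool, cascade=7)
        assert {e.entity for e in events} == {2, 3}
        assert all(e.kind == SECONDARY and e.cascade == 7 for e in events)

    def test_modifier_loss_removes_needers(self, small_pool):
        small_pool.eat[4, 0] = True  # D can fall back on basal food
        state = empty_community(small_pool)
        _colonize(state, small_pool, 1, 4)
        state.present[1] = False
        _, ev = resolve_cascade(state, small_pool)
        assert state.disconnected[5]
        assert state.present[4]  # modifier still present: D survives
        _, events = apply_modifier_loss(state, small_pool, 5)
        assert not state.present[5]
        assert not state.present[4]  # lost its needed service
        kinds = [e.kind for e in events]
        assert kinds[0] == MODIFIER_LOSS and SECONDARY in kinds

    def test_losing_connected_modifier_is_contract_violation(self, small_pool):
        state = empty_community(small_pool)
        apply_colonization(state, small_pool, 1)
        with pytest.raises(ValueError):
            apply_modifier_loss(state, small_pool, 5)

    def test_cascade_fixpoint_order_independent(self, rng):
        # randomized oracle: sequential single-removal resolution in any
        # order reaches the same survivor set as the simultaneous fixpoint
        for seed in range(30):
            pool = generate_pool(
                PoolParams(n_species=15, p_e=0.15, p_n=0.05, seed=seed)
            )
            state = empty_community(pool)
            order = rng.permutation(15) + 1
            for s in order:
                if not state.present[s] and colonization_eligible(state, pool, s):
                    apply_colonization(state, pool, s)
            victim = next(
                (s for s in range(1, 16) if state.present[s]), None
            )
            if victim is None:
                continue
            ref = state.copy()
            ref.present[victim] = False
            ref, _ = resolve_cascade(ref, pool)

            alt = state.copy()
            alt.present[victim] = False
            removed = True
            while removed:
                removed = False
                for s in rng.permutation(15) + 1:
                    if not alt.present[s]:
                        continue
                    diet_ok = (pool.eat[s] & alt.present).any()
                    needs_ok = not (pool.need[s] & ~alt.present).any()
                    if not (diet_ok and needs_ok):
                        alt.present[s] = False
                        removed = True
            assert np.array_equal(ref.present, alt.present)


class TestRunAssembly:
    def test_single_species_pool_saturates(self):
        pool = build_pool(1, 0, eat={(1, 0)})
        traj = run_assembly(pool, AssemblyParams(max_iterations=50), seed=1)
        assert traj.terminated_early  # absorbing after its colonization
        assert traj.richness[-1] == 1

    def test_seeded_determinism(self, small_pool):
        p = AssemblyParams(max_iterations=200)
        a = run_assembly(small_pool, p, seed=11)
        b = run_assembly(small_pool, p, seed=11)
        assert a.events == b.events
        assert np.array_equal(a.richness, b.richness)

    def test_replay_reproduces_final_state(self):
        pool = generate_pool(PoolParams(n_species=60, p_e=0.04, p_n=0.01, eta=0.8, seed=2))
        traj = run_assembly(pool, AssemblyParams(max_iterations=800), seed=3)
        assert np.array_equal(traj.presence_at(traj.n_iterations), traj.final_present)

    def test_conservation_per_entity(self):
        pool = generate_pool(PoolParams(n_species=50, p_e=0.05, seed=4))
        traj = run_assembly(pool, AssemblyParams(max_iterations=600), seed=5)
        balance = np.zeros(pool.n_entities, dtype=int)
        for ev in traj.events:
            if ev.kind == COLONIZATION:
                balance[ev.entity] += 1
            elif ev.kind in (PRIMARY, SECONDARY, MODIFIER_LOSS):
                balance[ev.entity] -= 1
        final = traj.final_present
        for s in range(1, pool.n_species + 1):
            assert balance[s] == int(final[s])

    def test_invariants_hold_throughout(self):
        pool = generate_pool(PoolParams(n_species=40, p_e=0.06, p_n=0.02, eta=1.0, seed=6))
        run_assembly(
            pool, AssemblyParams(max_iterations=500), seed=7, check_invariants=True
        )

    def test_iteration_counts_trigger_events_only(self):
        pool = generate_pool(PoolParams(n_species=50, p_e=0.05, seed=8))
        traj = run_assembly(pool, AssemblyParams(max_iterations=300), seed=9)
        triggers = {e.iteration for e in traj.events if e.kind != SECONDARY}
        assert len(triggers) == traj.n_iterations
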