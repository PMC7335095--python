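"""Event-driven (Gillespie) assembly of a community from a source pool.

Starting from a community containing only the basal resource, three
event classes compete in continuous time:

* colonization (rate ``r_c`` per eligible species): a pool species whose
  needs are all present and which has at least one present resource may
  enter; an engineer brings its modifiers with it;
* primary extinction (rate ``r_e`` per at-risk species): a species that
  is outcompeted on its resources (see :func:`at_risk`) leaves, possibly
  triggering a deterministic cascade of secondary extinctions;
* modifier loss (rate ``r_m`` per disconnected modifier): a modifier
  whose makers are all gone lingers and then disappears, again possibly
  cascading.

Secondary extinctions — species losing their last present resource or
any needed entity — are resolved instantly to a fixpoint inside the
triggering event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from numba import njit

from .params import AssemblyParams
from .pool import BASAL, SpeciesPool

__all__ = [
    "CommunityState",
    "Event",
    "Trajectory",
    "empty_community",
    "colonization_eligible",
    "eligible_colonizers",
    "competitive_strength",
    "strengths",
    "at_risk",
    "at_risk_species",
    "disconnected_modifiers",
    "event_rates",
    "gillespie_draw",
    "apply_colonization",
    "resolve_cascade",
    "apply_primary_extinction",
    "apply_modifier_loss",
    "run_assembly",
]

COLONIZATION = "colonization"
PRIMARY = "primary_extinction"
SECONDARY = "secondary_extinction"
MODIFIER_LOSS = "modifier_loss"


class Event(NamedTuple):
    kind: str
    entity: int
    time: float
    iteration: int
    cascade: int  # groups a trigger with its secondary extinctions


@dataclass
class CommunityState:
    """Presence/absence of every entity at a moment of the assembly.

    ``present`` is boolean over entities (basal always True).
    ``disconnected`` marks present modifiers whose makers are all absent;
    they persist until their stochastic loss event fires.
    """

    present: np.ndarray
    disconnected: np.ndarray
    time: float = 0.0
    iteration: int = 0

    def copy(self) -> "CommunityState":
        return CommunityState(
            self.present.copy(), self.disconnected.copy(), self.time, self.iteration
        )

    def richness(self, pool: SpeciesPool) -> int:
        return int(self.present[1 : pool.n_species + 1].sum())


def empty_community(pool: SpeciesPool) -> CommunityState:
    present = np.zeros(pool.n_entities, dtype=bool)
    present[BASAL] = True
    return CommunityState(present, np.zeros(pool.n_entities, dtype=bool))


# ---------------------------------------------------------------------
# elementary queries
# ---------------------------------------------------------------------

def colonization_eligible(state: CommunityState, pool: SpeciesPool, species: int) -> bool:
    """True iff ``species`` may colonize: all needs present, >=1 resource present."""
    if state.present[species]:
        raise ValueError(f"species {species} is already present")
    if not pool.is_species(species):
        raise ValueError(f"entity {species} is not a species")
    needs = pool.need[species]
    if np.any(needs & ~state.present):
        return False
    return bool(np.any(pool.eat[species] & state.present))


def eligible_colonizers(state: CommunityState, pool: SpeciesPool) -> np.ndarray:
    """Ids of all absent species currently able to colonize."""
    S = pool.n_species
    sp = slice(1, S + 1)
    pres = state.present.astype(np.float64)
    eat_ok = pool.eat[sp] @ pres > 0
    need_cnt = pool.need[sp].sum(axis=1)
    need_ok = pool.need[sp] @ pres == need_cnt
    mask = ~state.present[sp] & eat_ok & need_ok
    return np.flatnonzero(mask) + 1


def strengths(state: CommunityState, pool: SpeciesPool, params: AssemblyParams) -> np.ndarray:
    """sigma for every species id 1..S (meaningful for present species).

    sigma_i = c_n * n_i - c_e * e_i - c_v * v_i with n_i the number of
    entities i needs (all present by construction for present species),
    e_i its resources under ``params.competition_scope`` and v_i its
    present species consumers.
    """
    S = pool.n_species
    sp = slice(1, S + 1)
    pres = state.present.astype(np.float64)
    n_i = pool.need[sp].sum(axis=1)
    if params.competition_scope == "realized":
        e_i = pool.eat[sp] @ pres
    else:  # pool scope: every resource the species can eat
        e_i = pool.eat[sp].sum(axis=1)
    v_i = pool.species_eat_matrix().T @ pres[sp]
    return params.c_n * n_i - params.c_e * e_i - params.c_v * v_i


def competitive_strength(
    species: int, state: CommunityState, pool: SpeciesPool, params: AssemblyParams
) -> float:
    return float(strengths(state, pool, params)[species - 1])


def _risk_mask(
    sub: np.ndarray, sigma: np.ndarray, any_rule: bool, tie_risk: bool
) -> np.ndarray:
    """Risk flags for present consumers from the arena matrix.

    ``sub[i, r]`` marks consumer i eating arena resource r, ``sigma[i]``
    its competitive strength.  For each consumer the strongest OTHER
    consumer per resource is found via the column top-2, so tie handling
    is explicit: with ``tie_risk`` being "the strongest" requires a
    strictly unique maximum.
    """
    P, E = sub.shape
    with_sigma = np.where(sub, sigma[:, None], -np.inf)
    if not tie_risk:
        # ties share the top, so the column max is all that matters:
        # sigma_i < top1 means strictly outcompeted, sigma_i == top1
        # means (tied-)strongest
        top1 = with_sigma.max(axis=0) if P else np.full(E, -np.inf)
        if any_rule:
            return (sub & (sigma[:, None] < top1[None, :])).any(axis=1)
        best = sub & (sigma[:, None] >= top1[None, :])
        return sub.any(axis=1) & ~best.any(axis=1)
    # strict-uniqueness ties: compare against the strongest OTHER
    # consumer per column, which needs the column top-2
    if P >= 2:
        part = np.partition(with_sigma, P - 2, axis=0)
        top1, top2 = part[-1], part[-2]
    else:
        top1 = with_sigma.max(axis=0) if P else np.full(E, -np.inf)
        top2 = np.full(E, -np.inf)
    other_max = np.where(sigma[:, None] >= top1[None, :], top2[None, :], top1[None, :])
    if any_rule:
        return (sub & (sigma[:, None] <= other_max)).any(axis=1)
    best = sub & (sigma[:, None] > other_max)
    return sub.any(axis=1) & ~best.any(axis=1)


def at_risk_species(
    state: CommunityState, pool: SpeciesPool, params: AssemblyParams
) -> np.ndarray:
    """Ids of present species at risk of competitive exclusion.

    For each present arena resource the strongest present consumer is
    found.  Under "outcompeted_on_any" a species is at risk if it is
    below the top on at least one of its present resources; under
    "outcompeted_on_all" only if it tops none of them.  Tie handling
    follows ``params.tie_risk``.
    """
    S = pool.n_species
    pidx = np.flatnonzero(state.present[1 : S + 1]) + 1
    if pidx.size == 0:
        return pidx
    eidx = np.flatnonzero(state.present)
    if not params.basal_competition:
        eidx = eidx[eidx != BASAL]
    sigma = strengths(state, pool, params)[pidx - 1]
    sub = pool.eat[np.ix_(pidx, eidx)]
    risk = _risk_mask(
        sub, sigma, params.risk_rule == "outcompeted_on_any", params.tie_risk
    )
    return pidx[risk]


def at_risk(
    species: int, state: CommunityState, pool: SpeciesPool, params: AssemblyParams
) -> bool:
    if not state.present[species]:
        raise ValueError(f"species {species} is not present")
    return species in at_risk_species(state, pool, params)


def disconnected_modifiers(state: CommunityState, pool: SpeciesPool) -> np.ndarray:
    """Present modifiers with no present maker (pending stochastic loss)."""
    return np.flatnonzero(state.disconnected)


def _refresh_disconnected(state: CommunityState, pool: SpeciesPool) -> None:
    S = pool.n_species
    if pool.n_modifiers == 0:
        return
    makers_present = pool.make[1 : S + 1, S + 1 :].T @ state.present[1 : S + 1].astype(
        np.float64
    )
    mod_pres = state.present[S + 1 :]
    state.disconnected[S + 1 :] = mod_pres & (makers_present == 0)


# ---------------------------------------------------------------------
# rates and the Gillespie draw
# ---------------------------------------------------------------------

@dataclass
class RateTable:
    """Per-candidate event rates at a moment of the assembly."""

    colonizers: np.ndarray   # species ids
    at_risk: np.ndarray      # species ids
    disconnected: np.ndarray  # modifier ids
    rate_c: float
    rate_e: float
    rate_m: float  # per disconnected modifier

    @property
    def total(self) -> float:
        return (
            self.rate_c * self.colonizers.size
            + self.rate_e * self.at_risk.size
            + self.rate_m * self.disconnected.size
        )

    def entries(self) -> tuple[np.ndarray, np.ndarray]:
        """(entity ids, rates) flattened across the three event classes."""
        ids = np.concatenate([self.colonizers, self.at_risk, self.disconnected])
        rates = np.concatenate(
            [
                np.full(self.colonizers.size, self.rate_c),
                np.full(self.at_risk.size, self.rate_e),
                np.full(self.disconnected.size, self.rate_m),
            ]
        )
        return ids, rates


def event_rates(
    state: CommunityState, pool: SpeciesPool, params: AssemblyParams
) -> RateTable:
    """Rates of every possible next event.  Empty table = absorbing state."""
    disc = disconnected_modifiers(state, pool)
    r_m = params.r_m
    if params.modifier_decay == "density_scaled":
        r_m = params.r_m * disc.size
    return RateTable(
        colonizers=eligible_colonizers(state, pool),
        at_risk=at_risk_species(state, pool, params),
        disconnected=disc,
        rate_c=params.r_c,
        rate_e=params.r_e,
        rate_m=r_m,
    )


def gillespie_draw(rates: np.ndarray, rng: np.random.Generator) -> tuple[float, int]:
    """One Gillespie step over candidate ``rates``.

    Returns the exponential waiting time (mean ``1 / sum(rates)``) and
    the index of the selected event (probability proportional to its
    rate).
    """
    rates = np.asarray(rates, dtype=np.float64)
    total = rates.sum()
    if total <= 0:
        raise ValueError("total rate must be positive")
    dt = rng.exponential(1.0 / total)
    u = rng.random() * total
    idx = int(np.searchsorted(np.cumsum(rates), u, side="right"))
    return dt, min(idx, rates.size - 1)


# ---------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------

def apply_colonization(
    state: CommunityState, pool: SpeciesPool, species: int
) -> CommunityState:
    """Colonize ``species`` (must be eligible); its modifiers arrive too."""
    if not colonization_eligible(state, pool, species):
        raise ValueError(f"species {species} is not eligible to colonize")
    state.present[species] = True
    made = pool.make[species]
    if made.any():
        state.present |= made
    _refresh_disconnected(state, pool)
    return state


def resolve_cascade(
    state: CommunityState,
    pool: SpeciesPool,
    *,
    time: float = 0.0,
    iteration: int = 0,
    cascade: int = 0,
) -> tuple[CommunityState, list[Event]]:
    """Remove every present species left unsupported, to a fixpoint.

    A present species is unsupported when none of its resources is
    present or any of its needed entities is absent.  All violators are
    removed simultaneously each pass, which makes the fixpoint
    independent of removal order.  Modifiers whose last maker is removed
    become disconnected (they stay present until their own loss event).
    """
    S = pool.n_species
    sp = slice(1, S + 1)
    need_cnt = pool.need[sp].sum(axis=1)
    events: list[Event] = []
    while True:
        pres = state.present.astype(np.float64)
        supported = (pool.eat[sp] @ pres > 0) & (pool.need[sp] @ pres == need_cnt)
        violators = np.flatnonzero(state.present[sp] & ~supported) + 1
        if violators.size == 0:
            break
        state.present[violators] = False
        for s in violators:
            events.append(Event(SECONDARY, int(s), time, iteration, cascade))
    _refresh_disconnected(state, pool)
    return state, events


def apply_primary_extinction(
    state: CommunityState,
    pool: SpeciesPool,
    species: int,
    *,
    time: float = 0.0,
    iteration: int = 0,
    cascade: int = 0,
) -> tuple[CommunityState, list[Event]]:
    """Remove ``species`` by competitive exclusion and resolve the cascade."""
    if not state.present[species]:
        raise ValueError(f"species {species} is not present")
    state.present[species] = False
    events = [Event(PRIMARY, int(species), time, iteration, cascade)]
    _refresh_disconnected(state, pool)
    state, secondary = resolve_cascade(
        state, pool, time=time, iteration=iteration, cascade=cascade
    )
    events.extend(secondary)
    return state, events


def apply_modifier_loss(
    state: CommunityState,
    pool: SpeciesPool,
    modifier: int,
    *,
    time: float = 0.0,
    iteration: int = 0,
    cascade: int = 0,
) -> tuple[CommunityState, list[Event]]:
    """Remove a disconnected ``modifier`` and resolve the cascade."""
    if not state.disconnected[modifier]:
        raise ValueError(f"modifier {modifier} is not disconnected")
    state.present[modifier] = False
    state.disconnected[modifier] = False
    events = [Event(MODIFIER_LOSS, int(modifier), time, iteration, cascade)]
    state, secondary = resolve_cascade(
        state, pool, time=time, iteration=iteration, cascade=cascade
    )
    events.extend(secondary)
    return state, events


@njit(cache=True)
def _arena_risk_kernel(
    indptr, indices, present, sigma, any_rule, tie_risk, include_basal,
    seen, flag,
):
    """Per-resource competition scan over the sparse consumer lists.

    ``indices[indptr[r]:indptr[r+1]]`` are the species able to eat
    entity r.  Fills ``seen[s]`` (species s eats >=1 present arena
    resource) and ``flag[s]`` — under the any-rule: s is strictly beaten
    somewhere; under the all-rule: s is (tied-)best somewhere, or
    uniquely best when ties are risky.
    """
    seen[:] = False
    flag[:] = False
    n = present.shape[0]
    start = 0 if include_basal else 1
    for r in range(start, n):
        if not present[r]:
            continue
        top = -1.0e300
        topcount = 0
        for k in range(indptr[r], indptr[r + 1]):
            s = indices[k]
            if present[s]:
                v = sigma[s - 1]
                if v > top:
                    top = v
                    topcount = 1
                elif v == top:
                    topcount += 1
        if topcount == 0:
            continue
        for k in range(indptr[r], indptr[r + 1]):
            s = indices[k]
            if not present[s]:
                continue
            v = sigma[s - 1]
            seen[s] = True
            if any_rule:
                if v < top or (tie_risk and v == top and topcount > 1):
                    flag[s] = True
            else:
                if v == top and not (tie_risk and topcount > 1):
                    flag[s] = True


def _consumer_csr(pool: SpeciesPool) -> tuple[np.ndarray, np.ndarray]:
    """CSR lists of potential consumers (species ids) per entity."""
    S = pool.n_species
    cols = pool.eat[1 : S + 1]  # (S, N): consumer rows
    counts = cols.sum(axis=0)
    indptr = np.zeros(pool.n_entities + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(counts)
    src, dst = np.nonzero(cols)
    order = np.argsort(dst, kind="stable")
    indices = (src[order] + 1).astype(np.int64)
    return indptr, indices


# ---------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------

@dataclass
class Trajectory:
    """Complete record of one assembly run.

    ``richness[k]``, ``n_links[k]`` and ``times[k]`` describe the state
    after iteration k (index 0 is the initial basal-only community);
    ``n_links`` counts realized species-species trophic links.  The event
    log is sufficient to reconstruct the presence vector at any
    iteration, see :meth:`presence_at` and :meth:`snapshots`.
    """

    pool: SpeciesPool
    params: AssemblyParams
    events: list[Event]
    richness: np.ndarray
    n_links: np.ndarray
    times: np.ndarray
    seed: object = None
    terminated_early: bool = False
    termination_reason: str = "max_iterations"
    final_present: np.ndarray | None = None
    final_disconnected: np.ndarray | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.richness) - 1

    def _replay(self, present: np.ndarray, event: Event) -> None:
        if event.kind == COLONIZATION:
            present[event.entity] = True
            present |= self.pool.make[event.entity]
        else:
            present[event.entity] = False

    def snapshots(self, iterations: Sequence[int]) -> Iterator[tuple[int, np.ndarray]]:
        """Yield (iteration, presence vector) for sorted ``iterations``."""
        iterations = sorted(int(i) for i in iterations)
        present = np.zeros(self.pool.n_entities, dtype=bool)
        present[BASAL] = True
        ei = 0
        for it in iterations:
            if it > self.n_iterations:
                raise IndexError(f"iteration {it} beyond trajectory ({self.n_iterations})")
            while ei < len(self.events) and self.events[ei].iteration <= it:
                self._replay(present, self.events[ei])
                ei += 1
            yield it, present.copy()

    def presence_at(self, iteration: int) -> np.ndarray:
        for _, snap in self.snapshots([iteration]):
            return snap
        raise AssertionError  # pragma: no cover

    def state_at(self, iteration: int) -> CommunityState:
        present = self.presence_at(iteration)
        state = CommunityState(present, np.zeros_like(present), iteration=iteration)
        _refresh_disconnected(state, self.pool)
        it = min(iteration, self.n_iterations)
        state.time = float(self.times[it])
        return state

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(self.events, columns=Event._fields)


# ---------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------

def _count_links(pool: SpeciesPool, present: np.ndarray) -> int:
    sp = present[1 : pool.n_species + 1]
    ess = pool.species_eat_matrix()
    return int((ess @ sp.astype(np.float64))[sp].sum())

def _check_state(state: CommunityState, pool: SpeciesPool) -> None:
    assert state.present[BASAL], "basal resource must always be present"
    S = pool.n_species
    sp = slice(1, S + 1)
    pres = state.present.astype(np.float64)
    need_cnt = pool.need[sp].sum(axis=1)
    supported = (pool.eat[sp] @ pres > 0) & (pool.need[sp] @ pres == need_cnt)
    assert not np.any(state.present[sp] & ~supported), "unsupported species present"
    if pool.n_modifiers:
        makers = pool.make[sp, S + 1 :].T @ pres[sp]
        mod_pres = state.present[S + 1 :]
        bad = mod_pres & (makers == 0) & ~state.disconnected[S + 1 :]
        assert not bad.any(), "maker-less modifier not flagged as disconnected"


def run_assembly(
    pool: SpeciesPool,
    params: AssemblyParams,
    seed=None,
    *,
    check_invariants: bool = False,
) -> Trajectory:
    """Run one Gillespie assembly on ``pool`` and return its trajectory.

    One iteration is one stochastic event (colonization, primary
    extinction or modifier loss) together with the deterministic cascade
    it triggers.  The run stops after ``params.max_iterations`` events or
    earlier if no event is possible (absorbing state, recorded in
    ``termination_reason``).
    """
    if seed is None:
        seed = params.seed
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    elif isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    S = pool.n_species
    sp = slice(1, S + 1)
    eat_sn = pool.eat[sp].astype(np.float64)
    need_sn = pool.need[sp].astype(np.float64)
    need_cnt = need_sn.sum(axis=1)
    eat_ss_T = pool.species_eat_matrix().T.astype(np.float64)
    pool_eat_tot = eat_sn.sum(axis=1)
    realized_scope = params.competition_scope == "realized"
    any_rule = params.risk_rule == "outcompeted_on_any"
    density_scaled = params.modifier_decay == "density_scaled"
    basal_arena = params.basal_competition
    tie_risk = params.tie_risk
    csr_indptr, csr_indices = _consumer_csr(pool)
    seen_buf = np.zeros(pool.n_entities, dtype=np.bool_)
    flag_buf = np.zeros(pool.n_entities, dtype=np.bool_)

    state = empty_community(pool)
    events: list[Event] = []
    n_iter = params.max_iterations
    richness = np.zeros(n_iter + 1, dtype=np.int32)
    n_links = np.zeros(n_iter + 1, dtype=np.int32)
    times = np.zeros(n_iter + 1, dtype=np.float64)
    terminated = False
    reason = "max_iterations"

    it = 0
    while it < n_iter:
        pres = state.present.astype(np.float64)
        pres_sp = state.present[sp]

        realized_eat = eat_sn @ pres
        need_have = need_sn @ pres
        eligible = np.flatnonzero(
            ~pres_sp & (realized_eat > 0) & (need_have == need_cnt)
        ) + 1

        if pres_sp.any():
            e_i = realized_eat if realized_scope else pool_eat_tot
            sigma_all = params.c_n * need_cnt - params.c_e * e_i - params.c_v * (
                eat_ss_T @ pres[sp]
            )
            _arena_risk_kernel(
                csr_indptr, csr_indices, state.present, sigma_all,
                any_rule, tie_risk, basal_arena, seen_buf, flag_buf,
            )
            if any_rule:
                risky = np.flatnonzero(flag_buf)
            else:
                risky = np.flatnonzero(seen_buf & ~flag_buf)
        else:
            risky = np.empty(0, dtype=np.int64)

        disc = np.flatnonzero(state.disconnected)
        rate_m = params.r_m * disc.size if density_scaled else params.r_m
        total = (
            params.r_c * eligible.size
            + params.r_e * risky.size
            + rate_m * disc.size
        )
        if total <= 0:
            terminated = True
            reason = "absorbing_state"
            break

        dt = rng.exponential(1.0 / total)
        state.time += dt
        it += 1
        state.iteration = it
        u = rng.random() * total
        rc_block = params.r_c * eligible.size
        re_block = rc_block + params.r_e * risky.size
        if u < rc_block:
            species = int(eligible[min(int(u / params.r_c), eligible.size - 1)])
            state.present[species] = True
            made = pool.make[species]
            if made.any():
                state.present |= made
                _refresh_disconnected(state, pool)
            events.append(Event(COLONIZATION, species, state.time, it, it))
        elif u < re_block:
            species = int(risky[min(int((u - rc_block) / params.r_e), risky.size - 1)])
            _, evs = apply_primary_extinction(
                state, pool, species, time=state.time, iteration=it, cascade=it
            )
            events.extend(evs)
        else:
            modifier = int(disc[min(int((u - re_block) / rate_m), disc.size - 1)])
            _, evs = apply_modifier_loss(
                state, pool, modifier, time=state.time, iteration=it, cascade=it
            )
            events.extend(evs)

        richness[it] = int(state.present[sp].sum())
        n_links[it] = _count_links(pool, state.present)
        times[it] = state.time
        if check_invariants:
            _check_state(state, pool)

    if terminated:
        # freeze the remaining iterations at the absorbing state
        richness[it + 1 :] = richness[it]
        n_links[it + 1 :] = n_links[it]
        times[it + 1 :] = times[it]
        richness = richness[: it + 1]
        n_links = n_links[: it + 1]
        times = times[: it + 1]

    return Trajectory(
        pool=pool,
        params=params,
        events=events,
        richness=richness,
        n_links=n_links,
        times=times,
        seed=seed,
        terminated_early=terminated,
        termination_reason=reason,
        final_present=state.present.copy(),
        final_disconnected=state.disconnected.copy(),
    )
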