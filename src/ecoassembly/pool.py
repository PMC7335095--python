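"""Source-pool generation: species, modifiers, and eat/need/make relations.

Entities are indexed densely: 0 is the abiotic basal resource, 1..S are
species, and S+1..S+M' are abiotic modifiers.  The three interaction
relations are stored as boolean adjacency matrices over all entities,
``rel[x, y]`` meaning "x eats y" / "x needs y" / "x makes y".  Only
species ever originate eat, need or make links; modifiers and the basal
resource are passive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterError, PoolParams

__all__ = [
    "BASAL",
    "SpeciesPool",
    "draw_modifier_assignment",
    "sample_interactions",
    "ensure_basal_rules",
    "generate_pool",
    "validate_pool",
]

BASAL = 0  # entity index of the basal resource


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SpeciesPool:
    """A static source pool of S species, M' modifiers and a basal resource.

    Attributes
    ----------
    n_species, n_modifiers
        Counts S and M'.  Total entities N = 1 + S + M'.
    eat, need, make
        Boolean (N, N) adjacency matrices, row = source, col = target.
    params
        The :class:`PoolParams` the pool was drawn from (None for pools
        assembled by hand or loaded from minimal files).
    """

    n_species: int
    n_modifiers: int
    eat: np.ndarray
    need: np.ndarray
    make: np.ndarray
    params: PoolParams | None = None

    # -- index helpers -------------------------------------------------
    @property
    def n_entities(self) -> int:
        return 1 + self.n_species + self.n_modifiers

    @property
    def species_ids(self) -> np.ndarray:
        return np.arange(1, self.n_species + 1)

    @property
    def modifier_ids(self) -> np.ndarray:
        return np.arange(self.n_species + 1, self.n_entities)

    def is_species(self, i: int) -> bool:
        return 1 <= i <= self.n_species

    def is_modifier(self, i: int) -> bool:
        return self.n_species < i < self.n_entities

    def category(self, i: int) -> str:
        if i == BASAL:
            return "basal"
        if self.is_species(i):
            return "species"
        if self.is_modifier(i):
            return "modifier"
        raise IndexError(f"entity {i} outside pool of {self.n_entities} entities")

    # -- convenience views ---------------------------------------------
    def makers_of(self, modifier: int) -> np.ndarray:
        """Species ids that make ``modifier``."""
        return np.flatnonzero(self.make[:, modifier])

    def engineers(self) -> np.ndarray:
        """Species ids that make at least one modifier."""
        return np.flatnonzero(self.make.any(axis=1))

    def species_eat_matrix(self) -> np.ndarray:
        """Species-species trophic submatrix (S, S), basal excluded."""
        s = slice(1, self.n_species + 1)
        return self.eat[s, s]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpeciesPool):
            return NotImplemented
        return (
            self.n_species == other.n_species
            and self.n_modifiers == other.n_modifiers
            and np.array_equal(self.eat, other.eat)
            and np.array_equal(self.need, other.need)
            and np.array_equal(self.make, other.make)
        )


def draw_modifier_assignment(
    n_species: int, eta: float, redundant: bool, rng
) -> np.ndarray:
    """Draw the make relation as a boolean (S, M') species-by-modifier matrix.

    Each species makes ``Poisson(eta)`` modifiers.  In redundant mode the
    make links target ``round(eta * S)`` candidate modifier slots
    uniformly at random; slots nobody makes are dropped and survivors are
    re-indexed densely, so the expected surviving count is
    ``eta * S * (e - 1) / e``.  In unique mode every link creates a fresh
    modifier, so each modifier has exactly one maker and M' is the total
    number of links drawn.
    """
    if n_species < 1:
        raise ParameterError(f"n_species must be >= 1, got {n_species}")
    if eta < 0:
        raise ParameterError(f"eta must be >= 0, got {eta}")
    rng = _rng(rng)
    counts = rng.poisson(eta, size=n_species)
    total = int(counts.sum())
    sources = np.repeat(np.arange(n_species), counts)
    if total == 0:
        return np.zeros((n_species, 0), dtype=bool)
    if redundant:
        n_slots = int(round(eta * n_species))
        if n_slots == 0:
            return np.zeros((n_species, 0), dtype=bool)
        slots = rng.integers(0, n_slots, size=total)
        used, dense = np.unique(slots, return_inverse=True)
        make = np.zeros((n_species, used.size), dtype=bool)
        make[sources, dense] = True
    else:
        make = np.zeros((n_species, total), dtype=bool)
        make[sources, np.arange(total)] = True
    return make


def sample_interactions(
    n_species: int, n_modifiers: int, params: PoolParams, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the eat and need relations as boolean (N, N) matrices.

    Species-species links are i.i.d. Bernoulli(p_e)/Bernoulli(p_n) per
    ordered pair, species-modifier links Bernoulli(q_e)/Bernoulli(q_n).
    Self-interactions are excluded; nothing targets or originates from
    the basal resource here (basal links are handled by
    :func:`ensure_basal_rules`) and no species needs the basal resource.
    """
    rng = _rng(rng)
    n = 1 + n_species + n_modifiers
    eat = np.zeros((n, n), dtype=bool)
    need = np.zeros((n, n), dtype=bool)
    sp = slice(1, n_species + 1)
    mod = slice(n_species + 1, n)

    ss_eat = rng.random((n_species, n_species)) < params.p_e
    ss_need = rng.random((n_species, n_species)) < params.p_n
    np.fill_diagonal(ss_eat, False)
    np.fill_diagonal(ss_need, False)
    eat[sp, sp] = ss_eat
    need[sp, sp] = ss_need

    if n_modifiers:
        eat[sp, mod] = rng.random((n_species, n_modifiers)) < params.q_e_resolved
        need[sp, mod] = rng.random((n_species, n_modifiers)) < params.q_n_resolved
    return eat, need


def ensure_basal_rules(pool: SpeciesPool, p_e: float, rng) -> SpeciesPool:
    """Apply the basal-resource rules in place and return the pool.

    The first species (entity 1) always eats the basal resource; every
    other species eats it with probability ``p_e``; finally any species
    left with an empty diet is linked to basal (treated as a primary
    producer).  The Bernoulli draw happens before the fallback.
    """
    rng = _rng(rng)
    S = pool.n_species
    pool.eat[1, BASAL] = True
    if S > 1:
        draws = rng.random(S - 1) < p_e
        pool.eat[2 : S + 1, BASAL] |= draws
    diet_sizes = pool.eat[1 : S + 1].sum(axis=1)
    orphans = np.flatnonzero(diet_sizes == 0) + 1
    pool.eat[orphans, BASAL] = True
    return pool


def generate_pool(params: PoolParams, seed=None) -> SpeciesPool:
    """Generate a complete, valid source pool from ``params``.

    Deterministic given a seed.  ``seed`` (int, SeedSequence or
    Generator) overrides ``params.seed`` when given.
    """
    if seed is None:
        seed = params.seed
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = _rng(seed)
    S = params.n_species
    make_sm = draw_modifier_assignment(
        S, params.eta, params.redundant_engineering, rng
    )
    M = make_sm.shape[1]
    eat, need = sample_interactions(S, M, params, rng)
    n = 1 + S + M
    make = np.zeros((n, n), dtype=bool)
    if M:
        make[1 : S + 1, S + 1 :] = make_sm
    pool = SpeciesPool(S, M, eat, need, make, params=params)
    ensure_basal_rules(pool, params.p_e, rng)
    return pool


def validate_pool(pool: SpeciesPool) -> list[str]:
    """Check every structural invariant; return a list of violations.

    An empty list means the pool is well formed.  Checked invariants:
    only species originate eat/need/make links; make targets are
    modifiers; every modifier has at least one maker; every species has a
    non-empty diet; species 1 eats basal; nothing needs the basal
    resource; no self-interactions; matrices are square and consistent
    with the declared counts.
    """
    v: list[str] = []
    n = pool.n_entities
    for name, rel in (("eat", pool.eat), ("need", pool.need), ("make", pool.make)):
        if rel.shape != (n, n):
            v.append(f"{name} matrix shape {rel.shape} != ({n}, {n})")
            return v
        if np.diagonal(rel).any():
            v.append(f"{name} relation contains self-interactions")
    S = pool.n_species
    sp = slice(1, S + 1)
    non_species = np.ones(n, dtype=bool)
    non_species[sp] = False
    for name, rel in (("eat", pool.eat), ("need", pool.need), ("make", pool.make)):
        if rel[non_species].any():
            v.append(f"non-species entities originate {name} links")
    if pool.make[:, : S + 1].any():
        v.append("make links target non-modifier entities")
    if pool.n_modifiers:
        maker_counts = pool.make[sp, S + 1 :].sum(axis=0)
        for m in np.flatnonzero(maker_counts == 0):
            v.append(f"orphan modifier {S + 1 + m} has no maker")
    if pool.need[:, BASAL].any():
        v.append("a species needs the basal resource")
    diet = pool.eat[sp].sum(axis=1)
    for i in np.flatnonzero(diet == 0):
        v.append(f"unsupported species {i + 1} has an empty diet")
    if S >= 1 and not pool.eat[1, BASAL]:
        v.append("species 1 does not eat the basal resource")
    return v
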