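"""Parameter containers for pool generation and assembly dynamics.

All model scalars live here.  ``PoolParams`` describes the static source
pool (pool size, interaction probabilities, engineering intensity) and
``AssemblyParams`` the event-driven dynamics (competition coefficients,
event rates, iteration budget, rule variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = ["ParameterError", "PoolParams", "AssemblyParams"]


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


COMPETITION_SCOPES = ("realized", "pool")
RISK_RULES = ("outcompeted_on_any", "outcompeted_on_all")
MODIFIER_DECAYS = ("constant", "density_scaled")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class PoolParams:
    """Source-pool configuration.

    Parameters
    ----------
    n_species
        Number of species S in the pool (the basal resource is extra).
    eta
        Expected number of abiotic modifiers made per species; each
        species makes ``Poisson(eta)`` modifiers.  ``eta = 0`` disables
        ecosystem engineering entirely.
    p_e, p_n
        Per ordered species pair, the probability that one eats /
        obligately needs the other.
    q_e, q_n
        Species-modifier analogues of ``p_e``/``p_n``.  ``None`` means
        "same as the species-species probability", the simplifying
        assumption used throughout.
    redundant_engineering
        If True, modifier identities are shared: every make link targets
        one of ``round(eta * S)`` candidate modifiers uniformly at random,
        so several engineers can make the same modifier.  If False each
        make link creates a fresh modifier with a single maker.
    seed
        RNG seed for pool generation; ``None`` draws fresh entropy.
    """

    n_species: int = 200
    eta: float = 0.0
    p_e: float = 0.01
    p_n: float = 0.0
    q_e: float | None = None
    q_n: float | None = None
    redundant_engineering: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ParameterError(f"n_species must be >= 1, got {self.n_species}")
        if self.eta < 0:
            raise ParameterError(f"eta must be >= 0, got {self.eta}")
        _check_prob("p_e", self.p_e)
        _check_prob("p_n", self.p_n)
        if self.q_e is not None:
            _check_prob("q_e", self.q_e)
        if self.q_n is not None:
            _check_prob("q_n", self.q_n)

    @property
    def q_e_resolved(self) -> float:
        return self.p_e if self.q_e is None else self.q_e

    @property
    def q_n_resolved(self) -> float:
        return self.p_n if self.q_n is None else self.q_n

    def replace(self, **kwargs) -> "PoolParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AssemblyParams:
    """Dynamics configuration for the event-driven assembly process.

    Competitive strength of a present species i is

        sigma_i = c_n * n_i - c_e * e_i - c_v * v_i

    where n_i counts its needs, e_i its resources (realized or pool
    scope) and v_i its present consumers.  The ordering c_n > c_e > c_v
    is required: gaining a mutualistic service helps more than an extra
    resource or predator hurts.

    ``r_c``, ``r_e`` and ``r_m`` are the per-candidate Gillespie rates of
    colonization, primary extinction of an at-risk species, and decay of
    a maker-less ("disconnected") modifier.

    Rule variants
    -------------
    competition_scope
        "pool" (default) counts every resource the species can eat when
        computing e_i; "realized" counts only resources present in the
        community.  The default is the calibrated cell of the rule-
        variant grid (see docs/methods.md).
    risk_rule
        "outcompeted_on_all" (default): a species is at risk only when
        it is the strongest consumer on none of its present resources.
        "outcompeted_on_any": at risk as soon as some other present
        consumer is strictly stronger on at least one of them.
    modifier_decay
        "constant": each disconnected modifier decays at rate r_m;
        "density_scaled": at rate r_m * D where D is the current number
        of disconnected modifiers (shorter lingering when many).
    basal_competition
        Whether the abiotic basal resource counts as an arena in the
        per-resource competition comparison.  Default False: the basal
        resource is non-limiting, so consumers are never excluded over
        it (biotic resources and engineered modifiers always compete).
    tie_risk
        How sigma ties are read against "the strongest competitor".
        False (default): a consumer tied for the top on a resource
        counts as strongest there (ties never create risk).  True: being
        strongest requires a strictly unique maximum, so tied consumers
        are all at risk on that resource.
    """

    c_n: float = math.pi
    c_e: float = math.sqrt(2.0)
    c_v: float = 1.0
    r_c: float = 1.0
    r_e: float = 1.0
    r_m: float = 1.0
    max_iterations: int = 4000
    competition_scope: str = "pool"
    risk_rule: str = "outcompeted_on_all"
    modifier_decay: str = "constant"
    basal_competition: bool = False
    tie_risk: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.c_n > self.c_e > self.c_v):
            raise ParameterError(
                "competition coefficients must satisfy c_n > c_e > c_v, got "
                f"c_n={self.c_n}, c_e={self.c_e}, c_v={self.c_v}"
            )
        for name in ("r_c", "r_e", "r_m"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.competition_scope not in COMPETITION_SCOPES:
            raise ParameterError(
                f"competition_scope must be one of {COMPETITION_SCOPES}"
            )
        if self.risk_rule not in RISK_RULES:
            raise ParameterError(f"risk_rule must be one of {RISK_RULES}")
        if self.modifier_decay not in MODIFIER_DECAYS:
            raise ParameterError(f"modifier_decay must be one of {MODIFIER_DECAYS}")

    def replace(self, **kwargs) -> "AssemblyParams":
        return replace(self, **kwargs)


def params_to_dict(p) -> dict:
    """Flat dict of a params dataclass (for manifests and headers)."""
    return {f.name: getattr(p, f.name) for f in fields(p)}
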