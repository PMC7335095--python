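"""Structural and dynamical measures of assembled communities.

All species-level metrics (connectance, generality, trophic levels,
UNODF) are computed over realized species-species links; the basal
resource and abiotic modifiers do not count toward richness or link
totals, except that the basal resource anchors the trophic-level
recursion at level 0 (so strict autotrophs sit exactly at level 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import PRIMARY, SECONDARY, COLONIZATION, CommunityState, Trajectory
from .pool import BASAL, SpeciesPool

__all__ = [
    "connectance",
    "TrophicProfile",
    "trophic_levels",
    "GeneralityProfile",
    "generality",
    "combined_adjacency",
    "unodf",
    "steady_state_window",
    "steady_state_onset",
    "extinction_rates",
    "persistence",
    "trophic_mode",
]


def _present_species(state: CommunityState, pool: SpeciesPool) -> np.ndarray:
    return np.flatnonzero(state.present[1 : pool.n_species + 1]) + 1


def connectance(state: CommunityState, pool: SpeciesPool) -> float:
    """Trophic connectance C = L / S^2 over realized species-species links."""
    ids = _present_species(state, pool)
    if ids.size == 0:
        raise ValueError("connectance undefined for a community with no species")
    L = int(pool.eat[np.ix_(ids, ids)].sum())
    return L / ids.size**2


@dataclass
class TrophicProfile:
    """Prey-averaged trophic levels of the present species.

    ``levels`` maps entity id -> trophic level for present species;
    abiotic entities (basal, modifiers) sit at level 0 by convention, so
    a species eating only abiotic resources has level exactly 1.
    """

    species: np.ndarray   # entity ids, aligned with values
    values: np.ndarray

    @property
    def tl_max(self) -> float:
        return float(self.values.max()) if self.values.size else float("nan")

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else float("nan")

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(v) for s, v in zip(self.species, self.values)}


def trophic_levels(state: CommunityState, pool: SpeciesPool) -> TrophicProfile:
    """Solve the prey-averaged trophic-level system over present species.

    TL_i = 1 + mean(TL_r over the present diet of i), with abiotic
    resources fixed at level 0.  Solving the linear system (rather than
    recursing) handles trophic cycles; the solution satisfies TL >= 1
    for every supported species.
    """
    ids = _present_species(state, pool)
    if ids.size == 0:
        return TrophicProfile(ids, np.empty(0))
    diets = pool.eat[ids] & state.present[None, :]
    k = diets.sum(axis=1).astype(np.float64)
    if np.any(k == 0):
        raise ValueError("present species with empty realized diet (cascade not resolved?)")

    # A trophic level is only defined for species whose energy can be
    # traced to an abiotic source.  Species supported purely by a
    # detached trophic cycle (rare, but reachable through cascades that
    # sever a cycle's link to the base) make the prey-averaged system
    # singular; they are excluded from the profile.
    abiotic = np.ones(pool.n_entities, dtype=bool)
    abiotic[1 : pool.n_species + 1] = False
    anchored = (diets & abiotic[None, :]).any(axis=1)
    sub = diets[:, ids]  # species-species realized links
    while True:
        newly = ~anchored & (sub & anchored[None, :]).any(axis=1)
        if not newly.any():
            break
        anchored |= newly
    aidx = np.flatnonzero(anchored)
    W = sub[np.ix_(aidx, aidx)].astype(np.float64) / k[aidx, None]
    tl = np.linalg.solve(np.eye(aidx.size) - W, np.ones(aidx.size))
    return TrophicProfile(ids[aidx], tl)


@dataclass
class GeneralityProfile:
    """Scaled trophic generality G_i = k_i_in / (L*/S*) of present species."""

    species: np.ndarray
    values: np.ndarray
    mode: str
    reference_density: float

    @property
    def specialist_fraction(self) -> float:
        if self.values.size == 0:
            return float("nan")
        return float(np.mean(self.values < 1.0))

    @property
    def generalist_fraction(self) -> float:
        if self.values.size == 0:
            return float("nan")
        return float(np.mean(self.values > 1.0))


def generality(
    state: CommunityState,
    pool: SpeciesPool,
    reference_density: float,
    mode: str = "functional",
) -> GeneralityProfile:
    """Trophic generality of each present species.

    ``functional`` counts realized species-species resources (links to
    basal and modifiers are ignored); ``potential`` counts every species
    resource in the pool, as if all its trophic interactions were
    realized.  ``reference_density`` is the steady-state link density
    L*/S* used as the specialist/generalist cutoff scale.
    """
    if reference_density <= 0:
        raise ValueError("reference_density must be > 0")
    if mode not in ("functional", "potential"):
        raise ValueError(f"unknown generality mode {mode!r}")
    ids = _present_species(state, pool)
    sp = slice(1, pool.n_species + 1)
    if mode == "functional":
        k_in = (pool.eat[ids, sp] & state.present[None, sp]).sum(axis=1)
    else:
        k_in = pool.eat[ids, sp].sum(axis=1)
    return GeneralityProfile(ids, k_in / reference_density, mode, reference_density)


def combined_adjacency(state: CommunityState, pool: SpeciesPool) -> np.ndarray:
    """Binary adjacency over present species: trophic OR service link."""
    ids = _present_species(state, pool)
    A = pool.eat[np.ix_(ids, ids)] | pool.need[np.ix_(ids, ids)]
    np.fill_diagonal(A, False)
    return A


def unodf(adjacency: np.ndarray) -> float:
    """Unipartite nestedness based on overlap and decreasing fill.

    For every unordered node pair the overlap of the lower-degree node's
    neighborhood within the higher-degree node's is scored
    ``|N_i & N_j| / k_low`` when ``k_high > k_low > 0`` (equal degrees or
    an empty neighborhood score 0).  The mean over all pairs is taken
    once for out-neighborhoods (rows) and once for in-neighborhoods
    (columns); UNODF is the average of the two.  The diagonal is ignored.
    """
    A = np.asarray(adjacency)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(A, (0, 1, True, False)).all():
        raise ValueError("adjacency must be binary")
    A = A.astype(bool).copy()
    np.fill_diagonal(A, False)
    n = A.shape[0]
    if n < 2:
        return 0.0

    def _score(M: np.ndarray) -> float:
        k = M.sum(axis=1).astype(np.float64)
        overlap = (M.astype(np.float64) @ M.T.astype(np.float64))
        kmin = np.minimum(k[:, None], k[None, :])
        valid = (k[:, None] != k[None, :]) & (kmin > 0)
        contrib = np.where(valid, overlap / np.where(kmin > 0, kmin, 1.0), 0.0)
        iu = np.triu_indices(n, 1)
        return float(contrib[iu].sum()) / (n * (n - 1) / 2)

    return 0.5 * (_score(A) + _score(A.T))


# ---------------------------------------------------------------------
# trajectory-level measures
# ---------------------------------------------------------------------

def steady_state_window(trajectory: Trajectory, fraction: float = 0.5) -> tuple[int, int]:
    """Default steady-state window: the final ``fraction`` of iterations."""
    n = trajectory.n_iterations
    if n < 2:
        raise ValueError("trajectory too short for a steady-state window")
    start = int(np.floor(n * (1.0 - fraction)))
    return start, n


def steady_state_onset(
    richness: np.ndarray, window: int = 50, tol: float = 0.05
) -> int | None:
    """Earliest iteration after which richness stops drifting.

    Compares trailing sliding-window means of S(t): the onset is the
    smallest t such that from t onward every consecutive pair of
    adjacent windows of length ``window`` differs by less than ``tol``
    relative.  Returns None when the plateau is never reached.
    """
    s = np.asarray(richness, dtype=np.float64)
    if s.size < 2 * window + 1:
        raise ValueError("trajectory shorter than two sliding windows")
    c = np.concatenate([[0.0], np.cumsum(s)])
    means = (c[window:] - c[:-window]) / window  # means[t] = mean(s[t:t+window])
    prev = means[:-window]
    nxt = means[window:]
    denom = np.maximum(np.abs(prev), 1e-12)
    ok = np.abs(nxt - prev) / denom < tol
    if not ok.any():
        return None
    # suffix condition: stable from t onward
    bad = np.flatnonzero(~ok)
    onset = 0 if bad.size == 0 else int(bad[-1]) + 1
    if onset >= ok.size:
        return None
    return onset


def extinction_rates(
    trajectory: Trajectory, window: tuple[int, int], per: str = "iteration"
) -> tuple[float, float]:
    """(primary, secondary) extinction rates inside ``window``.

    Counts primary-extinction and secondary-extinction events with
    iteration in (start, end], divided by the window length in
    iterations (default) or in Gillespie time (``per="time"``).
    """
    start, end = window
    if not 0 <= start < end <= trajectory.n_iterations:
        raise ValueError(f"invalid window {window}")
    n_primary = n_secondary = 0
    for ev in trajectory.events:
        if start < ev.iteration <= end:
            if ev.kind == PRIMARY:
                n_primary += 1
            elif ev.kind == SECONDARY:
                n_secondary += 1
    if per == "iteration":
        span = end - start
    elif per == "time":
        span = float(trajectory.times[end] - trajectory.times[start])
    else:
        raise ValueError(f"unknown rate denominator {per!r}")
    if span <= 0:
        raise ValueError("empty window")
    return n_primary / span, n_secondary / span


def persistence(
    trajectory: Trajectory,
    window: tuple[int, int],
    weighting: str = "time",
) -> tuple[dict[int, float], float]:
    """Per-species fraction of the window spent present, and its mean.

    Only species present at some point inside the window enter the
    community mean.  ``weighting="time"`` weights by Gillespie time,
    ``"iteration"`` by event count.
    """
    start, end = window
    if not 0 <= start < end <= trajectory.n_iterations:
        raise ValueError(f"invalid window {window}")
    pool = trajectory.pool
    S = pool.n_species

    if weighting == "time":
        marks = trajectory.times
    elif weighting == "iteration":
        marks = np.arange(trajectory.n_iterations + 1, dtype=np.float64)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    t0, t1 = float(marks[start]), float(marks[end])
    span = t1 - t0
    if span <= 0:
        raise ValueError("empty window")

    present = np.zeros(pool.n_entities, dtype=bool)
    present[BASAL] = True
    occupied = np.zeros(S + 1, dtype=np.float64)
    last_mark = t0
    ever = np.zeros(S + 1, dtype=bool)

    for ev in trajectory.events:
        if ev.iteration > end:
            break
        if ev.iteration <= start:
            trajectory._replay(present, ev)
            continue
        mark = float(marks[ev.iteration])
        sp_present = present[1 : S + 1]
        occupied[1:][sp_present] += mark - last_mark
        ever[1:] |= sp_present
        last_mark = mark
        trajectory._replay(present, ev)
    sp_present = present[1 : S + 1]
    occupied[1:][sp_present] += t1 - last_mark
    ever[1:] |= sp_present

    ids = np.flatnonzero(ever)
    values = np.clip(occupied[ids] / span, 0.0, 1.0)
    per_species = {int(i): float(v) for i, v in zip(ids, values)}
    mean = float(values.mean()) if values.size else float("nan")
    return per_species, mean


def trophic_mode(tl_samples: np.ndarray, bin_width: float = 0.25) -> float:
    """Center of the fullest trophic-level histogram bin.

    Bins are centered on integer multiples of ``bin_width`` (so the bin
    labeled 4.75 covers [4.625, 4.875) at the default width).  Ties go to
    the lowest bin.
    """
    samples = np.asarray(tl_samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("empty trophic-level sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError("no finite trophic-level samples")
    idx = np.round(samples / bin_width).astype(np.int64)
    offset = idx.min()
    counts = np.bincount(idx - offset)
    return float((int(np.argmax(counts)) + offset) * bin_width)
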