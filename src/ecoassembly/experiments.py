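"""Replicate management and the parameter sweeps over service frequency
and engineering intensity.

A replicate is the independent assembly of an independently drawn source
pool.  Replicate seeds are spawned deterministically from a master seed
and a (cell, replicate) key, so ensembles are reproducible and invariant
to execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as mx
from .engine import Trajectory, run_assembly
from .params import AssemblyParams, PoolParams
from .pool import SpeciesPool, generate_pool

__all__ = [
    "SweepConfig",
    "replicate_seed",
    "run_replicate",
    "summarize_replicate",
    "run_replicates",
    "sweep_service",
    "sweep_engineering",
    "redundancy_ratio",
    "spearman_trend",
    "unimodal_peak",
]


@dataclass
class SweepConfig:
    """Grids and replication for the sweep experiments.

    The default p_n grid spans the no-mutualism baseline up to the
    highest service frequency at which default pools still assemble
    sizeable communities (beyond p_n ~ 0.004 at S=200, p_e=0.01 the
    obligate needs leave too few unconstrained basal feeders to
    bootstrap colonization and the steady state collapses).  The eta
    grid spans rare (<=0.5) through common (>0.5) engineering.  p_e is
    held fixed across cells so only the focal axis varies.
    """

    pool: PoolParams = field(default_factory=PoolParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    p_n_grid: tuple[float, ...] = (0.0, 0.0005, 0.001, 0.002, 0.003)
    eta_grid: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5, 1.0, 1.5, 2.0)
    replicates: int = 50
    master_seed: int = 0
    n_window_samples: int = 20


def replicate_seed(master_seed: int, cell: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed stream."""
    return np.random.SeedSequence(master_seed, spawn_key=(cell, replicate))


def run_replicate(
    pool_params: PoolParams,
    assembly_params: AssemblyParams,
    seed: np.random.SeedSequence | int,
) -> tuple[SpeciesPool, Trajectory]:
    """Draw one pool and assemble it; pool and dynamics use independent
    child RNG streams so pools can be reused across dynamics variants."""
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    pool_ss, asm_ss = seed.spawn(2)
    pool = generate_pool(pool_params, seed=pool_ss)
    traj = run_assembly(pool, assembly_params, seed=asm_ss)
    return pool, traj


_ROW_FIELDS = (
    "s_star", "l_star", "ref_density", "connectance", "specialist_fraction",
    "potential_specialist_fraction", "tl_mean", "tl_max", "tl_max_end",
    "tl_mean_end", "specialist_fraction_end", "unodf", "primary_rate",
    "secondary_rate", "persistence", "onset", "early_tl", "terminated_early",
)


def summarize_replicate(
    traj: Trajectory,
    n_window_samples: int = 6,
    early_iteration: int = 5,
) -> tuple[dict, dict]:
    """Steady-state summary of one trajectory.

    Returns a row of scalar metrics plus extras (pooled trophic-level
    samples from the window, the richness curve) that ensemble-level
    statistics need.  Window metrics are averages over
    ``n_window_samples`` snapshots evenly spaced through the steady-state
    window (the final half of the run); the ``*_end`` fields describe the
    single steady-state community at the last iteration.
    """
    pool = traj.pool
    try:
        start, end = mx.steady_state_window(traj)
    except ValueError:
        # absorbed before a window exists (e.g. nobody can colonize)
        row = {k: np.nan for k in _ROW_FIELDS}
        row["s_star"] = float(traj.richness[-1])
        row["terminated_early"] = traj.terminated_early
        return row, {
            "tl_samples": np.empty(0),
            "tl_end": np.empty(0),
            "richness": traj.richness,
        }
    window = (start, end)

    s_star = float(traj.richness[start:end + 1].mean())
    l_star = float(traj.n_links[start:end + 1].mean())
    ref_density = l_star / s_star if s_star > 0 else np.nan

    sample_iters = np.unique(
        np.linspace(start + 1, end, n_window_samples).astype(int)
    )
    tl_samples: list[float] = []
    tl_max_vals, tl_mean_vals = [], []
    spec_frac, pot_spec_frac, conn_vals, unodf_vals = [], [], [], []
    for _, present in traj.snapshots(sample_iters):
        state = mx.CommunityState(present, np.zeros_like(present))
        if not present[1 : pool.n_species + 1].any():
            continue
        prof = mx.trophic_levels(state, pool)
        tl_samples.extend(prof.values.tolist())
        tl_max_vals.append(prof.tl_max)
        tl_mean_vals.append(prof.mean)
        conn_vals.append(mx.connectance(state, pool))
        unodf_vals.append(mx.unodf(mx.combined_adjacency(state, pool)))
        if np.isfinite(ref_density) and ref_density > 0:
            g = mx.generality(state, pool, ref_density, mode="functional")
            spec_frac.append(g.specialist_fraction)
            gp = mx.generality(state, pool, ref_density, mode="potential")
            pot_spec_frac.append(gp.specialist_fraction)

    # the assembled community at the end of the run (deep in the window)
    tl_max_end = tl_mean_end = spec_frac_end = np.nan
    tl_end = np.empty(0)
    end_present = traj.final_present
    if end_present is None:
        end_present = traj.presence_at(end)
    if end_present[1 : pool.n_species + 1].any():
        end_state = mx.CommunityState(end_present, np.zeros_like(end_present))
        end_prof = mx.trophic_levels(end_state, pool)
        tl_end = end_prof.values
        tl_max_end = end_prof.tl_max
        tl_mean_end = end_prof.mean
        if np.isfinite(ref_density) and ref_density > 0:
            spec_frac_end = mx.generality(
                end_state, pool, ref_density, mode="functional"
            ).specialist_fraction

    primary_rate, secondary_rate = mx.extinction_rates(traj, window)
    _, mean_persistence = mx.persistence(traj, window, weighting="time")
    try:
        onset = mx.steady_state_onset(traj.richness)
    except ValueError:
        onset = None

    early_tl = np.nan
    if traj.n_iterations >= early_iteration:
        present = traj.presence_at(early_iteration)
        if present[1 : pool.n_species + 1].any():
            state = mx.CommunityState(present, np.zeros_like(present))
            early_tl = mx.trophic_levels(state, pool).mean

    def _m(vals):
        return float(np.mean(vals)) if vals else np.nan

    row = {
        "s_star": s_star,
        "l_star": l_star,
        "ref_density": ref_density,
        "connectance": _m(conn_vals),
        "specialist_fraction": _m(spec_frac),
        "potential_specialist_fraction": _m(pot_spec_frac),
        "tl_mean": _m(tl_mean_vals),
        "tl_max": _m(tl_max_vals),
        "tl_max_end": tl_max_end,
        "tl_mean_end": tl_mean_end,
        "specialist_fraction_end": spec_frac_end,
        "unodf": _m(unodf_vals),
        "primary_rate": primary_rate,
        "secondary_rate": secondary_rate,
        "persistence": mean_persistence,
        "onset": np.nan if onset is None else onset,
        "early_tl": early_tl,
        "terminated_early": traj.terminated_early,
    }
    extras = {
        "tl_samples": np.asarray(tl_samples),
        "tl_end": tl_end,
        "richness": traj.richness,
    }
    return row, extras


def run_replicates(
    pool_params: PoolParams,
    assembly_params: AssemblyParams,
    n: int,
    master_seed: int = 0,
    cell: int = 0,
    n_window_samples: int = 20,
    collect: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict]:
    """Run ``n`` independent replicates of one parameterization.

    Returns a per-replicate metrics table and, when requested through
    ``collect``, pooled ``"tl_samples"`` and the stacked ``"richness"``
    curves.  Failures are recorded (column ``failed``) rather than
    silently dropped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, tl_pool, tl_end_pool, curves = [], [], [], []
    for rep in range(n):
        seed = replicate_seed(master_seed, cell, rep)
        try:
            _, traj = run_replicate(pool_params, assembly_params, seed)
            row, extras = summarize_replicate(traj, n_window_samples)
            row.update(replicate=rep, cell=cell, failed=False)
            if "tl_samples" in collect:
                tl_pool.append(extras["tl_samples"])
            if "tl_end" in collect:
                tl_end_pool.append(extras["tl_end"])
            if "richness" in collect:
                curves.append(extras["richness"])
        except Exception as exc:  # noqa: BLE001 - logged, never dropped
            row = {"replicate": rep, "cell": cell, "failed": True, "error": str(exc)}
        rows.append(row)
    table = pd.DataFrame(rows)
    extras: dict = {}
    if "tl_samples" in collect:
        extras["tl_samples"] = (
            np.concatenate(tl_pool) if tl_pool else np.empty(0)
        )
    if "tl_end" in collect:
        extras["tl_end"] = (
            np.concatenate(tl_end_pool) if tl_end_pool else np.empty(0)
        )
    if "richness" in collect:
        # absorbing-state runs end short; pad with their final richness
        n_max = max(len(c) for c in curves) if curves else 0
        mat = np.stack(
            [np.pad(c, (0, n_max - len(c)), mode="edge") for c in curves]
        ) if curves else np.empty((0, 0))
        extras["richness"] = mat
    return table, extras


def _cell_means(table: pd.DataFrame, keys: dict) -> dict:
    ok = table[~table["failed"]]
    out = dict(keys)
    out["n_ok"] = len(ok)
    out["n_failed"] = int(table["failed"].sum())
    for col in (
        "s_star", "l_star", "connectance", "specialist_fraction", "tl_mean",
        "tl_max", "unodf", "primary_rate", "secondary_rate", "persistence",
    ):
        out[col] = float(ok[col].mean()) if len(ok) else np.nan
        out[col + "_sd"] = float(ok[col].std(ddof=1)) if len(ok) > 1 else np.nan
    return out


def sweep_service(config: SweepConfig) -> pd.DataFrame:
    """Sweep the service-interaction frequency p_n (= q_n) at fixed p_e.

    Returns one row per grid cell with ensemble means and SDs of the
    structural (UNODF) and stability (extinction rates, persistence,
    richness) measures.
    """
    rows = []
    for ci, p_n in enumerate(config.p_n_grid):
        pp = config.pool.replace(p_n=p_n, q_n=None)
        table, _ = run_replicates(
            pp, config.assembly, config.replicates, config.master_seed,
            cell=ci, n_window_samples=config.n_window_samples,
        )
        rows.append(_cell_means(table, {"p_n": p_n, "cell": ci}))
    return pd.DataFrame(rows)


def sweep_engineering(
    config: SweepConfig, p_n_values: tuple[float, ...] | None = None
) -> pd.DataFrame:
    """Sweep engineering intensity eta, optionally crossed with p_n."""
    if p_n_values is None:
        p_n_values = tuple(config.p_n_grid)
    rows = []
    ci = 0
    for p_n in p_n_values:
        for eta in config.eta_grid:
            pp = config.pool.replace(p_n=p_n, q_n=None, eta=eta)
            table, _ = run_replicates(
                pp, config.assembly, config.replicates, config.master_seed,
                cell=ci, n_window_samples=config.n_window_samples,
            )
            rows.append(_cell_means(table, {"p_n": p_n, "eta": eta, "cell": ci}))
            ci += 1
    return pd.DataFrame(rows)


def redundancy_ratio(
    config: SweepConfig,
    p_n_values: tuple[float, ...] | None = None,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Compare redundant vs unique engineering: the richness ratio S*/S_u*.

    Both arms share the (p_n, eta) grid but draw pools independently.
    The ratio of mean steady-state richness is reported per cell with a
    percentile bootstrap CI; cells where the unique arm collapses to
    ~zero richness are censored.
    """
    if p_n_values is None:
        p_n_values = tuple(config.p_n_grid)
    rng = np.random.default_rng(np.random.SeedSequence(config.master_seed, spawn_key=(0xB00,)))
    rows = []
    ci = 0
    for p_n in p_n_values:
        for eta in config.eta_grid:
            arms = {}
            for arm, redundant in (("redundant", True), ("unique", False)):
                pp = config.pool.replace(
                    p_n=p_n, q_n=None, eta=eta, redundant_engineering=redundant
                )
                table, _ = run_replicates(
                    pp, config.assembly, config.replicates, config.master_seed,
                    cell=ci, n_window_samples=config.n_window_samples,
                )
                arms[arm] = table[~table["failed"]]["s_star"].to_numpy()
                ci += 1
            s, su = arms["redundant"], arms["unique"]
            mean_su = float(su.mean()) if su.size else np.nan
            censored = not np.isfinite(mean_su) or mean_su < 1.0
            ratio = np.nan if censored else float(s.mean()) / mean_su
            lo = hi = np.nan
            if not censored and s.size > 1 and su.size > 1:
                boots = []
                for _ in range(n_boot):
                    bs = rng.choice(s, s.size)
                    bu = rng.choice(su, su.size)
                    if bu.mean() >= 1.0:
                        boots.append(bs.mean() / bu.mean())
                if boots:
                    lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {
                    "p_n": p_n, "eta": eta,
                    "s_star": float(s.mean()) if s.size else np.nan,
                    "s_star_unique": mean_su,
                    "ratio": ratio, "ratio_lo": float(lo), "ratio_hi": float(hi),
                    "censored": censored,
                    "n_redundant": s.size, "n_unique": su.size,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# trend statistics
# ---------------------------------------------------------------------

def spearman_trend(x, y, alternative: str = "greater") -> tuple[float, float]:
    """One-sided Spearman rank trend over sweep-cell means."""
    from scipy import stats

    rho, p = stats.spearmanr(x, y, alternative=alternative)
    return float(rho), float(p)


def unimodal_peak(x, y) -> tuple[int, float]:
    """Best unimodal (increasing-then-decreasing) fit to cell means.

    For each candidate peak position an isotonic fit rises to the peak
    and falls after it; the position with minimal squared error wins.
    Returns (peak index into x, SSE of the best fit).
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    best = (0, np.inf)
    for p in range(n):
        left = _pava(y[: p + 1], increasing=True)
        right = _pava(y[p:], increasing=False)
        fit = np.concatenate([left[:-1], [max(left[-1], right[0])], right[1:]])
        sse = float(((fit - y) ** 2).sum())
        if sse < best[1]:
            best = (p, sse)
    return best


def _pava(y: np.ndarray, increasing: bool = True) -> np.ndarray:
    """Pool-adjacent-violators for a monotone least-squares fit."""
    y = y if increasing else y[::-1]
    level = [float(v) for v in y]
    weight = [1.0] * len(level)
    i = 0
    while i < len(level) - 1:
        if level[i] > level[i + 1] + 1e-15:
            merged = (level[i] * weight[i] + level[i + 1] * weight[i + 1]) / (
                weight[i] + weight[i + 1]
            )
            level[i : i + 2] = [merged]
            weight[i : i + 2] = [weight[i] + weight[i + 1]]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.repeat(level, [int(w) for w in weight])
    return out if increasing else out[::-1]
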