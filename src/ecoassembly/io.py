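"""Serialization, configuration files, network export, run manifests.

Entity ids are 0-based everywhere: 0 is the basal resource, 1..S are
species, S+1..S+M' are modifiers.  Pools travel as a CSV edge list
(source_id, target_id, interaction) preceded by one JSON header comment
line carrying the counts and parameters, so a single file round-trips a
pool exactly.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Event, Trajectory
from .params import AssemblyParams, ParameterError, PoolParams, params_to_dict
from .pool import SpeciesPool, validate_pool

__all__ = [
    "save_pool",
    "load_pool",
    "export_network",
    "pool_to_networkx",
    "save_trajectory_events",
    "load_config",
    "write_manifest",
    "read_manifest",
    "file_checksum",
]

RELATIONS = ("eat", "need", "make")


# ---------------------------------------------------------------------
# pool serialization
# ---------------------------------------------------------------------

def save_pool(pool: SpeciesPool, path) -> Path:
    """Write a pool as '# <json header>' + CSV edge list."""
    path = Path(path)
    header = {
        "n_species": pool.n_species,
        "n_modifiers": pool.n_modifiers,
        "params": params_to_dict(pool.params) if pool.params else None,
    }
    lines = [f"# {json.dumps(header)}", "source_id,target_id,interaction"]
    for name in RELATIONS:
        rel = getattr(pool, name)
        for s, t in zip(*np.nonzero(rel)):
            lines.append(f"{s},{t},{name}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_pool(path) -> SpeciesPool:
    """Inverse of :func:`save_pool`; validates the result."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[2:])
        df = pd.read_csv(fh)
    S, M = int(header["n_species"]), int(header["n_modifiers"])
    n = 1 + S + M
    rels = {name: np.zeros((n, n), dtype=bool) for name in RELATIONS}
    for name, grp in df.groupby("interaction"):
        if name not in rels:
            raise ValueError(f"{path}: unknown interaction type {name!r}")
        rels[name][grp["source_id"].to_numpy(), grp["target_id"].to_numpy()] = True
    params = None
    if header.get("params"):
        params = PoolParams(**header["params"])
    pool = SpeciesPool(S, M, rels["eat"], rels["need"], rels["make"], params=params)
    violations = validate_pool(pool)
    if violations:
        raise ValueError(f"{path}: invalid pool: " + "; ".join(violations))
    return pool


# ---------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------

def pool_to_networkx(pool: SpeciesPool, present: np.ndarray | None = None):
    """Directed multigraph of the pool (or of a community when
    ``present`` is given) with node attribute ``category`` and edge
    attribute ``interaction``."""
    import networkx as nx

    g = nx.MultiDiGraph()
    ids = range(pool.n_entities) if present is None else np.flatnonzero(present)
    for i in ids:
        g.add_node(int(i), category=pool.category(int(i)))
    for name in RELATIONS:
        rel = getattr(pool, name)
        for s, t in zip(*np.nonzero(rel)):
            if present is None or (present[s] and present[t]):
                g.add_edge(int(s), int(t), interaction=name)
    return g


def export_network(pool: SpeciesPool, path, fmt: str, present: np.ndarray | None = None) -> Path:
    """Export as 'edgelist' CSV, 'graphml', or dense 'adjacency' CSV.

    The adjacency CSV encodes the three relations in one integer matrix
    (bits: eat=1, need=2, make=4) with entity ids as header row/column.
    """
    path = Path(path)
    if fmt == "edgelist":
        return save_pool(pool, path)
    if fmt == "graphml":
        import networkx as nx

        nx.write_graphml(pool_to_networkx(pool, present), path)
        return path
    if fmt == "adjacency":
        n = pool.n_entities
        coded = (
            pool.eat.astype(int) + 2 * pool.need.astype(int) + 4 * pool.make.astype(int)
        )
        df = pd.DataFrame(coded, index=range(n), columns=range(n))
        df.to_csv(path)
        return path
    raise ValueError(f"unknown export format {fmt!r}")


def save_trajectory_events(traj: Trajectory, path) -> Path:
    path = Path(path)
    traj.events_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

_POOL_KEYS = {f.name for f in fields(PoolParams)}
_ASM_KEYS = {f.name for f in fields(AssemblyParams)}
_SWEEP_KEYS = {"p_n_grid", "eta_grid", "replicates", "master_seed", "n_window_samples"}


def load_config(path) -> dict:
    """Load a TOML or JSON config into validated parameter bundles.

    Recognized sections: ``[pool]``, ``[assembly]``, ``[sweep]``.
    Missing fields take the model defaults; unknown sections or keys are
    rejected with a field-level message.  Returns a dict with keys
    'pool' (PoolParams), 'assembly' (AssemblyParams) and 'sweep' (dict of
    sweep settings, possibly empty).
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        with path.open("rb") as fh:
            raw = tomllib.load(fh)
    unknown_sections = set(raw) - {"pool", "assembly", "sweep"}
    if unknown_sections:
        raise ParameterError(f"unknown config sections: {sorted(unknown_sections)}")
    for section, allowed in (("pool", _POOL_KEYS), ("assembly", _ASM_KEYS), ("sweep", _SWEEP_KEYS)):
        extra = set(raw.get(section, {})) - allowed
        if extra:
            raise ParameterError(f"unknown keys in [{section}]: {sorted(extra)}")
    return {
        "pool": PoolParams(**raw.get("pool", {})),
        "assembly": AssemblyParams(**raw.get("assembly", {})),
        "sweep": dict(raw.get("sweep", {})),
    }


# ---------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------

def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir, params: dict, seed, files: list[str], termination: str = "completed"
) -> Path:
    """Record a run: parameters, seed, outputs and their checksums."""
    out_dir = Path(out_dir)
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "termination": termination,
        "params": {
            k: (params_to_dict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in params.items()
        },
        "files": {name: file_checksum(out_dir / name) for name in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
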