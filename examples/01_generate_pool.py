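"""Draw a source pool and inspect its interaction structure.

A pool holds S species, a basal resource, and (optionally) engineered
abiotic modifiers, wired by three directed relations: eat (trophic),
need (obligate service), make (engineering).
"""

import numpy as np

from ecoassembly import PoolParams, generate_pool, validate_pool

params = PoolParams(n_species=200, p_e=0.01, p_n=0.005, eta=1.0, seed=42)
pool = generate_pool(params)

print(f"species:            {pool.n_species}")
print(f"surviving modifiers:{pool.n_modifiers:5d}   (expected ~ eta*S*(e-1)/e = "
      f"{params.eta * params.n_species * (np.e - 1) / np.e:.0f})")
print(f"engineers:          {pool.engineers().size}")
print(f"species-species eat links: {int(pool.species_eat_matrix().sum())} "
      f"(expected ~ p_e*S*(S-1) = {params.p_e * 200 * 199:.0f})")
print(f"need links:         {int(pool.need.sum())}")
print(f"validation:         {validate_pool(pool) or 'ok'}")

# Redundant engineering: several species can make the same modifier, so
# losing one engineer does not necessarily remove its modifiers.
makers = pool.make[:, pool.modifier_ids].sum(axis=0)
print(f"makers per modifier: mean {makers.mean():.2f}, max {makers.max()}")
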