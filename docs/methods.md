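# Model and methods

## The assembly model

`ecoassembly` simulates the assembly of an ecological community from a
fixed source pool of interacting entities.  Entities are of three
kinds: an abiotic **basal resource** (entity 0, always present), **S
species**, and **M′ abiotic modifiers** — environmental effects
produced by ecosystem-engineering species (beaver ponds, burrows,
engineered metabolites).  Three directed relations wire them together:

* `x eat y` — trophic consumption (predation or parasitism); targets
  may be species, modifiers, or the basal resource;
* `x need y` — an obligate service dependency (pollination, dispersal,
  habitat); a classic mutualism is an eat link one way plus a need link
  the other;
* `x make y` — engineering: species x produces modifier y.

### Pool construction

The pool is drawn once per replicate:

1. Each species makes `M_i ~ Poisson(eta)` modifiers.  With redundant
   engineering (default) the make links target `round(eta * S)`
   candidate modifiers uniformly at random; candidates nobody makes are
   dropped, so E[M′] = eta·S·(e−1)/e and several engineers can share a
   modifier.  In the unique-engineering variant every link creates a
   fresh modifier with exactly one maker and M′ = ΣM_i.
2. Every ordered species pair gets an eat link with probability `p_e`
   and a need link with probability `p_n`; species–modifier pairs use
   `q_e`, `q_n` (defaulting to `p_e`, `p_n`).  Self-links are excluded,
   and nothing needs the basal resource.
3. The first species always eats the basal resource; every other
   species eats it with probability `p_e`; any species still lacking a
   diet after those draws is linked to basal and treated as a primary
   producer.  The Bernoulli draw precedes the fallback.

### Dynamics

Starting from the basal-only community, a Gillespie (event-driven)
process runs for `max_iterations` events (default 4000):

* **Colonization** (rate `r_c` per candidate): an absent species whose
  needs are all present and which has at least one present resource may
  enter.  An engineer brings all its modifiers along.
* **Primary extinction** (rate `r_e` per candidate): an at-risk species
  leaves.  Risk comes from competition: the competitive strength of a
  present species is

      sigma_i = c_n * n_i − c_e * e_i − c_v * v_i

  with `n_i` its number of needs (all present by construction), `e_i`
  its resource count, and `v_i` its present consumers.  Services are a
  fitness benefit, resource generalism and predation pressure are
  costs, and the required ordering `c_n > c_e > c_v` (defaults pi,
  sqrt(2), 1) makes one extra mutualism outweigh one extra resource or
  predator.  A species is at risk when it is the strongest consumer
  (ties count as strongest) on **none** of its present resources.
* **Modifier loss** (rate `r_m` per candidate): a modifier whose makers
  are all gone lingers as "disconnected" until its loss event fires.
* **Secondary extinctions** are deterministic: after any removal, every
  present species that lost its last present resource or any needed
  entity is removed, iterated to a fixpoint within the same event.
  All violators are removed simultaneously each pass, so the fixpoint
  does not depend on removal order.

One *iteration* is one stochastic event together with its cascade;
continuous Gillespie time is recorded alongside.  An empty rate table
(an absorbing state) terminates the run early and is logged.

### Design decisions on under-determined rules

Several micro-rules admit more than one reading; all variants are
implemented behind switches, and the defaults are the cell of the
variant grid under which the model assembles communities with the
structure the framework is meant to produce (an early richness plateau,
deep food webs, moderate turnover):

* `competition_scope="pool"` (default): `e_i` counts every resource a
  species *can* eat; `"realized"` counts only present ones.
* `risk_rule="outcompeted_on_all"` (default): at risk only when
  strongest on no present resource, symmetric with the
  one-resource-suffices colonization rule; `"outcompeted_on_any"` is
  the harsher reading (at risk as soon as beaten anywhere).
* `basal_competition=False` (default): the abiotic basal resource is
  treated as non-limiting and is not a competitive arena.  Making it
  one puts every consumed primary producer permanently at risk, which
  destabilizes the base of the web: richness never plateaus within the
  iteration budget and community persistence collapses.  Biotic
  resources and engineered modifiers always compete.
* `tie_risk=False` (default): equal-strength consumers tied at the top
  of a resource both count as strongest (ties never create risk).
* `modifier_decay="constant"` (default): disconnected modifiers decay
  at rate `r_m` each; `"density_scaled"` multiplies by the number of
  disconnected modifiers, shortening the lingering time when many
  accumulate.
* Event rates `r_c = r_e = r_m = 1`: with presence/absence dynamics
  only rate ratios matter; equal rates are the neutral choice.
* A needed or eaten entity counts as available whenever it is
  *present*, including disconnected-but-not-yet-lost modifiers.

## Metrics

All species-level metrics use realized species–species links; the
basal resource and modifiers do not count toward richness or link
totals.

* **Connectance** C = L/S² over present species.
* **Trophic levels** solve the prey-averaged linear system
  TL_i = 1 + mean(TL over the realized diet), with abiotic resources
  (basal, modifiers) fixed at level 0, so strict autotrophs sit exactly
  at TL 1.  Solving the linear system handles trophic cycles (a cycle
  anchored to the base gets finite levels).  Species supported only by
  a detached cycle with no path to an abiotic source have no defined
  prey-averaged level; they are excluded from the profile (they are
  rare: a cascade must sever a cycle's anchor without starving it).
* **Generality** G_i = k_in / (L*/S*): realized ("functional") or pool
  ("potential") species resources, scaled by the replicate's own
  steady-state link density.  G < 1 marks a specialist, G > 1 a
  generalist.
* **UNODF** (unipartite nestedness based on overlap and decreasing
  fill), computed from its definition: for every unordered node pair
  with distinct positive degrees, the overlap of the smaller
  neighborhood inside the larger divided by the smaller degree; mean
  over all pairs, computed on out-neighborhoods and in-neighborhoods
  and averaged.  Equal degrees and empty neighborhoods contribute zero;
  the diagonal is ignored.  The community matrix scored is the union of
  trophic and service links among present species.  The implementation
  is verified against exhaustive brute-force enumeration in the test
  suite.
* **Steady-state window**: the final half of the iterations.  The
  plateau onset detector compares adjacent length-50 sliding-window
  means of richness and reports the earliest iteration from which all
  subsequent changes stay below 5%.
* **Extinction rates**: primary and secondary event counts in a window
  divided by its length; per-iteration by default, per unit Gillespie
  time optionally.
* **Persistence**: per species ever present in the window, the fraction
  of window (Gillespie) time it was present; averaged over those
  species.  Iteration weighting is available.
* **Modal trophic level**: the center of the fullest histogram bin,
  bins centered on multiples of the bin width (default 0.25).
  Note that obligate primary producers form an atom at exactly TL = 1.0
  (about 13.5% of a default pool draws no species prey), so with fine
  bins the mode of the full distribution sits at 1.0 even when
  intermediate levels dominate in aggregate.

## Ensembles and sweeps

A replicate is an independently drawn pool assembled independently;
per-replicate seeds are spawned from a master seed keyed by (cell,
replicate), so ensembles are order-independent and reproducible.  The
pool and the dynamics consume separate child streams, so a pool can be
reused across dynamics variants.

Window metrics average a handful of snapshots (default 6) evenly spaced
through the steady-state window; `*_end` metrics describe the single
community at the last iteration.  The sweep experiments cover the
service-frequency axis (`p_n` grid, `p_e` fixed), the engineering axis
(`eta` grid, optionally crossed with `p_n`), and the redundant-vs-unique
engineering comparison reported as the richness ratio S*/S*_u with a
percentile-bootstrap CI (cells whose unique arm collapses below one
species are censored).

At high service frequency (`p_n` ≳ 0.01 with S = 200) a pool may leave
no basal-eating species with all needs satisfiable, so the empty
community is absorbing; such replicates terminate at iteration 0 and
enter the tables as degenerate rows (richness 0) rather than being
dropped.

## Problem sizes

Default study conditions: S = 200, p_e = 0.01, eta = 0, c_n = pi,
c_e = sqrt(2), c_v = 1, 4000 iterations.  The reproduction script uses
200 replicates for the headline ensemble statistics; sweep-based trend
checks use 50 replicates per cell with grids p_n in {0, 0.0005, 0.001,
0.002, 0.003} (the regime where communities assemble, see above) and
eta in {0, 0.25, 0.5, 1, 2}.  These sizes keep a full reproduction
within minutes on one core; ensembles of 10^4 replicates are
configurable through the same interfaces.

## What the generator does and does not emulate

The pool generator realizes the model's own null assumptions:
interactions are i.i.d. Bernoulli, engineering is Poisson, and there is
no phylogenetic, trait, or body-size structure ordering who eats whom.
Passing tests therefore validate the assembly *process* and its
metrics, not the realism of any particular empirical web; quantities
that depend on niche ordering (e.g. intervality, diet contiguity) are
outside what this pool can express.  The pool is static: no speciation,
invasion from outside, or rewiring during assembly.

## Known limitations

* Presence/absence only — no abundances, biomass flows, or ODE
  dynamics; competitive exclusion is threshold-based, not dynamical.
* Secondary extinctions are instantaneous within an event; rate-limited
  cascades would interleave with colonizations.
* The prey-averaged trophic level is undefined for detached cycles
  (excluded, see above).
* With fine histogram bins the modal trophic level reflects the
  autotroph atom rather than the dominant intermediate levels; use
  coarser bins or inspect the full distribution.
* Single community, single patch; no spatial structure.
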