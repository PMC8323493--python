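# Methods

This note documents the model, the numerical choices and the limits of the
bundled fixtures, in the package's own terms.

## Dynamics and attractors

Networks are Boolean: each non-input node has one update rule over node
names (`NOT`/`AND`/`OR`, precedence `NOT > AND > OR`); inputs are rule-less
and hold their value. Updating is **synchronous and deterministic**: all
nodes read the same pre-state, so from any initial state the trajectory
enters a unique attractor — a fixed point or a cycle. Cycles are stored in
canonical rotation (lexicographically smallest state first) and carry an
*activity vector*, the per-node mean over the cycle, which is
rotation-invariant.

Clamping overwrites a node with a constant at every step (applied to the
initial state and after each update), so an attractor under clamps is an
attractor of the clamped map. Clamps encode everything external to the
wiring: environmental inputs, mutations (gain of function → 1, loss → 0)
and drugs (activate → 1, inhibit → 0).

**Probabilistic clamps.** A clamp value `v in [0,1]` means: per sampled
trajectory, the node is hard-clamped to 1 with probability `v` (drawn once
per trajectory, Bernoulli), else to 0. `v in {0,1}` is a deterministic hard
clamp, and the implementation draws the uniform variate in either case, so
hard and extreme-Bernoulli clamps consume the same random stream and give
bit-identical results. This semantics lets continuous, expression-derived
input levels (and ±10% perturbations of them) move fate propensities
continuously while the core dynamics stay Boolean. A config switch
(`binarize_threshold`) hardens `v >= threshold` to 1 for users who prefer
discrete inputs; it is off by default.

## Basin sizes

Two modes, sharing one attractor representation:

* **Exhaustive** (the oracle): every assignment of the free nodes is
  enumerated once; basin counts are integers over `2^n_free`, so ratios sum
  to exactly 1. The enumeration cutoff is 20 free nodes (hard cap 25).
* **Sampled** (the workhorse): N initial states (default 10,000) are drawn
  with replacement — clamp realizations Bernoulli, free nodes uniform —
  and each trajectory is run to its attractor. Attractors realized under
  different clamp draws are kept distinct by clamp signature and aggregate
  at the fate level. Ratios are counts/N.

The core loop uses tuples of 0/1 ints, per-network compiled update
callables, and memoized state→attractor resolution with path compression
(per clamp signature), so identical seeds give bit-identical landscapes on
any platform: no floating point enters the loop. The trajectory-length
guard is `4 * 2^min(n_free, 20)` steps; exceeding it indicates an engine
bug, not a user error.

**Bootstrap dispersion.** "Bootstrapping on 10,000 network states" is
interpreted as: each replicate draws 10,000 initial states with replacement
from the state space; per-fate dispersion is computed across replicates
(default 30), with SEM = SD/sqrt(replicates). Replicate seeds derive from
the master seed via `numpy.random.SeedSequence.spawn`, so replicate streams
are independent and reproducible.

## Fate classification

An attractor's activity vector is binarized at a threshold (default 0.5,
`>=` counts as ON; fixed points are unchanged by any threshold) and matched
against an ordered list of marker conjunctions; the **first matching entry
wins** and unmatched attractors take the reserved `uncharacterized` fate.
Classification is exclusive (one fate per attractor) so fate propensities
partition the basin mass exactly. File order as priority is a deliberate
tie-break: the bundled classifications put apoptosis first because the
death effector dominates a cell's fate regardless of co-active programs.
Note one consequence: a period-2 cycle with activity exactly 0.5 binarizes
to ON at the default threshold, so half-active cycles join the fate their
markers name rather than falling back to `uncharacterized`.

## Expression annotation

The default normalization (`global_minmax`) min-max scales each gene's rpkm
across all cell-type × region cells of its row, then averages the five
scaled regional values of the requested cell type. It is invariant to
multiplying a gene row by a positive constant; constant rows map to 0 (not
NaN) on the reasoning that a gene with no dynamic range anywhere carries no
activating evidence. Two alternatives are registered and recorded in the
output's provenance: `region_minmax` (scale within the requested cell
type's regions only — normalization after regional restriction rather than
before) and `rank` (rank of the regional mean among all genes, invariant
under monotone transforms). Whether regions are averaged before or after
scaling is genuinely underdetermined by the data layout; both readings are
available and the method id travels with every derived clamp profile.
Stress and cancer conditions are override files applied after expression:
override > expression, with no partial blending.

## Robustness

Per replicate, input clamps are perturbed multiplicatively,
`v -> clip(v * (1 + u), 0, 1)` with `u ~ Uniform(-f, +f)` and f = 0.1 by
default; an additive mode (`v -> clip(v + u)`) is available because a
multiplicative ±10% cannot move a 0-valued input. Perturbation applies to
input stimuli only — mutation and drug clamps are fixed facts of the
scenario, not noisy measurements. With f = 0 and matched seeds the analysis
reproduces plain bootstrap dispersion exactly (tested), so the reported SEM
cleanly decomposes into sampling noise plus input-noise response.

## Therapy semantics

* **Horizontal** evaluation runs scenarios independently side by side
  (progressive mutation sets), with an auto-prepended empty control; every
  scenario shares one seed so differences are intervention-driven.
* **Vertical** evaluation stacks interventions in one scenario — drugs on
  top of mutations — with later interventions overriding earlier ones on a
  shared node (a drug administered after a mutation wins that node).
* `percent_change(before, after) = 100*(after-before)/before`, with
  `0 -> 0` defined as 0 and `0 -> positive` as +infinity.
* Combination screening enumerates single drugs, then pairs/triples of the
  druggability table (a drug is the bundle of all its direct and indirect
  target rows), scores each by
  `capped(Δapoptosis%) − capped(Δproliferation%)` where only infinite
  sentinels are capped (at ±200), and ranks with deterministic tie-breaks:
  fewer drugs first, then lexicographic names. The composite score and the
  sentinel cap are artifact conventions chosen to make rankings total and
  order-invariant; per-fate changes are always reported alongside.
* Drug class assessment (ε = 0.01 by default, a chosen convention):
  class I = proliferation drops by more than ε in the mutated model while
  wild-type proliferation moves at most ε; class II = wild-type
  proliferation rises by more than ε; anything else is indeterminate.

## Personalized pipeline

Patient mutation rows carry an optional effect column; missing effects are
inferred from a bundled, editable role table (oncogene → GoF, suppressor →
LoF) and unresolvable genes are excluded from interventions but always
listed in the report. Homolog mapping is many-to-one; several genes hitting
one node collapse to a single intervention with LoF dominating (loss wins
over gain on the same node). Chemotherapy is modeled solely through the
merged microtubule sub-network plus the taxane's clamp on the
microtubule-stabilization input (resting value 0); the merged model uses a
classification whose proliferation condition additionally requires mitotic
competence (`stg`), which is what lets microtubule stabilization abolish
proliferation. A patient whose best mono-therapy already reaches
proliferation 0 is reported "targeted therapy only" before pairs are
recommended. Per-patient seeds are derived from the master seed XOR a
digest of the patient id, so cohort results are order-independent.

## Synthetic data

The generator module defines the study conditions for the test suite:

* **Random networks**: in-degrees from a zeta(2)-like distribution
  truncated at 4 (so exhaustive oracles stay feasible), regulators chosen
  with preferential weighting toward earlier nodes (heavy-tailed
  out-degree), rules as random AND/OR chains with literals negated at 0.3,
  and a guaranteed input→output path (one output is rewired onto an
  input-reachable node if needed).
* **Expression tables**: log-normal rpkm with gene-, cell-type- and
  region-specific multiplicative effects (dispersion sigma 0.8), so
  normalization has real structure to recover.
* **Cohorts**: mutation counts ~ 1 + Poisson(burden − 1) over a gene pool
  with fixed oncogene/suppressor roles (default burden 4, cohort 10).
* **Druggability**: each drug targets 1–2 upstream (non-output) nodes; a
  planted drug inhibiting a known proliferation driver provides the
  ground-truth winner for screening tests.

What the generators deliberately do **not** emulate: real FlyGut-seq
marginals, mutation signatures, linkage between mutations, or dosage.
Passing tests therefore demonstrate correctness of the machinery
(enumeration agreement, determinism, invariance properties, ranking logic)
on data with known structure — not biological accuracy on real tissue.

## Bundled reconstruction fixtures

The shipped ISC model is a **synthetic reconstruction**: 48 nodes / 70
edges wired from the nine named pathways with the published structural
counts and the standard input/output vocabulary (ten readout nodes:
Apc2, Cdc42, hid, Su(H), pros, dlg1, Stat92E, rl, pan, myc). Its exact
rules, clamp levels (normal/stress/cancer), fate markers, homolog and
druggability tables are documented curations chosen once, up front, to
exhibit the canonical phenomenology — apoptosis-dominant homeostasis,
Ras-driven apoptosis collapse and hyper-proliferation, taxane-induced
mitotic arrest — not to reproduce any published propensity value.
Quantitative propensities from this fixture are properties of the
reconstruction only. Users with curated rule files load them through the
same parsers (every `flydpm.data` loader takes a path override).

## Problem sizes and defaults

Monte-Carlo landscapes default to 10,000 samples (the standard analysis
size); oracle-agreement checks use 50,000 samples against ≤12-node
enumerations with a 3-standard-error criterion per attractor (a ~0.3%
false-alarm rate per comparison, documented flaky-test tolerance).
Bootstrap and robustness default to 30 replicates; the replicate-scaling
checks use 10 vs 40. The synthetic cohort runs use 3 patients at 2,000
samples. Screening defaults to pairs (`max_size=2`) with a 5,000-
combination budget guard.

## Known limitations

* Synchronous updating only; asynchronous and stochastic-rule schemes are
  out of scope, as is symbolic (SAT/BDD) attractor detection — sampling
  plus enumeration suffice at this scale.
* Cell types are modeled independently; there is no lineage tracking or
  cell–cell coupling, so only per-network fates are computed.
* Drug action is a hard clamp on target nodes: no dose, kinetics, or
  synergy indices beyond the fate-change score.
* Fate classification is exclusive single-label; co-active programs
  resolve by file-order priority.
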