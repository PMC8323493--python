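# flydpm

Boolean network attractor analysis and *in silico* therapy screening for
Drosophila midgut cell-fate models.

## The problem

The adult *Drosophila* midgut epithelium is maintained by a handful of cell
types — intestinal stem cells (ISC), enteroblasts (EB), enterocytes (EC),
enteroendocrine cells (EE) and visceral muscle (VM) — whose fate decisions
(divide, differentiate, die, extrude) are governed by nine conserved
signaling pathways: Notch, BMP, EGFR, WNT, JAK-STAT, JNK, Hippo, Insulin
and Robo/Slit. Because most colorectal-cancer driver genes are conserved in
the fly, a logical model of this tissue can be *personalized*: human tumor
mutations are mapped onto fly homologs, encoded as node clamps, and
candidate drug combinations are screened for their ability to push the
mutated model back toward apoptosis and away from hyper-proliferation.

`flydpm` implements that pipeline as a library:

1. **netio** — a plain-text rule grammar (`node = expr` over `NOT/AND/OR`,
   precedence `NOT > AND > OR`) with parser, canonical writer and network
   merging (extensions with `REPLACE`/`OR`/`AND` override directives).
2. **engine** — synchronous deterministic dynamics
   `x_i(t+1) = f_i(x(t))`, attractor (fixed point / cycle) detection,
   and basin-size estimation: exact enumeration for small state spaces and
   seeded Monte-Carlo sampling (default 10,000 initial states) for the full
   models. Clamp values `v in [0,1]` hold a node at 1 with probability `v`
   per sampled trajectory (`v in {0,1}` are hard clamps), so propensities
   vary continuously with expression-derived inputs.
3. **fates** — attractors are classified to cell fates by binarizing the
   cycle-mean activity at a threshold (default 0.5) and matching ordered
   marker conditions; the propensity of a fate is the summed basin-size
   ratio of its attractors, a partition of 1 including the reserved
   `uncharacterized` fallback.
4. **annotation** — FlyGut-seq-shaped rpkm tables (gene x 5 cell types x
   midgut regions R1–R5) are min-max normalized per gene and averaged over
   regions to produce input clamps in [0,1], and model output-node
   propensities are compared back against expression.
5. **robustness** — input clamps perturbed by ±10% (multiplicative,
   uniform, clipped), landscape re-sampled per replicate; per-fate
   SEM = SD/sqrt(replicates) quantifies stability.
6. **therapeutics** — mutations (GoF→1, LoF→0) and drugs (activate→1,
   inhibit→0) as hard clamps; side-by-side (horizontal) scenario matrices,
   stacked (vertical) drugs-on-mutations evaluation, class I / class II
   cytotoxicity assessment, and exhaustive single/pair/triple
   combination screening ranked by
   `score = capped(Δapoptosis%) − capped(Δproliferation%)`.
7. **patient** — end-to-end personalized runs: mutation TSV → effect
   inference (oncogene→GoF, suppressor→LoF) → homolog mapping (unmapped
   genes reported) → mutated model → screening → self-contained report.
8. **synthdata** — seeded generators for every input shape (random Boolean
   networks, expression tables, patient cohorts, druggability tables) and
   small oracle fixtures with fully enumerated landscapes.

The package bundles a documented **reconstruction** of the ISC model
(48 nodes / 70 edges, the published structural counts) plus a microtubule
extension (6 nodes / 13 interactions; merged: 54 / 83) that makes taxane
chemotherapy representable. These fixtures are synthetic curations — the
exact published rule sets are not redistributed — and every loader accepts
a path override so curated files can be dropped in.

## Worked example

`python examples/05_mutation_scenarios.py` evaluates progressive
colorectal-cancer driver mutations in the bundled stem-cell model:

```
scenario           apoptosis     proliferation           EB_fate  delta_production
control                0.340             0.243             0.154             0.227
Apc                    0.346             0.240             0.149             0.227
Ras                    0.000             0.489             0.162             0.349
Apc+Ras                0.000             0.498             0.156             0.346
```

Each row is a fate-propensity profile at 10,000 sampled initial states
under normal input clamps. The control column shows the homeostatic
baseline (apoptosis-dominant). Gain-of-function Ras clamps the EGFR
cascade ON, which forces ERK (`rl`) active in every attractor: the
apoptosis effector `hid` (which requires ERK OFF) can no longer fire, and
the proliferation markers (`rl`, `myc`) double their basin mass — the
hallmark hyper-proliferation / apoptosis-loss phenotype. The other
examples cover landscapes (`01`), ambient conditions (`02`), robustness
(`03`), expression annotation (`04`), drug screening (`06`) and the full
personalized pipeline (`07`).

A thin CLI mirrors the library (`flydpm da|annotate|robustness|therapy|
screen|dpm|synth --help`).

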