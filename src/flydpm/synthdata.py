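"""Synthetic input generation.

Everything the pipeline consumes can be generated here with a seed: random
Boolean networks with heavy-tailed in-degrees, small oracle fixtures whose
landscapes are fully enumerated, FlyGut-seq-shaped expression tables,
cBioPortal-shaped patient cohorts and PanDrugs-shaped druggability tables.
These generators define the study conditions for the test-suite: same spec +
seed always yields byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .annotation import CELL_TYPES, REGIONS, ExpressionTable
from .engine import AttractorLandscape, exhaustive_landscape
from .netio import (
    And,
    BooleanExpression,
    BooleanNetwork,
    ClampProfile,
    DruggabilityTable,
    DrugTarget,
    FateClassification,
    Not,
    Or,
    Var,
    parse_network,
)
from .patient import MutationRecord, PatientProfile

import pandas as pd

__all__ = [
    "GeneratorSpec",
    "OracleFixture",
    "generate_random_network",
    "oracle_fixtures",
    "midgut_demo",
    "generate_expression_table",
    "generate_patient_cohort",
    "generate_druggability",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic world.

    n: network size (nodes).  k: mean in-degree target (truncated at 4 so
    exhaustive oracles stay feasible).  input_fraction / output_fraction:
    shares of rule-less input and designated output nodes.  dispersion:
    log-normal sigma of the rpkm noise.  cohort_size and mutation_burden
    parameterize the patient generator (burden ~ 1 + Poisson(burden - 1))."""

    seed: int = 0
    n: int = 12
    k: float = 2.0
    input_fraction: float = 0.25
    output_fraction: float = 0.25
    dispersion: float = 0.8
    cohort_size: int = 10
    mutation_burden: float = 4.0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for f in (self.input_fraction, self.output_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError("fractions must be in (0, 1)")


# ---------------------------------------------------------------------------
# Random Boolean networks
# ---------------------------------------------------------------------------

_MAX_IN_DEGREE = 4


def _draw_in_degree(rng: np.random.Generator) -> int:
    """Heavy-tailed in-degree: zeta(2)-like mass truncated at 4."""
    weights = np.array([1.0, 1.0 / 4.0, 1.0 / 9.0, 1.0 / 16.0])
    probs = weights / weights.sum()
    return int(rng.choice(np.arange(1, _MAX_IN_DEGREE + 1), p=probs))


def _random_rule(regulators: Sequence[str], rng: np.random.Generator) -> BooleanExpression:
    """Random AND/OR tree over the chosen regulators, literals negated with
    probability 0.3."""
    leaves: list[BooleanExpression] = []
    for r in regulators:
        lit: BooleanExpression = Var(r)
        if rng.random() < 0.3:
            lit = Not(lit)
        leaves.append(lit)
    rng.shuffle(leaves)
    expr = leaves[0]
    for leaf in leaves[1:]:
        expr = And(expr, leaf) if rng.random() < 0.5 else Or(expr, leaf)
    return expr


def generate_random_network(spec: GeneratorSpec, name: str | None = None) -> BooleanNetwork:
    """Random scale-free-ish Boolean network honoring all BooleanNetwork
    invariants, with at least one input -> output path."""
    rng = np.random.default_rng(spec.seed)
    n_inputs = max(1, round(spec.input_fraction * spec.n))
    n_outputs = max(1, round(spec.output_fraction * spec.n))
    if n_inputs + n_outputs >= spec.n:
        raise ValueError("infeasible spec: inputs + outputs must leave ruled interior nodes")
    nodes = [f"n{i:02d}" for i in range(spec.n)]
    inputs = nodes[:n_inputs]
    outputs = nodes[-n_outputs:]
    ruled = nodes[n_inputs:]

    # preferential-attachment flavored regulator choice: earlier nodes are
    # chosen more often, giving a heavy-tailed out-degree as well
    rules: dict[str, BooleanExpression] = {}
    for target in ruled:
        k = min(_draw_in_degree(rng), spec.n - 1)
        # mean in-degree scales toward spec.k
        if spec.k > 2.0 and rng.random() < min(1.0, (spec.k - 2.0) / 2.0):
            k = min(k + 1, _MAX_IN_DEGREE)
        candidates = [m for m in nodes if m != target]
        weights = np.array([1.0 / (1 + i) for i, m in enumerate(candidates)])
        probs = weights / weights.sum()
        regs = list(rng.choice(candidates, size=min(k, len(candidates)), replace=False, p=probs))
        rules[target] = _random_rule(regs, rng)

    net = BooleanNetwork(
        name=name or f"random-n{spec.n}-s{spec.seed}",
        nodes=nodes,
        rules=rules,
        explicit_outputs=outputs,
    )
    # guarantee an input -> output path; if absent, rewire one output onto a
    # node reachable from an input
    g = nx.DiGraph(list(net.edges))
    g.add_nodes_from(nodes)
    reachable: set[str] = set()
    for i in inputs:
        reachable |= nx.descendants(g, i) | {i}
    if not any(o in reachable for o in outputs):
        anchor = next((m for m in reachable if m != outputs[0]), inputs[0])
        rules[outputs[0]] = Var(anchor)
        net = BooleanNetwork(name=net.name, nodes=nodes, rules=rules, explicit_outputs=outputs)
    return net


# ---------------------------------------------------------------------------
# Oracle fixtures
# ---------------------------------------------------------------------------

@dataclass
class OracleFixture:
    """A small network together with its fully enumerated landscape (computed
    by the exhaustive engine at construction) and, where meaningful, a fate
    classification and a normal clamp profile."""

    name: str
    network: BooleanNetwork
    landscape: AttractorLandscape
    classification: FateClassification | None = None
    normal_clamps: ClampProfile | None = None
    hard_clamps: dict[str, int] = field(default_factory=dict)


_MIDGUT_DEMO_RULES = """\
# midgut-demo: a deliberately small ISC-like teaching network wired from the
# core vocabulary of the nine midgut pathways.  This is a synthetic
# reconstruction for oracle testing, not a curated model.
INPUT: EGF Wg Dl_ext ROS
OUTPUT: hid myc SuH Mmp1
Ras = EGF
Arm = Wg
N = Dl_ext
Bsk = ROS
myc = Ras AND Arm AND NOT Bsk
hid = Bsk AND NOT Ras
SuH = N
Mmp1 = Bsk
"""

_MIDGUT_DEMO_FATES = [
    ("apoptosis", (("hid", 1),)),
    ("proliferation", (("myc", 1),)),
    ("EB_fate", (("SuH", 1),)),
    ("extrusion", (("Mmp1", 1),)),
]

_MIDGUT_DEMO_CLAMPS = {"EGF": 0.8, "Wg": 0.8, "Dl_ext": 0.5, "ROS": 0.2}


def midgut_demo() -> OracleFixture:
    """The documented teaching fixture: a 12-node ISC-like network (EGFR,
    WNT, Notch and JNK arms) with an apoptosis / proliferation /
    differentiation / extrusion classification.  Explicitly a reconstruction
    of midgut-style wiring at toy scale."""
    net = parse_network(_MIDGUT_DEMO_RULES, name="midgut-demo")
    return OracleFixture(
        name="midgut-demo",
        network=net,
        landscape=exhaustive_landscape(net),
        classification=FateClassification(list(_MIDGUT_DEMO_FATES), name="midgut-demo-fates"),
        normal_clamps=ClampProfile(dict(_MIDGUT_DEMO_CLAMPS), name="midgut-demo-normal"),
    )


def oracle_fixtures() -> list[OracleFixture]:
    """Catalog of <=12-node networks with exhaustively enumerated basins."""
    fixtures: list[OracleFixture] = []

    toggle = parse_network("A = B\nB = A\n", name="two-node-toggle")
    fixtures.append(OracleFixture("two-node-toggle", toggle, exhaustive_landscape(toggle)))

    blinker = parse_network("B = NOT B\n", name="blinker")
    fixtures.append(OracleFixture("blinker", blinker, exhaustive_landscape(blinker)))

    clamped = parse_network("A = NOT B\nB = A\n", name="clamped-pair")
    fixtures.append(
        OracleFixture(
            "clamped-pair",
            clamped,
            exhaustive_landscape(clamped, {"A": 1}),
            hard_clamps={"A": 1},
        )
    )

    chain = parse_network(
        "INPUT: I\nX = I\nY = X AND NOT Z\nZ = Y\n", name="relay-chain"
    )
    fixtures.append(OracleFixture("relay-chain", chain, exhaustive_landscape(chain)))

    for seed in (3, 11):
        spec = GeneratorSpec(seed=seed, n=10)
        net = generate_random_network(spec, name=f"random-oracle-{seed}")
        fixtures.append(OracleFixture(net.name, net, exhaustive_landscape(net)))

    fixtures.append(midgut_demo())
    return fixtures


# ---------------------------------------------------------------------------
# Expression / cohort / druggability generators
# ---------------------------------------------------------------------------

def generate_expression_table(spec: GeneratorSpec, genes: Sequence[str]) -> ExpressionTable:
    """Log-normal rpkm with gene-, cell-type- and region-specific effects so
    normalization has real structure to find."""
    rng = np.random.default_rng(spec.seed)
    gene_scale = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    cell_shift = rng.normal(0.0, 1.0, size=(len(genes), len(CELL_TYPES)))
    region_shift = rng.normal(0.0, 0.5, size=(len(genes), len(REGIONS)))
    data = {}
    for ci, cell in enumerate(CELL_TYPES):
        for ri, region in enumerate(REGIONS):
            noise = rng.lognormal(mean=0.0, sigma=spec.dispersion, size=len(genes))
            vals = gene_scale * np.exp(cell_shift[:, ci] + region_shift[:, ri]) * noise
            data[f"{cell}_{region}"] = np.round(vals, 3)
    df = pd.DataFrame(data, index=list(genes))
    df.index.name = "gene"
    return ExpressionTable(df)


def generate_patient_cohort(spec: GeneratorSpec,
                            gene_roles: dict[str, str]) -> list[PatientProfile]:
    """Synthetic cBioPortal-style cohort: mutation counts ~ 1 + Poisson over
    the gene pool, variant classes drawn to match each gene's role
    (suppressors get truncating-style variants, oncogenes missense-style)."""
    rng = np.random.default_rng(spec.seed)
    pool = sorted(gene_roles)
    profiles: list[PatientProfile] = []
    for i in range(spec.cohort_size):
        burden = 1 + int(rng.poisson(max(0.0, spec.mutation_burden - 1)))
        burden = min(burden, len(pool))
        genes = list(rng.choice(pool, size=burden, replace=False))
        muts = []
        for g in sorted(genes):
            if gene_roles[g] == "suppressor":
                variant = str(rng.choice(["truncating", "nonsense", "frameshift", "deletion"]))
            else:
                variant = str(rng.choice(["missense", "amplification"]))
            muts.append(MutationRecord(gene=g, variant_class=variant, effect="unknown"))
        # effects resolved downstream via the role table
        resolved = [
            MutationRecord(m.gene, m.variant_class,
                           "GoF" if gene_roles[m.gene] == "oncogene" else "LoF")
            for m in muts
        ]
        profiles.append(PatientProfile(patient_id=f"SYN-{i + 1:03d}", mutations=resolved))
    return profiles


def generate_druggability(spec: GeneratorSpec, net: BooleanNetwork,
                          planted_target: str | None = None) -> DruggabilityTable:
    """Drugs targeting 1-2 ruled nodes each.  When ``planted_target`` is
    given, the first drug inhibits exactly that node (the 'beneficial'
    target used by screening tests)."""
    rng = np.random.default_rng(spec.seed)
    # drugs act on upstream machinery; designated outputs are readouts
    candidates = [n for n in net.nodes if n in net.rules and n not in set(net.outputs)]
    rows: list[DrugTarget] = []
    if planted_target is not None:
        if planted_target not in net.nodes:
            raise ValueError(f"planted target {planted_target!r} not in network")
        rows.append(DrugTarget("benefistat", planted_target, "inhibit", "direct",
                               "planted beneficial target"))
    n_drugs = min(4, max(2, len(candidates) // 3))
    for d in range(n_drugs):
        drug = f"syndrug{d + 1}"
        n_targets = 1 + int(rng.random() < 0.4)
        targets = rng.choice(candidates, size=min(n_targets, len(candidates)), replace=False)
        for j, t in enumerate(targets):
            action = "inhibit" if rng.random() < 0.5 else "activate"
            mode = "direct" if j == 0 else "indirect"
            if planted_target is not None and str(t) == planted_target and action == "inhibit":
                action = "activate"  # keep the planted drug the only inhibitor of its node
            if any(r.drug == drug and r.target == str(t) for r in rows):
                continue
            rows.append(DrugTarget(drug, str(t), action, mode, "synthetic"))
    return DruggabilityTable(rows, name=f"synthetic-s{spec.seed}")
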