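"""Mutations and drugs as network interventions; scenario evaluation, drug
classification and combination screening.

Interventions are hard clamps: gain-of-function mutations and activating
drugs clamp their target node to 1; loss-of-function mutations and
inhibitory drugs clamp it to 0.  *Horizontal* evaluation runs scenarios
independently side by side (e.g. progressive mutation sets); *vertical*
evaluation stacks interventions within one scenario (drugs on top of a
mutated network), with later interventions overriding earlier ones on a
shared target node.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .engine import (
    AnalysisConfig,
    AttractorLandscape,
    CompiledNetwork,
    compile_network,
    exhaustive_landscape,
    sampled_landscape,
    spawn_seeds,
)
from .fates import FateProfile, fate_propensities
from .netio import BooleanNetwork, ClampProfile, DruggabilityTable, FateClassification

__all__ = [
    "Intervention",
    "Scenario",
    "DrugClassAssessment",
    "CombinationEntry",
    "CombinationReport",
    "apply_interventions",
    "evaluate_scenarios",
    "percent_change",
    "assess_drug_class",
    "interventions_for_drug",
    "parse_scenarios",
    "restrict_druggability",
    "screen_combinations",
]

from .netio import NetworkFormatError

KINDS = ("mutation_GoF", "mutation_LoF", "drug_inhibit", "drug_activate")
_CLAMP_OF = {"mutation_GoF": 1, "mutation_LoF": 0, "drug_inhibit": 0, "drug_activate": 1}


@dataclass(frozen=True)
class Intervention:
    kind: str  # mutation_GoF | mutation_LoF | drug_inhibit | drug_activate
    target: str
    source: str = ""  # gene or drug name
    mode: str = "direct"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")

    @property
    def clamp_value(self) -> int:
        return _CLAMP_OF[self.kind]


@dataclass
class Scenario:
    label: str
    interventions: list[Intervention] = field(default_factory=list)


def apply_interventions(base: ClampProfile, scenario: Scenario,
                        net: BooleanNetwork | None = None) -> ClampProfile:
    """Apply interventions in order on top of the base clamps; later
    interventions win on a shared target node; intervened nodes end up
    hard-clamped (0/1)."""
    if net is not None:
        net.require_nodes((iv.target for iv in scenario.interventions), role="intervention target")
    values = dict(base.values)
    for iv in scenario.interventions:
        values[iv.target] = float(iv.clamp_value)
    return ClampProfile(values, name=f"{base.name}+{scenario.label}" if scenario.label else base.name)


def _landscape(cn: CompiledNetwork, clamps: ClampProfile, cfg: AnalysisConfig,
               exhaustive: bool) -> AttractorLandscape:
    if exhaustive:
        hard = {}
        ok = all(v in (0.0, 1.0) for v in clamps.values.values())
        if ok:
            hard = {n: int(v) for n, v in clamps.items()}
            free = cn.n - len(hard)
            if free <= cfg.exhaustive_cutoff:
                return exhaustive_landscape(cn, hard, cfg)
    return sampled_landscape(cn, clamps, cfg)


def evaluate_scenarios(net: BooleanNetwork | CompiledNetwork,
                       base: ClampProfile,
                       scenarios: Sequence[Scenario],
                       classification: FateClassification,
                       cfg: AnalysisConfig,
                       threshold: float = 0.5,
                       prefer_exhaustive: bool = False) -> dict[str, FateProfile]:
    """Horizontal evaluation: each scenario independently, with an automatic
    empty ``control`` scenario prepended.  Every scenario is evaluated under
    the same seed so differences are intervention-driven, not sampling-driven."""
    if not scenarios:
        raise ValueError("need at least one scenario")
    cn = net if isinstance(net, CompiledNetwork) else compile_network(net)
    all_scenarios = [Scenario(label="control")] + list(scenarios)
    results: dict[str, FateProfile] = {}
    for sc in all_scenarios:
        if sc.label in results:
            raise ValueError(f"duplicate scenario label {sc.label!r}")
        clamps = apply_interventions(base, sc, cn.net)
        land = _landscape(cn, clamps, cfg, prefer_exhaustive)
        results[sc.label] = fate_propensities(land, classification, threshold,
                                              node_order=cn.net.nodes)
    return results


_SHORT_KIND = {"GoF": "mutation_GoF", "LoF": "mutation_LoF",
               "inhibit": "drug_inhibit", "activate": "drug_activate"}


def parse_scenarios(text: str) -> list[Scenario]:
    """Scenario TSV: ``label<TAB>kind:target[,kind:target...]`` with kind in
    {GoF, LoF, inhibit, activate}; an empty intervention list is allowed."""
    scenarios: list[Scenario] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("label\t"):
            continue
        parts = line.split("\t")
        label = parts[0].strip()
        ivs: list[Intervention] = []
        if len(parts) > 1 and parts[1].strip():
            for term in parts[1].split(","):
                term = term.strip()
                if ":" not in term:
                    raise NetworkFormatError(f"malformed intervention {term!r}", line_no)
                kind, target = (s.strip() for s in term.split(":", 1))
                if kind not in _SHORT_KIND:
                    raise NetworkFormatError(
                        f"unknown intervention kind {kind!r} (allowed: {sorted(_SHORT_KIND)})",
                        line_no,
                    )
                ivs.append(Intervention(kind=_SHORT_KIND[kind], target=target))
        scenarios.append(Scenario(label=label, interventions=ivs))
    return scenarios


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100*(after-before)/before, with the documented
    conventions: before=0 and after>0 -> +inf sentinel; before=after=0 -> 0."""
    if before < 0:
        raise ValueError("before must be >= 0")
    if before == 0:
        return 0.0 if after == 0 else math.inf
    return 100.0 * (after - before) / before


@dataclass
class DrugClassAssessment:
    """Cytotoxicity classes for a drug evaluated on wild-type and mutated models.

    Class I: the drug reverses proliferation in the mutated network
    (decrease beyond epsilon) without disturbing wild-type proliferation
    (|change| <= epsilon).  Class II: the drug itself drives wild-type
    proliferation up beyond epsilon (cytotoxic / tumorigenic side effect).
    Anything else is indeterminate."""

    drug: str
    delta_wt_proliferation: float
    delta_wt_apoptosis: float
    delta_mut_proliferation: float
    delta_mut_apoptosis: float
    assigned_class: str  # "I" | "II" | "indeterminate"
    epsilon: float


def assess_drug_class(wt_before: FateProfile, wt_after: FateProfile,
                      mut_before: FateProfile, mut_after: FateProfile,
                      epsilon: float = 0.01,
                      proliferation_fate: str = "proliferation",
                      apoptosis_fate: str = "apoptosis",
                      drug: str = "") -> DrugClassAssessment:
    profiles = (wt_before, wt_after, mut_before, mut_after)
    fate_sets = {tuple(sorted(p.propensities)) for p in profiles}
    if len(fate_sets) != 1:
        raise ValueError("the four fate profiles must share one fate set")
    d_wt_p = wt_after[proliferation_fate] - wt_before[proliferation_fate]
    d_wt_a = wt_after[apoptosis_fate] - wt_before[apoptosis_fate]
    d_mut_p = mut_after[proliferation_fate] - mut_before[proliferation_fate]
    d_mut_a = mut_after[apoptosis_fate] - mut_before[apoptosis_fate]
    if d_wt_p > epsilon:
        assigned = "II"
    elif d_mut_p < -epsilon and abs(d_wt_p) <= epsilon:
        assigned = "I"
    else:
        assigned = "indeterminate"
    return DrugClassAssessment(
        drug=drug,
        delta_wt_proliferation=d_wt_p,
        delta_wt_apoptosis=d_wt_a,
        delta_mut_proliferation=d_mut_p,
        delta_mut_apoptosis=d_mut_a,
        assigned_class=assigned,
        epsilon=epsilon,
    )


def restrict_druggability(table: DruggabilityTable, net: BooleanNetwork) -> DruggabilityTable:
    """Drop drugs with any target outside the network (a drug acts as the
    bundle of all its mechanisms, so partial applicability drops the drug)."""
    node_set = set(net.nodes)
    keep_drugs = [
        d for d in table.drugs if all(r.target in node_set for r in table.rows_for(d))
    ]
    rows = [r for r in table.rows if r.drug in keep_drugs]
    return DruggabilityTable(rows, name=f"{table.name}@{net.name}")


def interventions_for_drug(druggability: DruggabilityTable, drug: str) -> list[Intervention]:
    """All of a drug's rows (direct and indirect mechanisms) as interventions."""
    rows = druggability.rows_for(drug)
    if not rows:
        raise KeyError(f"drug {drug!r} not in druggability table")
    return [
        Intervention(
            kind="drug_inhibit" if r.action == "inhibit" else "drug_activate",
            target=r.target,
            source=r.drug,
            mode=r.mode,
        )
        for r in rows
    ]


_SCORE_CAP = 200.0


def _capped(pc: float) -> float:
    if math.isinf(pc):
        return _SCORE_CAP if pc > 0 else -_SCORE_CAP
    return pc


@dataclass
class CombinationEntry:
    drugs: tuple[str, ...]
    before: FateProfile
    after: FateProfile
    apoptosis_change: float      # signed percent (may be +/- inf)
    proliferation_change: float  # signed percent (may be +/- inf)
    score: float                 # capped(apoptosis %) - capped(proliferation %)


@dataclass
class CombinationReport:
    baseline: FateProfile
    entries: list[CombinationEntry]
    max_size: int
    no_beneficial_target: bool

    @property
    def best(self) -> CombinationEntry | None:
        return self.entries[0] if self.entries else None


def screen_combinations(net: BooleanNetwork | CompiledNetwork,
                        patient_clamps: ClampProfile,
                        druggability: DruggabilityTable,
                        classification: FateClassification,
                        max_size: int,
                        cfg: AnalysisConfig,
                        threshold: float = 0.5,
                        proliferation_fate: str = "proliferation",
                        apoptosis_fate: str = "apoptosis",
                        prefer_exhaustive: bool = False,
                        max_combinations: int = 5000) -> CombinationReport:
    """Enumerate single drugs, then pairs/triples, each applied vertically on
    top of the patient clamps (which already carry the mutations); rank by
    score = capped(apoptosis % change) - capped(proliferation % change),
    ties broken by fewer drugs then lexicographic drug names.

    All evaluations share one seed so the ranking is intervention-driven and
    invariant to the row order of the druggability table."""
    if max_size not in (1, 2, 3):
        raise ValueError("max_size must be 1, 2 or 3")
    if not druggability.rows:
        raise ValueError("druggability table is empty")
    cn = net if isinstance(net, CompiledNetwork) else compile_network(net)
    cn.net.require_nodes((r.target for r in druggability.rows), role="drug target")

    drugs = sorted(druggability.drugs)
    combos: list[tuple[str, ...]] = []
    for k in range(1, max_size + 1):
        combos.extend(itertools.combinations(drugs, k))
    if len(combos) > max_combinations:
        raise ValueError(
            f"{len(combos)} combinations exceed the budget guard ({max_combinations}); "
            "raise max_combinations explicitly if intended"
        )

    base_land = _landscape(cn, patient_clamps, cfg, prefer_exhaustive)
    baseline = fate_propensities(base_land, classification, threshold, node_order=cn.net.nodes)

    entries: list[CombinationEntry] = []
    for combo in combos:
        ivs: list[Intervention] = []
        for d in combo:
            ivs.extend(interventions_for_drug(druggability, d))
        sc = Scenario(label="+".join(combo), interventions=ivs)
        clamps = apply_interventions(patient_clamps, sc, cn.net)
        land = _landscape(cn, clamps, cfg, prefer_exhaustive)
        after = fate_propensities(land, classification, threshold, node_order=cn.net.nodes)
        d_apop = percent_change(baseline[apoptosis_fate], after[apoptosis_fate])
        d_prol = percent_change(baseline[proliferation_fate], after[proliferation_fate])
        score = _capped(d_apop) - _capped(d_prol)
        entries.append(
            CombinationEntry(
                drugs=combo,
                before=baseline,
                after=after,
                apoptosis_change=d_apop,
                proliferation_change=d_prol,
                score=score,
            )
        )
    entries.sort(key=lambda e: (-e.score, len(e.drugs), e.drugs))
    no_benefit = all(e.score <= 0 for e in entries)
    return CombinationReport(
        baseline=baseline,
        entries=entries,
        max_size=max_size,
        no_beneficial_target=no_benefit,
    )
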