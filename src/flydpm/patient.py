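"""End-to-end personalized pipeline: patient mutation profile -> fly homolog
mapping -> mutated network model -> combination screening -> report.

Human mutations (cBioPortal-style extracts) are translated to network
interventions via a homolog table (human gene -> fly network node) and a
gene-role table (oncogene -> gain of function, tumor suppressor -> loss of
function).  Genes with no homolog in the network, or with unknown effect, are
excluded from the interventions but listed in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .engine import AnalysisConfig, CompiledNetwork, compile_network, spawn_seeds
from .fates import FateProfile
from .netio import (
    BooleanNetwork,
    ClampProfile,
    DruggabilityTable,
    FateClassification,
    NetworkExtension,
    NetworkFormatError,
    merge_networks,
)
from .therapeutics import (
    CombinationReport,
    Intervention,
    Scenario,
    apply_interventions,
    evaluate_scenarios,
    percent_change,
    screen_combinations,
)

__all__ = [
    "PatientProfile",
    "MutationRecord",
    "PatientReport",
    "VARIANT_CLASSES",
    "parse_patient_profile",
    "parse_homolog_table",
    "parse_gene_roles",
    "map_to_network",
    "run_dpm",
    "run_cohort",
    "report_summary_rows",
]

EFFECTS = ("GoF", "LoF", "unknown")
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "truncating",
    "frameshift",
    "splice",
    "amplification",
    "deletion",
    "fusion",
    "inframe",
    "other",
)


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    variant_class: str
    effect: str  # GoF | LoF | unknown


@dataclass
class PatientProfile:
    patient_id: str
    mutations: list[MutationRecord]

    def __post_init__(self):
        if not self.patient_id:
            raise NetworkFormatError("patient id must be non-empty")
        for m in self.mutations:
            if m.effect not in EFFECTS:
                raise NetworkFormatError(f"bad effect {m.effect!r} for gene {m.gene!r}")


def parse_gene_roles(text: str) -> dict[str, str]:
    """TSV ``gene<TAB>role`` with role in {oncogene, suppressor}; used to
    infer mutation effects when the patient file has no effect column."""
    roles: dict[str, str] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("gene\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1].strip() not in ("oncogene", "suppressor"):
            raise NetworkFormatError("expected 'gene<TAB>oncogene|suppressor'", line_no)
        roles[parts[0].strip()] = parts[1].strip()
    return roles


def parse_patient_profile(text: str, patient_id: str | None = None,
                          gene_roles: Mapping[str, str] | None = None) -> PatientProfile:
    """Parse a patient TSV (``gene<TAB>variant_class[<TAB>effect]``).

    A leading ``patient<TAB><id>`` line may carry the id; otherwise pass it
    explicitly.  Missing effects are inferred from the role table
    (oncogene -> GoF, suppressor -> LoF); genes absent from the table get
    effect ``unknown`` and are excluded from interventions but reported."""
    roles = dict(gene_roles or {})
    mutations: list[MutationRecord] = []
    pid = patient_id
    seen_any = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("gene\t"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if parts[0].lower() == "patient" and len(parts) == 2:
            pid = parts[1]
            continue
        seen_any = True
        if len(parts) < 2:
            raise NetworkFormatError("expected 'gene<TAB>variant_class[<TAB>effect]'", line_no)
        gene, variant = parts[0], parts[1]
        if variant not in VARIANT_CLASSES:
            raise NetworkFormatError(f"unknown variant classification {variant!r}", line_no)
        if len(parts) >= 3 and parts[2]:
            effect = parts[2]
            if effect not in EFFECTS:
                raise NetworkFormatError(f"unknown effect {effect!r}", line_no)
        elif gene in roles:
            effect = "GoF" if roles[gene] == "oncogene" else "LoF"
        else:
            effect = "unknown"
        mutations.append(MutationRecord(gene=gene, variant_class=variant, effect=effect))
    if not seen_any:
        raise NetworkFormatError("empty patient file")
    return PatientProfile(patient_id=pid or "patient", mutations=mutations)


def parse_homolog_table(text: str) -> dict[str, str]:
    """TSV ``human_gene<TAB>fly_node`` (many-to-one allowed)."""
    table: dict[str, str] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("human"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkFormatError("expected 'human_gene<TAB>fly_node'", line_no)
        table[parts[0].strip()] = parts[1].strip()
    return table


def map_to_network(profile: PatientProfile,
                   homologs: Mapping[str, str],
                   net: BooleanNetwork) -> tuple[list[Intervention], list[str]]:
    """One intervention per mapped, effect-known gene.  Genes with no
    homolog, a homolog outside the network, or unknown effect go to the
    skipped list.  Several genes hitting one node collapse to a single
    intervention with LoF taking precedence (loss dominates)."""
    node_set = set(net.nodes)
    per_node: dict[str, tuple[str, str]] = {}  # node -> (kind, source)
    order: list[str] = []
    skipped: list[str] = []
    for m in profile.mutations:
        node = homologs.get(m.gene)
        if m.effect == "unknown" or node is None or node not in node_set:
            skipped.append(m.gene)
            continue
        kind = "mutation_GoF" if m.effect == "GoF" else "mutation_LoF"
        if node in per_node:
            if per_node[node][0] == "mutation_GoF" and kind == "mutation_LoF":
                per_node[node] = (kind, m.gene)
        else:
            per_node[node] = (kind, m.gene)
            order.append(node)
    interventions = [
        Intervention(kind=per_node[n][0], target=n, source=per_node[n][1]) for n in order
    ]
    return interventions, skipped


@dataclass
class PatientReport:
    """Self-contained record of one patient's run: every number is
    recomputable from the stored inputs, config and seed."""

    patient_id: str
    interventions: list[Intervention]
    skipped_genes: list[str]
    control: FateProfile
    mutated: FateProfile
    screening: CombinationReport | None
    best_drugs: tuple[str, ...] | None
    best_apoptosis_change: float | None
    best_proliferation_change: float | None
    targeted_therapy_only: bool
    no_model_relevant_mutations: bool
    chemo: bool
    config: AnalysisConfig
    seed: int | None


def run_dpm(net: BooleanNetwork | CompiledNetwork,
            profile: PatientProfile,
            homologs: Mapping[str, str],
            druggability: DruggabilityTable,
            classification: FateClassification,
            base_clamps: ClampProfile,
            cfg: AnalysisConfig,
            chemo_extension: NetworkExtension | None = None,
            chemo_base_clamps: Mapping[str, float] | None = None,
            max_size: int = 2,
            threshold: float = 0.5,
            proliferation_fate: str = "proliferation",
            apoptosis_fate: str = "apoptosis",
            screen: bool = True) -> PatientReport:
    """Full personalized pipeline for one patient.

    When ``chemo_extension`` is given it is merged into the network before
    analysis (chemotherapy acts through the added microtubule machinery);
    ``chemo_base_clamps`` supplies resting clamp values for any new input
    nodes the extension introduces (e.g. no microtubule stabilization without
    the drug).  Seeds are derived from ``cfg.seed`` and the patient id, so a
    patient's result is identical whether run singly or in a cohort."""
    base_net = net.net if isinstance(net, CompiledNetwork) else net
    chemo = chemo_extension is not None
    if chemo:
        base_net = merge_networks(base_net, chemo_extension)
        if chemo_base_clamps:
            base_clamps = base_clamps.updated(chemo_base_clamps)
    cn = compile_network(base_net)

    # per-patient deterministic seed stream, independent of cohort order
    pid_digest = sum(ord(c) * (31 ** i) for i, c in enumerate(profile.patient_id)) % (2**20)
    patient_seed = None if cfg.seed is None else (spawn_seeds(cfg.seed, 1)[0] ^ pid_digest) % (2**31)
    run_cfg = replace(cfg, seed=patient_seed)

    interventions, skipped = map_to_network(profile, homologs, base_net)
    mutated_scenario = Scenario(label="mutated", interventions=interventions)
    results = evaluate_scenarios(cn, base_clamps, [mutated_scenario], classification,
                                 run_cfg, threshold=threshold)
    control, mutated = results["control"], results["mutated"]

    screening: CombinationReport | None = None
    best_drugs = None
    best_apop = None
    best_prol = None
    targeted_only = False
    if screen and druggability.rows:
        patient_clamps = apply_interventions(base_clamps, mutated_scenario, base_net)
        mono = screen_combinations(cn, patient_clamps, druggability, classification,
                                   max_size=1, cfg=run_cfg, threshold=threshold,
                                   proliferation_fate=proliferation_fate,
                                   apoptosis_fate=apoptosis_fate)
        best_mono = mono.best
        if best_mono is not None and best_mono.after[proliferation_fate] == 0.0:
            # a single targeted drug already abolishes proliferation
            screening = mono
            targeted_only = True
        elif max_size > 1:
            screening = screen_combinations(cn, patient_clamps, druggability, classification,
                                            max_size=max_size, cfg=run_cfg, threshold=threshold,
                                            proliferation_fate=proliferation_fate,
                                            apoptosis_fate=apoptosis_fate)
        else:
            screening = mono
        if screening.best is not None:
            best = screening.best
            best_drugs = best.drugs
            best_apop = best.apoptosis_change
            best_prol = best.proliferation_change

    return PatientReport(
        patient_id=profile.patient_id,
        interventions=interventions,
        skipped_genes=skipped,
        control=control,
        mutated=mutated,
        screening=screening,
        best_drugs=best_drugs,
        best_apoptosis_change=best_apop,
        best_proliferation_change=best_prol,
        targeted_therapy_only=targeted_only,
        no_model_relevant_mutations=not interventions,
        chemo=chemo,
        config=cfg,
        seed=patient_seed,
    )


def run_cohort(net: BooleanNetwork | CompiledNetwork,
               profiles: Sequence[PatientProfile],
               homologs: Mapping[str, str],
               druggability: DruggabilityTable,
               classification: FateClassification,
               base_clamps: ClampProfile,
               cfg: AnalysisConfig,
               **kwargs) -> list[PatientReport]:
    """Run the pipeline for a whole cohort; per-patient seed streams are keyed
    by patient id, so results are order-independent."""
    return [
        run_dpm(net, p, homologs, druggability, classification, base_clamps, cfg, **kwargs)
        for p in profiles
    ]


def report_summary_rows(reports: Sequence[PatientReport],
                        proliferation_fate: str = "proliferation",
                        apoptosis_fate: str = "apoptosis") -> list[dict]:
    """Before/after table across a cohort (one row per patient)."""
    rows = []
    for r in reports:
        after_apop = after_prol = None
        if r.screening is not None and r.screening.best is not None:
            after_apop = r.screening.best.after[apoptosis_fate]
            after_prol = r.screening.best.after[proliferation_fate]
        rows.append(
            {
                "patient": r.patient_id,
                "apoptosis_before": r.mutated[apoptosis_fate],
                "proliferation_before": r.mutated[proliferation_fate],
                "apoptosis_after": after_apop,
                "proliferation_after": after_prol,
                "best_therapy": "+".join(r.best_drugs) if r.best_drugs else "",
                "targeted_therapy_only": r.targeted_therapy_only,
            }
        )
    return rows
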