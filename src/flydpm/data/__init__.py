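"""Bundled reconstruction fixtures.

All files here are documented *reconstructions*: synthetic curations with
the structural counts and vocabulary of the midgut cell-type models, not the
curated rule sets themselves.  Every loader accepts an optional ``path``
override so user-supplied curated files take precedence.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..annotation import parse_node_gene_map
from ..netio import (
    BooleanNetwork,
    ClampProfile,
    DruggabilityTable,
    FateClassification,
    NetworkExtension,
    parse_alias_table,
    parse_clamp_profile,
    parse_druggability,
    parse_extension,
    parse_fate_classification,
    parse_network,
)
from ..patient import PatientProfile, parse_gene_roles, parse_homolog_table, parse_patient_profile

__all__ = [
    "read_text",
    "load_isc_network",
    "load_microtubule_extension",
    "load_isc_fates",
    "load_isc_chemo_fates",
    "load_isc_normal_clamps",
    "load_isc_stress_overrides",
    "load_isc_cancer_overrides",
    "load_druggability",
    "load_homologs",
    "load_gene_roles",
    "load_kras_crc_patient",
    "load_node_gene_map",
    "load_aliases",
]


def read_text(filename: str, path: str | Path | None = None) -> str:
    if path is not None:
        return Path(path).read_text()
    return resources.files(__package__).joinpath(filename).read_text()


def load_isc_network(path: str | Path | None = None) -> BooleanNetwork:
    return parse_network(read_text("isc_reconstruction.bnet", path), name="ISC-reconstruction")


def load_microtubule_extension(path: str | Path | None = None) -> NetworkExtension:
    return parse_extension(read_text("microtubule_extension.bnetx", path), name="microtubule")


def load_isc_fates(path: str | Path | None = None) -> FateClassification:
    return parse_fate_classification(read_text("isc_fates.tsv", path), name="isc-fates")


def load_isc_chemo_fates(path: str | Path | None = None) -> FateClassification:
    return parse_fate_classification(read_text("isc_chemo_fates.tsv", path), name="isc-chemo-fates")


def load_isc_normal_clamps(path: str | Path | None = None) -> ClampProfile:
    return parse_clamp_profile(read_text("isc_normal_clamps.tsv", path), name="isc-normal")


def load_isc_stress_overrides(path: str | Path | None = None) -> dict[str, float]:
    return dict(parse_clamp_profile(read_text("isc_stress_overrides.tsv", path)).values)


def load_isc_cancer_overrides(path: str | Path | None = None) -> dict[str, float]:
    return dict(parse_clamp_profile(read_text("isc_cancer_overrides.tsv", path)).values)


def load_druggability(path: str | Path | None = None) -> DruggabilityTable:
    return parse_druggability(read_text("druggability.tsv", path), name="druggability")


def load_homologs(path: str | Path | None = None) -> dict[str, str]:
    return parse_homolog_table(read_text("homologs.tsv", path))


def load_gene_roles(path: str | Path | None = None) -> dict[str, str]:
    return parse_gene_roles(read_text("gene_roles.tsv", path))


def load_kras_crc_patient(path: str | Path | None = None) -> PatientProfile:
    return parse_patient_profile(read_text("kras_crc_patient.tsv", path),
                                 gene_roles=load_gene_roles())


def load_node_gene_map(path: str | Path | None = None) -> dict[str, str]:
    return parse_node_gene_map(read_text("node_gene_map.tsv", path))


def load_aliases(path: str | Path | None = None) -> dict[str, str]:
    return parse_alias_table(read_text("aliases.tsv", path))
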