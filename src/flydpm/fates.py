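"""Mapping attractors onto biological cell fates.

An attractor's *activity vector* (per-node mean over its cycle) is binarized
at a threshold and matched against an ordered list of marker conditions; the
first matching condition wins and unmatched attractors fall back to the
reserved ``uncharacterized`` fate.  Per-fate propensities are the summed
basin ratios of the attractors classified to that fate, so they always
partition the basin mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .engine import Attractor, AttractorLandscape
from .netio import FateClassification

__all__ = [
    "FateProfile",
    "NodePropensityProfile",
    "binarized_activity",
    "classify_attractor",
    "fate_propensities",
    "output_node_propensities",
]


@dataclass
class FateProfile:
    """Fate name -> propensity in [0, 1], summing to 1 (including the
    fallback fate); optional per-fate dispersion from bootstrap."""

    propensities: dict[str, float]
    landscape_id: str = ""
    classification_id: str = ""
    sd: dict[str, float] | None = None
    sem: dict[str, float] | None = None

    def __getitem__(self, fate: str) -> float:
        return self.propensities[fate]

    def get(self, fate: str, default: float = 0.0) -> float:
        return self.propensities.get(fate, default)

    @property
    def fates(self) -> list[str]:
        return list(self.propensities)


@dataclass
class NodePropensityProfile:
    """Output node -> basin-weighted mean activity in [0, 1]."""

    values: dict[str, float]
    landscape_id: str = ""

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    @property
    def nodes(self) -> list[str]:
        return list(self.values)


def binarized_activity(attractor: Attractor, threshold: float = 0.5) -> tuple[int, ...]:
    """Threshold the activity vector: activity >= threshold -> 1.

    Fixed points come back unchanged for any threshold in (0, 1]."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    return tuple(1 if a >= threshold else 0 for a in attractor.activity)


def classify_attractor(attractor: Attractor, classification: FateClassification,
                       node_index: Mapping[str, int], threshold: float = 0.5) -> str:
    """First classification entry (file order) whose marker conjunction holds
    on the binarized activity wins; no match -> ``uncharacterized``."""
    binary = binarized_activity(attractor, threshold)
    for fate, cond in classification.entries:
        ok = True
        for node, required in cond:
            if node not in node_index:
                raise KeyError(f"marker node {node!r} missing from network")
            if binary[node_index[node]] != required:
                ok = False
                break
        if ok:
            return fate
    return FateClassification.FALLBACK


def fate_propensities(landscape: AttractorLandscape,
                      classification: FateClassification,
                      threshold: float = 0.5,
                      node_order: Sequence[str] | None = None,
                      node_index: Mapping[str, int] | None = None) -> FateProfile:
    """Aggregate basin counts per fate.

    Landscapes store states positionally, so the caller passes the network's
    node order (or a prebuilt node -> index map) to locate marker nodes.
    """
    if node_index is None:
        if node_order is None:
            raise ValueError("fate_propensities needs node_order or node_index")
        node_index = {n: i for i, n in enumerate(node_order)}
    counts: dict[str, int] = {f: 0 for f in classification.fate_names}
    for attractor, count in zip(landscape.attractors, landscape.counts):
        fate = classify_attractor(attractor, classification, node_index, threshold)
        counts[fate] += count
    props = {f: c / landscape.total for f, c in counts.items()}
    return FateProfile(
        propensities=props,
        landscape_id=f"{landscape.network_name}:{landscape.mode}:{landscape.seed}",
        classification_id=classification.name,
    )


def output_node_propensities(landscape: AttractorLandscape,
                             outputs: Sequence[str],
                             node_order: Sequence[str]) -> NodePropensityProfile:
    """Basin-weighted mean activity of the designated output nodes:
    value(node) = sum over attractors of basin_ratio * activity(node)."""
    idx = {n: i for i, n in enumerate(node_order)}
    missing = [n for n in outputs if n not in idx]
    if missing:
        raise KeyError(f"requested output node(s) not in network: {missing}")
    values = {n: 0.0 for n in outputs}
    for attractor, count in zip(landscape.attractors, landscape.counts):
        w = count / landscape.total
        act = attractor.activity
        for n in outputs:
            values[n] += w * act[idx[n]]
    return NodePropensityProfile(
        values=values,
        landscape_id=f"{landscape.network_name}:{landscape.mode}:{landscape.seed}",
    )
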