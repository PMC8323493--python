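"""Expression-to-logic annotation.

Converts FlyGut-seq-style per-region RNA-seq tables (rpkm; genes x
{cell type} x {region R1..R5}) into input clamp profiles for the Boolean
models, and compares model output-node propensities back against the same
normalized expression.

The wide TSV layout has a ``gene`` column followed by ``CELL_REGION``
columns, e.g. ``ISC_R1 ... VM_R5``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fates import NodePropensityProfile
from .netio import ClampProfile, NetworkFormatError

__all__ = [
    "CELL_TYPES",
    "REGIONS",
    "ExpressionTable",
    "NormalizedExpression",
    "NORMALIZATION_METHODS",
    "read_expression_table",
    "normalize_expression",
    "derive_input_clamps",
    "compare_outputs",
    "parse_node_gene_map",
]

CELL_TYPES = ("ISC", "EB", "EC", "EE", "VM")
REGIONS = ("R1", "R2", "R3", "R4", "R5")
NORMALIZATION_METHODS = ("global_minmax", "region_minmax", "rank")


@dataclass
class ExpressionTable:
    """rpkm values, rows = gene symbols, columns = CELL_REGION."""

    data: pd.DataFrame  # index: gene, columns: e.g. "ISC_R1"

    def __post_init__(self):
        expected = [f"{c}_{r}" for c in CELL_TYPES for r in REGIONS]
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise NetworkFormatError(f"expression table missing column(s) {missing}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise NetworkFormatError(f"duplicate gene symbol(s) {dup}")
        if (self.data[expected] < 0).any().any():
            raise NetworkFormatError("negative rpkm values are not allowed")
        self.data = self.data[expected].astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def columns_for(self, cell_type: str) -> list[str]:
        if cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {cell_type!r} (allowed: {CELL_TYPES})")
        return [f"{cell_type}_{r}" for r in REGIONS]


def read_expression_table(text_or_path, from_path: bool = False) -> ExpressionTable:
    if from_path:
        df = pd.read_csv(text_or_path, sep="\t")
    else:
        from io import StringIO

        df = pd.read_csv(StringIO(text_or_path), sep="\t")
    if "gene" not in df.columns:
        raise NetworkFormatError("expression table must have a 'gene' column")
    return ExpressionTable(df.set_index("gene"))


@dataclass
class NormalizedExpression:
    """(gene -> value in [0, 1]) for one cell type, with the method recorded."""

    cell_type: str
    values: dict[str, float]
    method: str

    def __post_init__(self):
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown normalization method {self.method!r}")
        for g, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"normalized value for {g!r} outside [0, 1]: {v}")

    def __getitem__(self, gene: str) -> float:
        return self.values[gene]


def normalize_expression(table: ExpressionTable, cell_type: str,
                         method: str = "global_minmax") -> NormalizedExpression:
    """Scale each gene's expression into [0, 1] and summarize the requested
    cell type over the five midgut regions.

    global_minmax (default): per gene, min-max scale across all
        cell-type x region cells of that gene's row, then average the five
        scaled regional values of the requested cell type.  Constant rows
        (no dynamic range anywhere) map to 0 by convention.
    region_minmax: min-max scale within the requested cell type's five
        regions only, then average.
    rank: rank of the gene's regional mean among all genes, scaled to [0, 1]
        (invariant under monotone transforms of the rpkm scale).
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    cols = table.columns_for(cell_type)
    df = table.data
    values: dict[str, float] = {}
    if method == "global_minmax":
        row_min = df.min(axis=1)
        row_max = df.max(axis=1)
        span = row_max - row_min
        for g in df.index:
            if span[g] == 0:
                values[g] = 0.0
            else:
                scaled = (df.loc[g, cols] - row_min[g]) / span[g]
                values[g] = float(scaled.mean())
    elif method == "region_minmax":
        sub = df[cols]
        row_min = sub.min(axis=1)
        row_max = sub.max(axis=1)
        span = row_max - row_min
        for g in df.index:
            if span[g] == 0:
                values[g] = 0.0
            else:
                values[g] = float(((sub.loc[g] - row_min[g]) / span[g]).mean())
    else:  # rank
        means = df[cols].mean(axis=1)
        n = len(means)
        if n == 1:
            values = {means.index[0]: 0.0}
        else:
            ranks = means.rank(method="average") - 1.0
            for g in df.index:
                values[g] = float(ranks[g] / (n - 1))
    return NormalizedExpression(cell_type=cell_type, values=values, method=method)


def parse_node_gene_map(text: str) -> dict[str, str]:
    """TSV ``node<TAB>gene`` mapping network input/output nodes to genes."""
    out: dict[str, str] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("node\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkFormatError("expected 'node<TAB>gene'", line_no)
        out[parts[0].strip()] = parts[1].strip()
    return out


def derive_input_clamps(norm: NormalizedExpression,
                        input_nodes: Sequence[str],
                        node_gene_map: Mapping[str, str],
                        condition_overrides: Mapping[str, float] | None = None,
                        name: str | None = None) -> ClampProfile:
    """Clamp(node) = normalized expression of its mapped gene, with
    condition overrides (stress/cancer files) taking precedence.

    Every input node must be mapped to a gene present in ``norm`` or be
    listed in the overrides."""
    overrides = dict(condition_overrides or {})
    values: dict[str, float] = {}
    for node in input_nodes:
        if node in overrides:
            values[node] = float(overrides[node])
        elif node in node_gene_map:
            gene = node_gene_map[node]
            if gene not in norm.values:
                raise KeyError(f"gene {gene!r} (for input node {node!r}) missing from expression")
            values[node] = norm[gene]
        else:
            raise KeyError(f"input node {node!r} has no gene mapping and no override")
    return ClampProfile(values, name=name or f"{norm.cell_type}:{norm.method}")


@dataclass
class OutputComparison:
    """Per-node model vs expression values; pure report, no pass/fail."""

    table: pd.DataFrame  # columns: node, model, expression, abs_diff
    mean_abs_difference: float
    rank_correlation: float


def compare_outputs(model: NodePropensityProfile,
                    norm: NormalizedExpression,
                    node_gene_map: Mapping[str, str]) -> OutputComparison:
    rows = []
    for node, m in model.values.items():
        if node not in node_gene_map:
            raise KeyError(f"output node {node!r} has no gene mapping")
        gene = node_gene_map[node]
        if gene not in norm.values:
            raise KeyError(f"gene {gene!r} (for output node {node!r}) missing from expression")
        e = norm[gene]
        rows.append({"node": node, "model": m, "expression": e, "abs_diff": abs(m - e)})
    df = pd.DataFrame(rows)
    mad = float(df["abs_diff"].mean())
    if len(df) >= 2 and df["model"].nunique() > 1 and df["expression"].nunique() > 1:
        rho = float(stats.spearmanr(df["model"], df["expression"]).statistic)
    else:
        rho = float("nan")
    return OutputComparison(table=df, mean_abs_difference=mad, rank_correlation=rho)
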