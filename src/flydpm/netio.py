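"""Reading, writing and merging Boolean network models and companion tables.

The network file format is a line-oriented plain-text grammar::

    # comment
    INPUT: EGF Wg
    OUTPUT: hid pan
    Ras = Egfr
    Arm = Dsh AND NOT Sgg AND NOT Apc2

One rule per line (``node = expression``).  Expressions are built from node
names, ``NOT``, ``AND``, ``OR`` and parentheses with precedence
``NOT > AND > OR``.  Nodes without a rule are *inputs* (they hold their
initial/clamped value under the dynamics); nodes referenced by no rule body
are *outputs* unless an explicit ``OUTPUT:`` line designates them.

Companion files are TSV: clamp profiles (``node\\tvalue`` with values in
[0, 1]), cell-fate classifications (``fate\\tmarker=val[,marker=val...]``),
druggability tables and alias tables.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Var",
    "Not",
    "And",
    "Or",
    "BooleanExpression",
    "BooleanNetwork",
    "NetworkExtension",
    "ClampProfile",
    "FateClassification",
    "DrugTarget",
    "DruggabilityTable",
    "NetworkFormatError",
    "parse_expression",
    "write_expression",
    "parse_network",
    "write_network",
    "parse_extension",
    "merge_networks",
    "parse_clamp_profile",
    "write_clamp_profile",
    "parse_fate_classification",
    "parse_druggability",
    "parse_alias_table",
]


class NetworkFormatError(ValueError):
    """Raised on malformed network/companion files, with line/column info."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {col}" if col is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col


# ---------------------------------------------------------------------------
# Boolean expression AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Not:
    arg: "BooleanExpression"


@dataclass(frozen=True)
class And:
    left: "BooleanExpression"
    right: "BooleanExpression"


@dataclass(frozen=True)
class Or:
    left: "BooleanExpression"
    right: "BooleanExpression"


BooleanExpression = Var | Not | And | Or


def expression_variables(expr: BooleanExpression) -> set[str]:
    """Distinct node names appearing in an expression."""
    if isinstance(expr, Var):
        return {expr.name}
    if isinstance(expr, Not):
        return expression_variables(expr.arg)
    return expression_variables(expr.left) | expression_variables(expr.right)


def evaluate_expression(expr: BooleanExpression, assignment: Mapping[str, int]) -> int:
    if isinstance(expr, Var):
        return 1 if assignment[expr.name] else 0
    if isinstance(expr, Not):
        return 1 - evaluate_expression(expr.arg, assignment)
    if isinstance(expr, And):
        return evaluate_expression(expr.left, assignment) and evaluate_expression(expr.right, assignment)
    return evaluate_expression(expr.left, assignment) or evaluate_expression(expr.right, assignment)


# precedence levels used by the writer (higher binds tighter)
_PREC = {Or: 1, And: 2, Not: 3, Var: 4}


def write_expression(expr: BooleanExpression) -> str:
    """Serialize an AST with the minimal parentheses that make
    ``parse_expression(write_expression(e)) == e`` hold exactly
    (binary AND/OR are left-associative in the parser, so right children at
    equal precedence are parenthesized to preserve tree shape)."""

    def emit(e: BooleanExpression, parent_prec: int, right_side: bool) -> str:
        prec = _PREC[type(e)]
        if isinstance(e, Var):
            return e.name
        if isinstance(e, Not):
            s = "NOT " + emit(e.arg, prec, False)
        else:
            op = " AND " if isinstance(e, And) else " OR "
            s = emit(e.left, prec, False) + op + emit(e.right, prec, True)
        if prec < parent_prec or (prec == parent_prec and right_side):
            return "(" + s + ")"
        return s

    return emit(expr, 0, False)


# ---------------------------------------------------------------------------
# Expression parsing: tokenizer + recursive descent
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<lp>\()|(?P<rp>\))|(?P<eq>=))")
_KEYWORDS = {"AND", "OR", "NOT"}


def _tokenize(text: str, line_no: int) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            col = pos + (len(text[pos:]) - len(stripped)) + 1
            raise NetworkFormatError(f"unexpected character {stripped[0]!r}", line_no, col)
        if m.lastgroup is None:  # trailing whitespace only
            break
        kind = m.lastgroup
        value = m.group(kind)
        tokens.append((kind, value, m.start(kind) + 1))
        pos = m.end()
    return tokens


class _ExprParser:
    def __init__(self, tokens: list[tuple[str, str, int]], line_no: int):
        self.tokens = tokens
        self.pos = 0
        self.line_no = line_no

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def error(self, msg: str):
        tok = self.peek()
        col = tok[2] if tok else None
        raise NetworkFormatError(msg, self.line_no, col)

    def parse(self) -> BooleanExpression:
        expr = self.parse_or()
        if self.peek() is not None:
            self.error(f"unexpected token {self.peek()[1]!r}")
        return expr

    def parse_or(self) -> BooleanExpression:
        expr = self.parse_and()
        while (tok := self.peek()) and tok[0] == "name" and tok[1] == "OR":
            self.pos += 1
            expr = Or(expr, self.parse_and())
        return expr

    def parse_and(self) -> BooleanExpression:
        expr = self.parse_not()
        while (tok := self.peek()) and tok[0] == "name" and tok[1] == "AND":
            self.pos += 1
            expr = And(expr, self.parse_not())
        return expr

    def parse_not(self) -> BooleanExpression:
        tok = self.peek()
        if tok and tok[0] == "name" and tok[1] == "NOT":
            self.pos += 1
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> BooleanExpression:
        tok = self.peek()
        if tok is None:
            raise NetworkFormatError("unexpected end of expression", self.line_no)
        kind, value, col = tok
        if kind == "lp":
            self.pos += 1
            expr = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != "rp":
                self.error("expected ')'")
            self.pos += 1
            return expr
        if kind == "name":
            if value in _KEYWORDS:
                self.error(f"unexpected keyword {value!r}")
            self.pos += 1
            return Var(value)
        self.error(f"unexpected token {value!r}")


def parse_expression(text: str, line_no: int = 1) -> BooleanExpression:
    tokens = _tokenize(text, line_no)
    if any(t[0] == "eq" for t in tokens):
        raise NetworkFormatError("'=' not allowed inside an expression", line_no)
    return _ExprParser(tokens, line_no).parse()


# ---------------------------------------------------------------------------
# BooleanNetwork
# ---------------------------------------------------------------------------

@dataclass
class BooleanNetwork:
    """A named Boolean network: ordered nodes, one update rule per non-input
    node, inputs (rule-less, hold their value), and designated outputs.

    ``edges`` is the derived set of distinct (regulator, target) pairs; the
    number of edges is the interaction count as reported for published models (self-loops count,
    duplicate occurrences of a regulator in one rule do not)."""

    name: str
    nodes: list[str]
    rules: dict[str, BooleanExpression]
    explicit_outputs: list[str] | None = None

    def __post_init__(self):
        self.validate()

    # -- derived structure ---------------------------------------------------
    @property
    def inputs(self) -> list[str]:
        return [n for n in self.nodes if n not in self.rules]

    @property
    def outputs(self) -> list[str]:
        if self.explicit_outputs is not None:
            return list(self.explicit_outputs)
        referenced = self._referenced()
        return [n for n in self.nodes if n not in referenced and n in self.rules]

    def _referenced(self) -> set[str]:
        refs: set[str] = set()
        for expr in self.rules.values():
            refs |= expression_variables(expr)
        return refs

    @property
    def edges(self) -> set[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        for target, expr in self.rules.items():
            for reg in expression_variables(expr):
                pairs.add((reg, target))
        return pairs

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for n in self.nodes:
            if not n or any(c.isspace() for c in n):
                raise NetworkFormatError(f"invalid node name {n!r}")
            if n in seen:
                raise NetworkFormatError(f"duplicate node name {n!r}")
            seen.add(n)
        for target, expr in self.rules.items():
            if target not in seen:
                raise NetworkFormatError(f"rule for undeclared node {target!r}")
            missing = expression_variables(expr) - seen
            if missing:
                raise NetworkFormatError(
                    f"rule for {target!r} references undeclared node(s) {sorted(missing)}"
                )
        if self.explicit_outputs is not None:
            for n in self.explicit_outputs:
                if n not in seen:
                    raise NetworkFormatError(f"OUTPUT declares unknown node {n!r}")

    def require_nodes(self, names: Iterable[str], role: str = "node") -> None:
        known = set(self.nodes)
        missing = [n for n in names if n not in known]
        if missing:
            raise NetworkFormatError(f"unknown {role}(s) in network {self.name!r}: {missing}")


def parse_network(text: str, name: str = "network") -> BooleanNetwork:
    """Parse a rule file into a validated :class:`BooleanNetwork`.

    Declaration order: ``INPUT:``-declared nodes first (file order), then rule
    targets, then names only ever referenced in rule bodies (inferred inputs).
    """
    declared_inputs: list[str] = []
    declared_outputs: list[str] | None = None
    rule_order: list[str] = []
    rules: dict[str, BooleanExpression] = {}
    referenced_order: list[str] = []

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("INPUT:"):
            declared_inputs.extend(line[len("INPUT:"):].split())
            continue
        if line.startswith("OUTPUT:"):
            if declared_outputs is None:
                declared_outputs = []
            declared_outputs.extend(line[len("OUTPUT:"):].split())
            continue
        if "=" not in line:
            raise NetworkFormatError("expected 'node = expression'", line_no)
        lhs, rhs = line.split("=", 1)
        target = lhs.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", target):
            raise NetworkFormatError(f"invalid node name {target!r}", line_no)
        if target in rules:
            raise NetworkFormatError(f"duplicate rule for node {target!r}", line_no)
        expr = parse_expression(rhs, line_no)
        rules[target] = expr
        rule_order.append(target)
        for v in _ordered_variables(expr):
            if v not in referenced_order:
                referenced_order.append(v)

    for n in declared_inputs:
        if n in rules:
            raise NetworkFormatError(f"INPUT-declared node {n!r} has a rule")

    nodes: list[str] = []
    for n in declared_inputs + rule_order + referenced_order:
        if n not in nodes:
            nodes.append(n)
    return BooleanNetwork(name=name, nodes=nodes, rules=rules, explicit_outputs=declared_outputs)


def _ordered_variables(expr: BooleanExpression) -> list[str]:
    if isinstance(expr, Var):
        return [expr.name]
    if isinstance(expr, Not):
        return _ordered_variables(expr.arg)
    out = _ordered_variables(expr.left)
    for v in _ordered_variables(expr.right):
        if v not in out:
            out.append(v)
    return out


def write_network(net: BooleanNetwork) -> str:
    """Canonical text form; ``parse_network(write_network(net))`` is
    structurally identical (same node order, same rule ASTs, same outputs)."""
    buf = io.StringIO()
    if net.inputs:
        buf.write("INPUT: " + " ".join(net.inputs) + "\n")
    if net.explicit_outputs is not None:
        buf.write("OUTPUT: " + " ".join(net.explicit_outputs) + "\n")
    for n in net.nodes:
        if n in net.rules:
            buf.write(f"{n} = {write_expression(net.rules[n])}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Network extensions and merging
# ---------------------------------------------------------------------------

_MERGE_MODES = ("REPLACE", "OR", "AND")


@dataclass
class NetworkExtension:
    """New nodes/rules plus per-node override directives for an existing
    network.  Override modes: ``REPLACE`` swaps the rule, ``OR``/``AND``
    combine the old and new rule with the corresponding connective."""

    name: str
    new_rules: dict[str, BooleanExpression] = field(default_factory=dict)
    new_node_order: list[str] = field(default_factory=list)
    overrides: dict[str, tuple[str, BooleanExpression]] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.new_rules and not self.overrides and not self.new_node_order


def parse_extension(text: str, name: str = "extension") -> NetworkExtension:
    """Extension files reuse the rule grammar; override lines are prefixed
    ``OVERRIDE <REPLACE|OR|AND> node = expr``.  Plain rule lines define new
    nodes; names referenced but never defined become new inputs."""
    ext = NetworkExtension(name=name)
    referenced: list[str] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("OVERRIDE"):
            parts = line.split(None, 2)
            if len(parts) < 3 or parts[1] not in _MERGE_MODES:
                raise NetworkFormatError(
                    "expected 'OVERRIDE <REPLACE|OR|AND> node = expr'", line_no
                )
            mode, rest = parts[1], parts[2]
            if "=" not in rest:
                raise NetworkFormatError("expected '=' in override", line_no)
            lhs, rhs = rest.split("=", 1)
            target = lhs.strip()
            if target in ext.overrides:
                raise NetworkFormatError(f"duplicate override for {target!r}", line_no)
            ext.overrides[target] = (mode, parse_expression(rhs, line_no))
            continue
        if "=" not in line:
            raise NetworkFormatError("expected 'node = expression'", line_no)
        lhs, rhs = line.split("=", 1)
        target = lhs.strip()
        if target in ext.new_rules:
            raise NetworkFormatError(f"duplicate rule for node {target!r}", line_no)
        expr = parse_expression(rhs, line_no)
        ext.new_rules[target] = expr
        if target not in ext.new_node_order:
            ext.new_node_order.append(target)
        for v in _ordered_variables(expr):
            if v not in referenced:
                referenced.append(v)
    for mode, expr in ext.overrides.values():
        for v in _ordered_variables(expr):
            if v not in referenced:
                referenced.append(v)
    # referenced-only names are either base nodes or new rule-less inputs;
    # merge_networks resolves which once the base is known
    ext._referenced = referenced  # type: ignore[attr-defined]
    return ext


def merge_networks(base: BooleanNetwork, ext: NetworkExtension,
                   name: str | None = None) -> BooleanNetwork:
    """Integrate an extension into a base network.

    New-node names must be disjoint from the base unless listed as overrides;
    referenced-but-undefined extension names that are not base nodes become
    new inputs.  Node count is additive for disjoint extensions and the edge
    set is the union of base edges and the extension's distinct new pairs.
    """
    base_set = set(base.nodes)
    for n in ext.new_rules:
        if n in base_set:
            raise NetworkFormatError(
                f"extension redefines base node {n!r} without an OVERRIDE directive"
            )
    for n in ext.overrides:
        if n not in base_set:
            raise NetworkFormatError(f"override targets unknown base node {n!r}")

    rules = dict(base.rules)
    for target, (mode, expr) in ext.overrides.items():
        if target not in rules:  # base input being given a rule
            if mode != "REPLACE":
                raise NetworkFormatError(
                    f"override of input node {target!r} must use REPLACE (it has no rule to merge)"
                )
            rules[target] = expr
        elif mode == "REPLACE":
            rules[target] = expr
        elif mode == "OR":
            rules[target] = Or(rules[target], expr)
        else:
            rules[target] = And(rules[target], expr)

    nodes = list(base.nodes)
    for n in ext.new_node_order:
        if n not in base_set and n not in nodes:
            nodes.append(n)
    # referenced-only extension names become new rule-less inputs
    referenced = getattr(ext, "_referenced", [])
    for n in referenced:
        if n not in base_set and n not in nodes:
            nodes.append(n)
    for target, expr in ext.new_rules.items():
        rules[target] = expr

    merged = BooleanNetwork(
        name=name or f"{base.name}+{ext.name}",
        nodes=nodes,
        rules=rules,
        explicit_outputs=list(base.explicit_outputs) if base.explicit_outputs is not None else None,
    )
    return merged


# ---------------------------------------------------------------------------
# Companion tables
# ---------------------------------------------------------------------------

@dataclass
class ClampProfile:
    """Per-node clamp values in [0, 1].

    Semantics (see engine): per sampled trajectory a clamped node is held at 1
    with probability v, else at 0; v in {0, 1} is a deterministic hard clamp;
    absent nodes are free."""

    values: dict[str, float]
    name: str = "clamps"

    def __post_init__(self):
        for node, v in self.values.items():
            if not (0.0 <= float(v) <= 1.0):
                raise NetworkFormatError(f"clamp value for {node!r} outside [0, 1]: {v}")
            self.values[node] = float(v)

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    def __contains__(self, node: str) -> bool:
        return node in self.values

    def items(self):
        return self.values.items()

    def updated(self, other: Mapping[str, float], name: str | None = None) -> "ClampProfile":
        merged = dict(self.values)
        merged.update({k: float(v) for k, v in other.items()})
        return ClampProfile(merged, name=name or self.name)


def parse_clamp_profile(text: str, name: str = "clamps") -> ClampProfile:
    values: dict[str, float] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("node\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkFormatError("expected 'node<TAB>value'", line_no)
        node, sval = parts[0].strip(), parts[1].strip()
        if node in values:
            raise NetworkFormatError(f"duplicate clamp for node {node!r}", line_no)
        try:
            v = float(sval)
        except ValueError:
            raise NetworkFormatError(f"malformed clamp value {sval!r}", line_no) from None
        if not (0.0 <= v <= 1.0):
            raise NetworkFormatError(f"clamp value outside [0, 1]: {v}", line_no)
        values[node] = v
    return ClampProfile(values, name=name)


def write_clamp_profile(profile: ClampProfile) -> str:
    lines = ["node\tvalue"]
    for node, v in profile.items():
        lines.append(f"{node}\t{v:.6g}")
    return "\n".join(lines) + "\n"


@dataclass
class FateClassification:
    """Ordered (fate, marker-condition) pairs; a condition is a conjunction of
    (node, required binarized activity) pairs and file order is match
    priority.  ``uncharacterized`` is the reserved fallback fate."""

    entries: list[tuple[str, tuple[tuple[str, int], ...]]]
    name: str = "fates"

    FALLBACK = "uncharacterized"

    def __post_init__(self):
        seen: set[str] = set()
        for fate, cond in self.entries:
            if fate in seen:
                raise NetworkFormatError(f"duplicate fate name {fate!r}")
            if fate == self.FALLBACK:
                raise NetworkFormatError(f"{self.FALLBACK!r} is reserved for unmatched attractors")
            seen.add(fate)
            for node, val in cond:
                if val not in (0, 1):
                    raise NetworkFormatError(f"marker value for {node!r} must be 0 or 1")

    @property
    def fate_names(self) -> list[str]:
        return [f for f, _ in self.entries] + [self.FALLBACK]

    @property
    def marker_nodes(self) -> set[str]:
        return {node for _, cond in self.entries for node, _ in cond}


def parse_fate_classification(text: str, name: str = "fates") -> FateClassification:
    entries: list[tuple[str, tuple[tuple[str, int], ...]]] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("fate\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkFormatError("expected 'fate<TAB>marker=val[,marker=val...]'", line_no)
        fate, spec_str = parts[0].strip(), parts[1].strip()
        cond: list[tuple[str, int]] = []
        for term in spec_str.split(","):
            term = term.strip()
            if "=" not in term:
                raise NetworkFormatError(f"malformed marker term {term!r}", line_no)
            node, sval = (s.strip() for s in term.split("=", 1))
            if sval not in ("0", "1"):
                raise NetworkFormatError(f"marker value must be 0 or 1, got {sval!r}", line_no)
            cond.append((node, int(sval)))
        entries.append((fate, tuple(cond)))
    try:
        return FateClassification(entries, name=name)
    except NetworkFormatError:
        raise


ACTIONS = ("inhibit", "activate")
MODES = ("direct", "indirect")


@dataclass(frozen=True)
class DrugTarget:
    drug: str
    target: str
    action: str  # inhibit | activate
    mode: str    # direct | indirect
    note: str = ""


@dataclass
class DruggabilityTable:
    """Static drug -> target-node table (PanDrugs-style lookups frozen to a
    file).  One drug may have several rows (direct + indirect mechanisms)."""

    rows: list[DrugTarget]
    name: str = "druggability"

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        for r in self.rows:
            if r.action not in ACTIONS:
                raise NetworkFormatError(f"bad action {r.action!r} (allowed: {ACTIONS})")
            if r.mode not in MODES:
                raise NetworkFormatError(f"bad mode {r.mode!r} (allowed: {MODES})")
            key = (r.drug, r.target)
            if key in seen:
                raise NetworkFormatError(f"duplicate (drug, target) pair {key}")
            seen.add(key)

    @property
    def drugs(self) -> list[str]:
        out: list[str] = []
        for r in self.rows:
            if r.drug not in out:
                out.append(r.drug)
        return out

    def rows_for(self, drug: str) -> list[DrugTarget]:
        return [r for r in self.rows if r.drug == drug]


def parse_druggability(text: str, name: str = "druggability") -> DruggabilityTable:
    rows: list[DrugTarget] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip("\n")
        if not line.strip() or line.lower().startswith("drug\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise NetworkFormatError(
                "expected 'drug<TAB>target<TAB>action<TAB>mode[<TAB>note]'", line_no
            )
        drug, target, action, mode = (p.strip() for p in parts[:4])
        note = parts[4].strip() if len(parts) > 4 else ""
        rows.append(DrugTarget(drug, target, action, mode, note))
    return DruggabilityTable(rows, name=name)


def parse_alias_table(text: str) -> dict[str, str]:
    """Two-column TSV mapping long names to network node symbols."""
    aliases: dict[str, str] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("alias\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise NetworkFormatError("expected 'alias<TAB>symbol'", line_no)
        aliases[parts[0].strip()] = parts[1].strip()
    return aliases
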