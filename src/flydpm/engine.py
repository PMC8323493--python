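"""Synchronous Boolean dynamics, attractor detection and basin-size
estimation.

The update is deterministic and synchronous: every node is updated from the
same pre-state, ``x_i' = f_i(x)`` for ruled nodes, while inputs (rule-less
nodes) hold their value.  Clamped nodes are overwritten with their clamp
value at every step, so an attractor under clamps is an attractor of the
clamped map.

Basin sizes come in two modes:

* ``exhaustive_landscape`` enumerates every state of the free nodes (the
  oracle mode; exact counts / 2**n_free ratios);
* ``sampled_landscape`` draws initial states (and Bernoulli realizations of
  probabilistic clamps) at random, the Monte-Carlo mode used for the full
  midgut networks where enumeration is infeasible.

The core loop works on tuples of 0/1 ints with per-network compiled update
functions and memoized state -> attractor resolution, so identical seeds give
bit-identical landscapes on any platform (no floats in the loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .netio import (
    And,
    BooleanExpression,
    BooleanNetwork,
    ClampProfile,
    Not,
    Or,
    Var,
)

__all__ = [
    "AnalysisConfig",
    "Attractor",
    "AttractorLandscape",
    "CompiledNetwork",
    "compile_network",
    "step",
    "find_attractor",
    "exhaustive_landscape",
    "sampled_landscape",
    "bootstrap_propensities",
    "BootstrapResult",
]

State = tuple[int, ...]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the deterministic-analysis pipeline.

    samples: initial network states drawn per landscape (default 10,000,
        drawn with replacement from the state space).
    replicates: bootstrap replicates for dispersion statistics (default 30).
    seed: master seed; every stream derives from it.
    exhaustive_cutoff: max number of free nodes for exhaustive enumeration.
    binarize_threshold: optional; when set, probabilistic clamp values v are
        hardened to 1 if v >= threshold else 0 before sampling.
    """

    samples: int = 10_000
    replicates: int = 30
    seed: int | None = None
    exhaustive_cutoff: int = 20
    binarize_threshold: float | None = None

    def __post_init__(self):
        if self.samples < 1:
            raise ValueError("samples must be >= 1")
        if self.exhaustive_cutoff > 25:
            raise ValueError("exhaustive_cutoff must be <= 25")


@dataclass(frozen=True)
class Attractor:
    """A fixed point (period 1) or cycle of the synchronous dynamics, stored
    in canonical rotation (lexicographically smallest state first)."""

    states: tuple[State, ...]
    clamp_signature: tuple[tuple[str, int], ...] = ()

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @property
    def activity(self) -> tuple[float, ...]:
        """Per-node mean activity over the cycle (rotation-invariant)."""
        n = len(self.states[0])
        period = len(self.states)
        return tuple(sum(s[i] for s in self.states) / period for i in range(n))

    def key(self) -> tuple:
        return (self.clamp_signature, self.states)


def _canonical_rotation(cycle: Sequence[State]) -> tuple[State, ...]:
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:]) + tuple(cycle[:k])


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def _expr_to_py(expr: BooleanExpression, idx: Mapping[str, int]) -> str:
    if isinstance(expr, Var):
        return f"x[{idx[expr.name]}]"
    if isinstance(expr, Not):
        return f"(not {_expr_to_py(expr.arg, idx)})"
    if isinstance(expr, And):
        return f"({_expr_to_py(expr.left, idx)} and {_expr_to_py(expr.right, idx)})"
    return f"({_expr_to_py(expr.left, idx)} or {_expr_to_py(expr.right, idx)})"


@dataclass
class CompiledNetwork:
    """A network with its synchronous update map compiled to one Python
    callable ``state -> state`` (tuples of 0/1)."""

    net: BooleanNetwork
    index: dict[str, int]
    update: Callable[[State], State]

    @property
    def n(self) -> int:
        return len(self.net.nodes)


def compile_network(net: BooleanNetwork) -> CompiledNetwork:
    idx = {n: i for i, n in enumerate(net.nodes)}
    parts = []
    for n in net.nodes:
        if n in net.rules:
            parts.append(f"1 if {_expr_to_py(net.rules[n], idx)} else 0")
        else:
            parts.append(f"x[{idx[n]}]")  # inputs hold their value
    body = ", ".join(parts)
    if len(parts) == 1:
        body += ","
    src = f"lambda x: ({body})"
    return CompiledNetwork(net=net, index=idx, update=eval(src))  # noqa: S307


def _clamp_items(net_index: Mapping[str, int], hard_clamps: Mapping[str, int],
                 network_name: str) -> list[tuple[int, int]]:
    items = []
    for node, v in hard_clamps.items():
        if node not in net_index:
            raise KeyError(f"clamped node {node!r} not in network {network_name!r}")
        if v not in (0, 1):
            raise ValueError(f"hard clamp for {node!r} must be 0 or 1, got {v}")
        items.append((net_index[node], int(v)))
    return items


def _apply_clamps(state: State, clamp_items: Sequence[tuple[int, int]]) -> State:
    if not clamp_items:
        return state
    s = list(state)
    for i, v in clamp_items:
        s[i] = v
    return tuple(s)


# ---------------------------------------------------------------------------
# Single-trajectory operations
# ---------------------------------------------------------------------------

def step(net: BooleanNetwork | CompiledNetwork, state: Sequence[int],
         hard_clamps: Mapping[str, int] | None = None) -> State:
    """One synchronous update; clamped nodes are held at their clamp value."""
    cn = net if isinstance(net, CompiledNetwork) else compile_network(net)
    items = _clamp_items(cn.index, hard_clamps or {}, cn.net.name)
    pre = _apply_clamps(tuple(int(b) for b in state), items)
    return _apply_clamps(cn.update(pre), items)


def _trajectory_guard(n_free: int) -> int:
    return 4 * (1 << min(n_free, 20))


def find_attractor(net: BooleanNetwork | CompiledNetwork, initial: Sequence[int],
                   hard_clamps: Mapping[str, int] | None = None) -> Attractor:
    """Walk the trajectory from ``initial`` until a state repeats; return the
    entered cycle in canonical rotation."""
    cn = net if isinstance(net, CompiledNetwork) else compile_network(net)
    items = _clamp_items(cn.index, hard_clamps or {}, cn.net.name)
    sig = tuple(sorted((node, int(v)) for node, v in (hard_clamps or {}).items()))
    guard = _trajectory_guard(cn.n - len(items))

    state = _apply_clamps(tuple(int(b) for b in initial), items)
    seen: dict[State, int] = {state: 0}
    traj = [state]
    for _ in range(guard):
        state = _apply_clamps(cn.update(state), items)
        if state in seen:
            cycle = traj[seen[state]:]
            return Attractor(states=_canonical_rotation(cycle), clamp_signature=sig)
        seen[state] = len(traj)
        traj.append(state)
    raise RuntimeError(
        "trajectory guard exceeded — this indicates an engine bug, not a user error"
    )


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------

@dataclass
class AttractorLandscape:
    """Attractors with integer basin counts.  Ratios are counts/total, so
    they sum to exactly 1 by construction."""

    network_name: str
    attractors: list[Attractor]
    counts: list[int]
    total: int
    mode: str  # "exhaustive" | "sampled"
    seed: int | None = None
    clamps: dict[str, float] = field(default_factory=dict)

    @property
    def ratios(self) -> list[float]:
        return [c / self.total for c in self.counts]

    def ratio_of(self, attractor: Attractor) -> float:
        for a, c in zip(self.attractors, self.counts):
            if a.key() == attractor.key():
                return c / self.total
        return 0.0

    def to_rows(self, nodes: Sequence[str]) -> list[dict]:
        rows = []
        for i, (a, c) in enumerate(zip(self.attractors, self.counts)):
            rows.append(
                {
                    "attractor": i,
                    "period": a.period,
                    "basin_count": c,
                    "basin_ratio": c / self.total,
                    "activity": ";".join(f"{v:.6g}" for v in a.activity),
                    "clamp_signature": ";".join(f"{n}={v}" for n, v in a.clamp_signature),
                }
            )
        return rows


class _BasinAccumulator:
    def __init__(self):
        self.attractors: list[Attractor] = []
        self.counts: list[int] = []
        self._by_key: dict[tuple, int] = {}

    def add(self, attractor: Attractor, count: int = 1) -> int:
        aid = self._by_key.get(attractor.key())
        if aid is None:
            aid = len(self.attractors)
            self._by_key[attractor.key()] = aid
            self.attractors.append(attractor)
            self.counts.append(0)
        self.counts[aid] += count
        return aid


def _resolve_attractor(cn: CompiledNetwork, state: State,
                       clamp_items: Sequence[tuple[int, int]],
                       sig: tuple[tuple[str, int], ...],
                       memo: dict[State, Attractor], guard: int) -> Attractor:
    """find_attractor with cross-trajectory memoization (path compression)."""
    if state in memo:
        return memo[state]
    path: list[State] = [state]
    path_index: dict[State, int] = {state: 0}
    attractor: Attractor | None = None
    s = state
    for _ in range(guard):
        s = _apply_clamps(cn.update(s), clamp_items)
        if s in memo:
            attractor = memo[s]
            break
        if s in path_index:
            cycle = path[path_index[s]:]
            attractor = Attractor(states=_canonical_rotation(cycle), clamp_signature=sig)
            break
        path_index[s] = len(path)
        path.append(s)
    if attractor is None:
        raise RuntimeError(
            "trajectory guard exceeded — this indicates an engine bug, not a user error"
        )
    for p in path:
        memo[p] = attractor
    return attractor


def exhaustive_landscape(net: BooleanNetwork | CompiledNetwork,
                         hard_clamps: Mapping[str, int] | None = None,
                         cfg: AnalysisConfig | None = None) -> AttractorLandscape:
    """Enumerate every state of the free nodes once; exact basin counts."""
    cn = net if isinstance(net, CompiledNetwork) else compile_network(net)
    cfg = cfg or AnalysisConfig()
    hard_clamps = dict(hard_clamps or {})
    items = _clamp_items(cn.index, hard_clamps, cn.net.name)
    sig = tuple(sorted((node, int(v)) for node, v in hard_clamps.items()))
    clamped_idx = {i for i, _ in items}
    free = [i for i in range(cn.n) if i not in clamped_idx]
    if len(free) > cfg.exhaustive_cutoff:
        raise ValueError(
            f"{len(free)} free nodes exceed exhaustive cutoff {cfg.exhaustive_cutoff}"
        )
    guard = _trajectory_guard(len(free))

    base = [0] * cn.n
    for i, v in items:
        base[i] = v
    acc = _BasinAccumulator()
    memo: dict[State, Attractor] = {}
    for code in range(1 << len(free)):
        s = list(base)
        for bit, i in enumerate(free):
            s[i] = (code >> bit) & 1
        attractor = _resolve_attractor(cn, tuple(s), items, sig, memo, guard)
        acc.add(attractor)
    return AttractorLandscape(
        network_name=cn.net.name,
        attractors=acc.attractors,
        counts=acc.counts,
        total=1 << len(free),
        mode="exhaustive",
        seed=None,
        clamps={k: float(v) for k, v in hard_clamps.items()},
    )


def _effective_clamps(clamps: ClampProfile | Mapping[str, float],
                      cfg: AnalysisConfig) -> list[tuple[str, float]]:
    items = list(clamps.items())
    if cfg.binarize_threshold is not None:
        thr = cfg.binarize_threshold
        items = [(n, 1.0 if v >= thr else 0.0) for n, v in items]
    return items


def sampled_landscape(net: BooleanNetwork | CompiledNetwork,
                      clamps: ClampProfile | Mapping[str, float] | None,
                      cfg: AnalysisConfig) -> AttractorLandscape:
    """Monte-Carlo landscape: for each of ``cfg.samples`` initial states,
    realize probabilistic clamps (node ON with probability v, per
    trajectory), draw free-node initial values uniformly, and run the
    dynamics to its attractor.  Attractors realized under different clamp
    draws are kept distinct by clamp signature."""
    cn = net if isinstance(net, CompiledNetwork) else compile_network(net)
    clamp_items_f = _effective_clamps(clamps or {}, cfg)
    for node, _ in clamp_items_f:
        if node not in cn.index:
            raise KeyError(f"clamped node {node!r} not in network {cn.net.name!r}")
    free = [i for i in range(cn.n) if cn.net.nodes[i] not in dict(clamp_items_f)]
    guard = _trajectory_guard(len(free))
    rng = np.random.default_rng(cfg.seed)

    acc = _BasinAccumulator()
    memos: dict[tuple, dict[State, Attractor]] = {}
    n_clamped = len(clamp_items_f)
    for _ in range(cfg.samples):
        u = rng.random(n_clamped) if n_clamped else ()
        realized = [(node, 1 if u[j] < v else 0) for j, (node, v) in enumerate(clamp_items_f)]
        sig = tuple(sorted(realized))
        items = [(cn.index[node], v) for node, v in realized]
        init_bits = rng.integers(0, 2, size=len(free))
        s = [0] * cn.n
        for i, v in items:
            s[i] = v
        for bit, i in enumerate(free):
            s[i] = int(init_bits[bit])
        memo = memos.setdefault(sig, {})
        attractor = _resolve_attractor(cn, tuple(s), items, sig, memo, guard)
        acc.add(attractor)
    return AttractorLandscape(
        network_name=cn.net.name,
        attractors=acc.attractors,
        counts=acc.counts,
        total=cfg.samples,
        mode="sampled",
        seed=cfg.seed,
        clamps={n: float(v) for n, v in (clamps or {}).items()},
    )


# ---------------------------------------------------------------------------
# Bootstrap dispersion
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Per-fate propensity mean/SD/SEM across bootstrap replicates."""

    fates: list[str]
    mean: dict[str, float]
    sd: dict[str, float]
    sem: dict[str, float]
    replicates: int
    samples_per_replicate: int
    seed: int | None
    replicate_table: list[dict[str, float]] = field(default_factory=list)


def spawn_seeds(master_seed: int | None, count: int) -> list[int]:
    """Derive ``count`` independent integer seeds (< 2**31) from a master."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(count)]


def bootstrap_propensities(net: BooleanNetwork | CompiledNetwork,
                           clamps: ClampProfile | Mapping[str, float] | None,
                           classification,
                           cfg: AnalysisConfig,
                           threshold: float = 0.5) -> BootstrapResult:
    """Replicate the sampled landscape + fate classification ``cfg.replicates``
    times on independent seed streams; SEM = SD / sqrt(replicates)."""
    from .fates import fate_propensities  # local import to avoid a cycle

    if cfg.replicates < 2:
        raise ValueError("replicates must be >= 2")
    cn = net if isinstance(net, CompiledNetwork) else compile_network(net)
    seeds = spawn_seeds(cfg.seed, cfg.replicates)
    fates = classification.fate_names
    table: list[dict[str, float]] = []
    for s in seeds:
        land = sampled_landscape(cn, clamps, replace(cfg, seed=s))
        profile = fate_propensities(land, classification, threshold=threshold,
                                    node_order=cn.net.nodes)
        table.append(dict(profile.propensities))
    mean = {f: float(np.mean([row[f] for row in table])) for f in fates}
    sd = {f: float(np.std([row[f] for row in table], ddof=1)) for f in fates}
    sem = {f: sd[f] / np.sqrt(cfg.replicates) for f in fates}
    return BootstrapResult(
        fates=fates,
        mean=mean,
        sd=sd,
        sem=sem,
        replicates=cfg.replicates,
        samples_per_replicate=cfg.samples,
        seed=cfg.seed,
        replicate_table=table,
    )
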