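"""Synchronous dynamics, attractor detection and basin estimation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flydpm.engine import (
    AnalysisConfig,
    bootstrap_propensities,
    compile_network,
    exhaustive_landscape,
    find_attractor,
    sampled_landscape,
    step,
)
from flydpm.netio import parse_fate_classification, parse_network
from flydpm.synthdata import GeneratorSpec, generate_random_network


# --- step ------------------------------------------------------------------

def test_step_swap_pair():
    net = parse_network("A = B\nB = A\n")
    assert step(net, (0, 1)) == (1, 0)


def test_step_respects_clamps():
    net = parse_network("A = NOT B\nB = A\n")
    # B' reads the pre-state A; A is pinned at 1 before and after the update
    assert step(net, (0, 0), {"A": 1}) == (1, 1)
    assert step(net, (0, 1), {"A": 1}) == (1, 1)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000), st.integers(0, 2**10 - 1))
def test_step_agrees_with_per_node_truth_table(seed, code):
    """Independent oracle: evaluate each node's rule on a dict assignment."""
    from flydpm.netio import evaluate_expression

    net = generate_random_network(GeneratorSpec(seed=seed, n=10))
    state = tuple((code >> i) & 1 for i in range(10))
    assignment = dict(zip(net.nodes, state))
    expected = tuple(
        evaluate_expression(net.rules[n], assignment) if n in net.rules else assignment[n]
        for n in net.nodes
    )
    assert step(net, state) == expected


# --- find_attractor --------------------------------------------------------

def test_negation_gives_period_two_cycle():
    net = parse_network("B = NOT B\n")
    attr = find_attractor(net, (0,))
    assert attr.period == 2
    assert set(attr.states) == {(0,), (1,)}
    assert attr.states[0] == (0,)  # canonical rotation


def test_swap_pair_trajectories():
    net = parse_network("A = B\nB = A\n")
    cyc = find_attractor(net, (0, 1))
    assert cyc.states == ((0, 1), (1, 0))
    fp = find_attractor(net, (1, 1))
    assert fp.is_fixed_point and fp.states == ((1, 1),)


def test_clamped_negation_reaches_clamped_fixed_point():
    net = parse_network("A = NOT B\nB = A\n")
    for b in (0, 1):
        attr = find_attractor(net, (1, b), {"A": 1})
        assert attr.states == ((1, 1),)


def test_attractor_closure_under_step(oracle_catalog):
    for fx in oracle_catalog:
        cn = compile_network(fx.network)
        for attr in fx.landscape.attractors:
            for k, s in enumerate(attr.states):
                nxt = step(cn, s, fx.hard_clamps)
                assert nxt == attr.states[(k + 1) % attr.period]


# --- exhaustive landscape --------------------------------------------------

def test_exhaustive_swap_pair_basins():
    net = parse_network("A = B\nB = A\n")
    land = exhaustive_landscape(net)
    by_period = {}
    for a, c in zip(land.attractors, land.counts):
        by_period.setdefault(a.period, []).append(c)
    assert sorted(by_period[1]) == [1, 1]  # two fixed points, basin 1/4 each
    assert by_period[2] == [2]             # the swap cycle, basin 1/2
    assert land.total == 4
    assert sum(land.counts) == land.total


def test_all_clamped_single_fixed_point(isc_net):
    hard = {n: 1 for n in isc_net.nodes}
    land = exhaustive_landscape(isc_net, hard)
    assert len(land.attractors) == 1
    assert land.counts == [1] and land.total == 1


def test_exhaustive_ratios_sum_exactly_to_one():
    net = generate_random_network(GeneratorSpec(seed=42, n=12))
    land = exhaustive_landscape(net)
    assert sum(land.counts) == land.total == 2**12


def test_exhaustive_cutoff_enforced():
    net = generate_random_network(GeneratorSpec(seed=1, n=12))
    with pytest.raises(ValueError, match="cutoff"):
        exhaustive_landscape(net, cfg=AnalysisConfig(exhaustive_cutoff=8))


# --- sampled landscape -----------------------------------------------------

def test_sampled_matches_exhaustive_within_3se(oracle_catalog):
    n_samples = 50_000
    for fx in oracle_catalog:
        cn = compile_network(fx.network)
        clamps = {n: float(v) for n, v in fx.hard_clamps.items()}
        samp = sampled_landscape(cn, clamps, AnalysisConfig(samples=n_samples, seed=2024))
        for a, c in zip(fx.landscape.attractors, fx.landscape.counts):
            p = c / fx.landscape.total
            phat = samp.ratio_of(a)
            se = math.sqrt(p * (1 - p) / n_samples)
            assert abs(phat - p) <= max(3 * se, 1e-12), (fx.name, p, phat)


def test_bernoulli_clamp_closed_form():
    net = parse_network("INPUT: I\nX = I\n")
    n = 50_000
    land = sampled_landscape(net, {"I": 0.3}, AnalysisConfig(samples=n, seed=17))
    on = sum(c for a, c in zip(land.attractors, land.counts) if a.states[0][1] == 1)
    se = math.sqrt(0.3 * 0.7 / n)
    assert abs(on / n - 0.3) <= 3 * se


def test_hard_clamp_equals_bernoulli_extreme():
    net = parse_network("A = NOT B\nB = A\n")
    cfg = AnalysisConfig(samples=500, seed=3)
    bern = sampled_landscape(net, {"A": 1.0}, cfg)
    hard = sampled_landscape(net, {"A": 1}, cfg)
    assert bern.counts == hard.counts
    assert [a.key() for a in bern.attractors] == [a.key() for a in hard.attractors]


def test_seed_determinism_bit_identical(isc_compiled, isc_normal_clamps):
    cfg = AnalysisConfig(samples=2_000, seed=99)
    a = sampled_landscape(isc_compiled, isc_normal_clamps, cfg)
    b = sampled_landscape(isc_compiled, isc_normal_clamps, cfg)
    assert a.counts == b.counts
    assert [x.key() for x in a.attractors] == [x.key() for x in b.attractors]


def test_sampled_ratios_sum_to_one():
    net = generate_random_network(GeneratorSpec(seed=8, n=10))
    land = sampled_landscape(net, None, AnalysisConfig(samples=3_000, seed=5))
    assert sum(land.counts) == land.total == 3_000


def test_attractors_respect_realized_clamps():
    net = parse_network("INPUT: I\nX = I AND NOT Y\nY = X\n")
    land = sampled_landscape(net, {"I": 0.5}, AnalysisConfig(samples=2_000, seed=1))
    i_pos = net.nodes.index("I")
    for attr in land.attractors:
        sig = dict(attr.clamp_signature)
        for s in attr.states:
            assert s[i_pos] == sig["I"]


# --- bootstrap -------------------------------------------------------------

def test_bootstrap_zero_variance_when_fully_clamped():
    net = parse_network("A = B\nB = A\n")
    fc = parse_fate_classification("alive\tA=1\n")
    cfg = AnalysisConfig(samples=200, replicates=5, seed=4)
    res = bootstrap_propensities(net, {"A": 1.0, "B": 1.0}, fc, cfg)
    assert res.mean["alive"] == 1.0
    assert res.sd["alive"] == 0.0 and res.sem["alive"] == 0.0


def test_bootstrap_sem_scales_inverse_sqrt_replicates():
    net = parse_network("INPUT: I\nX = I\n")
    fc = parse_fate_classification("on\tX=1\n")
    r1, r2 = 8, 32
    res1 = bootstrap_propensities(net, {"I": 0.5}, fc, AnalysisConfig(samples=400, replicates=r1, seed=6))
    res2 = bootstrap_propensities(net, {"I": 0.5}, fc, AnalysisConfig(samples=400, replicates=r2, seed=6))
    # SD estimates the same sampling noise; SEM carries the 1/sqrt(B) factor
    ratio = res1.sem["on"] / res2.sem["on"]
    assert 1.2 <= ratio <= 3.5  # expect ~2, wide band for SD estimation noise


def test_bootstrap_mean_tracks_exhaustive_propensity():
    net = parse_network("A = B\nB = A\n")
    fc = parse_fate_classification("dead\tA=0,B=0\nalive\tA=1,B=1\n")
    cfg = AnalysisConfig(samples=2_000, replicates=10, seed=12)
    res = bootstrap_propensities(net, None, fc, cfg)
    # exhaustive partition: fp(0,0) 1/4 -> dead; fp(1,1) 1/4 and the swap
    # cycle 1/2 both binarize to (1,1) -> alive 3/4
    for fate, p in [("dead", 0.25), ("alive", 0.75), ("uncharacterized", 0.0)]:
        se = math.sqrt(p * (1 - p) / 2_000)
        assert abs(res.mean[fate] - p) <= 3 * se + 3 * res.sem[fate]
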