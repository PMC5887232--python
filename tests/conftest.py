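"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive - full enumeration over partial
assignments, completions and state spaces - so they are independent of the
code paths they check.
"""

from __future__ import annotations

import itertools

import pytest

import pckernel as pk
from pckernel.model import PartialAssignment


@pytest.fixture(scope="session")
def example_net():
    return pk.example_network()

@pytest.fixture(scope="session")
def pheno_p0():
    return pk.PhenotypeSpec(("P",), (0,))


def signaling_net(seed: int, family: str = "nested", n_nodes: int = 8,
                  **overrides) -> pk.BooleanNetwork:
    """A random signaling-style network under the package's default study
    conditions (sink phenotype, no self-loops, in-degree 1-3)."""
    cfg = pk.GeneratorConfig(n_nodes=n_nodes, rule_family=family, seed=seed,
                             **overrides)
    return pk.random_network(cfg)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def rule_truth_table(rule) -> tuple[tuple[str, ...], list[int]]:
    inputs = rule.inputs
    table = []
    for bits in range(1 << len(inputs)):
        env = {x: (bits >> j) & 1 for j, x in enumerate(inputs)}
        table.append(rule.evaluate(env))
    return inputs, table


def brute_forcing_solutions(rule, value: int) -> list[PartialAssignment]:
    """All minimal forcing partial assignments by explicit enumeration:
    every subset of inputs x every value combination, checked against every
    completion, then filtered for subset-minimality."""
    inputs, table = rule_truth_table(rule)
    forcing: list[PartialAssignment] = []
    for r in range(len(inputs) + 1):
        for subset in itertools.combinations(range(len(inputs)), r):
            for vals in itertools.product((0, 1), repeat=r):
                fixed = dict(zip(subset, vals))
                ok = True
                for bits in range(1 << len(inputs)):
                    if all((bits >> j) & 1 == v for j, v in fixed.items()):
                        if table[bits] != value:
                            ok = False
                            break
                if ok:
                    forcing.append(
                        PartialAssignment({inputs[j]: v for j, v in fixed.items()})
                    )
    minimal = [a for a in forcing
               if not any(b != a and b.issubset(a) for b in forcing)]
    return sorted(set(minimal))


def stg_attractors(net) -> set[frozenset[int]]:
    """Attractor cycles read off the full state-transition graph with
    networkx (attracting components of a functional graph)."""
    import networkx as nx

    g = nx.DiGraph()
    for s in net.enumerate_states():
        g.add_edge(s, net.step_int(s))
    return {frozenset(comp) for comp in nx.attracting_components(g)}
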