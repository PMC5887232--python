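"""Forcing solutions of Boolean equations.

For one equation ``n = f(x_1..x_a)`` a *forcing solution* (the per-node
"signal" feeding the converging tree) is a minimal partial assignment of the
rule's direct inputs under which f evaluates to n for every completion of
the unassigned inputs - i.e. a prime implicant of the indicator function
[f = n].  Prime implicants are computed by Quine-McCluskey cube merging
over the rule's truth table, which yields ALL of them (not just a minimal
cover) and is exact at the in-degrees biological rule sets exhibit.

For a system of equations (a multi-node control set whose every node must
hold its value), solutions are Cartesian products of per-equation solution
sets merged by union, dropping internally conflicting tuples and keeping the
subset-minimal survivors.  A node's own clamp ``{K = n}`` also satisfies its
equation - clamping K holds the value directly - so per-equation collections
can optionally carry that *self-clamp*; the converging tree uses this for
the root and for multi-node parents (without it, sets that force a sibling
node of the parent through the dynamics would be missed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .model import (
    BooleanNetwork,
    MAX_RULE_INPUTS,
    ModelError,
    PartialAssignment,
    Rule,
)

__all__ = ["ForcingSolutionSet", "forcing_solutions", "system_solutions", "minimal_elements"]


@dataclass(frozen=True)
class ForcingSolutionSet:
    """All minimal input assignments forcing one rule to a target value.

    ``solutions`` is complete, pairwise non-included, and sorted
    (by size, then node names and values) so downstream trees are
    reproducible byte-for-byte.  ``unsatisfiable`` marks rules that can
    never attain the target value (the empty solution list is then legal).
    """

    target: str
    value: int
    solutions: tuple[PartialAssignment, ...]

    @property
    def unsatisfiable(self) -> bool:
        return not self.solutions


def _truth_table(rule: Rule) -> tuple[tuple[str, ...], list[int]]:
    inputs = rule.inputs
    if len(inputs) > MAX_RULE_INPUTS:
        raise ModelError(
            f"rule for {rule.target!r} has {len(inputs)} inputs, above the "
            f"enumeration bound {MAX_RULE_INPUTS}"
        )
    table = []
    for bits in range(1 << len(inputs)):
        env = {x: (bits >> j) & 1 for j, x in enumerate(inputs)}
        table.append(rule.evaluate(env))
    return inputs, table


def _prime_implicants(minterms: Sequence[int], width: int) -> list[tuple[Optional[int], ...]]:
    """Quine-McCluskey: all prime implicants of the on-set ``minterms``.

    Cubes are tuples of 0/1/None over ``width`` positions; two cubes merge
    when they differ in exactly one cared position.  Cubes never merged into
    a larger one are prime.
    """
    if not minterms:
        return []
    cubes = {tuple((m >> j) & 1 for j in range(width)) for m in minterms}
    primes: set[tuple[Optional[int], ...]] = set()
    while cubes:
        merged_from: set[tuple[Optional[int], ...]] = set()
        next_cubes: set[tuple[Optional[int], ...]] = set()
        cube_list = sorted(cubes, key=lambda c: tuple(-1 if x is None else x for x in c))
        for a, b in itertools.combinations(cube_list, 2):
            diff = -1
            for j in range(width):
                if a[j] != b[j]:
                    if a[j] is None or b[j] is None or diff >= 0:
                        diff = -2
                        break
                    diff = j
            if diff >= 0:
                merged = tuple(None if j == diff else a[j] for j in range(width))
                next_cubes.add(merged)
                merged_from.add(a)
                merged_from.add(b)
        primes.update(c for c in cubes if c not in merged_from)
        cubes = next_cubes
    return sorted(primes, key=lambda c: tuple((-1 if x is None else x) for x in c))


def forcing_solutions(rule: Rule, value: int) -> ForcingSolutionSet:
    """All minimal partial input assignments forcing ``rule`` to ``value``.

    Threshold rules are expanded to truth tables over their inputs first.
    A rule constantly equal to ``value`` is forced by the empty assignment;
    a rule never equal to it yields an empty, ``unsatisfiable`` set.
    """
    if value not in (0, 1):
        raise ModelError(f"target value must be 0 or 1, got {value!r}")
    inputs, table = _truth_table(rule)
    minterms = [m for m, out in enumerate(table) if out == value]
    sols = []
    for cube in _prime_implicants(minterms, len(inputs)):
        sols.append(
            PartialAssignment({inputs[j]: b for j, b in enumerate(cube) if b is not None})
        )
    return ForcingSolutionSet(rule.target, value, tuple(sorted(sols)))


def minimal_elements(assignments: Iterable[PartialAssignment]) -> list[PartialAssignment]:
    """Deduplicate and drop every assignment that properly includes another
    (i.e. keep the subset-minimal elements), in deterministic sorted order."""
    unique = sorted(set(assignments))
    kept: list[PartialAssignment] = []
    for a in unique:
        if not any(b.issubset(a) for b in kept if b != a):
            kept.append(a)
    return kept


def system_solutions(
    parent: Union[PartialAssignment, dict],
    net: BooleanNetwork,
    include_self_clamps: bool = True,
    exclude_nodes: Iterable[str] = (),
) -> list[PartialAssignment]:
    """Candidate children of a control set: minimal solutions of the system
    of Boolean equations ``value_K = f_K(inputs)`` over the parent's nodes.

    Per-equation solution sets are the forcing solutions of each rule, plus
    (when ``include_self_clamps``) the node's own clamp.  The sets are
    combined by Cartesian product and union-merge; tuples assigning some
    node both values are dropped, and only subset-minimal merged results are
    kept.  Wholly empty merges (every equation already constant at its
    target value) are discarded - such a parent needs no perturbation.

    Nodes in ``exclude_nodes`` are barred from appearing in any solution
    (the tree passes the parent's own node here for non-root singleton
    parents).  If any parent node has no rule (an input node) or is clamped,
    there are no children: the parent is a leaf.
    """
    parent = PartialAssignment(parent)
    exclude = set(exclude_nodes)
    per_equation: list[list[PartialAssignment]] = []
    for node, value in parent.items():
        if node in net.clamps or node not in net.rules:
            return []
        fss = forcing_solutions(net.rules[node], value)
        options = [s for s in fss.solutions if not any(n in exclude for n in s)]
        self_ok = include_self_clamps and node not in exclude
        if self_ok:
            options.append(PartialAssignment({node: value}))
        if not options:
            return []
        per_equation.append(minimal_elements(options))

    merged: list[PartialAssignment] = []
    for combo in itertools.product(*per_equation):
        out = combo[0]
        ok = True
        for nxt in combo[1:]:
            if out.conflicts(nxt) is not None:
                ok = False
                break
            out = out.union(nxt)
        if ok and len(out) > 0:
            merged.append(out)
    return minimal_elements(merged)
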