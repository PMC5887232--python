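"""Ground-truth verification of any-to-multiple phenotype control.

A control set passes when, with its nodes clamped, *every* initial state
reaches an attractor whose every state carries the desired phenotype values
(the strict reading of a steady phenotype: an attractor in which a
phenotype node oscillates does not count).  Exhaustive mode enumerates the
full state space, so it is exact and is the oracle the converging tree is
checked against; sampled mode follows seeded random initial states and is
what scales to large models.

``brute_force_kernel`` enumerates every small clamp combination directly,
giving an independent ground truth for the kernel property: every minimal
forcing assignment found by brute force should contain a PCK member.
Phenotype nodes themselves are not admitted as clamp candidates - clamping
the phenotype node trivially "forces" its own value and is not a control
strategy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Union

from .model import (
    Attractor,
    BooleanNetwork,
    ModelError,
    PartialAssignment,
    _trace_attractors,
    apply_control,
)
from .tree import PhenotypeSpec

__all__ = [
    "VerificationReport",
    "verify_control_set",
    "verify_minimality",
    "brute_force_kernel",
    "forces_by_substitution",
]


def forces_by_substitution(
    net: BooleanNetwork,
    control: Union[PartialAssignment, Mapping[str, int]],
    pheno: PhenotypeSpec,
) -> bool:
    """Does clamping ``control`` pin the phenotype values by substitution?

    Iteratively fixes every node whose rule is *semantically* constant given
    the values fixed so far (its truth table restricted to the known inputs
    is constant), until nothing more becomes constant.  This is exactly the
    guarantee a converging-tree control set provides: each level's values
    force the next level's rules for every completion, so the phenotype is
    reached regardless of the initial state and of timing.  It is a
    sufficient condition for dynamic forcing; the converse fails when
    convergence relies on reachability (which states actually occur), not
    on the rules alone.
    """
    control = PartialAssignment(control)
    known: dict[str, int] = dict(net.clamps)
    known.update(control)
    pending = {n: net.rules[n] for n in net.nodes if n not in known and n in net.rules}
    changed = True
    while changed:
        changed = False
        for name in sorted(pending):
            rule = pending[name]
            inputs = rule.inputs
            free = [x for x in inputs if x not in known]
            outs = set()
            for bits in range(1 << len(free)):
                env = dict(known)
                for j, x in enumerate(free):
                    env[x] = (bits >> j) & 1
                outs.add(rule.evaluate(env))
                if len(outs) > 1:
                    break
            if len(outs) == 1:
                known[name] = outs.pop()
                del pending[name]
                changed = True
    return all(known.get(n) == v for n, v in zip(pheno.nodes, pheno.values))


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of verifying one control set.

    ``holds`` is True iff every examined attractor satisfies all phenotype
    values in every cycle state.  On failure, ``counterexample`` gives an
    initial state (node -> value), the reached attractor and one violated
    phenotype node.
    """

    control: PartialAssignment
    mode: str
    holds: bool
    attractors_after: tuple[Attractor, ...]
    counterexample: Optional[dict] = None
    n_init: Optional[int] = None
    seed: Optional[int] = None

    def to_json_obj(self, net: BooleanNetwork) -> dict:
        obj = {
            "control": dict(self.control.items()),
            "mode": self.mode,
            "holds": self.holds,
            "n_attractors": len(self.attractors_after),
            "attractors": [a.as_dicts(net) for a in self.attractors_after],
        }
        if self.mode == "sampled":
            obj["n_init"] = self.n_init
            obj["seed"] = self.seed
        if self.counterexample is not None:
            obj["counterexample"] = self.counterexample
        return obj


def _initial_states(net: BooleanNetwork, mode: str, n_init: int, seed: int):
    import random as _random

    if mode == "exhaustive":
        return net.enumerate_states()
    if mode == "sampled":
        rng = _random.Random(seed)
        free = [net.index[n] for n in net.free_nodes]
        base = net.force_clamps(0)
        out = []
        for _ in range(n_init):
            s = base
            for i in free:
                if rng.random() < 0.5:
                    s |= 1 << i
            out.append(s)
        return out
    raise ModelError(f"unknown verification mode {mode!r}")


def verify_control_set(
    net: BooleanNetwork,
    control: Union[PartialAssignment, Mapping[str, int]],
    pheno: PhenotypeSpec,
    mode: str = "exhaustive",
    n_init: int = 1000,
    seed: int = 0,
    node_bound: int = 22,
) -> VerificationReport:
    """Clamp ``control`` and check that all reached attractors carry the
    desired phenotype values in every cycle state."""
    control = PartialAssignment(control)
    controlled = apply_control(net, control)
    if mode == "exhaustive" and len(controlled.free_nodes) > node_bound:
        raise ModelError(
            f"exhaustive verification refused: {len(controlled.free_nodes)} free "
            f"nodes exceeds the bound of {node_bound}"
        )
    target = pheno.as_assignment()
    attractors, basin = _trace_attractors(
        controlled, _initial_states(controlled, mode, n_init, seed)
    )
    counterexample = None
    holds = True
    for idx, att in enumerate(attractors):
        if not att.satisfies(controlled, target):
            holds = False
            bad_node = next(
                n
                for n in pheno.nodes
                for s in att.states
                if (s >> controlled.index[n]) & 1 != target[n]
            )
            init = next(s for s, i in basin.items() if i == idx)
            counterexample = {
                "initial_state": controlled.unpack_state(init),
                "attractor": att.as_dicts(controlled),
                "violated_node": bad_node,
            }
            break
    ordered = tuple(sorted(attractors, key=lambda a: a.states))
    return VerificationReport(
        control=control,
        mode=mode,
        holds=holds,
        attractors_after=ordered,
        counterexample=counterexample,
        n_init=n_init if mode == "sampled" else None,
        seed=seed if mode == "sampled" else None,
    )


def verify_minimality(
    net: BooleanNetwork,
    control: Union[PartialAssignment, Mapping[str, int]],
    pheno: PhenotypeSpec,
    mode: str = "exhaustive",
    **kwargs,
) -> tuple[bool, Optional[PartialAssignment]]:
    """True iff no proper subset of ``control`` (the empty set included)
    already passes verification; otherwise returns the passing subset."""
    control = PartialAssignment(control)
    items = control.items_sorted
    for r in range(len(items)):
        for sub in itertools.combinations(items, r):
            candidate = PartialAssignment(dict(sub))
            if verify_control_set(net, candidate, pheno, mode=mode, **kwargs).holds:
                return False, candidate
    return True, None


def brute_force_kernel(
    net: BooleanNetwork,
    pheno: PhenotypeSpec,
    max_size: int = 3,
    node_bound: int = 12,
) -> list[PartialAssignment]:
    """All subset-minimal forcing assignments of up to ``max_size`` nodes.

    Exhaustive search over every clamp combination of non-phenotype nodes,
    filtered by exhaustive verification; supersets of a passing set are
    skipped, so the result is exactly the minimal forcing sets.  An empty
    result with the empty set passing means the network already converges to
    the phenotype without control.
    """
    if len(net.free_nodes) > node_bound:
        raise ModelError(
            f"brute-force kernel refused: {len(net.free_nodes)} free nodes "
            f"exceeds the bound of {node_bound}"
        )
    candidates = [n for n in net.free_nodes if n not in pheno.nodes]
    if verify_control_set(net, {}, pheno, mode="exhaustive").holds:
        return []
    found: list[PartialAssignment] = []
    for size in range(1, max_size + 1):
        for names in itertools.combinations(candidates, size):
            for values in itertools.product((0, 1), repeat=size):
                a = PartialAssignment(dict(zip(names, values)))
                if any(f.issubset(a) for f in found):
                    continue  # proper superset of a known forcing set
                if verify_control_set(net, a, pheno, mode="exhaustive").holds:
                    found.append(a)
    return sorted(found)
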