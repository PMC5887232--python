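"""Constant propagation through Boolean update rules.

Fixing input values and mutations (clamps) typically forces a cascade of
other nodes to constant values: an AND with a 0 regulator is 0, an OR with a
1 regulator is 1, a threshold sum whose fixed part already dominates the
remaining weights has a decided sign.  Substituting those constants back into
the rules until nothing more becomes constant splits the network into a
fixed-value map and a smaller network over the remaining nodes with reduced
rules.  Synchronous attractors are preserved by this reduction (checked
empirically in the test suite at desk scale): a forced-constant node holds
its value in every attractor, so projecting attractors of the clamped
original onto the surviving nodes reproduces the attractors of the
simplified network.

Only algebraic constant folding is performed - non-constant rules are not
minimized - because downstream forcing-solution computation does not depend
on syntactic minimality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

from .model import (
    Ast,
    BooleanNetwork,
    LogicRule,
    ModelError,
    PartialAssignment,
    ThresholdRule,
)

__all__ = ["SimplificationResult", "ContradictionError", "propagate_constants", "simplify_ast"]


class ContradictionError(ModelError):
    """A supplied value conflicts with a value derived from the rules.

    ``chain`` lists (node, value, origin) steps leading to the contradiction,
    so self-inconsistent models abort with a diagnostic instead of silently
    preferring one side.
    """

    def __init__(self, message: str, chain: list[tuple[str, int, str]]):
        super().__init__(message)
        self.chain = chain


@dataclass(frozen=True)
class SimplificationResult:
    """Outcome of constant propagation.

    ``fixed_values`` covers every node forced constant (the supplied values
    included); ``simplified`` is the network over the remaining nodes, whose
    rules no longer reference any fixed node.  The two node sets are disjoint
    and jointly cover the original network.
    """

    fixed_values: PartialAssignment
    simplified: BooleanNetwork


def simplify_ast(ast: Ast, env: Mapping[str, int]) -> Ast:
    """Fold constants of ``env`` into an expression.

    AND short-circuits on 0, OR on 1, NOT of a constant flips it; single-arm
    AND/OR collapse.  The result is either ``("const", v)`` or an expression
    free of every variable in ``env``.
    """
    tag = ast[0]
    if tag == "const":
        return ast
    if tag == "var":
        name = ast[1]
        return ("const", env[name]) if name in env else ast
    if tag == "not":
        sub = simplify_ast(ast[1], env)
        if sub[0] == "const":
            return ("const", 1 - sub[1])
        return ("not", sub)
    if tag in ("and", "or"):
        absorber = 0 if tag == "and" else 1
        parts = []
        for s in ast[1]:
            ss = simplify_ast(s, env)
            if ss[0] == "const":
                if ss[1] == absorber:
                    return ("const", absorber)
                continue  # neutral element, drop
            parts.append(ss)
        if not parts:
            return ("const", 1 - absorber)
        if len(parts) == 1:
            return parts[0]
        return (tag, tuple(parts))
    raise ModelError(f"bad AST tag {tag!r}")


def _fold_threshold(rule: ThresholdRule, env: Mapping[str, int]) -> Union[ThresholdRule, int]:
    """Fold known regulator values into the bias; return an int when the sign
    of the weighted sum is decided for every completion of the free inputs."""
    bias = rule.bias
    remaining: list[tuple[str, int]] = []
    for src, w in rule.weighted_inputs:
        if src in env:
            bias += w * env[src]
        else:
            remaining.append((src, w))
    reach = sum(max(w, 0) for _, w in remaining)  # max attainable sum above bias
    drop = sum(min(w, 0) for _, w in remaining)
    if bias + drop > 0:
        return 1
    if bias + reach < 0:
        return 0
    if not remaining:
        # sum is exactly `bias` <= 0 here; a zero is decided by the tie policy
        if bias < 0 or rule.tie_policy == "zero":
            return 0 if bias <= 0 else 1
        # retain tie with no live regulators: the node holds its own value
        return ThresholdRule(rule.target, (), tie_policy="retain", bias=0)
    if bias + reach == 0 and rule.tie_policy == "zero" and bias + drop < 0:
        # even the best case only reaches zero, which the policy maps to 0
        return 0
    return ThresholdRule(rule.target, tuple(remaining), tie_policy=rule.tie_policy, bias=bias)


def propagate_constants(
    net: BooleanNetwork,
    given: Union[PartialAssignment, Mapping[str, int]],
    order: Optional[Sequence[str]] = None,
    check_consistency: bool = False,
) -> SimplificationResult:
    """Propagate ``given`` (inputs/mutations) to a fixpoint.

    Iteratively substitutes every known constant into the remaining rules;
    a rule that collapses to a constant fixes its target, which is then
    substituted in turn, until no rule changes.  The result is independent of
    the substitution order (``order`` only controls the scan order and exists
    so the confluence property can be exercised directly).

    Supplied values *override* their nodes' own rules - that is how a
    sustained mutation is modelled, so by default no comparison against the
    overridden rule is made.  With ``check_consistency`` the overridden
    rules are folded too, and a supplied value contradicted by its own
    rule's derived constant raises :class:`ContradictionError` with the
    derivation chain (use this when the supplied values are meant to be
    steady states of the intact rules rather than interventions).  A value
    conflicting with an existing clamp always raises.
    """
    given = PartialAssignment(given)
    for n in given:
        if n not in net.nodes:
            raise ModelError(f"given value for unknown node {n!r}")
    clash = given.conflicts(net.clamps)
    if clash is not None:
        raise ContradictionError(
            f"given value for {clash!r} conflicts with an existing clamp",
            [(clash, given[clash], "given"), (clash, net.clamps[clash], "clamp")],
        )

    known: dict[str, int] = dict(net.clamps)
    known.update(given)
    chain: list[tuple[str, int, str]] = [(n, v, "given") for n, v in sorted(known.items())]
    pinned = set(known)  # externally supplied; a rule may not override these

    current: dict[str, object] = {
        n: r for n, r in net.rules.items() if n not in known
    }
    scan = [n for n in (order or net.nodes) if n in current]
    scan += [n for n in net.nodes if n in current and n not in scan]

    changed = True
    while changed:
        changed = False
        for name in list(scan):
            rule = current.get(name)
            if rule is None:
                continue
            if isinstance(rule, LogicRule):
                folded = simplify_ast(rule.expression, known)
                if folded[0] == "const":
                    value: Union[int, None] = folded[1]
                    new_rule: object = None
                else:
                    value = None
                    new_rule = LogicRule(name, folded)
            else:
                result = _fold_threshold(rule, known)
                if isinstance(result, int):
                    value, new_rule = result, None
                else:
                    value, new_rule = None, result
            if value is not None:
                known[name] = value
                chain.append((name, value, f"rule of {name}"))
                del current[name]
                changed = True
            else:
                current[name] = new_rule

    if check_consistency:
        for name in sorted(pinned):
            rule = net.rules.get(name)
            if rule is None:
                continue
            if isinstance(rule, LogicRule):
                folded = simplify_ast(rule.expression, known)
                derived = folded[1] if folded[0] == "const" else None
            else:
                result = _fold_threshold(rule, known)
                derived = result if isinstance(result, int) else None
            if derived is not None and derived != known[name]:
                chain.append((name, derived, f"rule of {name}"))
                raise ContradictionError(
                    f"node {name!r} is supplied as {known[name]} but its rule "
                    f"derives the constant {derived}",
                    chain,
                )

    fixed = PartialAssignment(known)
    remaining_nodes = [n for n in net.nodes if n not in known]
    rules = [current[n] for n in remaining_nodes if n in current]
    simplified = BooleanNetwork(remaining_nodes, rules)  # type: ignore[arg-type]
    return SimplificationResult(fixed_values=fixed, simplified=simplified)
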