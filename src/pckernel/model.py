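"""Boolean network models with logic or threshold update rules.

A :class:`BooleanNetwork` is the single source of truth for the dynamics:
named nodes, one update rule per non-input node, and an optional set of
*clamps* (nodes whose value is permanently overridden by an external input,
the standard way of modelling a sustained intervention or mutation).

Update semantics are synchronous and deterministic: at every tick each
unclamped node with a rule evaluates it on the current state, clamped nodes
keep their clamp value, and rule-less *input* nodes hold whatever value the
state assigns them (equivalently, they carry an implicit self-loop).
An attractor is a set of states closed under this map - a fixed point or a
cycle - and cell phenotypes are read off attractor states.

Logic rules are plain Boolean expressions over regulator names written with
``&``, ``|``, ``!`` and parentheses (the common BoolNet-style dialect, one
``Target, expression`` or ``Target* = expression`` line per rule).  Threshold
rules compute the sign of a signed weighted sum of regulator values: the node
switches on when the sum is positive, off when negative, and a configurable
tie policy decides an exact zero (``zero``: switch off; ``retain``: keep the
current value).
"""

from __future__ import annotations

import random as _random
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

__all__ = [
    "ParseError",
    "ModelError",
    "PartialAssignment",
    "LogicRule",
    "ThresholdRule",
    "BooleanNetwork",
    "Attractor",
    "parse_logic_model",
    "parse_threshold_model",
    "serialize_logic_model",
    "serialize_threshold_model",
    "synchronous_step",
    "find_attractors",
    "apply_control",
]

NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_/.+-]*")

#: refuse exhaustive state-space enumeration above this many free nodes
EXHAUSTIVE_NODE_BOUND = 22
#: refuse truth-table expansion of a single rule above this in-degree
MAX_RULE_INPUTS = 16


class ParseError(ValueError):
    """A model file could not be parsed; carries the offending line number."""


class ModelError(ValueError):
    """A structurally invalid model or an invalid operation on one."""


# ---------------------------------------------------------------------------
# Partial assignments
# ---------------------------------------------------------------------------


class PartialAssignment(Mapping[str, int]):
    """An immutable, hashable map ``node -> {0, 1}``.

    This is the currency of the whole method: phenotype specifications,
    clamps, per-equation forcing solutions and control sets are all partial
    assignments.  Supports the subset ("includes"), conflict and union tests
    the removal rules are built on.
    """

    __slots__ = ("_items", "_dict")

    def __init__(self, items: Union[Mapping[str, int], Iterable[tuple[str, int]]] = ()):
        d = dict(items)
        for k, v in d.items():
            if v not in (0, 1):
                raise ModelError(f"assignment value for {k!r} must be 0 or 1, got {v!r}")
        self._dict = d
        self._items = tuple(sorted(d.items()))

    def __getitem__(self, key: str) -> int:
        return self._dict[key]

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._dict))

    def __len__(self) -> int:
        return len(self._dict)

    def __hash__(self) -> int:
        return hash(self._items)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, PartialAssignment):
            return self._items == other._items
        if isinstance(other, Mapping):
            return self._dict == dict(other)
        return NotImplemented

    def __lt__(self, other: "PartialAssignment") -> bool:
        # deterministic ordering: by size, then sorted (node, value) items
        return (len(self._items), self._items) < (len(other._items), other._items)

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v}" for k, v in self._items)
        return "{" + body + "}"

    @property
    def items_sorted(self) -> tuple[tuple[str, int], ...]:
        return self._items

    def issubset(self, other: "PartialAssignment") -> bool:
        """True iff every (node, value) pair of self appears in other."""
        od = other._dict
        return all(od.get(k) == v for k, v in self._items)

    def conflicts(self, other: "PartialAssignment") -> Optional[str]:
        """Name of a node assigned opposite values in self and other, or None."""
        od = other._dict
        for k, v in self._items:
            if k in od and od[k] != v:
                return k
        return None

    def union(self, other: "PartialAssignment") -> "PartialAssignment":
        """Merge two consistent assignments; raises ModelError on conflict."""
        clash = self.conflicts(other)
        if clash is not None:
            raise ModelError(f"conflicting values for node {clash!r}")
        merged = dict(self._dict)
        merged.update(other._dict)
        return PartialAssignment(merged)


# ---------------------------------------------------------------------------
# Logic expressions (AST + parser + serializer)
# ---------------------------------------------------------------------------

# AST nodes are plain tuples:
#   ("const", 0|1)  ("var", name)  ("not", sub)  ("and", (subs...))  ("or", (subs...))

Ast = tuple


def ast_variables(ast: Ast) -> list[str]:
    """Variables of an expression, in first-appearance order."""
    seen: dict[str, None] = {}

    def walk(a: Ast) -> None:
        tag = a[0]
        if tag == "var":
            seen.setdefault(a[1])
        elif tag == "not":
            walk(a[1])
        elif tag in ("and", "or"):
            for s in a[1]:
                walk(s)

    walk(ast)
    return list(seen)


def eval_ast(ast: Ast, env: Mapping[str, int]) -> int:
    tag = ast[0]
    if tag == "const":
        return ast[1]
    if tag == "var":
        return env[ast[1]]
    if tag == "not":
        return 1 - eval_ast(ast[1], env)
    if tag == "and":
        return int(all(eval_ast(s, env) for s in ast[1]))
    if tag == "or":
        return int(any(eval_ast(s, env) for s in ast[1]))
    raise ModelError(f"bad AST tag {tag!r}")


def format_ast(ast: Ast) -> str:
    """Render an expression with minimal parentheses (| < & < !)."""

    def fmt(a: Ast, parent: str) -> str:
        tag = a[0]
        if tag == "const":
            return str(a[1])
        if tag == "var":
            return a[1]
        if tag == "not":
            return "!" + fmt(a[1], "not")
        if tag == "and":
            body = "&".join(fmt(s, "and") for s in a[1])
            return f"({body})" if parent == "not" else body
        if tag == "or":
            body = "|".join(fmt(s, "or") for s in a[1])
            return f"({body})" if parent in ("not", "and") else body
        raise ModelError(f"bad AST tag {tag!r}")

    return fmt(ast, "top")


class _ExprParser:
    """Recursive-descent parser for ``& | !``-expressions.

    Grammar:  or := and ('|' and)* ;  and := not ('&' not)* ;
              not := '!' not | atom ;  atom := name | 0 | 1 | '(' or ')'
    """

    _TOKEN_RE = re.compile(r"\s*(?:(?P<op>[&|!()])|(?P<const>[01])(?![\w/.+-])|"
                           r"(?P<name>" + NAME_RE.pattern + r")|(?P<bad>\S))")

    def __init__(self, text: str):
        self.tokens: list[str] = []
        for m in self._TOKEN_RE.finditer(text):
            if m.lastgroup == "bad":
                raise ParseError(f"unexpected character {m.group('bad')!r} in expression {text!r}")
            self.tokens.append(m.group(m.lastgroup))
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Ast:
        ast = self.parse_or()
        if self.peek() is not None:
            raise ParseError(f"trailing tokens starting at {self.peek()!r}")
        return ast

    def parse_or(self) -> Ast:
        parts = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else ("or", tuple(parts))

    def parse_and(self) -> Ast:
        parts = [self.parse_not()]
        while self.peek() == "&":
            self.take()
            parts.append(self.parse_not())
        return parts[0] if len(parts) == 1 else ("and", tuple(parts))

    def parse_not(self) -> Ast:
        if self.peek() == "!":
            self.take()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Ast:
        tok = self.take()
        if tok == "(":
            inner = self.parse_or()
            if self.peek() != ")":
                raise ParseError("missing closing parenthesis")
            self.take()
            return inner
        if tok in ("0", "1"):
            return ("const", int(tok))
        if NAME_RE.fullmatch(tok):
            return ("var", tok)
        raise ParseError(f"unexpected token {tok!r}")


def parse_expression(text: str) -> Ast:
    return _ExprParser(text).parse()


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogicRule:
    """Synchronous update rule ``target(t+1) = expression(state(t))``."""

    target: str
    expression: Ast

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(ast_variables(self.expression))

    def evaluate(self, env: Mapping[str, int]) -> int:
        return eval_ast(self.expression, env)

    def __str__(self) -> str:
        return f"{self.target}, {format_ast(self.expression)}"


@dataclass(frozen=True)
class ThresholdRule:
    """Signed-threshold rule: on iff ``bias + sum(w_i * x_i) > 0``.

    ``weighted_inputs`` maps each regulator to a nonzero signed integer
    weight (positive = activator, negative = inhibitor).  ``bias`` absorbs
    regulators whose value was fixed by simplification.  A weighted sum of
    exactly zero is decided by ``tie_policy``: ``"zero"`` switches the node
    off, ``"retain"`` keeps its current value (making the node an implicit
    input to itself).
    """

    target: str
    weighted_inputs: tuple[tuple[str, int], ...]
    tie_policy: str = "zero"
    bias: int = 0

    def __post_init__(self):
        if self.tie_policy not in ("zero", "retain"):
            raise ModelError(f"unknown tie policy {self.tie_policy!r}")
        for src, w in self.weighted_inputs:
            if w == 0:
                raise ModelError(f"zero weight on edge {src!r} -> {self.target!r}")

    @property
    def inputs(self) -> tuple[str, ...]:
        names = [src for src, _ in self.weighted_inputs]
        if self.tie_policy == "retain" and self.target not in names:
            names.append(self.target)
        return tuple(names)

    def evaluate(self, env: Mapping[str, int]) -> int:
        total = self.bias + sum(w * env[src] for src, w in self.weighted_inputs)
        if total > 0:
            return 1
        if total < 0:
            return 0
        return env[self.target] if self.tie_policy == "retain" else 0


Rule = Union[LogicRule, ThresholdRule]


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------


class BooleanNetwork:
    """An ordered set of named nodes with at most one update rule each.

    Nodes without a rule are *input nodes*: their value is held at whatever
    the state assigns (they behave as constants along any trajectory).
    ``clamps`` permanently override node values regardless of rules.
    Instances are treated as immutable; :func:`apply_control` returns a new
    network.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        rules: Iterable[Rule],
        clamps: Union[PartialAssignment, Mapping[str, int], None] = None,
    ):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ModelError("duplicate node names")
        for n in self.nodes:
            if not NAME_RE.fullmatch(n):
                raise ModelError(f"invalid node name {n!r}")
        self.rules: dict[str, Rule] = {}
        for r in rules:
            if r.target in self.rules:
                raise ModelError(f"duplicate rule for node {r.target!r}")
            if r.target not in self.nodes:
                raise ModelError(f"rule for unknown node {r.target!r}")
            for inp in r.inputs:
                if inp not in self.nodes:
                    raise ModelError(f"rule for {r.target!r} references unknown node {inp!r}")
            self.rules[r.target] = r
        self.clamps = PartialAssignment(clamps or {})
        for n in self.clamps:
            if n not in self.nodes:
                raise ModelError(f"clamp on unknown node {n!r}")
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self._compiled: Optional[list[tuple]] = None

    # -- structure ---------------------------------------------------------

    @property
    def input_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.rules)

    @property
    def free_nodes(self) -> tuple[str, ...]:
        """Nodes whose value is not clamped (they vary over the state space)."""
        return tuple(n for n in self.nodes if n not in self.clamps)

    def regulators(self, node: str) -> tuple[str, ...]:
        """Direct regulators of ``node`` read from its update rule.

        Clamped nodes have no effective regulators; input nodes have none.
        The implicit self-dependency of a ``retain``-tie threshold rule is
        included because the dynamics genuinely read it.
        """
        if node in self.clamps or node not in self.rules:
            return ()
        return self.rules[node].inputs

    def n_links(self) -> int:
        return sum(len(set(r.inputs)) for r in self.rules.values())

    # -- compiled synchronous dynamics on integer-packed states -----------
    #
    # A state is an int with bit i = value of self.nodes[i]; per-node
    # evaluators are precomputed truth tables over the rule's input bits so
    # stepping is pure table lookup.

    def _compile(self) -> list[tuple]:
        if self._compiled is not None:
            return self._compiled
        compiled: list[tuple] = []
        for i, name in enumerate(self.nodes):
            if name in self.clamps:
                compiled.append(("const", self.clamps[name], i))
            elif name not in self.rules:
                compiled.append(("copy", i))
            else:
                rule = self.rules[name]
                inputs = rule.inputs
                if len(inputs) > MAX_RULE_INPUTS:
                    raise ModelError(
                        f"rule for {name!r} has {len(inputs)} inputs, above the "
                        f"truth-table bound {MAX_RULE_INPUTS}"
                    )
                idxs = tuple(self.index[x] for x in inputs)
                table = bytearray(1 << len(inputs))
                for bits in range(1 << len(inputs)):
                    env = {x: (bits >> j) & 1 for j, x in enumerate(inputs)}
                    table[bits] = rule.evaluate(env)
                compiled.append(("table", idxs, bytes(table), i))
        self._compiled = compiled
        return compiled

    def step_int(self, state: int) -> int:
        nxt = 0
        for entry in self._compile():
            kind = entry[0]
            if kind == "const":
                _, v, i = entry
                if v:
                    nxt |= 1 << i
            elif kind == "copy":
                i = entry[1]
                nxt |= state & (1 << i)
            else:
                _, idxs, table, i = entry
                bits = 0
                for j, k in enumerate(idxs):
                    bits |= ((state >> k) & 1) << j
                if table[bits]:
                    nxt |= 1 << i
        return nxt

    # -- state packing helpers --------------------------------------------

    def pack_state(self, values: Mapping[str, int]) -> int:
        missing = [n for n in self.nodes if n not in values]
        if missing:
            raise ModelError(f"state is missing nodes {missing}")
        s = 0
        for i, n in enumerate(self.nodes):
            if values[n]:
                s |= 1 << i
        return self.force_clamps(s)

    def unpack_state(self, state: int) -> dict[str, int]:
        return {n: (state >> i) & 1 for i, n in enumerate(self.nodes)}

    def force_clamps(self, state: int) -> int:
        for n, v in self.clamps.items():
            i = self.index[n]
            state = (state | (1 << i)) if v else (state & ~(1 << i))
        return state

    def enumerate_states(self) -> Iterator[int]:
        """All states with clamped bits held at their clamp values."""
        free = [self.index[n] for n in self.free_nodes]
        base = self.force_clamps(0)
        for combo in range(1 << len(free)):
            s = base
            for j, i in enumerate(free):
                if (combo >> j) & 1:
                    s |= 1 << i
            yield s


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_RULE_LINE_RE = re.compile(
    r"^\s*(?P<target>" + NAME_RE.pattern + r")\s*(?:\*\s*=|,|=)\s*(?P<expr>.+?)\s*$"
)


def parse_logic_model(text: str) -> BooleanNetwork:
    """Parse a BoolNet-style logic model.

    One rule per line, ``Target, expression`` or ``Target* = expression``,
    expressions over ``& | ! ( )`` and node names; ``#`` starts a comment and
    blank lines are ignored.  A ``targets, factors`` header line is accepted
    and skipped.  Names that appear only as regulators become input nodes.
    """
    rules: list[LogicRule] = []
    seen_targets: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if lineno == 1 and re.fullmatch(r"targets\s*[,]\s*factors", line, re.IGNORECASE):
            continue
        m = _RULE_LINE_RE.match(line)
        if m is None:
            raise ParseError(f"line {lineno}: cannot parse rule line {line!r}")
        target = m.group("target")
        if target in seen_targets:
            raise ParseError(f"line {lineno}: duplicate rule for target {target!r}")
        seen_targets.add(target)
        try:
            expr = parse_expression(m.group("expr"))
        except ParseError as e:
            raise ParseError(f"line {lineno}: {e}") from None
        rules.append(LogicRule(target, expr))

    # targets keep their file order; rule-less regulators (input nodes)
    # follow, in first-appearance order - so serialize(parse(text))
    # reproduces the file's rule order exactly
    order: dict[str, None] = {r.target: None for r in rules}
    for r in rules:
        for inp in r.inputs:
            order.setdefault(inp)
    return BooleanNetwork(list(order), rules)


def serialize_logic_model(net: BooleanNetwork) -> str:
    """Inverse of :func:`parse_logic_model` up to whitespace."""
    lines = []
    for n in net.nodes:
        r = net.rules.get(n)
        if r is None:
            continue
        if not isinstance(r, LogicRule):
            raise ModelError(f"node {n!r} has a threshold rule; use serialize_threshold_model")
        lines.append(str(r))
    return "\n".join(lines) + "\n"


def parse_threshold_model(text: str, tie_policy: str = "zero") -> BooleanNetwork:
    """Parse a signed-edge CSV (``source,target,weight`` with header).

    Each target with at least one row gets a :class:`ThresholdRule`; sources
    that are never targets become input nodes.
    """
    if tie_policy not in ("zero", "retain"):
        raise ParseError(f"unknown tie policy {tie_policy!r}")
    edges: dict[str, list[tuple[str, int]]] = {}
    order: dict[str, None] = {}
    first_data = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if first_data:
            first_data = False
            if [p.lower() for p in parts[:3]] == ["source", "target", "weight"]:
                continue
        if len(parts) != 3:
            raise ParseError(f"line {lineno}: expected 'source,target,weight', got {line!r}")
        src, tgt, w_text = parts
        for nm in (src, tgt):
            if not NAME_RE.fullmatch(nm):
                raise ParseError(f"line {lineno}: invalid node name {nm!r}")
        try:
            w = int(w_text)
        except ValueError:
            raise ParseError(f"line {lineno}: weight {w_text!r} is not an integer") from None
        if w == 0:
            raise ParseError(f"line {lineno}: zero weight on {src!r} -> {tgt!r}")
        order.setdefault(src)
        order.setdefault(tgt)
        edges.setdefault(tgt, []).append((src, w))
    rules = [
        ThresholdRule(tgt, tuple(ws), tie_policy=tie_policy) for tgt, ws in edges.items()
    ]
    return BooleanNetwork(list(order), rules)


def serialize_threshold_model(net: BooleanNetwork) -> str:
    lines = ["source,target,weight"]
    for n in net.nodes:
        r = net.rules.get(n)
        if r is None:
            continue
        if not isinstance(r, ThresholdRule):
            raise ModelError(f"node {n!r} has a logic rule; use serialize_logic_model")
        for src, w in r.weighted_inputs:
            lines.append(f"{src},{n},{w}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def synchronous_step(net: BooleanNetwork, state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update of a total state, as a node -> value dict."""
    return net.unpack_state(net.step_int(net.pack_state(state)))


@dataclass(frozen=True)
class Attractor:
    """A state cycle closed under the synchronous map, in canonical rotation.

    ``states`` holds packed integer states, rotated so the numerically
    smallest state comes first; a length-1 cycle is a point attractor.
    """

    states: tuple[int, ...]

    @property
    def kind(self) -> str:
        return "point" if len(self.states) == 1 else "cyclic"

    def __len__(self) -> int:
        return len(self.states)

    def as_dicts(self, net: BooleanNetwork) -> list[dict[str, int]]:
        return [net.unpack_state(s) for s in self.states]

    def satisfies(self, net: BooleanNetwork, assignment: Mapping[str, int]) -> bool:
        """True iff every state of the cycle matches the given node values."""
        for s in self.states:
            for n, v in assignment.items():
                if (s >> net.index[n]) & 1 != v:
                    return False
        return True


def _canonical_cycle(cycle: Sequence[int]) -> Attractor:
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return Attractor(tuple(cycle[k:]) + tuple(cycle[:k]))


def _trace_attractors(
    net: BooleanNetwork, initial_states: Iterable[int]
) -> tuple[list[Attractor], dict[int, int]]:
    """Follow trajectories, returning attractors and a state -> attractor-index
    memo covering every visited state (the basin information)."""
    attractors: list[Attractor] = []
    seen: dict[int, Attractor] = {}
    basin: dict[int, int] = {}
    index_of: dict[Attractor, int] = {}
    for s0 in initial_states:
        if s0 in basin:
            continue
        path: list[int] = []
        pos: dict[int, int] = {}
        s = s0
        while s not in basin and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = net.step_int(s)
        if s in basin:
            att_idx = basin[s]
        else:
            cyc = path[pos[s]:]
            att = _canonical_cycle(cyc)
            if att not in index_of:
                index_of[att] = len(attractors)
                attractors.append(att)
            att_idx = index_of[att]
        for t in path:
            basin[t] = att_idx
    return attractors, basin


def find_attractors(
    net: BooleanNetwork,
    mode: str = "exhaustive",
    n_init: int = 1000,
    seed: int = 0,
    node_bound: int = EXHAUSTIVE_NODE_BOUND,
) -> list[Attractor]:
    """All attractors (``mode="exhaustive"``) or those reached from ``n_init``
    seeded random initial states (``mode="sampled"``), deduplicated up to
    cyclic rotation and sorted by their canonical first state.

    Exhaustive mode refuses networks with more than ``node_bound`` free
    nodes rather than silently enumerating 2^n states.
    """
    if mode == "exhaustive":
        n_free = len(net.free_nodes)
        if n_free > node_bound:
            raise ModelError(
                f"exhaustive attractor search refused: {n_free} free nodes "
                f"exceeds the bound of {node_bound}"
            )
        initial: Iterable[int] = net.enumerate_states()
    elif mode == "sampled":
        rng = _random.Random(seed)
        free = [net.index[n] for n in net.free_nodes]
        base = net.force_clamps(0)
        states = []
        for _ in range(n_init):
            s = base
            for i in free:
                if rng.random() < 0.5:
                    s |= 1 << i
            states.append(s)
        initial = states
    else:
        raise ModelError(f"unknown attractor-search mode {mode!r}")
    attractors, _ = _trace_attractors(net, initial)
    return sorted(attractors, key=lambda a: a.states)


def apply_control(
    net: BooleanNetwork, control: Union[PartialAssignment, Mapping[str, int]]
) -> BooleanNetwork:
    """Clamp the control set's nodes permanently; returns a new network.

    This models sustained external intervention: the clamped nodes' own rules
    are overridden for all time, and the fixed values propagate through the
    update rules of everything downstream.
    """
    control = PartialAssignment(control)
    for n in control:
        if n not in net.nodes:
            raise ModelError(f"control set mentions unknown node {n!r}")
    merged = net.clamps.union(control)  # raises on conflict with existing clamp
    return BooleanNetwork(net.nodes, net.rules.values(), merged)
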