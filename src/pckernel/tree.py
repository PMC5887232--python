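"""Converging tree and phenotype control kernel (PCK).

The converging tree is built breadth-first from the root - the desired
phenotype assignment ``{(P_1..P_l) = (d_1..d_l)}``.  The children of a
control set are the minimal solutions of its system of Boolean equations
(see :mod:`pckernel.solver`): partial assignments that, clamped, make every
node of the parent hold its value after one step.  Because clamps are
permanent, values propagate level by level, so every surviving set forces
the phenotype from any initial state.  Two removal rules prune the tree:

* **Included** (rule 1): a candidate is removed when some already-found set
  is a subset of it with equal values - a smaller perturbation achieves at
  least as much.  Equal sets count: the earlier (lower-level) occurrence
  survives.
* **Contradictory** (rule 2): a candidate is removed when it assigns a node
  the opposite value of its parent/ancestor chain - applying it could never
  re-create the ancestor's values, so the chain to the phenotype breaks.

A surviving child may itself be a subset of a previously accepted set; then
the *older, larger* set is the redundant one.  If the old set is unrelated
to the child it is removed together with its descendants; if it is the
child's own parent or ancestor the tree is restructured: the lowest such
level L replaces the included set(s) by the including children, everything
below level L is discarded, and expansion resumes from L (a
visited-configuration guard aborts should restructuring ever cycle).

The PCK is the collection of all surviving non-root sets: every minimal set
of permanent node clamps driving every initial state to an attractor with
the desired phenotype values.  Removed sets are retained in the serialized
tree with their removal reason, which aids debugging and reproduces the
published tree drawings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .model import BooleanNetwork, ModelError, PartialAssignment
from .solver import system_solutions

__all__ = [
    "PhenotypeSpec",
    "ControlSet",
    "ConvergingTree",
    "PCK",
    "is_included",
    "is_contradictory",
    "build_converging_tree",
    "extract_pck",
    "find_sets_containing",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """Desired steady-state values for one or more phenotype nodes."""

    nodes: tuple[str, ...]
    values: tuple[int, ...]

    def __post_init__(self):
        if len(self.nodes) < 1:
            raise ModelError("phenotype spec needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ModelError("phenotype nodes must be distinct")
        if len(self.nodes) != len(self.values):
            raise ModelError("phenotype nodes and values differ in length")
        for v in self.values:
            if v not in (0, 1):
                raise ModelError(f"phenotype value must be 0 or 1, got {v!r}")

    @classmethod
    def from_strings(cls, specs: Iterable[str]) -> "PhenotypeSpec":
        """Parse ``NODE=VALUE`` strings, e.g. ``["P=0", "Apoptosis=1"]``."""
        nodes, values = [], []
        for s in specs:
            name, _, val = s.partition("=")
            name, val = name.strip(), val.strip()
            if not name or val not in ("0", "1"):
                raise ModelError(f"bad phenotype spec {s!r}; expected NODE=0 or NODE=1")
            nodes.append(name)
            values.append(int(val))
        return cls(tuple(nodes), tuple(values))

    def as_assignment(self) -> PartialAssignment:
        return PartialAssignment(dict(zip(self.nodes, self.values)))


@dataclass
class ControlSet:
    """A node of the converging tree: a partial assignment with bookkeeping.

    ``commitments`` is the union of this set's assignment with every value
    its ancestor chain guarantees to hold eventually; descendants must not
    contradict it.  For ordinary children it equals the union of the parent
    and ancestor sets; after a tree restructuring it additionally preserves
    the constraints of the chain the set was *originally* derived from,
    which its forcing guarantee relies on.
    """

    id: int
    assignment: PartialAssignment
    level: int
    parent_id: Optional[int]
    leaf: bool = False
    removed: bool = False
    removal_reason: str = "none"  # "included" | "contradictory" | "none"
    witness_id: Optional[int] = None
    commitments: PartialAssignment = field(default_factory=PartialAssignment)

    def to_json_obj(self) -> dict:
        return {
            "id": self.id,
            "level": self.level,
            "assignment": {k: v for k, v in self.assignment.items()},
            "parent_id": self.parent_id,
            "leaf": self.leaf,
            "removed": self.removed,
            "removal_reason": self.removal_reason,
            "witness_id": self.witness_id,
        }


class ConvergingTree:
    """Rooted tree of control sets with completion status.

    ``status`` is ``"complete"`` when every frontier set is a leaf,
    ``"level_capped"`` when expansion stopped at a requested maximum level,
    and ``"aborted"`` when a non-termination guard tripped.
    """

    def __init__(self, root: ControlSet):
        self.root = root
        self.sets: dict[int, ControlSet] = {root.id: root}
        self.order: list[int] = [root.id]  # discovery order
        self.status: str = "complete"

    # -- queries -----------------------------------------------------------

    def get(self, set_id: int) -> ControlSet:
        return self.sets[set_id]

    def surviving(self) -> list[ControlSet]:
        return [self.sets[i] for i in self.order if not self.sets[i].removed]

    def surviving_at(self, level: int) -> list[ControlSet]:
        return [c for c in self.surviving() if c.level == level]

    def ancestors(self, cs: ControlSet) -> list[ControlSet]:
        out = []
        cur = cs
        while cur.parent_id is not None:
            cur = self.sets[cur.parent_id]
            out.append(cur)
        return out

    def descendants(self, cs: ControlSet) -> list[ControlSet]:
        kids = [c for c in self.sets.values() if c.parent_id == cs.id]
        out = []
        for k in kids:
            out.append(k)
            out.extend(self.descendants(k))
        return out

    @property
    def n_levels(self) -> int:
        """Deepest level holding a surviving set (0 = root only)."""
        return max((c.level for c in self.surviving()), default=0)

    def to_json_obj(self) -> dict:
        return {
            "status": self.status,
            "root_id": self.root.id,
            "nodes": [self.sets[i].to_json_obj() for i in sorted(self.sets)],
        }

    def to_dot(self) -> str:
        """DOT rendering; removed sets are drawn dotted, as in tree figures."""
        lines = ["digraph converging_tree {", "  rankdir=TB;"]
        for i in sorted(self.sets):
            c = self.sets[i]
            label = ",".join(f"{k}={v}" for k, v in c.assignment.items())
            style = ', style=dotted' if c.removed else ""
            lines.append(f'  n{c.id} [label="{{{label}}}"{style}];')
            if c.parent_id is not None:
                lines.append(f"  n{c.parent_id} -> n{c.id};")
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class PCK:
    """The phenotype control kernel: all surviving minimal control sets.

    Carries the tree's completion status so kernels read off partial trees
    are clearly labelled.
    """

    sets: tuple[ControlSet, ...]
    status: str

    @property
    def assignments(self) -> tuple[PartialAssignment, ...]:
        return tuple(c.assignment for c in self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def to_json_obj(self) -> dict:
        return {
            "status": self.status,
            "control_sets": [
                {"level": c.level, "assignment": dict(c.assignment.items())}
                for c in self.sets
            ],
        }


# ---------------------------------------------------------------------------
# Removal rules
# ---------------------------------------------------------------------------


def is_included(
    candidate: Union[ControlSet, PartialAssignment],
    others: Iterable[Union[ControlSet, PartialAssignment]],
) -> tuple[bool, Optional[Union[ControlSet, PartialAssignment]]]:
    """First removal rule: is some other set a subset-with-equal-values of
    the candidate?  Returns (flag, witness)."""
    cand = candidate.assignment if isinstance(candidate, ControlSet) else candidate
    for other in others:
        oa = other.assignment if isinstance(other, ControlSet) else other
        if oa.issubset(cand):
            return True, other
    return False, None


def is_contradictory(
    candidate: Union[ControlSet, PartialAssignment],
    ancestors: Iterable[Union[ControlSet, PartialAssignment]],
) -> tuple[bool, Optional[Union[ControlSet, PartialAssignment]]]:
    """Second removal rule: does the candidate assign some node the opposite
    value of its parent/ancestor sets?  Returns (flag, witness)."""
    cand = candidate.assignment if isinstance(candidate, ControlSet) else candidate
    for anc in ancestors:
        aa = anc.assignment if isinstance(anc, ControlSet) else anc
        if cand.conflicts(aa) is not None:
            return True, anc
    return False, None


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


class _TreeBuilder:
    def __init__(
        self,
        net: BooleanNetwork,
        pheno: PhenotypeSpec,
        max_level: Optional[int],
        safety_cap: Optional[int],
    ):
        for p in pheno.nodes:
            if p not in net.nodes:
                raise ModelError(f"phenotype node {p!r} is not in the network")
        self.net = net
        self.pheno = pheno
        self.max_level = max_level
        self.safety_cap = safety_cap if safety_cap is not None else len(net.nodes) + 1
        self.next_id = 0
        root = self._new_set(pheno.as_assignment(), 0, None)
        root.commitments = root.assignment
        self.tree = ConvergingTree(root)
        self.tree.sets = {root.id: root}
        self.tree.order = [root.id]
        self.seen_configs: set = set()

    def _new_set(self, assignment: PartialAssignment, level: int, parent_id: Optional[int]) -> ControlSet:
        cs = ControlSet(self.next_id, assignment, level, parent_id)
        self.next_id += 1
        return cs

    def _add(self, cs: ControlSet) -> None:
        self.tree.sets[cs.id] = cs
        self.tree.order.append(cs.id)

    def _delete_below(self, level: int) -> None:
        """Physically drop every set deeper than ``level`` (they are rebuilt)."""
        doomed = [i for i, c in self.tree.sets.items() if c.level > level]
        for i in doomed:
            del self.tree.sets[i]
        self.tree.order = [i for i in self.tree.order if i in self.tree.sets]

    def _config_key(self):
        return frozenset((c.level, c.assignment) for c in self.tree.surviving())

    # -- one parent's expansion -------------------------------------------

    def _expand_parent(self, parent: ControlSet) -> tuple[list[ControlSet], Optional[int]]:
        """Generate, filter and attach the children of ``parent``.

        Returns (accepted children, restructure level or None)."""
        tree = self.tree
        is_root = parent.parent_id is None
        exclude: tuple[str, ...] = ()
        if not is_root and len(parent.assignment) == 1:
            exclude = tuple(parent.assignment)  # singleton: its node is barred
        candidates = system_solutions(
            parent.assignment, self.net, include_self_clamps=True, exclude_nodes=exclude
        )
        if not candidates:
            parent.leaf = True
            return [], None

        ancestor_chain = [parent] + tree.ancestors(parent)
        accepted: list[ControlSet] = []
        for assignment in candidates:
            child = self._new_set(assignment, parent.level + 1, parent.id)
            self._add(child)
            # rule 1: against every control set found so far (S + S_before)
            inc, witness = is_included(child, (c for c in tree.surviving() if c.id != child.id))
            if inc:
                child.removed = True
                child.removal_reason = "included"
                child.witness_id = witness.id  # type: ignore[union-attr]
                continue
            # rule 2: against everything the parent chain guarantees to hold
            # (the union of parent and ancestor sets, plus - after any
            # restructuring - the constraints of the original derivation
            # chain, without which the forcing guarantee would be unsound)
            clash = assignment.conflicts(parent.commitments)
            if clash is not None:
                _, witness = is_contradictory(child, ancestor_chain)
                child.removed = True
                child.removal_reason = "contradictory"
                child.witness_id = witness.id if witness is not None else parent.id
                continue
            child.commitments = assignment.union(parent.commitments)
            accepted.append(child)

        if not accepted:
            parent.leaf = True
            return [], None

        # A surviving child may be smaller than an older set: the older,
        # larger set is now redundant (it is "included in" the child).
        superseded: list[tuple[ControlSet, ControlSet]] = []  # (old set, including child)
        for child in accepted:
            for other in tree.surviving():
                if other.id == child.id or other.parent_id is None:
                    continue
                if child.assignment.issubset(other.assignment) and other.assignment != child.assignment:
                    superseded.append((other, child))
        if not superseded:
            return accepted, None

        ancestor_ids = set()
        for child in accepted:
            ancestor_ids.update(a.id for a in tree.ancestors(child))
        entangled = [(old, ch) for old, ch in superseded if old.id in ancestor_ids]
        if not entangled:
            # unrelated redundant sets: drop them and their subtrees
            for old, ch in superseded:
                if old.removed:
                    continue
                old.removed = True
                old.removal_reason = "included"
                old.witness_id = ch.id
                for d in tree.descendants(old):
                    if not d.removed:
                        d.removed = True
                        d.removal_reason = "included"
                        d.witness_id = old.id
            return accepted, None

        # restructure: replace the lowest-level superseded ancestor(s) by the
        # children that include them and rebuild everything below that level
        L = min(old.level for old, _ in entangled)
        at_L = [(old, ch) for old, ch in superseded if old.level == L]
        for old, ch in at_L:
            if not old.removed:
                old.removed = True
                old.removal_reason = "included"
                old.witness_id = ch.id
        replacements: dict[PartialAssignment, tuple[int, PartialAssignment]] = {}
        for old, _ in at_L:
            for child in accepted:
                if child.assignment.issubset(old.assignment):
                    replacements.setdefault(
                        child.assignment, (old.parent_id, child.commitments)
                    )
        child_ids = {c.assignment: c.id for c in accepted}
        self._delete_below(L)
        existing = {c.assignment for c in tree.surviving_at(L)}
        idmap: dict[int, int] = {}
        moved_sets: list[ControlSet] = []
        for assignment, (parent_id, commitments) in sorted(replacements.items()):
            if assignment in existing:
                continue
            moved = self._new_set(assignment, L, parent_id)
            moved.commitments = commitments
            self._add(moved)
            existing.add(assignment)
            moved_sets.append(moved)
            if assignment in child_ids:
                idmap[child_ids[assignment]] = moved.id
        # witnesses may point at deleted sets: repoint to the moved copy
        # where one exists, else drop the reference
        for c in tree.sets.values():
            if c.witness_id is not None and c.witness_id not in tree.sets:
                c.witness_id = idmap.get(c.witness_id)
        resume = self._resolve_inclusions(moved_sets, L)
        for c in tree.surviving_at(resume):
            c.leaf = False
        return [], resume

    def _resolve_inclusions(self, new_sets: list[ControlSet], level: int) -> int:
        """Reattached sets may still strictly include older surviving sets
        (the first removal rule in the other direction).  Remove such older
        sets with their subtrees; when the older set is an *ancestor* of the
        new one, restructure again at that level.  Terminates because every
        step removes a set or strictly raises a new set toward the root."""
        tree = self.tree
        resume = level
        queue = list(new_sets)
        while queue:
            m = queue.pop(0)
            if m.id not in tree.sets or m.removed:
                continue
            ancestor_ids = {a.id for a in tree.ancestors(m)}
            redo = True
            while redo:
                redo = False
                for x in list(tree.surviving()):
                    if x.id == m.id or x.parent_id is None:
                        continue
                    if not (m.assignment.issubset(x.assignment)
                            and x.assignment != m.assignment):
                        continue
                    x.removed = True
                    x.removal_reason = "included"
                    x.witness_id = m.id
                    if x.id in ancestor_ids:
                        lx, parent_id, commit = x.level, x.parent_id, m.commitments
                        assignment = m.assignment
                        self._delete_below(lx)  # removes m itself
                        for c in tree.sets.values():
                            if c.witness_id is not None and c.witness_id not in tree.sets:
                                c.witness_id = None
                        survivors = {c.assignment for c in tree.surviving_at(lx)}
                        if assignment not in survivors:
                            m = self._new_set(assignment, lx, parent_id)
                            m.commitments = commit
                            self._add(m)
                            queue.append(m)
                        resume = min(resume, lx)
                        break
                    for d in tree.descendants(x):
                        if d.id in tree.sets and not d.removed:
                            d.removed = True
                            d.removal_reason = "included"
                            d.witness_id = x.id
                    redo = True
                    break
        return resume

    # -- main loop ---------------------------------------------------------

    def build(self) -> ConvergingTree:
        tree = self.tree
        level = 0
        while True:
            parents = sorted(
                (c for c in tree.surviving_at(level) if not c.leaf),
                key=lambda c: c.assignment,
            )
            if not parents:
                tree.status = "complete"
                break
            if self.max_level is not None and level + 1 > self.max_level:
                tree.status = "level_capped"
                break
            if level + 1 > self.safety_cap:
                tree.status = "aborted"
                break
            restart = None
            for parent in parents:
                _, restart = self._expand_parent(parent)
                if restart is not None:
                    break
            if restart is not None:
                key = self._config_key()
                if key in self.seen_configs:
                    tree.status = "aborted"
                    break
                self.seen_configs.add(key)
                level = restart
                continue
            level += 1
        return tree


def build_converging_tree(
    net: BooleanNetwork,
    pheno: PhenotypeSpec,
    max_level: Optional[int] = None,
    safety_cap: Optional[int] = None,
) -> ConvergingTree:
    """Build the converging tree for a (simplified/clamped) network.

    Expansion is level-synchronous with parents processed in sorted order,
    so the result is deterministic given the network.  It stops when every
    frontier set is a leaf (``complete``), when ``max_level`` is reached
    (``level_capped``), or when a non-termination guard trips (``aborted``;
    the default safety cap is ``len(net.nodes) + 1`` levels, longer than any
    simple regulatory path).
    """
    return _TreeBuilder(net, pheno, max_level, safety_cap).build()


def extract_pck(tree: ConvergingTree) -> PCK:
    """All surviving non-root control sets, sorted by (level, assignment)."""
    members = sorted(
        (c for c in tree.surviving() if c.parent_id is not None),
        key=lambda c: (c.level, c.assignment),
    )
    return PCK(tuple(members), tree.status)


def find_sets_containing(
    net: BooleanNetwork,
    pheno: PhenotypeSpec,
    node: str,
    layered=None,
    max_level: Optional[int] = None,
) -> tuple[list[ControlSet], Optional[ConvergingTree]]:
    """Control sets containing ``node``, using the layered network as a guide.

    A node outside the layered network cannot influence the phenotype, so an
    empty answer is returned *without building the tree*.  Otherwise the tree
    is built to at least the node's layer index - the first level at which a
    set containing it can appear - and filtered.
    """
    if layered is None:
        from .layered import build_layered_network

        layered = build_layered_network(net, pheno)
    layer_of = layered.layer_of
    if node not in layer_of:
        return [], None
    depth = layer_of[node]
    if max_level is not None:
        depth = max(depth, max_level)
    tree = build_converging_tree(net, pheno, max_level=depth)
    hits = [c for c in extract_pck(tree).sets if node in c.assignment]
    return hits, tree
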