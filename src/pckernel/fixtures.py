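"""Packaged models and a seeded random Boolean-network generator.

``example_network`` is the seven-node illustration network used throughout
the documentation and tests.  ``simplified_mapk_fragment`` is the documented
core of the simplified MAPK cancer network around the Proliferation node -
a *fragment*, not the full 53-node model.  The full MAPK and cancer
signaling models are published as supplementary spreadsheets; when a
transcription file is placed in the package data directory the loaders pick
it up, and otherwise they raise :class:`FixtureUnavailable` with a clear
message instead of fabricating rules.

``random_network`` generates reproducible random networks (same config =>
identical network) for the oracle-equivalence test suites: random nested
AND/OR/NOT rules, random truth tables, or random signed-threshold rules,
optionally rewired so that every node has a regulatory path to the
phenotype node (needed by kernel-property tests, where non-influential
nodes would just be dead weight).
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass
from importlib import resources
from .model import (
    Ast,
    BooleanNetwork,
    LogicRule,
    ThresholdRule,
    parse_logic_model,
    parse_threshold_model,
)

__all__ = [
    "FixtureUnavailable",
    "example_network",
    "simplified_mapk_fragment",
    "mapk_fixture",
    "cancer_fixture",
    "GeneratorConfig",
    "random_network",
]


class FixtureUnavailable(RuntimeError):
    """A model that must be transcribed from supplementary material is absent."""


def _data_text(filename: str) -> str:
    ref = resources.files("pckernel").joinpath("data", filename)
    if not ref.is_file():
        raise FixtureUnavailable(
            f"fixture file {filename!r} is not packaged: it must be transcribed "
            "from the published supplementary material and placed in "
            "src/pckernel/data/ (see that directory's README note)"
        )
    return ref.read_text()


def example_network() -> BooleanNetwork:
    """The seven-node example network {A..F, P}; F is an input node."""
    return parse_logic_model(_data_text("example.bnet"))


_MAPK_FRAGMENT = """\
# Core of the simplified MAPK network around Proliferation, as documented in
# the published walkthrough (update rules quoted there verbatim; the
# MEK1_2 rule is the post-mutation form !AP1, PPP2CA = 0 already folded in).
# AP1 and p38 are left as input nodes: this is a FRAGMENT of the 29-rule
# simplified model, sufficient to reproduce construction steps 1-4.
Proliferation, p70&MYC
p70, ERK
MYC, MSK
ERK, MEK1_2
MSK, ERK|p38
MEK1_2, !AP1
"""


def simplified_mapk_fragment() -> BooleanNetwork:
    """Documented fragment of the simplified MAPK network (8 nodes)."""
    return parse_logic_model(_MAPK_FRAGMENT)


def mapk_fixture() -> BooleanNetwork:
    """The full MAPK logic model (53 nodes, 88 links), if transcribed."""
    return parse_logic_model(_data_text("mapk.bnet"))


def cancer_fixture(tie_policy: str = "zero") -> BooleanNetwork:
    """The threshold-rule cancer signaling model (96 nodes, 265 links), if
    transcribed.  ``tie_policy`` must match whichever convention reproduces
    the source model's attractors (document it with the transcription)."""
    return parse_threshold_model(_data_text("cancer.csv"), tie_policy=tie_policy)


# ---------------------------------------------------------------------------
# Random networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible random-network recipe (same config -> identical network).

    ``rule_family`` is one of ``"nested"`` (random AND/OR/NOT expressions),
    ``"table"`` (uniform random truth tables) or ``"threshold"`` (random
    signed weights in +-{1,2}).  With ``ensure_influence`` every node is
    rewired, if necessary, to have a directed path to a phenotype node.

    The defaults emulate signaling-network models: sparse regulation
    (in-degree 1-3), phenotype nodes as read-out sinks that regulate
    nothing, and no direct self-regulation - the shape of the published
    cascade models this kind of analysis targets.  Feedback loops between
    distinct non-phenotype nodes arise freely.
    """

    n_nodes: int = 8
    k_min: int = 1
    k_max: int = 3
    rule_family: str = "nested"
    n_phenotype: int = 1
    seed: int = 0
    ensure_influence: bool = True
    phenotype_is_sink: bool = True
    allow_self_loops: bool = False


def _minterm_ast(inputs: tuple[str, ...], table: list[int]) -> Ast:
    ons = [m for m, out in enumerate(table) if out]
    if not ons:
        return ("const", 0)
    if len(ons) == len(table):
        return ("const", 1)
    terms = []
    for m in ons:
        lits: list[Ast] = []
        for j, name in enumerate(inputs):
            lit: Ast = ("var", name)
            if not (m >> j) & 1:
                lit = ("not", lit)
            lits.append(lit)
        terms.append(lits[0] if len(lits) == 1 else ("and", tuple(lits)))
    return terms[0] if len(terms) == 1 else ("or", tuple(terms))


def _nested_ast(regs: list[str], rng: _random.Random) -> Ast:
    expr: Ast = ("var", regs[0])
    if rng.random() < 0.5:
        expr = ("not", expr)
    for name in regs[1:]:
        lit: Ast = ("var", name)
        if rng.random() < 0.5:
            lit = ("not", lit)
        expr = (rng.choice(("and", "or")), (expr, lit))
    return expr


def _make_rule(target: str, regs: list[str], family: str, rng: _random.Random):
    if family == "nested":
        return LogicRule(target, _nested_ast(regs, rng))
    if family == "table":
        table = [rng.randint(0, 1) for _ in range(1 << len(regs))]
        return LogicRule(target, _minterm_ast(tuple(regs), table))
    if family == "threshold":
        weights = tuple((r, rng.choice((-2, -1, 1, 2))) for r in regs)
        return ThresholdRule(target, weights, tie_policy="zero")
    raise ValueError(f"unknown rule family {family!r}")


def random_network(cfg: GeneratorConfig) -> BooleanNetwork:
    rng = _random.Random(cfg.seed)
    n_ph = cfg.n_phenotype
    pheno = ["P"] if n_ph == 1 else [f"P{i+1}" for i in range(n_ph)]
    others = [f"N{i+1}" for i in range(cfg.n_nodes - n_ph)]
    names = pheno + others

    regs_of: dict[str, list[str]] = {}
    for name in names:
        pool = list(names)
        if cfg.phenotype_is_sink:
            pool = [x for x in pool if x not in pheno]
        if not cfg.allow_self_loops:
            pool = [x for x in pool if x != name]
        if not pool:
            raise ValueError("no admissible regulators; relax the generator config")
        k = rng.randint(cfg.k_min, min(cfg.k_max, len(pool)))
        regs_of[name] = sorted(rng.sample(pool, k))

    if cfg.ensure_influence:
        def reaching() -> set[str]:
            reach = set(pheno)
            frontier = list(pheno)
            while frontier:
                node = frontier.pop()
                for src in regs_of[node]:
                    if src not in reach:
                        reach.add(src)
                        frontier.append(src)
            return reach

        guard = 0
        while True:
            reach = reaching()
            missing = sorted(set(names) - reach)
            if not missing:
                break
            u = missing[0]
            hosts = sorted(n for n in reach if u not in regs_of[n] and n != u)
            if not hosts:
                raise RuntimeError("influence rewiring has no admissible host")
            t = rng.choice(hosts)
            regs_of[t] = sorted(regs_of[t] + [u])
            guard += 1
            if guard > 4 * cfg.n_nodes:  # cannot happen, but never loop
                raise RuntimeError("influence rewiring did not converge")

    rules = [_make_rule(name, regs_of[name], cfg.rule_family, rng) for name in names]
    return BooleanNetwork(names, rules)
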