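"""Layered network: hierarchical shells of regulators of the phenotype nodes.

Layer 0 holds the phenotype nodes; layer i+1 holds every node that regulates
at least one node of layer i and sits in no earlier layer.  Construction
stops when no unused regulator remains, so a node's layer index equals the
shortest regulatory-path length from it to a phenotype node and the layered
network is unique.  Regulators are read from the update rules' variable
lists (not a separate edge table), which keeps the layering consistent with
the dynamics after simplification.

Nodes outside every layer have no directed path to any phenotype node, so no
perturbation of them can ever change the phenotype values: the layered /
non-layered split is exactly the influential / non-influential partition,
and the layer index lower-bounds the converging-tree level at which a node
can first appear in a control set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import BooleanNetwork, ModelError
from .tree import PhenotypeSpec

__all__ = ["LayeredNetwork", "build_layered_network", "influential_partition"]


@dataclass(frozen=True)
class LayeredNetwork:
    """Ordered, pairwise-disjoint layers of node names (layer 0 = phenotype)."""

    layers: tuple[tuple[str, ...], ...]

    @property
    def layer_of(self) -> dict[str, int]:
        return {n: k for k, layer in enumerate(self.layers) for n in layer}

    @property
    def layered_nodes(self) -> tuple[str, ...]:
        return tuple(n for layer in self.layers for n in layer)

    def __len__(self) -> int:
        return len(self.layers)

    def to_json_obj(self) -> dict[str, list[str]]:
        return {str(k): list(layer) for k, layer in enumerate(self.layers)}

    def to_dot(self) -> str:
        """DOT rendering with one rank per layer, phenotype at the bottom."""
        lines = ["digraph layered {", "  rankdir=BT;"]
        for k, layer in enumerate(self.layers):
            names = " ".join(f'"{n}";' for n in layer)
            lines.append(f"  {{ rank=same; {names} }}  // layer {k}")
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_layered_network(net: BooleanNetwork, pheno: PhenotypeSpec) -> LayeredNetwork:
    """Build the unique layered network for the given phenotype nodes."""
    for p in pheno.nodes:
        if p not in net.nodes:
            raise ModelError(f"phenotype node {p!r} is not in the network")

    # reversed adjacency: node -> nodes that regulate it
    placed = set(pheno.nodes)
    layers: list[tuple[str, ...]] = [tuple(sorted(pheno.nodes))]
    frontier = list(pheno.nodes)
    while True:
        nxt = set()
        for n in frontier:
            for reg in net.regulators(n):
                if reg not in placed:
                    nxt.add(reg)
        if not nxt:
            break
        layer = tuple(sorted(nxt))
        layers.append(layer)
        placed.update(nxt)
        frontier = list(layer)
    return LayeredNetwork(tuple(layers))


def influential_partition(
    net: BooleanNetwork, pheno: PhenotypeSpec
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split nodes into (layered, non-influential).

    Non-influential nodes appear in no layer: they have no regulatory path to
    the phenotype nodes, so clamping them can never change the phenotype.
    """
    layered = set(build_layered_network(net, pheno).layered_nodes)
    inside = tuple(n for n in net.nodes if n in layered)
    outside = tuple(n for n in net.nodes if n not in layered)
    return inside, outside
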