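# pckernel

Phenotype control kernels of Boolean network models.

Cellular phenotypes correspond to attractors of molecular regulatory
networks: with synchronous Boolean dynamics `x(t+1) = f(x(t))`, a phenotype
is defined by the steady values of a few read-out nodes (Apoptosis,
Proliferation, ...) in the attractor a cell settles into.  A therapy-style
intervention pins a handful of molecules at fixed values.  `pckernel`
answers the question: *which minimal sets of permanently clamped nodes
guarantee that every initial state ends in an attractor with the desired
phenotype values* `(P_1..P_l) = (d_1..d_l)`?  The collection of all such
minimal control sets is the **phenotype control kernel (PCK)**.  This is
"any-to-multiple" target control: any initial state, any attractor of the
right phenotype - including attractors that only exist under control.

The search combines two structures:

- the **layered network** - shells of direct and indirect regulators of the
  phenotype nodes; a node's layer index is its shortest regulatory distance
  to the phenotype, nodes outside every layer provably cannot control it,
  and the index lower-bounds where the node can appear in the tree;
- the **converging tree** - rooted at the phenotype assignment, where the
  children of a control set are the minimal solutions of its system of
  Boolean equations (prime implicants of `[f_K = v]` per node, combined by
  Cartesian product, plus each node's own clamp), pruned by two removal
  rules: *included* sets (a smaller perturbation already achieves as much)
  and *contradictory* sets (a value clashing with what the chain to the
  phenotype requires).

Every surviving set is verified against a ground-truth state-space oracle:
clamp it, enumerate all attractors exhaustively (or sample seeded initial
states at scale), and require the phenotype values in every attractor
state.  A brute-force enumerator of all small clamp combinations provides
the independent minimality and coverage checks.  Both logic-rule models
(BoolNet-style `&`, `|`, `!` text) and signed-threshold models
(`source,target,weight` CSV with a configurable tie policy) are supported,
plus a seeded generator of random signaling-style test networks.

## Worked example

The packaged seven-node network (`src/pckernel/data/example.bnet`):

```
A, F
B, C&(!F)
C, (!B)&D&E
D, A
E, D|F
P, C&E
```

`P` is the phenotype node; `F` has no rule, so it is an input.  Ask for
every minimal control set enforcing `P = 0`:

```sh
pck pck --model src/pckernel/data/example.bnet --phenotype P=0
```

prints (config block elided):

```json
{
  "control_sets": [
    {"assignment": {"C": 0}, "level": 1},
    {"assignment": {"E": 0}, "level": 1},
    {"assignment": {"B": 1}, "level": 2},
    {"assignment": {"D": 0}, "level": 2},
    {"assignment": {"A": 0}, "level": 3},
    {"assignment": {"F": 0}, "level": 4}
  ],
  "n_control_sets": 6,
  "status": "complete"
}
```

Six minimal one-node interventions control the phenotype.  The levels are
their depths in the converging tree: `{C=0}` and `{E=0}` force `P* = C&E`
to 0 directly; `{B=1}` kills `C* = (!B)&D&E` one step upstream; `{D=0}`,
`{A=0}` and `{F=0}` act through progressively longer cascades (`D* = A`,
`A* = F`).  `pck tree ... --dot tree.dot` exports the full tree including
the pruned candidates - here `{P=0}` and `{(D,F)=(0,0)}` removed as
*included* (a smaller set already achieves as much) and `{(C,F)=(1,0)}` as
*contradictory* (it needs `C=1` while its ancestor chain needs `C=0`).
Cross-checking with the oracle, `pck verify --model ... --phenotype P=0
--control C=0 --minimality` reports `"holds": true, "minimal": true`: with
C clamped to 0 the network has two fixed points (one per value of the
input F), both with `P = 0`, whereas the free network also has the fixed
point `(A,B,C,D,E,F,P) = (1,0,1,1,1,1,1)` with `P = 1` - the
any-to-multiple picture in miniature.

Other subcommands: `simplify` (constant propagation of inputs/mutations to
a fixpoint), `layers` (the layered network as JSON/DOT), `attractors`
(exhaustive or sampled), `generate` (seeded random test networks).  All
outputs are deterministic JSON embedding the full run configuration.

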