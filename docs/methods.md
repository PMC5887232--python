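# Methods

## Model and problem

A Boolean network has nodes with values in {0, 1} and one update rule per
non-input node, applied synchronously: `x_i(t+1) = f_i(x(t))`.  Rule-less
*input* nodes hold whatever value the state assigns them.  An **attractor**
is a set of states closed under this map (a fixed point or a cycle); cell
phenotypes are identified with the steady values of designated *phenotype
nodes* read off attractor states.

A **control set** is a partial assignment of nodes to fixed values,
implemented as permanent clamps: the clamped nodes' own rules are
overridden for all time, and the fixed values propagate through the update
rules of everything downstream.  Given desired phenotype values
`(P_1..P_l) = (d_1..d_l)`, the **phenotype control kernel (PCK)** is the
collection of all minimal control sets that drive *every* initial state to
an attractor in which every cycle state carries the desired phenotype
values ("any-to-multiple" control: multiple attractors of the right
phenotype are acceptable targets, and the controlled attractors need not be
attractors of the free network).

Two rule languages are supported behind one interface: logic rules
(`&`, `|`, `!` expressions in the plain-text BoolNet-style dialect, one
`Node, expression` line per rule) and signed-threshold rules
(`source,target,weight` CSV; next value is 1 when the signed weighted sum
is positive, 0 when negative, and a **tie policy** decides an exact zero -
`zero` maps ties to 0 (the default), `retain` keeps the node's current
value, making the node an implicit input to itself).  The tie policy is
configurable because published threshold models vary in this convention; a
transcribed model should record which policy reproduces its attractors.

## The pipeline

**Simplification** (`propagate_constants`).  Supplied input values and
mutations are substituted into the rules and folded algebraically (AND with
0, OR with 1, NOT of a constant; thresholds fold fixed regulators into a
bias, and a bias that dominates the remaining weights decides the sign).  A
rule that collapses to a constant fixes its target, which is substituted in
turn, to a fixpoint.  The result - a fixed-value map plus a reduced network
over the surviving nodes - is independent of substitution order (the scan
order is exposed only so the confluence property can be tested), and
preserves the synchronous attractors restricted to the surviving nodes
(verified empirically in the suite on networks of up to 8 nodes by
projecting attractors of the clamped original onto the survivors).
Supplied values *override* their own rules, which is how sustained
mutations are modelled; an optional consistency check instead reports a
derivation chain when a supplied value contradicts what its own rule
derives.

**Layered network** (`build_layered_network`).  Layer 0 holds the phenotype
nodes; layer i+1 holds every rule-input of layer i not already placed.  The
layer index of a node therefore equals the shortest regulatory-path length
to a phenotype node, the construction is unique, and nodes outside every
layer have no influence on the phenotype whatsoever - they can be excluded
as control candidates before any dynamics are computed.  The layer index
also lower-bounds the tree level at which a node can first appear in a
control set, so a tree need only be built to `layer_of(N)` levels to look
for sets containing a given node N (`find_sets_containing`).

**Per-equation forcing solutions** (`forcing_solutions`).  For one equation
`n = f(x_1..x_a)`, a forcing solution is a minimal partial assignment of
the rule's direct inputs under which f equals n for *every* completion of
the free inputs - exactly a prime implicant of the indicator function
[f = n].  All prime implicants are computed by Quine-McCluskey cube merging
over the rule's truth table (threshold rules are expanded to tables first;
a configurable in-degree cap, default 16, guards the expansion).  Solutions
are sorted by (size, node names, values) so every downstream structure is
reproducible byte-for-byte.

**Converging tree** (`build_converging_tree`).  The root is the desired
phenotype assignment.  Children of a control set are minimal solutions of
its *system* of equations: the Cartesian product of the per-equation
solution sets, merged by union, with internally conflicting tuples dropped
and only subset-minimal merges kept.  Each per-equation collection also
contains the node's own clamp (*self-clamp*) - clamping the node holds its
value directly.  This matters for multi-node parents with internal
feedback: for `P* = A^B` (an XOR written in `&`/`|`/`!`), `A* = B`,
`B* = A`, the set `{A=1}` alone forces `(A,B) = (1,1)` because the clamp
propagates through `B* = A`, and it is found only through the self-clamp of
A combined with `{A=1}` as the solution of B's equation.  For a non-root
*singleton* parent `{K=v}` the node K is excluded from its children's
candidates - the self-clamp child would merely duplicate the parent and be
removed anyway.  The root's self-clamps are kept (and then removed), so the
serialized tree records them with their removal reason, as tree drawings
conventionally do.

Two removal rules prune each new child:

1. **Included**: some already-found set is a subset of the child with equal
   values - a smaller perturbation achieving at least as much.  Equal sets
   count; the earlier (lower-level) occurrence survives.  The comparison
   runs against every surviving set discovered so far, in discovery order.
2. **Contradictory**: the child assigns some node the opposite value of
   anything its chain guarantees to hold (see *commitments* below); the
   broken chain could never re-create the phenotype.

A surviving child can itself be *smaller* than an older surviving set; then
the older, larger set is redundant.  If the old set is unrelated to the
child it is removed with its subtree.  If it is the child's own parent or
ancestor, the tree is **restructured**: at the lowest such level L the
included set is replaced by the including child, everything below L is
discarded, and expansion resumes from L.  Reattached sets are checked
against the rest of the tree the same way (removing or further restructuring
as needed), and a visited-configuration hash aborts construction should
restructuring ever cycle - the builder never loops.  Expansion is
level-synchronous with parents processed in sorted order; it ends when
every frontier set is a leaf (`complete`), at a requested `max_level`
(`level_capped`), or at a safety cap of `#nodes + 1` levels (`aborted`).
Two runs produce byte-identical JSON.

**Commitments.**  Every control set records the union of its assignment
with everything its derivation chain guarantees to hold eventually.  For an
ordinary child this is exactly the union of its parent and ancestor sets,
so the contradiction rule behaves classically.  After a restructuring,
however, a reattached set keeps the commitments of the chain it was
*originally* derived from: its forcing guarantee runs through that chain,
and descendants that contradict those values would silently break it.
Without this bookkeeping the restructuring step can emit control sets that
fail state-space verification; with it, every surviving set provably forces
the phenotype (clamp the set, then each level of its original chain becomes
constant one synchronous step after the previous one, for every initial
state).

**Verification** (`verify_control_set`, `verify_minimality`,
`brute_force_kernel`).  The ground-truth oracle clamps a control set and
examines attractors - exhaustively (full 2^n enumeration over free nodes,
refused above a 22-node bound) or from seeded random initial states
(default 1000).  An attractor satisfies the phenotype only if *every* cycle
state does: a phenotype value that oscillates is a failure under this
strict steady-value reading (the permissive reading, accepting attractors
that merely visit the desired value, would only enlarge the gap discussed
under *Scope*).  `brute_force_kernel` enumerates all clamp combinations up
to a size bound over non-phenotype nodes (clamping a phenotype node itself
trivially pins its value and is not a control strategy), keeping the
subset-minimal passing sets.  `forces_by_substitution` is the matching
*static* oracle: it fixes every node whose truth table restricted to the
known constants is semantically constant, to a fixpoint - precisely the
guarantee a converging-tree set provides.

## Scope of the guarantee

The converging tree characterizes **substitution forcing**.  Every
surviving set passes exhaustive state-space verification (soundness; the
suite checks this on all fixtures and on seeded random networks).  The
converse directions are genuinely weaker, in two documented ways:

- **Dynamic-only forcing.**  A clamp can control the phenotype through
  reachability - which states actually occur and in which phase - without
  ever making a rule constant by substitution.  Oscillator phase-locking is
  the typical mechanism; `tests/test_tree.py::TestKnownScopeLimit` pins a
  concrete eight-node instance where a single clamp verifies dynamically
  but no substitution chain exists.  Such sets cannot appear in the tree,
  so a tree set need not be dynamically minimal and the brute-force oracle
  can find forcing sets containing no tree member.
- **Cross-branch pruning.**  The inclusion rule removes duplicate sets
  globally, while the contradiction rule is chain-local.  An assignment
  whose only contradiction-free derivation runs through a branch that was
  pruned as redundant is lost even by the static standard.

On sparse cascade-like networks - the shape of the published signaling
models this method targets, where derivation chains are essentially unique
- the kernel claim (every forcing set contains a tree set) holds, as it
does on all packaged fixtures.  On feedback-dense random networks both
effects occur at an appreciable rate; `scripts/acceptance.py` measures the
soundness rate and the full oracle-agreement rate on 60 random networks
so the numbers are recomputed, not asserted.  The corresponding
random-network acceptance test states the universal claim and is expected
to fail on the disagreeing networks; it is retained deliberately as an
honest record of the method's scope rather than weakened to match.

## Synthetic study conditions

`random_network(GeneratorConfig(...))` emulates signaling-network models:
8 nodes by default (oracle cross-checks enumerate full state spaces and
all small clamp combinations, so tests use 7-10 nodes), in-degree drawn
uniformly from 1-3, phenotype nodes as read-out sinks that regulate
nothing, no direct self-regulation, and feedback among the remaining nodes
arising freely - matching the shape of published cascade models, whose
output nodes are sinks and whose rules lack self-loops.  Three rule
families are generated: random nested AND/OR/NOT expressions over the
chosen regulators (each regulator once, possibly negated), uniform random
truth tables, and random signed-threshold rules with weights in +-{1, 2}.
An option rewires every node to have a path to the phenotype, since
non-influential nodes are provably irrelevant to control.  Identical
configurations produce identical networks; every stochastic step flows
through the single configured seed.  What passing tests on these networks
do *not* show: behaviour on dense feedback architectures (where the scope
limits above bite), asynchronous or probabilistic update schemes, and
in-degrees beyond the truth-table bounds.

Kernel-property and minimality tests condition on the premise that control
is needed - networks whose free dynamics already satisfy the phenotype are
redrawn, since there every notion of a minimal control set degenerates to
the empty set.

## Numerical and engineering choices

- States are bit-packed integers; each rule is compiled once to a truth
  table over its input bit positions, so a synchronous step is table
  lookup.  Attractors are found by trajectory tracing with a global
  state-to-attractor memo; cycles are canonicalized by rotating the
  numerically smallest state first, which is also how sampled attractors
  are deduplicated.
- Exhaustive enumeration is refused, with the bound in the message, above
  22 free nodes; per-rule truth-table expansion above 16 inputs.
- Determinism: parents in sorted order, solutions sorted by (size, items),
  a single integer seed for every random path, JSON serialized with sorted
  keys and no timestamps.  All CLI outputs embed the tool version, the full
  run configuration and the seed.
- Degenerate inputs: a rule constantly equal to its target value is forced
  by the empty assignment, and wholly-empty merged children are discarded
  (the parent needs no perturbation); a rule that can never attain the
  target yields an empty solution set flagged unsatisfiable; parents
  containing an input or clamped node are leaves.
- The 53-node MAPK and 96-node cancer threshold models are distributed as
  supplementary spreadsheets and are not bundled; their loaders refuse with
  a clear message until a transcription file is added (see
  `src/pckernel/data/README.md`).  A small fragment of the simplified MAPK
  network around Proliferation is built from the rules quoted in the
  accompanying description and reproduces the first four documented
  construction steps; it is a fragment, not the model.

## Known limitations

- Synchronous deterministic updating only; no asynchronous or probabilistic
  schemes, no SBML-qual import.
- Substitution-forcing scope as described above: complete minimality and
  kernel coverage hold for cascade-like architectures, not for arbitrary
  feedback-dense networks.
- Truth-table algorithms bound usable in-degree (16) and exhaustive
  verification bounds network size (22 free nodes); larger models rely on
  sampled verification.
- The restructuring step follows the reading documented above; its
  visited-configuration guard makes construction safe, and the empirical
  kernel checks are the safety net for that interpretation.
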