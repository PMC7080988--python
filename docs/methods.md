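# Methods

## Model and assumptions

The model is a deterministic synchronous Boolean network on 29 named
molecules.  Each node is active (1) when its concentration or activity
exceeds an effect threshold; all nodes update simultaneously.  The
synchronous assumption means the model resolves neither reaction-rate
differences nor race conditions: cyclic attractors should be read as
sustained oscillatory programs (here driven by three negative feedback
circuits: SNAI1 self-inhibition, NOTCH→NRARP⊣NOTCH, SMAD1→SMAD6⊣SMAD1),
not as timed oscillations.

Seven nodes — DLL4, FGF2, HIF1a, PDGF_AB, TGFB, WNT5b, WNT7a — carry
identity rules and represent the extracellular microenvironment.  Their
bits never change, so the dynamics splits exactly into 128 independent
subsystems, one per microenvironment; this both pigeonholes at least 128
attractors and is the backbone of the enumeration algorithm.

Rules are compiled to truth tables at load time; the expression strings
are kept for `.bnet` export.  Conventions fixed once and asserted in
tests: node index 0 (AP1) is the least significant bit of the integer
state encoding, and truth-table rows read the regulator tuple as a binary
number with the first-listed regulator most significant.  One rule source
token (`VEGF2`, in the ETS1 equation) names no node of the model; it is
read as VEGFR2 — the receptor whose signalling activates ETS1, consistent
with the co-activation of ETS1 and VEGFR2 in every Tip attractor — and
the substitution is recorded in the network metadata rather than applied
silently.

## Exact attractor enumeration

Within one microenvironment the engine first *percolates constants*: the
source bits are fixed; any rule that becomes a constant function once its
already-determined regulators are fixed determines its node, and the
process iterates to a fixed point.  A node determined after `r` rounds
holds its constant from time `r` onward in **every** trajectory of that
environment, so all cycles lie in the subspace where determined nodes sit
at their constants — restricting to it is exact, not an approximation.
The surviving free nodes (typically 8–14 of the 22 non-source nodes)
span a reduced subspace that is enumerated exhaustively: the one-step
successor array is built vectorized from the restricted truth tables,
`f` pointer-doubling passes send every state onto its cycle, and cycles
are walked explicitly and canonicalized (rotation to the smallest packed
state).  Equality of attractors is equality of canonical keys; the atlas
is ordered by (environment id, canonical key) for reproducible output.

The same per-environment structures resolve arbitrary initial states:
a batch of states is stepped `r_max` times (the percolation depth, so all
constants have settled), projected to reduced coordinates, and looked up
in the pointer-doubled basin map.  This one engine powers trap-space
sampling, the cell-fate transition protocol, and the no-op identity
checks.  Correctness is established two ways: on all fixture networks of
up to 12 nodes the enumeration equals brute-force simulation from every
state using the scalar evaluation path, and on the bundled model the
per-environment census is cross-checked against the independently built
full `2^22` successor map (`dynamics.build_successor_map`, retained for
that purpose and for users who want the unreduced map).

Clamped (mutant) nodes have constant rules and are absorbed by the same
percolation, so knockout/overexpression scans reuse the engine unchanged.
A state-count budget (default `2^26` per environment) guards against
networks whose reduced subspace stays large.

## Classification

Marker predicates are Boolean expressions over node names, evaluated on
states; a cyclic attractor carries a label only if every cycle state
does (symmetrically for presence and absence markers):

| label | predicate |
|---|---|
| EC | FLI1 ∧ GATA2 |
| MC | ZEB1 ∧ ZEB2 ∧ TWIST1 ∧ (SNAI1 ∨ SNAI2) |
| Phalanx | EC ∧ ¬NRP1 ∧ ¬CTNNB ∧ ¬SNAI1 ∧ ¬SNAI2 |
| Tip | FLI1 ∧ GATA2 ∧ NRP1 ∧ ETS1 |
| Stalk | FLI1 ∧ GATA2 ∧ ¬NRP1 ∧ CTNNB *(configurable)* |

The overlapping labels are dissected into nine disjoint classes
(nECsnMCs, EConly, Phalanx, nMCStalk, MCStalk, nMCTip, MCTip, MCEConly,
MCsnECs).  Tip and Stalk are disjoint through NRP1; Phalanx excludes MC
through SNAI1/SNAI2 (asserted exhaustively at classifier load); with a
permissive Stalk marker a Phalanx attractor could also satisfy Stalk, in
which case Phalanx takes precedence so the nine classes stay a partition.

**Stalk marker calibration.** The biological Stalk marker, JAG1, is not a
network node, so the positive marker is proxied by the canonical-Wnt
drivers that induce it.  All three candidates ({LEF1, CTNNB, CTNNB∧LEF1})
are available in `ClassifierConfig`; CTNNB is the default because (a) on
the wild-type atlas CTNNB and CTNNB∧LEF1 give identical classifications
(every wild-type Stalk attractor co-expresses CTNNB and LEF1, so LEF1
appears in the emergent Stalk signature either way), and (b) in the
single-mutation scan CTNNB∧LEF1 makes LEF1 loss-of-function spuriously
abolish the Stalk classes, while CTNNB reproduces the reference mutant
classification exactly; LEF1 alone misclassifies the wild type.

## Trap-space estimation

The trap space of a class is the union of basins of its attractors.  Its
size is estimated by drawing initial states uniformly from all `2^29`
states (sources included, so microenvironments are weighted equally),
resolving each to its attractor with the exact engine, and reporting the
labelled fraction with binomial standard errors.  The generator is
NumPy's PCG64 with an explicit seed (default 42), recorded in the output.
The default of 10⁷ samples gives a standard error of ~0.005 percentage
points on the endothelial fraction; estimates at different sample sizes
agree within combined errors (property-tested).

## Structural analysis

A regulator is a functional activator (inhibitor) of its target if some
pair of regulator configurations differing only in that regulator raises
(lowers) the rule output; the scan runs over the `2^k` truth-table rows,
which is equivalent to scanning the full state space because a rule
depends only on its regulators.  One example witness row pair per sign is
stored on each edge and re-checkable.  The identity self-loops of the
seven source nodes encode constancy of the inputs rather than a
regulatory mechanism, so the interaction graph excludes them by default
(giving the model's 77 regulatory interactions; a flag restores all 84
self-loop-inclusive edges).

Feedback circuits are the elementary directed cycles of that graph
(Johnson's algorithm via networkx; self-loops count as length-1
circuits); a circuit is negative iff it contains an odd number of
inhibitions.  Circuit *functionality* uses a single-context witness
criterion: the circuit is functional if one assignment of the regulators
outside the circuit simultaneously gives every circuit edge a sign
witness (circuit-internal regulators other than the edge source are
existentially quantified).  This is deliberately lighter than the full
context algebra of dedicated logical-modelling tools and flags more
circuits functional (32 of 74 here, including all three negative circuits
that generate the cyclic behavior); replicating the full algebra is out
of scope, and both numbers are reported rather than forced to agree.

## Perturbation protocols

* **Mutation scans** clamp a node's rule to a constant.  "Qualitative
  behavior" is the set of nine classes represented by at least one
  attractor; a mutant is wild-type-like iff its set equals the
  unperturbed one, and per-class robustness is the fraction of the 58
  single clamps that keep the class represented.
* **Rule-flip robustness** samples a node uniformly (optionally: rows
  pooled across nodes, since "a random rule component" is ambiguous),
  flips one uniformly chosen truth-table output bit, and re-enumerates.
  The default population for desk runs is smaller than the reference
  100,000-instance protocol; the instance count is a parameter.
* **State-noise sensitivity** of component `f_i` at flip count `k` is the
  fraction of random states whose one-step output for `i` changes when
  `k` distinct uniformly chosen input bits flip (defaults: 500,000 states
  at `k=1`, 20,000 per `k` for 2–15).  For an identity rule the exact
  value is `k/n`, which the Monte Carlo must hit within 3 binomial
  standard errors — a built-in calibration of the sampler.
* **Cell-fate transitions** overwrite the bits of the ten probe nodes
  (the seven microenvironment ligands plus FLI1, GATA2, VEGFA) in an
  attractor state with each of the 1024 patterns and let the system relax
  freely.  The overwrite is instantaneous, not a sustained clamp; for the
  seven source nodes the two coincide.  Because the reference protocol
  does not specify the start state of a cyclic attractor, both "first
  canonical state" (default) and "every cycle state" modes are provided;
  a pattern counts toward a (source→destination) class transition if it
  moves at least one attractor of the source class.

## Numerical and implementation choices

States are packed into unsigned 64-bit integers; all bulk operations are
vectorized NumPy (per-environment arrays of at most `2^26` entries).
Trajectory convergence uses a visited-hash cycle detector with a default
bound of 10,000 steps (transients in this model are tens of steps; the
bound only guards user-supplied networks).  All stochastic operations
take an explicit seed and record it in their output; identical seeds give
byte-identical outputs.  Degenerate inputs (empty cycles, conflicting
clamps, non-source environment assignments, undeclared `.bnet` factors)
raise typed errors rather than propagating bad state.

## Limitations

The model is single-cell and qualitative: no multicellular or spatial
effects (lateral inhibition is only mimicked through the DLL4 input), no
shear-stress mechanics, no continuous concentrations or timing, and EC/MC
markers outside the network (VE-cadherin, PECAM1, αSMA, …) are inferred
from the included transcription factors, not computed.  Synchronous
updating can create artifact cycles that asynchronous semantics would
break; conclusions that depend on the precise period of cyclic attractors
should be read with that in mind.  The circuit-functionality criterion is
a documented approximation (above).  Trap-space sizes are Monte Carlo
estimates with the quoted errors, not exact basin counts.
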