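# Methods

## The modeling framework

`mechbool` simulates Boolean regulatory networks: each molecular species or
process is a node that is ON (expressed/active) or OFF, and updates through
a logic gate over its regulators.  Environmental conditions — ECM
stiffness, growth factors, cell density, external ligands — are encoded as
*input* nodes with no regulators of their own.  Inputs are held fixed by
the dynamics, so the full state space partitions into one sub-space per
input combination ("environment context"), and the attractor repertoire is
mapped context by context.

A node is classified as an input when its rule is an identity self-loop
(`A *= A`), when it appears as a regulator but has no rule, or when it is
declared explicitly (`# inputs: A, B`).  The loader records which mechanism
identified each input, since deposited rule files differ in convention.

Truth tables are compiled from the rule expressions by exhaustive
evaluation over all 2^k regulator combinations, with the combination index
reading the regulators in declaration order, first regulator as the most
significant bit.  Compilation refuses gates above 20 regulators (tables
would exceed a million rows); everything in this package's scope is far
below that.

## Update engines

Four engines share one contract — inputs never change within a context,
and all randomness flows through a single seeded generator per experiment
(order shuffles first, then noise draws, each step), so every run replays
bitwise from its seed:

* **synchronous** — all non-input nodes recompute simultaneously from the
  previous state; deterministic, used for attractor detection.
* **noisy synchronous** — synchronous step, then each non-input bit flips
  independently with probability `p_noise` (default 0.02, the value used
  for all sampling runs).  Noise never touches inputs: noisy inputs would
  leak trajectories between environment sub-spaces during sampling.
* **random-order asynchronous** — nodes update sequentially in a fresh
  uniformly random order each step, each node seeing all earlier updates
  within the step.
* **biased asynchronous** — as above, but a small list of
  condition-dependent rules pins nodes to the start or end of the order
  (start-rule nodes first in listed order; end-rule nodes last, first
  listed updated last).  Conditions (`if_on`, `if_off`, `always`) are
  evaluated on the state at the start of the step, before any node has
  moved, because they describe the node's "correct" pre-update state.  A
  node triggered by both lists goes to the start, with a logged warning.
  This scheme suppresses biologically impossible event orderings in
  cell-cycle logic (e.g. cytokinesis resolving before anaphase) while
  keeping the rest of the timing stochastic.

Fixed points are invariant under all four engines by construction; this is
property-tested across fixture models and sampled orders.

## Attractor detection and sampling

Attractor detection is synchronous-only: the deterministic map gives every
state a unique fate.  `descend_to_attractor` iterates the map with
hash-based cycle detection (step budget 10^6) and returns the cycle in
canonical form: rotated so its lexicographically smallest state comes
first, then content-hashed together with the context.  Identifiers are
therefore stable across runs and machines — two independent samplings of
the same model assign the same ID to the same attractor.  (Run-local
integer IDs are still written to `id_map.csv` for compact reference in
experiment files.)

The sampler runs, per context, `N_rnd` noisy trajectories of `N_series`
steps from uniform random initial states (defaults 200 and 5), descending
deterministically from every visited state — including the initial one, a
harmless superset of pausing only at later states — and, with the
neighborhood scan enabled, from every single non-input-bit flip of it.
The scan reaches small basins the noise never enters; flipping input bits
is excluded because it would exit the context.  Basin membership is
memoized per context, which makes repeated descents cheap without changing
any result.

`convergence_grid` re-runs the sampler over an `(N_rnd, N_series)` grid
(default 15×15 in steps of 5 at `p_noise` 0.02) and reports per-cell
attractor counts as a convergence heat map plus the union attractor table.
`environment_transition_map` follows each attractor through every
single-input flip and descends in the new context — an efficient way to
discover live states in environments dominated by large apoptotic basins;
targets the sampler missed are flagged and added.

The exhaustive enumerator (the test oracle) descends from every state of a
context sub-space using a vectorized bulk successor table, and refuses
above 22 non-input nodes.

## Gate surgery

Removing regulators from a gate (module isolation, link deletion) freezes
them ON or OFF.  Among all 2^|removed| frozen assignments the reduction
keeps those under which every remaining regulator is still functional
(changes the output somewhere) — a hard filter, relaxed only when no
assignment passes it — and then maximizes the gate entropy
H_G = −p·log p − (1−p)·log(1−p) over the OFF-output fraction p.  Natural
log; H(0) = H(1) = 0 by continuity; the base does not affect the argmax.
Ties break on the lexicographically smallest frozen assignment (removed
regulators in declaration order, 0 before 1), making the operation fully
deterministic.  All removed regulators of one gate are frozen in a single
joint choice; freezing them one at a time can give a different gate and is
deliberately not what this module does.  Removing every regulator yields a
constant gate at the majority output (tie → OFF), with a warning.

Module isolation applies this reduction per module node to its
out-of-module regulators.  Mutant ensembles apply three error types: nodes
locked to a random constant, random links removed (gates reduced as
above), and single truth-table rows flipped.  Environment inputs are never
mutated so that ensembles stay comparable across environment scans.

## Perturbations

Input schedules support constants, per-step ON-probabilities
(non-saturating signals near their response threshold; draws i.i.d. across
steps), and pulses (baseline flipped during a window).  Partial
knockdown/overexpression forces a non-input node OFF/ON with a per-step
probability, otherwise leaving it to its rule.  Per-step order: inputs are
drawn, the engine updates, then KD/OE overrides apply — an override wins
within its step, matching the dominance semantics of forcing a node.

The pulse protocol is fixed at 50 baseline steps, the flipped window, and
a return to baseline out to 400 total steps; durations above 350 are
rejected.  Probabilities 0 and 1 behave exactly as constants.

## Phenotypes and cell-cycle events

Phenotype signatures are conjunctions of node-state constraints, read from
`Name = (node=bit, ...)` text.  The packaged set covers contact-inhibited
(CIP/noCIP), migratory, and the EMT trio (Epithelial, Hybrid_EM,
Mesenchymal); the trio is mutually exclusive, so its dwell fractions sum to
at most 1, the deficit being time in transition.

Cell-cycle events are declarative patterns over marker transitions
(trigger edge + state requirements + pulses that must/must not have
occurred since a reset marker), shipped as data with defaults aimed at the
deposited models' marker names:

* **normal cycle** — cytokinesis pulse with attached kinetochores,
  following a CyclinB pulse;
* **G2→G1 reset** — the 4N-DNA flag rises with no CyclinB pulse since the
  last cytokinesis (re-replication from G2);
* **aberrant mitosis** — a Cdc20 pulse (metaphase→anaphase) without
  kinetochore attachment;
* **failed cytokinesis** — a new replication round after mitotic exit with
  no cytokinesis in between.

These operational definitions are validated on scripted trajectories; on a
real model they are a modeling choice, and both the patterns and the
apoptosis criterion (default: an `Apoptosis`/`Apoptotic` signature or
node locked ON) are configurable.

Long-run statistics accumulate live-cell time across apoptosis-triggered
restarts (restart state: the experiment's initial condition) until a
minimum live budget is reached (default 50,000 steps; figure-style runs
use 100,000).  Dwell fractions are per-signature dwell over live time;
event rates are occurrences per 21 live steps, the minimum length of one
full proliferative cycle in the deposited models, so a rate of 1 means
"every cycle".  If live time cannot accumulate (an always-lethal
environment) the result is flagged degenerate and fractions are NaN, never
silently zero.

## The EMT-switch fixture

The packaged switch encodes the tri-stable EMT core over ten marker nodes
(miR_34, miR_200, SNAI1, Twist1, SNAI2, ZEB1, ZEB1_H, N_bcatenin,
N_bcatenin_H, Ecadherin_mRNA) plus three frozen former regulators: NFkB
ON, GSK3 OFF (a mitogenic context), and c_Myb ON.  Two-level species use
the staircase convention — the `_H` node implies the base node is ON.  The
switch has exactly three synchronous attractors, all fixed points:
epithelial (miR-34, miR-200, E-cadherin ON; all EMT drivers OFF), hybrid
E/M (miR-34 OFF, miR-200 and E-cadherin still ON, Snai1/Twist/Snai2 ON
with moderate Zeb1 and moderate nuclear β-catenin), and mesenchymal (full
flip, with high Zeb1 and high nuclear β-catenin).

The miR-200 maintenance logic is the one genuinely open encoding choice:
miR-200 can be protected either through p21 interference with Zeb1 or
through c-Myb-driven transcription, with high Zeb1 overriding both.  The
fixture freezes c_Myb ON, which yields `miR_200 *= not ZEB1_H` after
freezing and reproduces the published tri-stable structure.  The test
suite documents the alternative: isolating the ten marker nodes alone
re-freezes c_Myb by the entropy rule's functionality filter (which prefers
keeping Snai1/Twist/Zeb1 functional, i.e. c_Myb OFF), and the hybrid state
is then no longer stable — only the terminal epithelial and mesenchymal
states survive.  This sensitivity is a property of the biology as encoded,
not an artifact.

## Synthetic test networks

Random Boolean networks (`generate_random_network`) draw, per non-input
node, 1..K regulators uniformly and a Bernoulli(bias) truth table;
defaults K = 3, bias 0.5, which at the test sizes (≤12 non-input nodes,
≤3 inputs) produce a realistic mix of fixed points, cycles, and small
basins — the regime where the neighborhood scan matters.  They emulate the
logical structure of regulatory networks, not their degree distribution or
the modular organization of the deposited models, so sampler tests on them
certify the algorithm, not biological conclusions.

## Problem sizes and numerics

The test suite and the acceptance script run the sampler–oracle comparison
on 100 random networks at the default sampling parameters, the
gate-reduction brute force on 500 random 4-input gates × all two-regulator
removals, fixed-point invariance over ≥1,000 sampled update orders, and
concentration checks (noise, schedule, and KD/OE frequencies) at 2·10^4
draws against 3σ binomial bounds.  Statistics demos use live budgets of
10^3–2·10^4 steps, which keep the stochastic checks comfortably inside
their tolerance bands.  Entropy comparisons round to 12 decimals before
the argmax so that exact symmetric ties (p versus 1−p) break by the
lexicographic rule rather than by floating-point noise.

## Limitations

* Full-model analyses (136/150-node counts, the 21-step proliferative
  cycle, the 95/95 environment phenotype mix) require the deposited rule
  files, which are not re-derived here; the corresponding checks skip with
  an explicit report when the files are absent.
* Attractor detection is synchronous-only; asynchronous attractors
  (loose attractors, complex asynchronous dynamics) are out of scope, as
  are trap-space/stable-motif methods and exact basin-size bookkeeping.
* The scheduler models inputs as i.i.d. per step; temporally correlated
  environments are not supported.
* Update bias lists are taken as given; no attempt is made to infer
  priorities beyond the declared rules.
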