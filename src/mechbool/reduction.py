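"""Gate surgery: frozen-input reduction, module isolation, mutant ensembles.

When regulators are removed from a gate (to isolate a sub-network or to
delete a regulatory link), the removed regulators are assumed frozen ON or
OFF.  The frozen combination is chosen so that (a) every remaining
regulator stays functional — still changes the output for some input
combination — if any combination achieves that, and (b) among those, the
gate-fragment entropy H_G = −p·log p − (1−p)·log(1−p) over the OFF-output
fraction p is maximal.  Ties break on the lexicographically smallest frozen
assignment (removed regulators in declaration order, 0 before 1), making
the reduction deterministic.  All removed regulators of a gate are frozen
in one joint choice (all-at-once semantics); removing them one at a time
may differ and is not what this module does.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import BooleanNetworkModel, NodeSpec

__all__ = [
    "MutantSpec",
    "gate_entropy",
    "reduce_gate_frozen_inputs",
    "isolate_module",
    "generate_mutant_ensemble",
]

log = logging.getLogger(__name__)

MUTANT_KINDS = ("node_lock", "link_removal", "gate_flip")


@dataclass(frozen=True)
class MutantSpec:
    """Ensemble request: what to perturb, how many errors, how many mutants."""

    kind: str
    errors_per_network: int
    ensemble_size: int
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in MUTANT_KINDS:
            raise ValueError(f"kind must be one of {MUTANT_KINDS}, got {self.kind!r}")
        if self.errors_per_network < 0 or self.ensemble_size < 0:
            raise ValueError("errors_per_network and ensemble_size must be >= 0")


def gate_entropy(table) -> float:
    """H_G of a truth table: −p·ln p − (1−p)·ln(1−p), p = OFF fraction.

    H(0) = H(1) = 0 by continuity; the log base does not affect argmax.
    """
    table = np.asarray(table)
    p = float(np.count_nonzero(table == 0)) / table.size
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log(p) - (1.0 - p) * math.log(1.0 - p)


def _table_to_expression(regulators: tuple[str, ...], table) -> str:
    """Disjunctive normal form reproducing ``table`` bit-for-bit."""
    table = list(table)
    if all(b == 0 for b in table):
        return "0"
    if all(b == 1 for b in table):
        return "1"
    k = len(regulators)
    terms = []
    for idx, out in enumerate(table):
        if not out:
            continue
        lits = []
        for j, r in enumerate(regulators):
            bit = (idx >> (k - 1 - j)) & 1
            lits.append(r if bit else f"not {r}")
        terms.append("(" + " and ".join(lits) + ")")
    return " or ".join(terms)


def _reduced_table(spec: NodeSpec, removed_pos: list[int],
                   frozen_bits: tuple[int, ...]) -> np.ndarray:
    """Table over the remaining regulators with removed ones frozen."""
    k = spec.k
    kept_pos = [j for j in range(k) if j not in removed_pos]
    table = np.asarray(spec.truth_table, dtype=np.uint8)
    out = np.empty(2 ** len(kept_pos), dtype=np.uint8)
    for i in range(2 ** len(kept_pos)):
        idx = 0
        kept_iter = iter(range(len(kept_pos) - 1, -1, -1))
        frozen = dict(zip(removed_pos, frozen_bits))
        for j in range(k):
            if j in frozen:
                bit = frozen[j]
            else:
                shift = next(kept_iter)
                bit = (i >> shift) & 1
            idx = (idx << 1) | bit
        out[i] = table[idx]
    return out


def _regulator_functional(table: np.ndarray, k: int, j: int) -> bool:
    """Does regulator j (MSB-first position) ever change the output?"""
    bit = 1 << (k - 1 - j)
    for idx in range(2 ** k):
        if idx & bit:
            continue
        if table[idx] != table[idx | bit]:
            return True
    return False


def reduce_gate_frozen_inputs(spec: NodeSpec, removed) -> NodeSpec:
    """Remove regulators from a gate by freezing them optimally.

    Enumerates all 2^|removed| frozen assignments in lexicographic order
    (removed regulators in declaration order, 0 before 1); keeps those under
    which every remaining regulator is functional if any exist; returns the
    first assignment maximizing the gate entropy H_G.

    Removing every regulator returns a constant gate frozen to the majority
    output (tie → OFF), with a logged warning.
    """
    removed = list(removed)
    if not removed:
        raise ValueError("removed must be a nonempty subset of the regulators")
    for r in removed:
        if r not in spec.regulators:
            raise ValueError(f"{r!r} is not a regulator of {spec.name!r}")
    if len(set(removed)) != len(removed):
        raise ValueError("duplicate entries in removed")

    remaining = tuple(r for r in spec.regulators if r not in removed)
    if not remaining:
        on = sum(spec.truth_table)
        majority = 1 if on * 2 > len(spec.truth_table) else 0
        log.warning("node %s: all regulators removed; frozen to constant %d "
                    "(majority output, tie -> OFF)", spec.name, majority)
        return NodeSpec(name=spec.name, regulators=(), expression=str(majority),
                        truth_table=(majority,))

    removed_decl = [r for r in spec.regulators if r in removed]
    removed_pos = [spec.regulators.index(r) for r in removed_decl]
    m = len(remaining)

    candidates = []  # (frozen_bits, table, all_functional)
    for frozen_bits in itertools.product((0, 1), repeat=len(removed_decl)):
        table = _reduced_table(spec, removed_pos, frozen_bits)
        functional = all(_regulator_functional(table, m, j) for j in range(m))
        candidates.append((frozen_bits, table, functional))
    pool = [c for c in candidates if c[2]] or candidates

    best = None
    best_h = -1.0
    for frozen_bits, table, _ in pool:  # lex order; first strict max wins
        h = gate_entropy(table)
        if h > best_h + 1e-12:
            best, best_h = (frozen_bits, table), h
    frozen_bits, table = best
    return NodeSpec(name=spec.name, regulators=remaining,
                    expression=_table_to_expression(remaining, table),
                    truth_table=tuple(int(b) for b in table))


def isolate_module(model: BooleanNetworkModel, module_nodes) -> BooleanNetworkModel:
    """Extract a self-contained sub-model over ``module_nodes``.

    Each module node loses its regulators outside the module via
    :func:`reduce_gate_frozen_inputs`; nodes reduced to zero regulators
    become constant gates frozen at the selected value.
    """
    module = list(dict.fromkeys(module_nodes))
    if not module:
        raise ValueError("module_nodes must be nonempty")
    unknown = [n for n in module if n not in model.node_index]
    if unknown:
        raise ValueError(f"unknown module nodes: {unknown}")
    module_set = set(module)
    specs = []
    inputs = []
    for name in (n.name for n in model.nodes if n.name in module_set):
        spec = model.nodes[model.node_index[name]]
        if model.is_input(name):
            specs.append(spec)
            inputs.append(name)
            continue
        outside = [r for r in spec.regulators if r not in module_set]
        if outside:
            spec = reduce_gate_frozen_inputs(spec, outside)
        specs.append(spec)
    return BooleanNetworkModel(specs, name=f"{model.name}_module",
                               input_nodes=tuple(inputs),
                               input_detection={i: "inherited" for i in inputs})


# ---------------------------------------------------------------------------
# mutant ensembles

def _lock_node(spec: NodeSpec, bit: int) -> NodeSpec:
    return NodeSpec(name=spec.name, regulators=(), expression=str(bit),
                    truth_table=(bit,))


def _flip_row(spec: NodeSpec, row: int) -> NodeSpec:
    table = list(spec.truth_table)
    table[row] ^= 1
    return NodeSpec(name=spec.name, regulators=spec.regulators,
                    expression=_table_to_expression(spec.regulators, table),
                    truth_table=tuple(table))


def generate_mutant_ensemble(model: BooleanNetworkModel, spec: MutantSpec,
                             rng: np.random.Generator | int | None = None):
    """Yield ``ensemble_size`` independently mutated copies of the model.

    * ``node_lock``: n random non-input nodes permanently locked to a random
      bit each.
    * ``link_removal``: n random regulatory links removed; affected gates
      reduced via the frozen-input rule (all removed links of a gate in one
      joint reduction).
    * ``gate_flip``: n random non-input nodes each get exactly one random
      truth-table row's output flipped.

    Environment inputs are never targeted, so mutant ensembles stay
    comparable across environment scans.
    """
    if rng is None and spec.seed is not None:
        rng = spec.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    targets = [model.nodes[i].name for i in model.noninput_indices]
    links = [(r, t) for t in targets
             for r in model.nodes[model.node_index[t]].regulators]
    n = spec.errors_per_network
    if spec.kind in ("node_lock", "gate_flip") and n > len(targets):
        raise ValueError(f"{n} errors requested but only {len(targets)} "
                         "non-input nodes available")
    if spec.kind == "link_removal" and n > len(links):
        raise ValueError(f"{n} link removals requested but the model has only "
                         f"{len(links)} links into non-input nodes")

    for _ in range(spec.ensemble_size):
        nodes = {s.name: s for s in model.nodes}
        if spec.kind == "node_lock":
            chosen = rng.choice(len(targets), size=n, replace=False)
            for ti in chosen:
                name = targets[int(ti)]
                nodes[name] = _lock_node(nodes[name], int(rng.integers(0, 2)))
        elif spec.kind == "gate_flip":
            chosen = rng.choice(len(targets), size=n, replace=False)
            for ti in chosen:
                name = targets[int(ti)]
                row = int(rng.integers(0, len(nodes[name].truth_table)))
                nodes[name] = _flip_row(nodes[name], row)
        else:  # link_removal
            chosen = rng.choice(len(links), size=n, replace=False)
            by_target: dict[str, list[str]] = {}
            for li in chosen:
                reg, tgt = links[int(li)]
                by_target.setdefault(tgt, []).append(reg)
            for tgt, regs in by_target.items():
                nodes[tgt] = reduce_gate_frozen_inputs(nodes[tgt], regs)
        yield BooleanNetworkModel([nodes[s.name] for s in model.nodes],
                                  name=f"{model.name}_mut", bias=model.bias,
                                  input_nodes=model.input_nodes,
                                  input_detection=model.input_detection)
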