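"""Update engines: synchronous, noisy synchronous, (biased) asynchronous.

All engines hold environmental inputs fixed at the values given by the
context; noise and update-order shuffling never touch inputs.  A single
seeded ``numpy.random.Generator`` per experiment supplies, in documented
order, (1) the update-order shuffle of each asynchronous step and (2) the
per-node noise draws of each noisy step, so runs replay exactly per seed.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import ALWAYS, IF_OFF, IF_ON, BooleanNetworkModel, UpdateBias

__all__ = [
    "ENGINES",
    "apply_context",
    "synchronous_step",
    "noisy_synchronous_step",
    "asynchronous_step",
    "biased_asynchronous_step",
    "run_trajectory",
    "successor_codes",
    "encode_state",
    "decode_state",
]

log = logging.getLogger(__name__)

ENGINES = ("sync", "noisy", "async", "biased-async")


def _context_arrays(model: BooleanNetworkModel, context: dict[str, int]):
    idx = model.input_indices
    vals = np.array([1 if context[model.nodes[i].name] else 0 for i in idx],
                    dtype=np.uint8)
    return idx, vals


def apply_context(model: BooleanNetworkModel, state: np.ndarray,
                  context: dict[str, int]) -> np.ndarray:
    """Return a copy of ``state`` with input nodes set from ``context``."""
    out = state.astype(np.uint8, copy=True)
    idx, vals = _context_arrays(model, context)
    out[idx] = vals
    return out


def _eval_node(model: BooleanNetworkModel, i: int, state: np.ndarray) -> int:
    regs = model._regs[i]
    if len(regs) == 0:
        return int(model._tables[i][0])
    idx = int(state[regs] @ model._weights[i])
    return int(model._tables[i][idx])


def synchronous_step(model: BooleanNetworkModel, state: np.ndarray,
                     context: dict[str, int]) -> np.ndarray:
    """All non-input nodes recompute simultaneously from the previous state."""
    new = state.astype(np.uint8, copy=True)
    for i in model.noninput_indices:
        new[i] = _eval_node(model, i, state)
    idx, vals = _context_arrays(model, context)
    new[idx] = vals
    return new


def noisy_synchronous_step(model: BooleanNetworkModel, state: np.ndarray,
                           context: dict[str, int], p_noise: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Synchronous step, then each non-input bit flips independently with
    probability ``p_noise`` (the incorrect gate output); inputs never flip."""
    if not 0.0 <= p_noise <= 1.0:
        raise ValueError(f"p_noise must be in [0, 1], got {p_noise}")
    new = synchronous_step(model, state, context)
    if p_noise > 0.0:
        flips = rng.random(len(model.noninput_indices)) < p_noise
        ni = model.noninput_indices[flips]
        new[ni] ^= 1
    return new


def _bias_order(model: BooleanNetworkModel, state: np.ndarray,
                bias: UpdateBias | None, rng: np.random.Generator) -> np.ndarray:
    """Update order for one biased asynchronous step.

    Triggered start-rule nodes come first in listed order; triggered
    end-rule nodes come last with the first listed updated last; the rest
    are shuffled uniformly in between.  Conditions are evaluated on the
    state at the start of the step.  A node triggered by both lists goes to
    the start (logged once per call site).
    """

    def triggered(rules):
        out = []
        for name, cond in rules:
            i = model.node_index[name]
            if (cond == ALWAYS or (cond == IF_ON and state[i]) or
                    (cond == IF_OFF and not state[i])):
                out.append(i)
        return out

    start: list[int] = []
    end: list[int] = []
    if bias is not None:
        start = triggered(bias.start_rules)
        end = triggered(bias.end_rules)
        both = set(start) & set(end)
        if both:
            names = sorted(model.nodes[i].name for i in both)
            log.warning("nodes %s selected by both start and end bias rules; "
                        "start precedence applied", names)
            end = [i for i in end if i not in both]
        end = end[::-1]  # first listed updated last
    pinned = set(start) | set(end)
    middle = np.array([i for i in model.noninput_indices if i not in pinned],
                      dtype=np.intp)
    rng.shuffle(middle)
    order = [i for i in start if not model._is_input[i]]
    order += middle.tolist()
    order += [i for i in end if not model._is_input[i]]
    return np.array(order, dtype=np.intp)


def biased_asynchronous_step(model: BooleanNetworkModel, state: np.ndarray,
                             context: dict[str, int],
                             bias: UpdateBias | None,
                             rng: np.random.Generator) -> np.ndarray:
    """Random-order asynchronous step with optional condition-dependent bias.

    Nodes update sequentially, each seeing all earlier updates within the
    step.  With ``bias=None`` this is the plain random-order scheme.
    """
    cur = apply_context(model, state, context)
    order = _bias_order(model, cur, bias, rng)
    for i in order:
        cur[i] = _eval_node(model, i, cur)
    return cur


def asynchronous_step(model: BooleanNetworkModel, state: np.ndarray,
                      context: dict[str, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Plain random-order asynchronous step (no bias)."""
    return biased_asynchronous_step(model, state, context, None, rng)


def _step(model, state, context, engine, rng, p_noise, bias):
    if engine == "sync":
        return synchronous_step(model, state, context)
    if engine == "noisy":
        return noisy_synchronous_step(model, state, context, p_noise, rng)
    if engine == "async":
        return biased_asynchronous_step(model, state, context, None, rng)
    if engine == "biased-async":
        return biased_asynchronous_step(model, state, context,
                                        bias if bias is not None else model.bias, rng)
    raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")


def run_trajectory(model: BooleanNetworkModel, initial: np.ndarray,
                   engine: str, schedule, n_steps: int,
                   rng: np.random.Generator | None = None,
                   p_noise: float = 0.02,
                   bias: UpdateBias | None = None,
                   kdoe=(),) -> np.ndarray:
    """Shared driver: run ``n_steps`` steps and return all states.

    ``schedule`` is either a constant context mapping or an object with a
    ``context_at(t, rng)`` method (see :mod:`mechbool.perturbation`).
    ``kdoe`` is a sequence of knockdown/overexpression specs applied after
    each step.  Returns an array of shape ``(n_steps + 1, n_nodes)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = np.empty((n_steps + 1, model.n_nodes), dtype=np.uint8)
    if hasattr(schedule, "context_at"):
        ctx0 = schedule.context_at(0, rng)
    else:
        ctx0 = dict(schedule)
    state = apply_context(model, np.asarray(initial, dtype=np.uint8), ctx0)
    out[0] = state
    for t in range(1, n_steps + 1):
        ctx = schedule.context_at(t, rng) if hasattr(schedule, "context_at") else ctx0
        state = _step(model, state, ctx, engine, rng, p_noise, bias)
        for spec in kdoe:
            state = spec.apply(model, state, rng)
        out[t] = state
    return out


# ---------------------------------------------------------------------------
# bulk synchronous successor map over a context sub-space
#
# Non-input nodes in declaration order define the bit layout of a state
# *code*: the j-th non-input node occupies bit j (LSB first).  Used by the
# exhaustive attractor oracle; chunked to bound memory.

def encode_state(model: BooleanNetworkModel, state: np.ndarray) -> int:
    code = 0
    for j, i in enumerate(model.noninput_indices):
        if state[i]:
            code |= 1 << j
    return int(code)


def decode_state(model: BooleanNetworkModel, code: int,
                 context: dict[str, int]) -> np.ndarray:
    state = np.zeros(model.n_nodes, dtype=np.uint8)
    for j, i in enumerate(model.noninput_indices):
        state[i] = (code >> j) & 1
    for name, bit in context.items():
        state[model.node_index[name]] = 1 if bit else 0
    return state


def successor_codes(model: BooleanNetworkModel, context: dict[str, int],
                    chunk: int = 1 << 16) -> np.ndarray:
    """Synchronous successor of every state in the context sub-space.

    Returns ``succ`` with ``succ[code]`` the code of the successor of the
    state encoded by ``code`` over non-input bits.
    """
    m = len(model.noninput_indices)
    n_states = 1 << m
    pos_of = {int(i): j for j, i in enumerate(model.noninput_indices)}
    ctx_bits = {model.node_index[name]: (1 if bit else 0)
                for name, bit in context.items()}
    succ = np.zeros(n_states, dtype=np.int64)
    for lo in range(0, n_states, chunk):
        hi = min(lo + chunk, n_states)
        codes = np.arange(lo, hi, dtype=np.int64)
        acc = np.zeros(hi - lo, dtype=np.int64)
        for j, i in enumerate(model.noninput_indices):
            regs = model._regs[i]
            w = model._weights[i]
            if len(regs) == 0:
                out = np.full(hi - lo, model._tables[i][0], dtype=np.int64)
            else:
                idx = np.zeros(hi - lo, dtype=np.int64)
                for rj, r in enumerate(regs):
                    r = int(r)
                    if r in pos_of:
                        bit = (codes >> pos_of[r]) & 1
                    else:
                        bit = ctx_bits[r]
                    idx += bit * int(w[rj])
                out = model._tables[i][idx].astype(np.int64)
            acc |= out << j
        succ[lo:hi] = acc
    return succ
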