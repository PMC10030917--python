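"""Attractor detection, stochastic basin sampling, and convergence grids.

Attractor detection is synchronous-only: the deterministic synchronous map
makes every state's fate well defined, so each environment context's
sub-space partitions into basins.  The sampler runs short noisy trajectories
from random initial conditions and descends deterministically from every
visited state (and, optionally, from every single-bit neighbor), which
reaches small basins that noise alone would miss.

Attractors are canonicalized content-addressed: the cycle is rotated so its
lexicographically smallest state comes first and hashed together with the
context, so the same attractor found twice — in the same run or across
independent runs — gets the same identifier.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (decode_state, encode_state, noisy_synchronous_step,
                       successor_codes, synchronous_step)
from .model import BooleanNetworkModel, partition_environments

__all__ = [
    "Attractor",
    "SamplingReport",
    "DescentBudgetExceeded",
    "descend_to_attractor",
    "enumerate_attractors_exhaustive",
    "sample_attractors",
    "convergence_grid",
    "environment_transition_map",
]

DEFAULT_DESCENT_BUDGET = 10 ** 6
EXHAUSTIVE_CAP = 22


class DescentBudgetExceeded(RuntimeError):
    """Deterministic descent exceeded its step budget (pathological instance)."""


@dataclass(frozen=True)
class Attractor:
    """A synchronous fixed point (period 1) or limit cycle, canonicalized."""

    states: tuple[tuple[int, ...], ...]
    context: tuple[tuple[str, int], ...]
    canonical_id: str
    period: int

    @staticmethod
    def from_cycle(cycle: list[np.ndarray], context: dict[str, int]) -> "Attractor":
        tuples = [tuple(int(b) for b in s) for s in cycle]
        k = min(range(len(tuples)), key=lambda i: tuples[i])
        rotated = tuple(tuples[k:] + tuples[:k])
        ctx = tuple(sorted((name, int(bit)) for name, bit in context.items()))
        digest = hashlib.sha1(repr((ctx, rotated)).encode()).hexdigest()[:12]
        return Attractor(states=rotated, context=ctx, canonical_id=digest,
                         period=len(rotated))

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def state_array(self, i: int = 0) -> np.ndarray:
        return np.array(self.states[i], dtype=np.uint8)

    def context_dict(self) -> dict[str, int]:
        return dict(self.context)


@dataclass
class SamplingReport:
    """Attractors found by a sampling run plus per-run convergence counts."""

    attractors: dict[str, Attractor] = field(default_factory=dict)
    local_ids: dict[str, int] = field(default_factory=dict)
    per_run_counts: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def add(self, att: Attractor) -> str:
        if att.canonical_id not in self.attractors:
            self.attractors[att.canonical_id] = att
            self.local_ids[att.canonical_id] = len(self.local_ids)
        return att.canonical_id

    def merge(self, other: "SamplingReport") -> None:
        for att in other.attractors.values():
            self.add(att)
        self.per_run_counts.update(other.per_run_counts)

    def by_local_id(self, local_id: int) -> Attractor:
        for cid, lid in self.local_ids.items():
            if lid == local_id:
                return self.attractors[cid]
        raise KeyError(f"no attractor with local id {local_id}")

    def table(self, model: BooleanNetworkModel) -> pd.DataFrame:
        """One column per attractor: context rows, period row, node rows.

        Cycles show the per-node mean over the cycle's states (0, 1, or a
        fraction for oscillating nodes).
        """
        cols = {}
        for cid, att in sorted(self.attractors.items(),
                               key=lambda kv: self.local_ids[kv[0]]):
            ctx = att.context_dict()
            col = {f"input:{k}": v for k, v in ctx.items()}
            col["period"] = att.period
            mean = np.mean([s for s in att.states], axis=0)
            for name, v in zip(model.node_names, mean):
                col[name] = float(v) if 0 < v < 1 else int(v)
            cols[f"A{self.local_ids[cid]}:{cid}"] = col
        return pd.DataFrame(cols)

    def to_csv(self, path, model: BooleanNetworkModel) -> None:
        self.table(model).to_csv(path)

    def grid(self) -> pd.DataFrame:
        """Convergence heat-map: mean attractor count per (N_rnd, N_series)."""
        rows = [
            {"N_rnd": nr, "N_series": ns, "mean_found": float(np.mean(counts)),
             "runs": len(counts)}
            for (nr, ns), counts in sorted(self.per_run_counts.items())
        ]
        return pd.DataFrame(rows)

    def grid_to_csv(self, path) -> None:
        self.grid().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# deterministic descent

def descend_to_attractor(model: BooleanNetworkModel, state: np.ndarray,
                         context: dict[str, int],
                         budget: int = DEFAULT_DESCENT_BUDGET,
                         _memo: dict | None = None) -> Attractor:
    """Follow the deterministic synchronous dynamics until it repeats.

    Returns the canonical attractor whose basin contains ``state``.  An
    optional memo dict (state bytes → Attractor) caches basin membership
    across repeated descents within one context.
    """
    from .dynamics import apply_context

    cur = apply_context(model, state, context)
    seen: dict[bytes, int] = {}
    path: list[np.ndarray] = []
    for _ in range(budget + 1):
        key = cur.tobytes()
        if _memo is not None and key in _memo:
            att = _memo[key]
            for s in path:
                _memo[s.tobytes()] = att
            return att
        if key in seen:
            cycle = path[seen[key]:]
            att = Attractor.from_cycle(cycle, context)
            if _memo is not None:
                for s in path:
                    _memo[s.tobytes()] = att
            return att
        seen[key] = len(path)
        path.append(cur)
        cur = synchronous_step(model, cur, context)
    raise DescentBudgetExceeded(
        f"no repeat within {budget} synchronous steps; the instance is "
        "pathological or the budget too small")


def enumerate_attractors_exhaustive(model: BooleanNetworkModel,
                                    context: dict[str, int],
                                    cap: int = EXHAUSTIVE_CAP) -> list[Attractor]:
    """Complete attractor list of one context by descending from every state.

    Refuses above ``cap`` non-input nodes (sub-space size 2^cap).
    """
    m = len(model.noninput_indices)
    if m > cap:
        raise ValueError(
            f"{m} non-input nodes exceeds the exhaustive-enumeration cap {cap}")
    succ = successor_codes(model, context)
    n_states = 1 << m
    label = np.full(n_states, -1, dtype=np.int64)
    attractors: list[Attractor] = []
    for start in range(n_states):
        if label[start] >= 0:
            continue
        path = []
        on_path = {}
        code = start
        while label[code] < 0 and code not in on_path:
            on_path[code] = len(path)
            path.append(code)
            code = int(succ[code])
        if label[code] >= 0:
            lab = int(label[code])
        else:
            cycle_codes = path[on_path[code]:]
            cycle = [decode_state(model, c, context) for c in cycle_codes]
            attractors.append(Attractor.from_cycle(cycle, context))
            lab = len(attractors) - 1
        for c in path:
            label[c] = lab
    return attractors


# ---------------------------------------------------------------------------
# stochastic sampling

def _random_state(model: BooleanNetworkModel, context: dict[str, int],
                  rng: np.random.Generator) -> np.ndarray:
    state = np.zeros(model.n_nodes, dtype=np.uint8)
    state[model.noninput_indices] = rng.integers(
        0, 2, size=len(model.noninput_indices), dtype=np.uint8)
    for name, bit in context.items():
        state[model.node_index[name]] = 1 if bit else 0
    return state


def _sample_context(model, context, n_rnd, n_series, p_noise, scan_neighbors,
                    rng, report, memo):
    counts = []
    for _ in range(n_rnd):
        found_ids = set()
        state = _random_state(model, context, rng)
        visited = [state]
        for _ in range(n_series):
            state = noisy_synchronous_step(model, state, context, p_noise, rng)
            visited.append(state)
        for s in visited:
            att = descend_to_attractor(model, s, context, _memo=memo)
            found_ids.add(report.add(att))
            if scan_neighbors:
                for i in model.noninput_indices:
                    nb = s.copy()
                    nb[i] ^= 1
                    att = descend_to_attractor(model, nb, context, _memo=memo)
                    found_ids.add(report.add(att))
        counts.append(len(found_ids))
    return counts


def sample_attractors(model: BooleanNetworkModel,
                      clamps: dict[str, int] | None = None,
                      n_rnd: int = 200, n_series: int = 5,
                      p_noise: float = 0.02, scan_neighbors: bool = True,
                      rng: np.random.Generator | int | None = None) -> SamplingReport:
    """Map attractors across every environment context compatible with clamps.

    For each context: ``n_rnd`` noisy trajectories of ``n_series`` steps
    from uniform random initial states (inputs held by the context); the
    attractor basin of every visited state — including the initial one —
    and, with ``scan_neighbors``, of every single non-input-bit flip of it,
    is identified by deterministic descent.
    """
    if n_rnd < 1 or n_series < 0:
        raise ValueError("n_rnd must be >= 1 and n_series >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    report = SamplingReport(params={
        "n_rnd": n_rnd, "n_series": n_series, "p_noise": p_noise,
        "scan_neighbors": scan_neighbors, "clamps": dict(clamps or {}),
        "model": model.name, "model_hash": model.content_hash()})
    for context in partition_environments(model, clamps):
        memo: dict[bytes, Attractor] = {}
        counts = _sample_context(model, context, n_rnd, n_series, p_noise,
                                 scan_neighbors, rng, report, memo)
        report.per_run_counts.setdefault((n_rnd, n_series), []).extend(counts)
    return report


def convergence_grid(model: BooleanNetworkModel,
                     clamps: dict[str, int] | None = None,
                     grid_spec: tuple[int, int, float, int] = (15, 15, 0.02, 5),
                     scan_neighbors: bool = True,
                     rng: np.random.Generator | int | None = None) -> SamplingReport:
    """Re-run the sampler over an (N_rnd, N_series) grid to test convergence.

    ``grid_spec = (n_rows, n_cols, p_noise, step)`` samples
    ``N_rnd ∈ {step, 2·step, …, n_rows·step}`` crossed with
    ``N_series ∈ {step, …, n_cols·step}``; the union attractor table and the
    per-cell counts (heat map) are returned in one report.
    """
    n_rows, n_cols, p_noise, step = grid_spec
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    union = SamplingReport(params={"grid_spec": grid_spec,
                                   "clamps": dict(clamps or {}),
                                   "model": model.name})
    for r in range(1, int(n_rows) + 1):
        for c in range(1, int(n_cols) + 1):
            cell = sample_attractors(model, clamps, n_rnd=r * step,
                                     n_series=c * step, p_noise=p_noise,
                                     scan_neighbors=scan_neighbors, rng=rng)
            union.merge(cell)
    return union


def environment_transition_map(model: BooleanNetworkModel,
                               report: SamplingReport,
                               clamps: dict[str, int] | None = None) -> pd.DataFrame:
    """Follow each attractor into every neighboring environment.

    For every attractor and every single clamped-free input flip, descend in
    the new context and record the target; targets the sampler missed are
    flagged and added to the report.  This reaches live states in contexts
    whose sub-space is dominated by large (e.g. apoptotic) basins.
    """
    clamps = dict(clamps or {})
    rows = []
    for cid in list(report.attractors):
        att = report.attractors[cid]
        ctx = att.context_dict()
        for inp in model.input_nodes:
            if inp in clamps:
                continue
            new_ctx = dict(ctx)
            new_ctx[inp] = 1 - ctx[inp]
            target = descend_to_attractor(model, att.state_array(0), new_ctx)
            newly = target.canonical_id not in report.attractors
            report.add(target)
            rows.append({
                "source": cid, "source_local": report.local_ids[cid],
                "input": inp, "new_value": new_ctx[inp],
                "target": target.canonical_id,
                "target_local": report.local_ids[target.canonical_id],
                "newly_discovered": newly,
            })
    return pd.DataFrame(rows)
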