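"""Environmental schedules and molecular perturbations.

Inputs can be constant, stochastic (ON with a per-step probability,
modeling a non-saturating signal near its response threshold), or pulsed
(baseline value flipped during a window).  Nodes can be partially knocked
down or overexpressed: forced OFF/ON with a per-step probability, otherwise
obeying their Boolean rule — mimicking siRNA, chemical inhibition, or a
pool of constitutively active protein.

Per-step order of operations: inputs are drawn first, then the engine
updates the network, then each KD/OE override is applied — so an override
wins within its step.  All stochastic draws are i.i.d. across steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attractors import Attractor
from .dynamics import run_trajectory
from .model import BooleanNetworkModel, UpdateBias

__all__ = [
    "InputSchedule",
    "KdOeSpec",
    "PulseResult",
    "apply_schedule_and_kdoe",
    "run_pulse_experiment",
    "scan_1env",
]

log = logging.getLogger(__name__)

PULSE_BASELINE_STEPS = 50
PULSE_TOTAL_STEPS = 400


@dataclass(frozen=True)
class KdOeSpec:
    """Partial knockdown (forced OFF) or overexpression (forced ON)."""

    node: str
    mode: str  # "KD" | "OE"
    probability: float = 1.0

    def __post_init__(self):
        if self.mode not in ("KD", "OE"):
            raise ValueError(f"mode must be 'KD' or 'OE', got {self.mode!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")

    def validate(self, model: BooleanNetworkModel) -> None:
        if self.node not in model.node_index:
            raise ValueError(f"KD/OE target {self.node!r} is not a node")
        if model.is_input(self.node):
            raise ValueError(
                f"KD/OE target {self.node!r} is an environmental input; "
                "use the input schedule instead")

    def apply(self, model: BooleanNetworkModel, state: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
        if self.probability > 0.0 and rng.random() < self.probability:
            state = state.copy()
            state[model.node_index[self.node]] = 1 if self.mode == "OE" else 0
        return state


class InputSchedule:
    """Per-input specification: constant bit, ON-probability, or pulse.

    ``specs`` maps each input name to an ``int`` (constant), a ``float``
    in (0, 1) (independent ON-draw each step), or a tuple
    ``("pulse", baseline, t_on, duration)`` (baseline bit flipped during
    ``[t_on, t_on + duration)``).
    """

    def __init__(self, specs: dict):
        self.specs = dict(specs)
        for name, s in self.specs.items():
            if isinstance(s, tuple):
                tag, baseline, t_on, duration = s
                if tag != "pulse" or baseline not in (0, 1) or t_on < 0 or duration < 0:
                    raise ValueError(f"bad pulse spec for {name!r}: {s}")
            elif isinstance(s, float) and not s.is_integer():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"probability for {name!r} out of [0, 1]")
            elif int(s) not in (0, 1):
                raise ValueError(f"constant for {name!r} must be 0 or 1")

    def validate(self, model: BooleanNetworkModel, n_steps: int | None = None) -> None:
        for name, s in self.specs.items():
            if name not in model.input_nodes:
                raise ValueError(f"schedule entry {name!r} is not an input node")
            if isinstance(s, tuple) and n_steps is not None:
                _, _, t_on, duration = s
                if t_on + duration > n_steps:
                    raise ValueError(f"pulse window for {name!r} exceeds the run")
        missing = set(model.input_nodes) - set(self.specs)
        if missing:
            raise ValueError(f"schedule is missing inputs: {sorted(missing)}")

    def context_at(self, t: int, rng: np.random.Generator) -> dict[str, int]:
        ctx = {}
        for name, s in self.specs.items():
            if isinstance(s, tuple):
                _, baseline, t_on, duration = s
                ctx[name] = int(baseline) ^ (1 if t_on <= t < t_on + duration else 0)
            elif isinstance(s, float) and not s.is_integer():
                ctx[name] = 1 if rng.random() < s else 0
            else:
                ctx[name] = int(s)
        return ctx


def apply_schedule_and_kdoe(model: BooleanNetworkModel, state: np.ndarray,
                            schedule: InputSchedule, kdoe_list, t: int,
                            rng: np.random.Generator, engine: str = "sync",
                            p_noise: float = 0.02,
                            bias: UpdateBias | None = None) -> np.ndarray:
    """One full perturbed step: draw inputs, update, apply KD/OE overrides."""
    from .dynamics import _step, apply_context

    seen = {}
    for spec in kdoe_list:
        spec.validate(model)
        if spec.node in seen and seen[spec.node] != spec.mode:
            raise ValueError(f"both KD and OE requested for node {spec.node!r}")
        seen[spec.node] = spec.mode
    ctx = schedule.context_at(t, rng)
    new = _step(model, apply_context(model, state, ctx), ctx, engine, rng,
                p_noise, bias)
    for spec in kdoe_list:
        new = spec.apply(model, new, rng)
    return new


@dataclass
class PulseResult:
    """Trajectory of a reversible environmental pulse plus derived tables."""

    trajectory: np.ndarray
    input_track: pd.DataFrame
    heatmap: pd.DataFrame
    phenotypes: list[set] | None = None
    params: dict = field(default_factory=dict)


def run_pulse_experiment(model: BooleanNetworkModel, initial,
                         pulsed_input: str, duration: int,
                         engine: str = "sync",
                         rng: np.random.Generator | int | None = None,
                         baseline_context: dict[str, int] | None = None,
                         signatures=None,
                         p_noise: float = 0.02,
                         bias: UpdateBias | None = None,
                         total_steps: int = PULSE_TOTAL_STEPS,
                         baseline_steps: int = PULSE_BASELINE_STEPS) -> PulseResult:
    """Reversible environmental change from a stable state.

    The run shows ``baseline_steps`` (default 50) steps in the baseline
    environment, flips ``pulsed_input`` for ``duration`` steps, flips it
    back, and follows the dynamics to ``total_steps`` (default 400) total.
    ``initial`` is an :class:`~mechbool.attractors.Attractor` (its context
    supplies the baseline) or a state array plus ``baseline_context``.
    """
    if duration > total_steps - baseline_steps:
        raise ValueError(
            f"duration {duration} exceeds the {total_steps - baseline_steps} "
            "steps available after the baseline window")
    if isinstance(initial, Attractor):
        baseline_context = initial.context_dict()
        state0 = initial.state_array(0)
    else:
        if baseline_context is None:
            raise ValueError("baseline_context required when initial is a state")
        state0 = np.asarray(initial, dtype=np.uint8)
    if pulsed_input not in model.input_nodes:
        raise ValueError(f"{pulsed_input!r} is not an input node")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    specs = {name: int(bit) for name, bit in baseline_context.items()}
    specs[pulsed_input] = ("pulse", int(baseline_context[pulsed_input]),
                           baseline_steps, duration)
    schedule = InputSchedule(specs)
    schedule.validate(model, total_steps)
    traj = run_trajectory(model, state0, engine, schedule, total_steps,
                          rng=rng, p_noise=p_noise, bias=bias)
    steps = np.arange(total_steps + 1)
    track = pd.DataFrame(
        {name: traj[:, model.node_index[name]] for name in model.input_nodes},
        index=pd.Index(steps, name="step"))
    heat = pd.DataFrame(traj.T, index=pd.Index(model.node_names, name="node"),
                        columns=steps)
    phenos = None
    if signatures is not None:
        from .phenotypes import classify_state
        phenos = [classify_state(model, s, signatures) for s in traj]
    return PulseResult(trajectory=traj, input_track=track, heatmap=heat,
                       phenotypes=phenos,
                       params={"pulsed_input": pulsed_input, "duration": duration,
                               "engine": engine, "baseline": dict(baseline_context),
                               "baseline_steps": baseline_steps,
                               "total_steps": total_steps})


def scan_1env(model: BooleanNetworkModel, initial,
              scanned_input: str, base_probabilities: dict,
              kdoe: KdOeSpec | None = None,
              levels=None,
              signatures=None,
              engine: str = "sync",
              t_min_live: int = 50_000,
              rng: np.random.Generator | int | None = None,
              **stats_kwargs) -> pd.DataFrame:
    """Phenotype statistics as one input's ON-probability is scanned.

    For each level the scanned input's ON-probability is set to that level
    and every other input follows ``base_probabilities``; a full
    phenotype-statistics run (dwell fractions, cell-cycle event rates,
    apoptosis rate) is accumulated at each level.  A ``kdoe`` spec with
    ``probability`` set adds a fixed partial knockdown/overexpression; with
    ``probability=None`` semantics use :func:`scan_1env` per KD level
    externally.  Returns a tidy frame: (level, quantity, value).
    """
    from .phenotypes import load_default_signatures, run_phenotype_statistics

    if scanned_input not in model.input_nodes:
        raise ValueError(f"{scanned_input!r} is not an input node")
    base = dict(base_probabilities)
    if scanned_input in base:
        log.warning("base probability for scanned input %r ignored", scanned_input)
        base.pop(scanned_input)
    if levels is None:
        levels = np.linspace(0.0, 1.0, 11)
    if signatures is None:
        signatures = load_default_signatures(model, strict=False)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(initial, Attractor):
        state0 = initial.state_array(0)
    else:
        state0 = np.asarray(initial, dtype=np.uint8)

    rows = []
    for level in levels:
        specs = dict(base)
        specs[scanned_input] = float(level)
        schedule = InputSchedule(specs)
        schedule.validate(model)
        stats = run_phenotype_statistics(
            model, initial_state=state0, schedule=schedule,
            kdoe=(kdoe,) if kdoe is not None else (),
            signatures=signatures, engine=engine, t_min_live=t_min_live,
            rng=rng, **stats_kwargs)
        for name, frac in stats.dwell_fractions.items():
            rows.append({"level": float(level), "quantity": f"dwell:{name}",
                         "value": frac})
        for name, rate in stats.event_rates.items():
            rows.append({"level": float(level), "quantity": f"rate:{name}",
                         "value": rate})
        rows.append({"level": float(level), "quantity": "rate:apoptosis",
                     "value": stats.apoptosis_rate})
    return pd.DataFrame(rows)
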