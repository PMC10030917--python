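"""Phenotype signatures, cell-cycle event detection, dwell-time statistics.

A phenotype signature is a named conjunction of node-state constraints
(e.g. epithelial = miR-34, miR-200 and E-cadherin mRNA ON with no high
Zeb1).  Signatures are data: the shipped defaults follow the convention of
the deposited EMT models, and any signature file in the same
``Name = (node=bit, ...)`` format can replace them.

Cell-cycle events are likewise declarative patterns over marker-node
transitions, not hard-coded logic: each detector names a trigger edge, the
marker states required at the trigger, and pulses that must (or must not)
have occurred since the detector's reset marker last rose.  The shipped
defaults target the cell-cycle marker names of the deposited models
(CyclinB, Cdc20, A_Kinetochores, Cytokinesis, Replication, f4N_DNA) and
are validated on scripted trajectories.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BooleanNetworkModel

__all__ = [
    "PhenotypeSignature",
    "EventDetector",
    "EventCounters",
    "PhenotypeStats",
    "DEFAULT_SIGNATURE_TEXT",
    "DEFAULT_EVENT_DETECTORS",
    "MIN_CYCLE_LENGTH",
    "load_signatures",
    "load_default_signatures",
    "classify_state",
    "detect_cycle_events",
    "run_phenotype_statistics",
    "DegenerateStatisticsError",
]

log = logging.getLogger(__name__)

#: Minimum length of one full proliferative cycle in time-steps; event rates
#: are reported per this many live steps.
MIN_CYCLE_LENGTH = 21

DEFAULT_SIGNATURE_TEXT = """\
CIP = (ApicalBasal_Pol=1, YAP=0, TAZ=0)
noCIP = (ApicalBasal_Pol=0, YAP=1, TAZ=1)
Migratory = (Fast_Migration=1)
Non-migratory = (Fast_Migration=0)
Epithelial = (miR_34=1, miR_200=1, Ecadherin_mRNA=1, ZEB1_H=0)
Mesenchymal = (miR_34=0, miR_200=0, Ecadherin_mRNA=0, ZEB1_H=1, N_bcatenin_H=1)
Hybrid_EM = (miR_34=0, miR_200=1, Ecadherin_mRNA=1, ZEB1_H=0, ZEB1=1, SNAI1=1)
"""


class DegenerateStatisticsError(RuntimeError):
    """Live time cannot be accumulated (e.g. every restart dies immediately)."""


@dataclass(frozen=True)
class PhenotypeSignature:
    """A named conjunction of (node, required bit) constraints."""

    name: str
    constraints: tuple[tuple[str, int], ...]

    def validate(self, model: BooleanNetworkModel) -> None:
        for node, _ in self.constraints:
            if node not in model.node_index:
                raise ValueError(
                    f"signature {self.name!r} references unknown node {node!r}")

    def matches(self, model: BooleanNetworkModel, state: np.ndarray) -> bool:
        return all(state[model.node_index[n]] == b for n, b in self.constraints)


_SIG_LINE = re.compile(r"^\s*(?P<name>[\w\-]+)\s*=\s*\((?P<body>.*)\)\s*$")


def load_signatures(text: str) -> list[PhenotypeSignature]:
    """Parse ``Name = (node=bit, node=bit, ...)`` lines.

    ``*`` markup around node names is stripped; an empty constraint list
    matches every state.  Node existence is checked at bind time via
    :meth:`PhenotypeSignature.validate`.
    """
    sigs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.strip().startswith(("#", "--")):
            continue
        m = _SIG_LINE.match(line)
        if not m:
            raise ValueError(f"line {lineno}: cannot parse signature {line!r}")
        constraints = []
        body = m.group("body").strip()
        if body:
            for part in body.split(","):
                node, _, bit = part.partition("=")
                node = node.strip().strip("*")
                bit = bit.strip()
                if bit not in ("0", "1"):
                    raise ValueError(
                        f"line {lineno}: constraint {part.strip()!r} must be node=0/1")
                constraints.append((node, int(bit)))
        sigs.append(PhenotypeSignature(m.group("name"), tuple(constraints)))
    return sigs


def load_default_signatures(model: BooleanNetworkModel | None = None,
                            strict: bool = True) -> list[PhenotypeSignature]:
    """The packaged signature set, optionally bound to a model.

    With ``strict=False``, signatures referencing nodes the model lacks are
    dropped (useful for isolated modules carrying only the EMT markers).
    """
    sigs = load_signatures(DEFAULT_SIGNATURE_TEXT)
    if model is None:
        return sigs
    kept = []
    for sig in sigs:
        try:
            sig.validate(model)
        except ValueError:
            if strict:
                raise
            continue
        kept.append(sig)
    return kept


def classify_state(model: BooleanNetworkModel, state: np.ndarray,
                   signatures) -> set[str]:
    """All signature names matching ``state`` (signatures may overlap)."""
    return {sig.name for sig in signatures if sig.matches(model, state)}


# ---------------------------------------------------------------------------
# cell-cycle events

@dataclass(frozen=True)
class EventDetector:
    """Declarative event pattern over marker transitions.

    The event fires when ``trigger`` node shows the named edge
    (``rise``/``fall``), provided every ``require`` (node, bit) holds on the
    post-edge state, every ``require_seen`` node has risen since the last
    rise of ``reset_on`` (default: the trigger itself), and no
    ``forbid_seen`` node has.
    """

    name: str
    trigger: tuple[str, str]
    require: tuple[tuple[str, int], ...] = ()
    require_seen: tuple[str, ...] = ()
    forbid_seen: tuple[str, ...] = ()
    reset_on: str | None = None

    def validate(self, model: BooleanNetworkModel) -> None:
        nodes = ([self.trigger[0]] + [n for n, _ in self.require] +
                 list(self.require_seen) + list(self.forbid_seen) +
                 ([self.reset_on] if self.reset_on else []))
        for n in nodes:
            if n not in model.node_index:
                raise ValueError(
                    f"event detector {self.name!r} references missing node {n!r}")
        if self.trigger[1] not in ("rise", "fall"):
            raise ValueError(f"trigger edge must be 'rise' or 'fall'")


#: Defaults for the deposited models' marker names.  normal_cycle: a
#: cytokinesis pulse with attached kinetochores after CyclinB activity;
#: g2_reset: the 4N-DNA flag rises with no CyclinB pulse since the last
#: cytokinesis (genome re-duplication from G2); aberrant_mitosis: a Cdc20
#: pulse (metaphase→anaphase) without kinetochore attachment; failed
#: cytokinesis: a new replication round after mitotic exit (Cdc20 pulse)
#: with no cytokinesis in between.
DEFAULT_EVENT_DETECTORS = (
    EventDetector("normal_cycle", trigger=("Cytokinesis", "rise"),
                  require=(("A_Kinetochores", 1),), require_seen=("CyclinB",)),
    EventDetector("g2_reset", trigger=("f4N_DNA", "rise"),
                  forbid_seen=("CyclinB",), reset_on="Cytokinesis"),
    EventDetector("aberrant_mitosis", trigger=("Cdc20", "rise"),
                  require=(("A_Kinetochores", 0),)),
    EventDetector("failed_cytokinesis", trigger=("Replication", "rise"),
                  require_seen=("Cdc20",), forbid_seen=("Cytokinesis",)),
)

_EVENT_COUNTER_FIELD = {
    "normal_cycle": "normal_cycles",
    "g2_reset": "g2_reset_duplications",
    "aberrant_mitosis": "aberrant_mitoses",
    "failed_cytokinesis": "failed_cytokineses",
}


@dataclass
class EventCounters:
    normal_cycles: int = 0
    g2_reset_duplications: int = 0
    aberrant_mitoses: int = 0
    failed_cytokineses: int = 0
    apoptoses: int = 0
    live_steps: int = 0
    dwell_steps: dict[str, int] = field(default_factory=dict)
    other_events: dict[str, int] = field(default_factory=dict)

    def bump(self, event_name: str) -> None:
        attr = _EVENT_COUNTER_FIELD.get(event_name)
        if attr is not None:
            setattr(self, attr, getattr(self, attr) + 1)
        else:
            self.other_events[event_name] = self.other_events.get(event_name, 0) + 1

    def event_counts(self) -> dict[str, int]:
        out = {name: getattr(self, attr)
               for name, attr in _EVENT_COUNTER_FIELD.items()}
        out.update(self.other_events)
        return out


class _DetectorState:
    """Per-run scan state for one detector (seen-pulse bookkeeping)."""

    def __init__(self, detector: EventDetector, model: BooleanNetworkModel):
        detector.validate(model)
        self.d = detector
        self.trigger_idx = model.node_index[detector.trigger[0]]
        self.rise = detector.trigger[1] == "rise"
        self.require_idx = [(model.node_index[n], b) for n, b in detector.require]
        self.watch = {n: False
                      for n in detector.require_seen + detector.forbid_seen}
        self.watch_idx = {n: model.node_index[n] for n in self.watch}
        self.reset_idx = (model.node_index[detector.reset_on]
                          if detector.reset_on else self.trigger_idx)

    def scan_step(self, prev: np.ndarray, cur: np.ndarray) -> bool:
        fired = False
        t_prev, t_cur = prev[self.trigger_idx], cur[self.trigger_idx]
        edge = (t_prev == 0 and t_cur == 1) if self.rise else (t_prev == 1 and t_cur == 0)
        if edge and all(cur[i] == b for i, b in self.require_idx):
            ok = all(self.watch[n] for n in self.d.require_seen)
            ok = ok and not any(self.watch[n] for n in self.d.forbid_seen)
            fired = ok
        # record pulses after evaluating the trigger at this step
        for n, i in self.watch_idx.items():
            if prev[i] == 0 and cur[i] == 1:
                self.watch[n] = True
        if prev[self.reset_idx] == 0 and cur[self.reset_idx] == 1:
            self.watch = {n: False for n in self.watch}
        return fired


def detect_cycle_events(model: BooleanNetworkModel, trajectory: np.ndarray,
                        detectors=DEFAULT_EVENT_DETECTORS,
                        counters: EventCounters | None = None) -> EventCounters:
    """Scan a trajectory with the event detectors and count occurrences."""
    counters = counters if counters is not None else EventCounters()
    states = [_DetectorState(d, model) for d in detectors]
    traj = np.asarray(trajectory)
    for t in range(1, len(traj)):
        for ds in states:
            if ds.scan_step(traj[t - 1], traj[t]):
                counters.bump(ds.d.name)
    return counters


# ---------------------------------------------------------------------------
# long-run statistics

@dataclass
class PhenotypeStats:
    """Accumulated dwell fractions and event rates over live-cell time."""

    counters: EventCounters
    dwell_fractions: dict[str, float]
    event_rates: dict[str, float]
    apoptosis_rate: float
    restarts: int
    degenerate: bool = False
    params: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        rows = [{"quantity": f"dwell:{k}", "value": v}
                for k, v in self.dwell_fractions.items()]
        rows += [{"quantity": f"rate:{k}", "value": v}
                 for k, v in self.event_rates.items()]
        rows.append({"quantity": "rate:apoptosis", "value": self.apoptosis_rate})
        rows.append({"quantity": "live_steps",
                     "value": self.counters.live_steps})
        return pd.DataFrame(rows)


def run_phenotype_statistics(model: BooleanNetworkModel, initial_state,
                             schedule, signatures,
                             kdoe=(),
                             engine: str = "sync",
                             t_min_live: int = 50_000,
                             apoptosis_signature="auto",
                             detectors=None,
                             p_noise: float = 0.02,
                             bias=None,
                             max_restarts: int = 100_000,
                             rng: np.random.Generator | int | None = None
                             ) -> PhenotypeStats:
    """Accumulate ≥ ``t_min_live`` live-cell steps of perturbed dynamics.

    Runs restart from ``initial_state`` at each apoptotic event (detected by
    ``apoptosis_signature``; ``"auto"`` uses a signature named
    ``Apoptotic``/``Apoptosis`` or a node of either name locked ON, and
    disables apoptosis tracking when neither exists).  Dwell fractions are
    per-signature dwell time over live time; event rates are occurrences per
    minimum cycle length (:data:`MIN_CYCLE_LENGTH` live steps).  If live
    time cannot accumulate within ``max_restarts`` restarts the result is
    flagged degenerate (dwell fractions NaN) rather than silently zero.
    """
    from .perturbation import apply_schedule_and_kdoe

    if t_min_live < 1:
        raise ValueError("t_min_live must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for sig in signatures:
        sig.validate(model)

    if apoptosis_signature == "auto":
        apoptosis_signature = None
        for sig in signatures:
            if sig.name.lower() in ("apoptotic", "apoptosis"):
                apoptosis_signature = sig
                break
        else:
            for cand in ("Apoptosis", "Apoptotic"):
                if cand in model.node_index:
                    apoptosis_signature = PhenotypeSignature(
                        "Apoptotic", ((cand, 1),))
                    break
    if apoptosis_signature is not None:
        apoptosis_signature.validate(model)

    if detectors is None:
        detectors = tuple(d for d in DEFAULT_EVENT_DETECTORS
                          if d.trigger[0] in model.node_index)

    counters = EventCounters(dwell_steps={sig.name: 0 for sig in signatures})
    initial_state = np.asarray(initial_state, dtype=np.uint8)
    restarts = 0
    degenerate = False
    while counters.live_steps < t_min_live:
        if restarts >= max_restarts:
            degenerate = True
            log.warning("phenotype statistics degenerate: %d restarts without "
                        "reaching %d live steps", restarts, t_min_live)
            break
        restarts += 1
        state = initial_state.copy()
        det_states = [_DetectorState(d, model) for d in detectors]
        t = 0
        while counters.live_steps < t_min_live:
            prev = state
            state = apply_schedule_and_kdoe(model, state, schedule, kdoe, t,
                                            rng, engine=engine,
                                            p_noise=p_noise, bias=bias)
            t += 1
            if apoptosis_signature is not None and \
                    apoptosis_signature.matches(model, state):
                counters.apoptoses += 1
                break
            counters.live_steps += 1
            for sig in signatures:
                if sig.matches(model, state):
                    counters.dwell_steps[sig.name] += 1
            for ds in det_states:
                if ds.scan_step(prev, state):
                    counters.bump(ds.d.name)
        if apoptosis_signature is None and counters.live_steps >= t_min_live:
            break

    live = counters.live_steps
    if live > 0 and not degenerate:
        dwell = {k: v / live for k, v in counters.dwell_steps.items()}
        rates = {k: v * MIN_CYCLE_LENGTH / live
                 for k, v in counters.event_counts().items()}
        apo_rate = counters.apoptoses * MIN_CYCLE_LENGTH / live
    else:
        dwell = {k: float("nan") for k in counters.dwell_steps}
        rates = {k: float("nan") for k in counters.event_counts()}
        apo_rate = float("nan")
    return PhenotypeStats(counters=counters, dwell_fractions=dwell,
                          event_rates=rates, apoptosis_rate=apo_rate,
                          restarts=restarts, degenerate=degenerate,
                          params={"engine": engine, "t_min_live": t_min_live})
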