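"""Self-contained test models: the isolated EMT switch, toy circuits,
random Boolean networks, and deposited-model loading.

The EMT switch encodes the tri-stable core of epithelial–mesenchymal
transition: mutual inhibition between the epithelial microRNAs miR-34 and
miR-200 and the transcription factors Snai1 and Zeb1, arranged as a
cascading pair of switches (miR-34 ⊣⊢ Snai1 flips first, giving the hybrid
E/M state; miR-200 ⊣⊢ high Zeb1 flips second, giving the mesenchymal
state).  Former regulators outside the switch (NF-κB, GSK3, c-Myb) are
frozen as constant gates at the values module isolation selects in a
mitogenic context, so the module is self-contained and reproduces the
published three-attractor structure: epithelial, hybrid E/M, mesenchymal —
all fixed points.
"""

from __future__ import annotations

import os

import numpy as np

from .model import (BooleanNetworkModel, NodeSpec, UpdateBias,
                    compile_truth_table, parse_model)

__all__ = [
    "EMT_SWITCH_RULES",
    "CELL_CYCLE_UPDATE_BIAS",
    "DepositedModelMissing",
    "build_emt_switch",
    "toggle_switch",
    "feedback_ring",
    "generate_random_network",
    "load_deposited_model",
    "marker_stub_model",
    "scripted_trajectory",
    "DEPOSITED_MODEL_COUNTS",
]

# Frozen former inputs: NFkB ON (mitogenic PI3K/AKT context), GSK3 OFF
# (inactivated by AKT), c_Myb ON (NF-κB-induced; maintains miR-200 unless
# overridden by high Zeb1).  Staircase convention: the _H node of a
# two-level pair implies the base node is ON.
EMT_SWITCH_RULES = """\
# isolated EMT switch
NFkB *= 1
GSK3 *= 0
c_Myb *= 1
miR_34 *= not (SNAI1 or ZEB1)
SNAI1 *= NFkB and not GSK3 and not miR_34
Twist1 *= SNAI1
SNAI2 *= Twist1 or N_bcatenin_H
ZEB1 *= SNAI2 or ZEB1_H
ZEB1_H *= ZEB1 and N_bcatenin_H and not miR_200
miR_200 *= not (ZEB1_H or (SNAI1 and Twist1 and ZEB1 and not c_Myb))
Ecadherin_mRNA *= not (SNAI1 and ZEB1_H)
N_bcatenin *= SNAI1 and not GSK3
N_bcatenin_H *= N_bcatenin and not miR_34 and not Ecadherin_mRNA and not miR_200
"""

#: Update bias used with the deposited full models: 12 cell-cycle nodes are
#: pinned to the start or end of each asynchronous step depending on their
#: pre-update state, so short-lived mitotic signals are followed up in a
#: physiological order.  Start-list nodes update first (in listed order);
#: end-list nodes update last, first listed updated last.
CELL_CYCLE_UPDATE_BIAS = UpdateBias(
    start_rules=(
        ("Pre_RC", "if_on"),
        ("Replication", "if_off"),
        ("U_Kinetochores", "if_off"),
        ("A_Kinetochores", "if_on"),
        ("Plk1_H", "if_on"),
        ("CyclinB", "if_on"),
        ("Cdc20", "if_off"),
    ),
    end_rules=(
        ("Replication", "if_on"),
        ("f4N_DNA", "always"),
        ("Cytokinesis", "if_off"),
        ("Ect2", "if_off"),
        ("A_Kinetochores", "if_off"),
        ("CyclinE", "if_on"),
        ("FoxM1", "if_on"),
        ("Cdc20", "if_on"),
        ("Plk1_H", "if_off"),
    ),
)

#: Published node/link counts for the deposited model files, checked on load.
DEPOSITED_MODEL_COUNTS = {
    "File_S5_EMT_Mechanosensing.booleannet": {"nodes": 136},
    "File_S6_EMT_Mechanosensing_TGFbeta.booleannet": {"nodes": 150, "links": 630},
}


class DepositedModelMissing(FileNotFoundError):
    """Optional deposited model file absent; dependent analyses are skipped."""


def build_emt_switch(deposited_path=None) -> BooleanNetworkModel:
    """The isolated EMT switch (see module docstring).

    If a deposited switch file is supplied (or found at
    ``fixtures/File_S4_EMT_Switch.booleannet``), it takes precedence and
    the hand encoding is cross-checked against it by attractor-set
    comparison in the test suite.
    """
    if deposited_path is None:
        candidate = os.path.join("fixtures", "File_S4_EMT_Switch.booleannet")
        deposited_path = candidate if os.path.exists(candidate) else None
    if deposited_path is not None:
        with open(deposited_path) as fh:
            return parse_model(fh.read(), name="EMT_Switch_deposited")
    return parse_model(EMT_SWITCH_RULES, name="EMT_Switch")


def toggle_switch() -> BooleanNetworkModel:
    """Two mutually repressing nodes: 2 fixed points + 1 period-2 cycle."""
    return parse_model("A *= not B\nB *= not A\n", name="toggle")


def feedback_ring(n: int = 3, negative: bool = True) -> BooleanNetworkModel:
    """A ring of n nodes, each activated by its predecessor; with
    ``negative`` the last link inhibits, giving a repressilator-style orbit."""
    lines = []
    for i in range(n):
        src = f"N{(i - 1) % n}"
        if negative and i == 0:
            lines.append(f"N{i} *= not {src}")
        else:
            lines.append(f"N{i} *= {src}")
    return parse_model("\n".join(lines), name=f"ring{n}")


def generate_random_network(n_nodes: int, n_inputs: int = 0,
                            max_in_degree: int = 3, bias: float = 0.5,
                            seed: int | None = None) -> BooleanNetworkModel:
    """Random Boolean network: random regulator sets, Bernoulli(bias) tables.

    The first ``n_inputs`` nodes are environmental inputs (identity
    self-loops); the rest draw 1..max_in_degree regulators uniformly from
    all nodes.  Fully reproducible per seed.
    """
    if n_inputs > n_nodes:
        raise ValueError("n_inputs cannot exceed n_nodes")
    if max_in_degree > n_nodes:
        raise ValueError("max_in_degree cannot exceed n_nodes")
    from .reduction import _table_to_expression

    rng = np.random.default_rng(seed)
    names = [f"N{i:02d}" for i in range(n_nodes)]
    specs: list[NodeSpec] = []
    for i, name in enumerate(names):
        if i < n_inputs:
            specs.append(compile_truth_table(name, (name,), name))
            continue
        k = int(rng.integers(1, max_in_degree + 1))
        regs = tuple(names[j] for j in sorted(
            rng.choice(n_nodes, size=k, replace=False)))
        table = tuple(int(b) for b in (rng.random(2 ** k) < bias))
        expr = _table_to_expression(regs, table)
        if expr in ("0", "1"):
            # a constant draw collapses to a regulator-free gate so that the
            # rule text round-trips bit-for-bit
            specs.append(NodeSpec(name, (), expr, (int(expr),)))
        else:
            specs.append(NodeSpec(name, regs, expr, table))
    inputs = tuple(names[:n_inputs])
    return BooleanNetworkModel(specs, name=f"random{n_nodes}", input_nodes=inputs,
                               input_detection={i: "generator" for i in inputs})


def load_deposited_model(path) -> tuple[BooleanNetworkModel, dict]:
    """Parse a deposited model file and check its published counts.

    Returns ``(model, report)``; ``report`` records node/link counts and,
    when the file name is recognized, whether they match the published
    values.  Raises :class:`DepositedModelMissing` when the file is absent
    so callers can skip deposited-model analyses explicitly.
    """
    if not os.path.exists(path):
        raise DepositedModelMissing(
            f"optional fixture {path!r} absent; deposited-model analyses skipped")
    with open(path) as fh:
        model = parse_model(fh.read(), name=os.path.splitext(os.path.basename(path))[0])
    report = {"nodes": model.n_nodes, "links": model.n_links,
              "inputs": list(model.input_nodes),
              "input_detection": dict(model.input_detection)}
    expected = DEPOSITED_MODEL_COUNTS.get(os.path.basename(path))
    if expected:
        report["expected"] = expected
        report["counts_match"] = all(
            report.get(key) == val for key, val in expected.items())
    return model, report


# ---------------------------------------------------------------------------
# scripted-trajectory support for event-detector tests

_MARKER_NODES = ("CyclinB", "Cdc20", "A_Kinetochores", "Cytokinesis",
                 "Replication", "f4N_DNA", "Apoptosis")


def marker_stub_model() -> BooleanNetworkModel:
    """A stub model exposing the cell-cycle marker nodes as free inputs, for
    scoring hand-scripted trajectories with the event detectors."""
    text = "\n".join(f"{n} *= {n}" for n in _MARKER_NODES)
    return parse_model(text, name="marker_stub")


def scripted_trajectory(model: BooleanNetworkModel,
                        tracks: dict[str, list[int]]) -> np.ndarray:
    """Build a trajectory array from per-node bit tracks (unlisted nodes 0)."""
    lengths = {len(v) for v in tracks.values()}
    if len(lengths) != 1:
        raise ValueError("all tracks must have the same length")
    (T,) = lengths
    traj = np.zeros((T, model.n_nodes), dtype=np.uint8)
    for name, bits in tracks.items():
        traj[:, model.node_index[name]] = bits
    return traj
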