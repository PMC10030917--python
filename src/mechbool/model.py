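"""Boolean network models: rule parsing, truth-table compilation, environments.

A model is an ordered collection of nodes, each with a Boolean update rule
over its regulators.  Rules are written in a BooleanNet-style text dialect::

    # comment
    -- also a comment
    NodeA *= NodeB and not NodeC
    NodeB *= NodeB          # identity self-loop marks an environmental input

Environmental inputs are nodes whose value encodes the microenvironment
(ECM stiffness, growth factors, cell density...).  They are detected
automatically: a node is an input iff its rule is an identity self-loop, or
it appears as a regulator but has no rule of its own (``auto_inputs``).
Inputs are held fixed by the dynamics within an environment *context*; the
full state space partitions into one sub-space per input combination.
"""

from __future__ import annotations

import ast
import hashlib
import itertools
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodeSpec",
    "UpdateBias",
    "BooleanNetworkModel",
    "ParseError",
    "compile_truth_table",
    "parse_model",
    "serialize_model",
    "partition_environments",
    "interaction_graph",
    "export_gml",
]

MAX_TABLE_REGULATORS = 20

IF_ON = "if_on"
IF_OFF = "if_off"
ALWAYS = "always"


class ParseError(ValueError):
    """Raised when a rule file cannot be parsed into a valid model."""


# ---------------------------------------------------------------------------
# expressions

_ALLOWED_AST = (ast.Expression, ast.BoolOp, ast.UnaryOp, ast.And, ast.Or,
                ast.Not, ast.Name, ast.Constant, ast.Load)


def _parse_expression(expression: str, regulators: tuple[str, ...]) -> ast.Expression:
    """Parse a Boolean formula (and/or/not, parentheses, 0/1 literals)."""
    try:
        tree = ast.parse(expression.strip(), mode="eval")
    except SyntaxError as exc:
        raise ParseError(f"malformed expression {expression!r}: {exc.msg}") from None
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_AST):
            raise ParseError(
                f"unsupported construct {type(node).__name__!r} in {expression!r}; "
                "only and/or/not, parentheses, node names and 0/1 are allowed")
        if isinstance(node, ast.Constant) and node.value not in (0, 1, True, False):
            raise ParseError(f"literal {node.value!r} in {expression!r} is not 0/1")
        if isinstance(node, ast.Name) and node.id not in regulators:
            raise ParseError(
                f"symbol {node.id!r} in expression {expression!r} is not a declared regulator")
    return tree


def compile_truth_table(name: str, regulators: tuple[str, ...],
                        expression: str) -> "NodeSpec":
    """Compile a rule expression into a :class:`NodeSpec` with its truth table.

    The table has one output bit per regulator combination; combination
    ``i`` assigns the binary digits of ``i`` to the regulators in declaration
    order, first regulator as the most significant bit.
    """
    regulators = tuple(regulators)
    if len(set(regulators)) != len(regulators):
        raise ParseError(f"node {name!r}: duplicate regulator")
    k = len(regulators)
    if k > MAX_TABLE_REGULATORS:
        raise ValueError(
            f"node {name!r} has {k} regulators; truth table with 2^{k} rows is "
            f"too large to materialize (limit {MAX_TABLE_REGULATORS})")
    tree = _parse_expression(expression, regulators)
    code = compile(tree, f"<rule:{name}>", "eval")
    table = np.empty(2 ** k, dtype=np.uint8)
    for i, bits in enumerate(itertools.product((0, 1), repeat=k)):
        env = dict(zip(regulators, bits))
        table[i] = 1 if eval(code, {"__builtins__": {}}, env) else 0
    return NodeSpec(name=name, regulators=regulators, expression=expression.strip(),
                    truth_table=tuple(int(b) for b in table))


@dataclass(frozen=True)
class NodeSpec:
    """One node: its regulators, rule expression and compiled truth table."""

    name: str
    regulators: tuple[str, ...]
    expression: str
    truth_table: tuple[int, ...]

    def __post_init__(self):
        if len(self.truth_table) != 2 ** len(self.regulators):
            raise ValueError(
                f"node {self.name!r}: table length {len(self.truth_table)} != "
                f"2^{len(self.regulators)}")

    @property
    def k(self) -> int:
        return len(self.regulators)

    @property
    def on_fraction(self) -> float:
        """Fraction of regulator combinations with ON output (popcount/2^k)."""
        return sum(self.truth_table) / len(self.truth_table)

    def is_identity_self_loop(self) -> bool:
        return self.regulators == (self.name,) and self.truth_table == (0, 1)

    def is_constant(self) -> bool:
        return len(set(self.truth_table)) == 1

    def evaluate(self, bits: dict[str, int]) -> int:
        idx = 0
        for r in self.regulators:
            idx = (idx << 1) | (1 if bits[r] else 0)
        return self.truth_table[idx]


@dataclass(frozen=True)
class UpdateBias:
    """Condition-dependent node priorities for biased asynchronous update.

    ``start_rules`` nodes whose condition holds on the pre-step state are
    updated first (in listed order); ``end_rules`` nodes are updated last,
    with the first listed updated *last*.  Conditions: ``if_on``, ``if_off``,
    ``always``.
    """

    start_rules: tuple[tuple[str, str], ...] = ()
    end_rules: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        for rules in (self.start_rules, self.end_rules):
            names = [n for n, _ in rules]
            if len(set(names)) != len(names):
                raise ValueError("a node appears more than once in a bias list")
            for _, cond in rules:
                if cond not in (IF_ON, IF_OFF, ALWAYS):
                    raise ValueError(f"unknown bias condition {cond!r}")

    def validate(self, model: "BooleanNetworkModel") -> None:
        for name, _ in self.start_rules + self.end_rules:
            if name not in model.node_index:
                raise ValueError(f"bias references unknown node {name!r}")

    @property
    def nodes(self) -> set[str]:
        return {n for n, _ in self.start_rules + self.end_rules}


class BooleanNetworkModel:
    """An ordered, validated, compiled Boolean network.

    Node order is declaration order and fixes the layout of state vectors:
    a state is a ``numpy`` ``uint8`` array with one bit per node.
    """

    def __init__(self, nodes: list[NodeSpec] | tuple[NodeSpec, ...],
                 name: str = "model",
                 input_nodes: tuple[str, ...] | None = None,
                 bias: UpdateBias | None = None,
                 input_detection: dict[str, str] | None = None):
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.name = name
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ParseError(f"duplicate node definition: {dup!r}")
        self.node_index: dict[str, int] = {n: i for i, n in enumerate(names)}
        for spec in self.nodes:
            for r in spec.regulators:
                if r not in self.node_index:
                    raise ParseError(
                        f"node {spec.name!r}: regulator {r!r} is not a declared node")
        if input_nodes is None:
            input_nodes = tuple(n.name for n in self.nodes
                                if n.is_identity_self_loop() and not n.regulators == ())
        for inp in input_nodes:
            spec = self.nodes[self.node_index[inp]]
            if spec.regulators not in ((), (inp,)):
                raise ParseError(
                    f"input node {inp!r} has regulators {spec.regulators}; "
                    "environmental inputs may only regulate themselves")
        self.input_nodes: tuple[str, ...] = tuple(input_nodes)
        self.input_detection = dict(input_detection or {})
        self.bias = bias
        if bias is not None:
            bias.validate(self)
        self._compile()

    # -- compiled form ------------------------------------------------------

    def _compile(self) -> None:
        n = len(self.nodes)
        self._is_input = np.zeros(n, dtype=bool)
        for inp in self.input_nodes:
            self._is_input[self.node_index[inp]] = True
        self.noninput_indices = np.flatnonzero(~self._is_input)
        self.input_indices = np.flatnonzero(self._is_input)
        self._regs: list[np.ndarray] = []
        self._weights: list[np.ndarray] = []
        self._tables: list[np.ndarray] = []
        for spec in self.nodes:
            ridx = np.array([self.node_index[r] for r in spec.regulators], dtype=np.intp)
            k = len(ridx)
            self._regs.append(ridx)
            self._weights.append((1 << np.arange(k - 1, -1, -1)).astype(np.int64)
                                 if k else np.zeros(0, dtype=np.int64))
            self._tables.append(np.array(spec.truth_table, dtype=np.uint8))

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        """Number of regulatory links (input self-loops excluded)."""
        return sum(len(s.regulators) for s in self.nodes
                   if s.name not in self.input_nodes)

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def is_input(self, name: str) -> bool:
        return name in self.input_nodes

    def content_hash(self) -> str:
        """Stable hash of the model's logic (names, regulators, tables)."""
        h = hashlib.sha256()
        for spec in self.nodes:
            h.update(repr((spec.name, spec.regulators, spec.truth_table)).encode())
        h.update(repr(sorted(self.input_nodes)).encode())
        return h.hexdigest()

    # -- states -------------------------------------------------------------

    def make_state(self, mapping: dict[str, int]) -> np.ndarray:
        """Build a full state vector from a name→bit mapping (must be total)."""
        missing = set(self.node_index) - set(mapping)
        if missing:
            raise ValueError(f"partial state; missing nodes: {sorted(missing)}")
        state = np.zeros(self.n_nodes, dtype=np.uint8)
        for name, bit in mapping.items():
            state[self.node_index[name]] = 1 if bit else 0
        return state

    def state_as_dict(self, state: np.ndarray) -> dict[str, int]:
        return {n.name: int(state[i]) for i, n in enumerate(self.nodes)}

    def replace_node(self, spec: NodeSpec) -> "BooleanNetworkModel":
        """Return a copy of the model with one node's rule replaced."""
        nodes = [spec if n.name == spec.name else n for n in self.nodes]
        inputs = tuple(i for i in self.input_nodes if i != spec.name
                       or spec.is_identity_self_loop())
        return BooleanNetworkModel(nodes, name=self.name, input_nodes=inputs,
                                   bias=self.bias,
                                   input_detection=self.input_detection)


# ---------------------------------------------------------------------------
# rule-file parsing

def _names_in_order(expr: str) -> list[str]:
    """Node names in an expression, first occurrence in source order."""
    tree = ast.parse(expr, mode="eval")
    out: list[str] = []

    def visit(node):
        if isinstance(node, ast.Name) and node.id not in out:
            out.append(node.id)
        for child in ast.iter_child_nodes(node):
            visit(child)

    visit(tree)
    return out


_RULE_RE = re.compile(r"^\s*(?P<name>\w+)\s*[*∗]\s*=\s*(?P<expr>.+?)\s*$")
_INPUTS_RE = re.compile(r"^\s*(?:#|--)\s*inputs?\s*:\s*(?P<names>.+)$", re.IGNORECASE)


def parse_model(text: str, name: str = "model", auto_inputs: bool = True,
                bias: UpdateBias | None = None) -> BooleanNetworkModel:
    """Parse BooleanNet-style rule text into a compiled, validated model.

    ``Target *= expression`` lines (``∗=`` also accepted); ``#``/``--``
    comment lines and blank lines are tolerated.  A comment of the form
    ``# inputs: A, B`` explicitly declares environmental inputs, overriding
    auto-detection.  With ``auto_inputs`` (default), a symbol used as a
    regulator but never defined becomes an input; otherwise it is a parse
    error naming the symbol and line.
    """
    rules: dict[str, tuple[str, int]] = {}
    declared_inputs: list[str] | None = None
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        m = _INPUTS_RE.match(line)
        if m:
            declared_inputs = [s.strip() for s in m.group("names").replace(",", " ").split()]
            continue
        if not stripped or stripped.startswith("#") or stripped.startswith("--"):
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ParseError(f"line {lineno}: cannot parse rule {line!r}")
        node = m.group("name")
        if node in rules:
            raise ParseError(f"line {lineno}: duplicate node definition {node!r}")
        rules[node] = (m.group("expr"), lineno)
        order.append(node)
    if not rules:
        raise ParseError("empty rule file: no node definitions found")

    # regulators without a rule of their own
    detection: dict[str, str] = {}
    implicit: list[str] = []
    for node in order:
        expr, lineno = rules[node]
        try:
            names = _names_in_order(expr)
        except SyntaxError as exc:
            raise ParseError(f"line {lineno}: malformed expression "
                             f"{expr!r}: {exc.msg}") from None
        for sym in names:
            if sym not in rules and sym not in implicit:
                if not auto_inputs:
                    raise ParseError(
                        f"line {lineno}: undeclared regulator {sym!r} in rule for {node!r}")
                implicit.append(sym)
    specs: list[NodeSpec] = []
    for node in order:
        expr, _ = rules[node]
        specs.append(compile_truth_table(node, tuple(_names_in_order(expr)), expr))
    for extra in implicit:
        specs.append(compile_truth_table(extra, (extra,), extra))
        detection[extra] = "implicit (regulator with no rule)"

    if declared_inputs is not None:
        inputs = tuple(declared_inputs)
        for inp in inputs:
            if inp not in {s.name for s in specs}:
                raise ParseError(f"declared input {inp!r} is not a node")
            detection.setdefault(inp, "explicit declaration")
    else:
        inputs = tuple(s.name for s in specs
                       if s.is_identity_self_loop() or s.name in detection)
        for s in specs:
            if s.is_identity_self_loop():
                detection.setdefault(s.name, "identity self-loop")
    return BooleanNetworkModel(specs, name=name, input_nodes=inputs, bias=bias,
                               input_detection=detection)


def serialize_model(model: BooleanNetworkModel) -> str:
    """Write a model back to rule text; ``parse_model`` round-trips it."""
    lines = [f"# {model.name}"]
    if model.input_nodes:
        lines.append(f"# inputs: {', '.join(model.input_nodes)}")
    for spec in model.nodes:
        lines.append(f"{spec.name} *= {spec.expression}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# environments

def partition_environments(model: BooleanNetworkModel,
                           clamps: dict[str, int] | None = None) -> list[dict[str, int]]:
    """All input-node assignments compatible with ``clamps``.

    Each returned context is a full ``input name → bit`` mapping; dynamics
    holds inputs fixed within a context.  Clamping a subset of inputs (e.g.
    a death-receptor ligand locked OFF) halves the enumeration per clamp.
    """
    clamps = dict(clamps or {})
    for name in clamps:
        if not model.is_input(name):
            raise ValueError(f"cannot clamp non-input node {name!r}")
    free = [i for i in model.input_nodes if i not in clamps]
    contexts = []
    for bits in itertools.product((0, 1), repeat=len(free)):
        ctx = dict(clamps)
        ctx.update(zip(free, bits))
        contexts.append({i: ctx[i] for i in model.input_nodes})
    return contexts


# ---------------------------------------------------------------------------
# interaction graph

def _link_sign(spec: NodeSpec, j: int) -> str:
    """Monotonicity of regulator j in a gate: activation, inhibition or mixed."""
    k = spec.k
    table = spec.truth_table
    up = down = False
    bit = 1 << (k - 1 - j)
    for idx in range(2 ** k):
        if idx & bit:
            continue
        lo, hi = table[idx], table[idx | bit]
        if hi > lo:
            up = True
        elif hi < lo:
            down = True
    if up and not down:
        return "+"
    if down and not up:
        return "-"
    return "0" if not (up or down) else "±"


def interaction_graph(model: BooleanNetworkModel):
    """Signed interaction graph as a networkx DiGraph (sign from monotonicity)."""
    import networkx as nx

    g = nx.DiGraph(name=model.name)
    for spec in model.nodes:
        g.add_node(spec.name, is_input=int(model.is_input(spec.name)))
    for spec in model.nodes:
        if model.is_input(spec.name):
            continue
        for j, r in enumerate(spec.regulators):
            g.add_edge(r, spec.name, sign=_link_sign(spec, j))
    return g


def export_gml(model: BooleanNetworkModel, path) -> None:
    import networkx as nx

    nx.write_gml(interaction_graph(model), path)
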