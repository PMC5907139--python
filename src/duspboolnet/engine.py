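"""Boolean network engine: rule parsing, synchronous/asynchronous simulation,
attractor detection and qualitative pattern classification.

Networks are defined in a plain-text rule dialect::

    # comment lines start with '#'
    #input: Herceptin Basal     # nodes clamped externally (no rule)
    ERK = True                  # optional declared initial value
    ERK* = (HER2 or Basal) and not DUSP5
    DUSP5* = ERK

Each non-input node carries exactly one update rule ``Name* = expr`` where
``expr`` is a Boolean expression over declared node names with ``and``,
``or``, ``not`` (case-insensitive) and parentheses; standard precedence
NOT > AND > OR applies.  States are binary: a node is ON (1) or OFF (0).
Synchronous updating rewrites every node from the previous state at once;
asynchronous updating rewrites a single, uniformly chosen non-input node
per step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "NetworkState",
    "Trajectory",
    "Attractor",
    "PatternClass",
    "ParseError",
    "parse_rules",
    "step_synchronous",
    "step_asynchronous",
    "simulate",
    "find_attractor",
    "classify_node_pattern",
    "node_values",
    "symbol_string",
    "export_heatmap",
]


class ParseError(ValueError):
    """Raised when rule text violates the dialect."""


# --------------------------------------------------------------------------
# expression AST


class Expr:
    def evaluate(self, state: Mapping[str, int]) -> int:  # pragma: no cover
        raise NotImplementedError

    def variables(self) -> set[str]:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, state):
        return state[self.name]

    def variables(self):
        return {self.name}

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, state):
        return 0 if self.operand.evaluate(state) else 1

    def variables(self):
        return self.operand.variables()

    def __str__(self):
        return f"not {self._paren(self.operand)}"

    @staticmethod
    def _paren(e):
        return f"({e})" if isinstance(e, (And, Or)) else str(e)


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr

    def evaluate(self, state):
        return 1 if (self.left.evaluate(state) and self.right.evaluate(state)) else 0

    def variables(self):
        return self.left.variables() | self.right.variables()

    def __str__(self):
        def p(e):
            return f"({e})" if isinstance(e, Or) else str(e)

        return f"{p(self.left)} and {p(self.right)}"


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr

    def evaluate(self, state):
        return 1 if (self.left.evaluate(state) or self.right.evaluate(state)) else 0

    def variables(self):
        return self.left.variables() | self.right.variables()

    def __str__(self):
        return f"{self.left} or {self.right}"


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z0-9_]*)")


def _tokenize(text: str, lineno: int) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ParseError(f"line {lineno}: cannot tokenize {rest!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive-descent parser, precedence NOT > AND > OR."""

    def __init__(self, tokens: list[str], lineno: int):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError(f"line {self.lineno}: unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ParseError(
                f"line {self.lineno}: unexpected token {self.peek()!r}"
            )
        return expr

    def parse_or(self) -> Expr:
        left = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            left = Or(left, self.parse_and())
        return left

    def parse_and(self) -> Expr:
        left = self.parse_not()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            left = And(left, self.parse_not())
        return left

    def parse_not(self) -> Expr:
        tok = self.peek()
        if tok is not None and tok.lower() == "not":
            self.next()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        tok = self.next()
        if tok == "(":
            expr = self.parse_or()
            if self.next() != ")":
                raise ParseError(f"line {self.lineno}: missing ')'")
            return expr
        if tok == ")":
            raise ParseError(f"line {self.lineno}: unexpected ')'")
        if tok.lower() in ("and", "or", "not"):
            raise ParseError(f"line {self.lineno}: misplaced operator {tok!r}")
        return Var(tok)


def parse_expression(text: str, lineno: int = 0) -> Expr:
    tokens = _tokenize(text, lineno)
    if not tokens:
        raise ParseError(f"line {lineno}: empty expression")
    return _ExprParser(tokens, lineno).parse()


# --------------------------------------------------------------------------
# network and state types


NetworkState = dict  # node -> 0/1; kept as a plain dict for speed


@dataclass
class BooleanNetwork:
    """A Boolean network over named binary nodes.

    ``nodes`` preserves declaration order; ``rules`` maps every non-input
    node to its update expression; ``inputs`` are externally clamped and
    carry no rule; ``initial`` holds declared initial values (may be
    partial); ``readouts`` flags output nodes (e.g. Survival).
    """

    nodes: list[str]
    rules: dict[str, Expr]
    inputs: list[str] = field(default_factory=list)
    initial: dict[str, int] = field(default_factory=dict)
    readouts: list[str] = field(default_factory=list)

    def __post_init__(self):
        declared = set(self.nodes)
        for node, expr in self.rules.items():
            if node not in declared:
                raise ParseError(f"rule for undeclared node {node!r}")
            undeclared = expr.variables() - declared
            if undeclared:
                raise ParseError(
                    f"rule for {node!r} references undeclared node(s) "
                    f"{sorted(undeclared)}"
                )
        for node in self.nodes:
            if node in self.inputs:
                if node in self.rules:
                    raise ParseError(f"input node {node!r} must not have a rule")
            elif node not in self.rules:
                raise ParseError(f"non-input node {node!r} has no rule")

    @property
    def free_nodes(self) -> list[str]:
        """Nodes updated by rules (everything that is not clamped)."""
        return [n for n in self.nodes if n not in self.inputs]

    def rule_text(self) -> str:
        lines = []
        if self.inputs:
            lines.append("#input: " + " ".join(self.inputs))
        for node, value in self.initial.items():
            lines.append(f"{node} = {'True' if value else 'False'}")
        for node in self.nodes:
            if node in self.rules:
                lines.append(f"{node}* = {self.rules[node]}")
        return "\n".join(lines) + "\n"


@dataclass
class Trajectory:
    states: list[NetworkState]
    mode: str  # "sync" | "async"
    clamps: dict[str, int]
    seed: int | None = None

    def values(self, node: str) -> list[int]:
        return [s[node] for s in self.states]

    def __len__(self):
        return len(self.states)


@dataclass
class Attractor:
    """Transient states followed by the repeating cycle (synchronous)."""

    transient: list[NetworkState]
    cycle: list[NetworkState]

    @property
    def transient_length(self) -> int:
        return len(self.transient)

    @property
    def cycle_length(self) -> int:
        return len(self.cycle)

    def values(self, node: str) -> list[int]:
        """Node values over transient plus one full cycle."""
        return [s[node] for s in self.transient + self.cycle]


class PatternClass:
    """Qualitative classes of a node's long-run Boolean behaviour."""

    CONSTANT_ON = "CONSTANT_ON"
    CONSTANT_OFF = "CONSTANT_OFF"
    OSCILLATING = "OSCILLATING"
    ON_THEN_OFF = "ON_THEN_OFF"
    OFF_THEN_ON = "OFF_THEN_ON"

    ALL = (CONSTANT_ON, CONSTANT_OFF, OSCILLATING, ON_THEN_OFF, OFF_THEN_ON)


# --------------------------------------------------------------------------
# parsing rule files


_INPUT_DIRECTIVE = re.compile(r"^#\s*input\s*:\s*(.*)$", re.IGNORECASE)
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def parse_rules(text: str) -> BooleanNetwork:
    """Parse rule-dialect text into a :class:`BooleanNetwork`.

    Raises :class:`ParseError` naming the offending node and line for
    undeclared references, duplicate rules and empty expressions.
    """
    inputs: list[str] = []
    initial: dict[str, int] = {}
    rule_exprs: dict[str, Expr] = {}
    order: list[str] = []  # declaration order

    def declare(name: str):
        if name not in order:
            order.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _INPUT_DIRECTIVE.match(line)
        if m:
            for name in re.split(r"[,\s]+", m.group(1).strip()):
                if not name:
                    continue
                if not _NAME_RE.match(name):
                    raise ParseError(f"line {lineno}: bad input name {name!r}")
                if name in inputs:
                    raise ParseError(f"line {lineno}: duplicate input {name!r}")
                inputs.append(name)
                declare(name)
            continue
        if line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected '=' in {line!r}")
        lhs, rhs = line.split("=", 1)
        lhs = lhs.strip()
        rhs = rhs.split("#", 1)[0].strip()
        if lhs.endswith("*"):
            node = lhs[:-1].strip()
            if not _NAME_RE.match(node):
                raise ParseError(f"line {lineno}: bad node name {node!r}")
            if node in rule_exprs:
                raise ParseError(f"line {lineno}: duplicate rule for {node!r}")
            if not rhs:
                raise ParseError(f"line {lineno}: empty expression for {node!r}")
            rule_exprs[node] = parse_expression(rhs, lineno)
            declare(node)
        else:
            node = lhs
            if not _NAME_RE.match(node):
                raise ParseError(f"line {lineno}: bad node name {node!r}")
            val = rhs.strip().lower()
            if val in ("true", "1", "on"):
                initial[node] = 1
            elif val in ("false", "0", "off"):
                initial[node] = 0
            else:
                raise ParseError(
                    f"line {lineno}: initial value for {node!r} must be "
                    f"True/False, got {rhs!r}"
                )
            declare(node)

    declared = set(order)
    for node, expr in rule_exprs.items():
        undeclared = sorted(expr.variables() - declared)
        if undeclared:
            raise ParseError(
                f"rule for {node!r} references undeclared node(s) {undeclared}"
            )
    for node in order:
        if node not in inputs and node not in rule_exprs:
            raise ParseError(f"node {node!r} has neither a rule nor input status")
    return BooleanNetwork(
        nodes=order, rules=rule_exprs, inputs=inputs, initial=initial
    )


def load_rules(path) -> BooleanNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_rules(fh.read())


# --------------------------------------------------------------------------
# simulation


def _check_clamps(net: BooleanNetwork, clamps: Mapping[str, int]):
    missing = [n for n in net.inputs if n not in clamps]
    if missing:
        raise ValueError(f"missing clamp value(s) for input node(s): {missing}")
    unknown = [n for n in clamps if n not in net.inputs]
    if unknown:
        raise ValueError(f"clamp given for non-input node(s): {unknown}")


def step_synchronous(
    net: BooleanNetwork, state: NetworkState, clamps: Mapping[str, int]
) -> NetworkState:
    """Apply one synchronous update: all rules evaluated on ``state``."""
    _check_clamps(net, clamps)
    nxt = {}
    for node in net.nodes:
        if node in net.inputs:
            nxt[node] = int(clamps[node])
        else:
            nxt[node] = net.rules[node].evaluate(state)
    return nxt


def step_asynchronous(
    net: BooleanNetwork,
    state: NetworkState,
    clamps: Mapping[str, int],
    rng: np.random.Generator,
) -> NetworkState:
    """Update exactly one uniformly chosen non-input node."""
    _check_clamps(net, clamps)
    free = net.free_nodes
    chosen = free[int(rng.integers(len(free)))]
    nxt = dict(state)
    for node in net.inputs:
        nxt[node] = int(clamps[node])
    nxt[chosen] = net.rules[chosen].evaluate(state)
    return nxt


def make_initial(
    net: BooleanNetwork,
    clamps: Mapping[str, int],
    overrides: Mapping[str, int] | None = None,
    default: int = 1,
) -> NetworkState:
    """Assemble a total initial state.

    Priority: explicit ``overrides`` > declared initial values in the rule
    file > ``default``.  Input nodes always take their clamp value.
    """
    _check_clamps(net, clamps)
    state = {}
    for node in net.nodes:
        if node in net.inputs:
            state[node] = int(clamps[node])
        elif overrides and node in overrides:
            state[node] = int(overrides[node])
        elif node in net.initial:
            state[node] = net.initial[node]
        else:
            state[node] = default
    return state


def simulate(
    net: BooleanNetwork,
    initial: NetworkState,
    clamps: Mapping[str, int],
    n_steps: int,
    mode: str = "sync",
    seed: int | None = None,
) -> Trajectory:
    """Simulate ``n_steps`` updates; trajectory has ``n_steps + 1`` states."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if mode not in ("sync", "async"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_clamps(net, clamps)
    state = dict(initial)
    for node in net.inputs:
        state[node] = int(clamps[node])
    states = [state]
    if mode == "sync":
        for _ in range(n_steps):
            state = step_synchronous(net, state, clamps)
            states.append(state)
        return Trajectory(states=states, mode="sync", clamps=dict(clamps))
    if seed is None:
        raise ValueError("asynchronous simulation requires a seed")
    rng = np.random.default_rng(seed)
    for _ in range(n_steps):
        state = step_asynchronous(net, state, clamps, rng)
        states.append(state)
    return Trajectory(states=states, mode="async", clamps=dict(clamps), seed=seed)


def find_attractor(
    net: BooleanNetwork, initial: NetworkState, clamps: Mapping[str, int]
) -> Attractor:
    """Iterate synchronously until a state repeats; always terminates within
    ``2**k + 1`` steps for ``k`` free nodes."""
    _check_clamps(net, clamps)
    state = dict(initial)
    for node in net.inputs:
        state[node] = int(clamps[node])
    seen: dict[tuple, int] = {}
    history: list[NetworkState] = []
    while True:
        key = tuple(state[n] for n in net.nodes)
        if key in seen:
            start = seen[key]
            return Attractor(transient=history[:start], cycle=history[start:])
        seen[key] = len(history)
        history.append(state)
        state = step_synchronous(net, state, clamps)


# --------------------------------------------------------------------------
# exhaustive state-transition-graph analysis (independent of find_attractor's
# iterative detection; used to cross-check it)


def transition_graph(
    net: BooleanNetwork, clamps: Mapping[str, int]
) -> dict[tuple, tuple]:
    """Full synchronous transition map over all 2^k free-node states."""
    _check_clamps(net, clamps)
    free = net.free_nodes
    if len(free) > 20:
        raise ValueError("exhaustive enumeration limited to 20 free nodes")
    graph: dict[tuple, tuple] = {}
    for bits in range(2 ** len(free)):
        state = {n: int(clamps[n]) for n in net.inputs}
        for i, n in enumerate(free):
            state[n] = (bits >> i) & 1
        nxt = step_synchronous(net, state, clamps)
        key = tuple(state[n] for n in free)
        graph[key] = tuple(nxt[n] for n in free)
    return graph


def attractor_from_graph(
    net: BooleanNetwork, initial: NetworkState, clamps: Mapping[str, int]
) -> tuple[int, int]:
    """(transient_length, cycle_length) from the precomputed full graph."""
    graph = transition_graph(net, clamps)
    free = net.free_nodes
    key = tuple(int(initial[n]) for n in free)
    order: dict[tuple, int] = {}
    while key not in order:
        order[key] = len(order)
        key = graph[key]
    return order[key], len(order) - order[key]


def async_reachable_states(
    net: BooleanNetwork, initial: NetworkState, clamps: Mapping[str, int]
) -> set[tuple]:
    """All states reachable by single-node asynchronous updates (BFS)."""
    _check_clamps(net, clamps)
    free = net.free_nodes
    start = dict(initial)
    for n in net.inputs:
        start[n] = int(clamps[n])
    key0 = tuple(start[n] for n in free)
    seen = {key0}
    frontier = [start]
    while frontier:
        state = frontier.pop()
        for node in free:
            nxt = dict(state)
            nxt[node] = net.rules[node].evaluate(state)
            key = tuple(nxt[n] for n in free)
            if key not in seen:
                seen.add(key)
                frontier.append(nxt)
    return seen


def random_network(
    n_nodes: int, rng: np.random.Generator, max_literals: int = 3
) -> BooleanNetwork:
    """A random Boolean network (no inputs) for engine stress-testing.

    Each node's rule is a random AND/OR tree over 1..max_literals uniformly
    chosen (possibly negated) node literals.
    """
    names = [f"N{i}" for i in range(n_nodes)]

    def literal() -> Expr:
        v: Expr = Var(names[int(rng.integers(n_nodes))])
        return Not(v) if rng.random() < 0.5 else v

    rules = {}
    for name in names:
        expr = literal()
        for _ in range(int(rng.integers(0, max_literals))):
            op = And if rng.random() < 0.5 else Or
            expr = op(expr, literal())
        rules[name] = expr
    return BooleanNetwork(nodes=names, rules=rules)


# --------------------------------------------------------------------------
# pattern classification


def node_values(traj_or_attr, node: str) -> list[int]:
    if isinstance(traj_or_attr, Attractor):
        return traj_or_attr.values(node)
    return traj_or_attr.values(node)


def classify_node_pattern(traj_or_attr, node: str) -> str:
    """Classify a node's qualitative long-run behaviour.

    With an :class:`Attractor`: OSCILLATING if the node varies within the
    cycle; otherwise the initial value is compared to the settled cycle
    value (1→0 ON_THEN_OFF, 0→1 OFF_THEN_ON, unchanged → CONSTANT_x).
    Transient excursions that return to the starting level do not alter a
    CONSTANT call.  With a plain :class:`Trajectory`, the trailing value is
    treated as the settled level (callers should simulate past the cycle).
    """
    if isinstance(traj_or_attr, Attractor):
        if node not in (traj_or_attr.transient + traj_or_attr.cycle)[0]:
            raise KeyError(f"unknown node {node!r}")
        cyc = [s[node] for s in traj_or_attr.cycle]
        all_vals = traj_or_attr.values(node)
    else:
        if node not in traj_or_attr.states[0]:
            raise KeyError(f"unknown node {node!r}")
        all_vals = traj_or_attr.values(node)
        cyc = [all_vals[-1]]
    if len(set(cyc)) > 1:
        return PatternClass.OSCILLATING
    settled = cyc[0]
    start = all_vals[0]
    if all(v == settled for v in all_vals):
        return PatternClass.CONSTANT_ON if settled else PatternClass.CONSTANT_OFF
    if start == 1 and settled == 0:
        return PatternClass.ON_THEN_OFF
    if start == 0 and settled == 1:
        return PatternClass.OFF_THEN_ON
    # returned to its initial level after a transient excursion
    return PatternClass.CONSTANT_ON if settled else PatternClass.CONSTANT_OFF


def symbol_string(values: Sequence[int], compress: bool = False) -> str:
    """Direction symbols (+/-/0) between consecutive Boolean values.

    With ``compress=True`` consecutive repeats are collapsed, reflecting
    that Boolean dwell times are arbitrary relative to experimental time.
    """
    syms = []
    for a, b in zip(values[:-1], values[1:]):
        syms.append("+" if b > a else "-" if b < a else "0")
    s = "".join(syms)
    if compress:
        s = re.sub(r"(.)\1+", r"\1", s)
    return s


# --------------------------------------------------------------------------
# export


def trajectory_matrix(traj: Trajectory):
    """Node × time 0/1 matrix (pandas DataFrame), rows in declaration order."""
    import pandas as pd

    nodes = list(traj.states[0].keys())
    data = {t: [s[n] for n in nodes] for t, s in enumerate(traj.states)}
    return pd.DataFrame(data, index=nodes)


def export_heatmap(traj: Trajectory, path_prefix) -> tuple[str, str]:
    """Write the trajectory as a TSV matrix and a two-colour PNG heatmap.

    Green marks ON states, red OFF.  Returns (tsv_path, png_path).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if not traj.states:
        raise ValueError("empty trajectory")
    df = trajectory_matrix(traj)
    tsv_path = f"{path_prefix}.tsv"
    png_path = f"{path_prefix}.png"
    df.to_csv(tsv_path, sep="\t")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * df.shape[1]), max(2, 0.4 * df.shape[0]))
    )
    cmap = ListedColormap(["#c0392b", "#27ae60"])  # red OFF, green ON
    ax.imshow(df.values, aspect="auto", cmap=cmap, vmin=0, vmax=1)
    ax.set_yticks(range(df.shape[0]), df.index)
    ax.set_xticks(range(0, df.shape[1], max(1, df.shape[1] // 16)))
    ax.set_xlabel("Boolean time step")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return tsv_path, png_path
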