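"""Evolvable-mathematical-model genomes.

An agent's controller is a system of difference equations encoded as a set
of directed expression trees (the genome).  Terminal nodes are variable
leaves (``x``, ``y``, ``win``, ``noise`` or an evolved state variable) or
numeric constant leaves; branch nodes apply one of the four basic
arithmetic operations to exactly two children.  Every genome carries one
tree for the motor heading ``theta``, one for the communication output
``omega_out``, and zero or more trees defining the per-step increment of
evolved state variables.  The motion equations

    dx = a * dt * cos(theta)      dy = a * dt * sin(theta)

are built in and immutable; they are never represented as mutable trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

__all__ = [
    "ExprNode",
    "EquationTree",
    "Genome",
    "AgentState",
    "TagAllocator",
    "GenomeError",
    "ParseError",
    "THETA",
    "OMEGA",
    "BASE_VARS",
    "branch",
    "var",
    "const",
    "fdiv",
    "evaluate_tree",
    "tree_node_count",
    "count_nodes",
    "nodes_equal",
    "copy_tree",
    "iter_nodes",
    "tree_depth",
    "tree_variables",
    "generate_random_tree",
    "ramped_half_and_half",
    "reduce_tree",
    "reduce_equations",
    "serialize_expr",
    "parse_expr",
    "serialize_genome",
    "parse_genome",
    "genome_to_dict",
    "genome_from_dict",
    "validate_genome",
    "compile_genome",
    "CompiledGenome",
]

# Target roles for equation trees.
THETA = "theta"
OMEGA = "omega_out"
DELTA_PREFIX = "delta:"

#: Variables every genome may reference without defining them.
BASE_VARS = ("x", "y", "win", "noise")

OPS = ("+", "-", "*", "/")

NODE_LIMIT = 200


class GenomeError(ValueError):
    """Raised on genome corruption (dangling variable, missing role tree...)."""


class ParseError(ValueError):
    """Malformed genome text; carries 1-based line and column."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class ExprNode:
    """One node of an expression tree.

    ``kind`` is "branch", "var" or "const".  Branch nodes hold an operator
    token from ``OPS`` and exactly two children; variable leaves hold a
    variable identifier; constant leaves hold a float.
    """

    __slots__ = ("kind", "op", "var_id", "value", "children")

    def __init__(self, kind, op=None, var_id=None, value=None, children=None):
        self.kind = kind
        self.op = op
        self.var_id = var_id
        self.value = value
        self.children = children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"ExprNode({serialize_expr(self)})"


def branch(op: str, left: ExprNode, right: ExprNode) -> ExprNode:
    if op not in OPS:
        raise ValueError(f"unknown operator {op!r}")
    return ExprNode("branch", op=op, children=[left, right])


def var(name: str) -> ExprNode:
    return ExprNode("var", var_id=name)


def const(value: float) -> ExprNode:
    return ExprNode("const", value=float(value))


def fdiv(a: float, b: float) -> float:
    """IEEE-754 style division: x/0 -> signed inf, 0/0 -> nan.

    Non-finite results propagate through the tree; the world engine turns
    them into an overflow death rather than protecting the division.
    """
    try:
        return a / b
    except ZeroDivisionError:
        if a == 0.0 or a != a:
            return math.nan
        return math.copysign(math.inf, a) * math.copysign(1.0, b)


def evaluate_tree(root: ExprNode, bindings: Mapping[str, float]) -> float:
    """Recursively evaluate a tree under the given variable bindings.

    Unresolvable variables raise :class:`GenomeError` (genome corruption).
    """
    kind = root.kind
    if kind == "const":
        return root.value
    if kind == "var":
        try:
            return bindings[root.var_id]
        except KeyError:
            raise GenomeError(f"unresolvable variable {root.var_id!r}") from None
    left = evaluate_tree(root.children[0], bindings)
    right = evaluate_tree(root.children[1], bindings)
    op = root.op
    if op == "+":
        return left + right
    if op == "-":
        return left - right
    if op == "*":
        return left * right
    return fdiv(left, right)


def iter_nodes(root: ExprNode) -> Iterator[ExprNode]:
    """Pre-order traversal."""
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        if node.kind == "branch":
            stack.append(node.children[1])
            stack.append(node.children[0])


def tree_node_count(root: ExprNode) -> int:
    return sum(1 for _ in iter_nodes(root))


def tree_depth(root: ExprNode) -> int:
    """Depth counted in nodes: a lone leaf has depth 1."""
    if root.kind != "branch":
        return 1
    return 1 + max(tree_depth(root.children[0]), tree_depth(root.children[1]))


def tree_variables(root: ExprNode) -> set:
    return {n.var_id for n in iter_nodes(root) if n.kind == "var"}


def nodes_equal(a: ExprNode, b: ExprNode) -> bool:
    if a.kind != b.kind:
        return False
    if a.kind == "const":
        # Bit-level identity (repr round-trips exactly); nan == nan here.
        return (a.value == b.value) or (a.value != a.value and b.value != b.value)
    if a.kind == "var":
        return a.var_id == b.var_id
    return (
        a.op == b.op
        and nodes_equal(a.children[0], b.children[0])
        and nodes_equal(a.children[1], b.children[1])
    )


def copy_tree(root: ExprNode) -> ExprNode:
    if root.kind == "branch":
        return ExprNode(
            "branch",
            op=root.op,
            children=[copy_tree(root.children[0]), copy_tree(root.children[1])],
        )
    if root.kind == "var":
        return ExprNode("var", var_id=root.var_id)
    return ExprNode("const", value=root.value)


@dataclass
class EquationTree:
    """A single mutable equation with its lineage identification tag."""

    tag: int
    target: str  # "theta", "omega_out" or "delta:<var>"
    root: ExprNode

    @property
    def is_delta(self) -> bool:
        return self.target.startswith(DELTA_PREFIX)

    @property
    def delta_var(self) -> str:
        if not self.is_delta:
            raise ValueError(f"tree {self.tag} targets {self.target}, not a state delta")
        return self.target[len(DELTA_PREFIX):]

    def copy(self) -> "EquationTree":
        return EquationTree(self.tag, self.target, copy_tree(self.root))


def delta_target(varname: str) -> str:
    return DELTA_PREFIX + varname


@dataclass
class Genome:
    """The full evolvable system: a set of equation trees plus v0.

    ``trees`` always contains exactly one theta tree and one omega_out
    tree; every evolved state variable referenced anywhere has a defining
    delta tree and an initial value in ``v0``.
    """

    trees: list = field(default_factory=list)
    v0: dict = field(default_factory=dict)

    @property
    def theta_tree(self) -> EquationTree:
        return next(t for t in self.trees if t.target == THETA)

    @property
    def omega_tree(self) -> EquationTree:
        return next(t for t in self.trees if t.target == OMEGA)

    @property
    def delta_trees(self) -> dict:
        return {t.delta_var: t for t in self.trees if t.is_delta}

    @property
    def evolved_vars(self) -> list:
        """Evolved state-variable names in tree order (x, y are built in)."""
        return [t.delta_var for t in self.trees if t.is_delta]

    @property
    def vocab(self) -> list:
        """All variable identifiers resolvable inside this genome."""
        return list(BASE_VARS) + self.evolved_vars

    @property
    def node_count(self) -> int:
        return count_nodes(self)

    def copy(self) -> "Genome":
        return Genome([t.copy() for t in self.trees], dict(self.v0))


@dataclass
class AgentState:
    """Runtime state of one agent.

    The motion gain ``a`` is drawn once at birth from N(1, 0.025) and is
    fixed for the agent's lifetime.  ``marked_for_death`` covers both the
    overflow rule and falling off the island edge; marked agents are the
    ones selected to die when the next birth occurs.
    """

    x: float
    y: float
    svals: list  # evolved state-variable values, genome order
    a: float
    theta: float = 0.0
    omega_out: float = 0.0
    omega_in: float = 0.0
    marked_for_death: bool = False
    repro_count: int = 0


class TagAllocator:
    """Monotonic source of globally unique equation tags."""

    def __init__(self, start: int = 0):
        self._next = start

    def new_tag(self) -> int:
        tag = self._next
        self._next += 1
        return tag

    @property
    def next_tag(self) -> int:
        return self._next


def count_nodes(genome: Genome) -> int:
    """Total nodes over all mutable trees (motion equations excluded)."""
    return sum(tree_node_count(t.root) for t in genome.trees)


# --------------------------------------------------------------------------
# Random tree generation (ramped half-and-half)
# --------------------------------------------------------------------------

def _random_terminal(vocab: Sequence[str], rng) -> ExprNode:
    # Variable leaf or constant leaf with equal probability; constants are
    # drawn uniformly from [-5, 5].
    if vocab and rng.random() < 0.5:
        return var(vocab[int(rng.integers(len(vocab)))])
    return const(rng.uniform(-5.0, 5.0))


def generate_random_tree(
    max_depth: int, method: str, vocab: Sequence[str], rng
) -> ExprNode:
    """Generate a random tree with the "full" or "grow" method.

    Depth is counted in nodes (a single leaf has depth 1).  With "full",
    every path reaches exactly ``max_depth`` and terminals appear only at
    the maximum depth; with "grow", nodes above the maximum depth are
    terminal or nonterminal with equal likelihood.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if method not in ("full", "grow"):
        raise ValueError(f"unknown method {method!r}")
    if max_depth == 1:
        return _random_terminal(vocab, rng)
    if method == "grow" and rng.random() < 0.5:
        return _random_terminal(vocab, rng)
    op = OPS[int(rng.integers(4))]
    return branch(
        op,
        generate_random_tree(max_depth - 1, method, vocab, rng),
        generate_random_tree(max_depth - 1, method, vocab, rng),
    )


def ramped_half_and_half(
    vocab: Sequence[str], rng, depths: Sequence[int] = (1, 2)
) -> ExprNode:
    """Full or grow with probability 1/2 each, max depth uniform over ``depths``.

    The default depth ramp {1, 2} is the one used both for primordial
    genomes and for subtrees generated at mutation time.
    """
    method = "full" if rng.random() < 0.5 else "grow"
    depth = int(depths[int(rng.integers(len(depths)))])
    return generate_random_tree(depth, method, vocab, rng)


def primordial_genome(tag_alloc: TagAllocator, rng) -> Genome:
    """A random starting genome: one theta tree and one omega_out tree.

    Primordial trees are ramped half-and-half with maximum depth 1 or 2;
    there are no evolved state equations at birth of the world, so v0 is
    empty.  New state equations arise only through mutation.
    """
    vocab = list(BASE_VARS)
    theta = EquationTree(tag_alloc.new_tag(), THETA, ramped_half_and_half(vocab, rng))
    omega = EquationTree(tag_alloc.new_tag(), OMEGA, ramped_half_and_half(vocab, rng))
    return Genome([theta, omega], {})


# --------------------------------------------------------------------------
# Equation reduction
# --------------------------------------------------------------------------

def _is_zero_const(node: ExprNode) -> bool:
    return node.kind == "const" and node.value == 0.0


def reduce_tree(root: ExprNode) -> ExprNode:
    """Apply the five rewrite rules recursively to a fixed point.

    1. const op const  ->  const (the encoded operation is performed)
    2. T + T           ->  2 * T      (identical subtrees)
    3. T - T           ->  0
    4. T * 0, 0 * T    ->  0
    5. 0 / T           ->  0          (T not the constant zero)
    """
    if root.kind != "branch":
        return root
    left = reduce_tree(root.children[0])
    right = reduce_tree(root.children[1])
    op = root.op
    if left.kind == "const" and right.kind == "const":
        if op == "+":
            return const(left.value + right.value)
        if op == "-":
            return const(left.value - right.value)
        if op == "*":
            return const(left.value * right.value)
        return const(fdiv(left.value, right.value))
    if op == "+" and nodes_equal(left, right):
        return reduce_tree(branch("*", const(2.0), left))
    if op == "-" and nodes_equal(left, right):
        return const(0.0)
    if op == "*" and (_is_zero_const(left) or _is_zero_const(right)):
        return const(0.0)
    if op == "/" and _is_zero_const(left) and not _is_zero_const(right):
        return const(0.0)
    return branch(op, left, right)


def reduce_equations(genome: Genome) -> Genome:
    """Return a new genome with every tree reduced (the input is untouched)."""
    return Genome(
        [EquationTree(t.tag, t.target, reduce_tree(copy_tree(t.root))) for t in genome.trees],
        dict(genome.v0),
    )


# --------------------------------------------------------------------------
# S-expression serialization
# --------------------------------------------------------------------------

def _render_const(value: float) -> str:
    if math.isnan(value):
        return "nan"
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    return repr(value)  # shortest decimal that round-trips bit-exactly


def serialize_expr(root: ExprNode) -> str:
    """Prefix S-expression over tokens (+ - * / x y win noise s<k> <decimal>)."""
    if root.kind == "const":
        return _render_const(root.value)
    if root.kind == "var":
        return root.var_id
    return "({} {} {})".format(
        root.op, serialize_expr(root.children[0]), serialize_expr(root.children[1])
    )


def _tokenize(text: str):
    tokens = []  # (token, line, col)
    line, col = 1, 1
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            col = 1
            i += 1
            continue
        if ch.isspace():
            col += 1
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, line, col))
            col += 1
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        tokens.append((text[i:j], line, col))
        col += j - i
        i = j
    return tokens


_VAR_TOKENS = set(BASE_VARS)


def _parse_tokens(tokens, pos):
    if pos >= len(tokens):
        last = tokens[-1] if tokens else ("", 1, 1)
        raise ParseError("unexpected end of input", last[1], last[2])
    tok, line, col = tokens[pos]
    if tok == "(":
        if pos + 1 >= len(tokens):
            raise ParseError("unexpected end of input", line, col)
        op, oline, ocol = tokens[pos + 1]
        if op not in OPS:
            raise ParseError(f"expected operator, got {op!r}", oline, ocol)
        left, pos = _parse_tokens(tokens, pos + 2)
        right, pos = _parse_tokens(tokens, pos)
        if pos >= len(tokens) or tokens[pos][0] != ")":
            where = tokens[pos] if pos < len(tokens) else tokens[-1]
            raise ParseError("expected ')'", where[1], where[2])
        return branch(op, left, right), pos + 1
    if tok == ")":
        raise ParseError("unexpected ')'", line, col)
    if tok in _VAR_TOKENS or (tok.startswith("s") and tok[1:].isdigit()):
        return var(tok), pos + 1
    try:
        return const(float(tok)), pos + 1
    except ValueError:
        raise ParseError(f"unrecognized token {tok!r}", line, col) from None


def parse_expr(text: str) -> ExprNode:
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty expression", 1, 1)
    node, pos = _parse_tokens(tokens, 0)
    if pos != len(tokens):
        tok, line, col = tokens[pos]
        raise ParseError(f"trailing token {tok!r}", line, col)
    return node


def genome_to_dict(genome: Genome) -> dict:
    return {
        "trees": [
            {"tag": t.tag, "target": t.target, "expr": serialize_expr(t.root)}
            for t in genome.trees
        ],
        "v0": {k: genome.v0[k] for k in sorted(genome.v0)},
    }


def genome_from_dict(data: dict) -> Genome:
    trees = [
        EquationTree(int(t["tag"]), str(t["target"]), parse_expr(t["expr"]))
        for t in data["trees"]
    ]
    v0 = {str(k): float(v) for k, v in data.get("v0", {}).items()}
    return Genome(trees, v0)


def serialize_genome(genome: Genome) -> str:
    """Byte-stable JSON text for one genome (sorted keys, repr'd floats)."""
    return json.dumps(genome_to_dict(genome), sort_keys=True, separators=(",", ":"))


def parse_genome(text: str) -> Genome:
    if not text.strip():
        raise ParseError("empty genome text", 1, 1)
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc.msg}", exc.lineno, exc.colno) from None
    return genome_from_dict(data)


# --------------------------------------------------------------------------
# Validation and compilation
# --------------------------------------------------------------------------

def validate_genome(genome: Genome, node_limit: int = NODE_LIMIT) -> None:
    """Raise :class:`GenomeError` unless the genome satisfies all invariants."""
    roles = [t.target for t in genome.trees]
    if roles.count(THETA) != 1:
        raise GenomeError(f"expected exactly one theta tree, found {roles.count(THETA)}")
    if roles.count(OMEGA) != 1:
        raise GenomeError(f"expected exactly one omega_out tree, found {roles.count(OMEGA)}")
    tags = [t.tag for t in genome.trees]
    if len(tags) != len(set(tags)):
        raise GenomeError("duplicate equation tags")
    defined = set(genome.evolved_vars)
    if len(defined) != len(genome.evolved_vars):
        raise GenomeError("duplicate state-variable definitions")
    scope = set(BASE_VARS) | defined
    for t in genome.trees:
        missing = tree_variables(t.root) - scope
        if missing:
            raise GenomeError(f"tree {t.tag} references undefined {sorted(missing)}")
    missing_v0 = defined - set(genome.v0)
    if missing_v0:
        raise GenomeError(f"missing v0 entries for {sorted(missing_v0)}")
    if node_limit is not None and count_nodes(genome) > node_limit:
        raise GenomeError(f"genome exceeds {node_limit} nodes")


def _expr_source(root: ExprNode, names: Mapping[str, str]) -> str:
    if root.kind == "const":
        v = root.value
        if math.isnan(v):
            return "_nan"
        if math.isinf(v):
            return "_inf" if v > 0 else "(-_inf)"
        return repr(v)
    if root.kind == "var":
        return names[root.var_id]
    left = _expr_source(root.children[0], names)
    right = _expr_source(root.children[1], names)
    if root.op == "/":
        return f"_div({left}, {right})"
    return f"({left} {root.op} {right})"


class CompiledGenome:
    """A genome compiled to a single Python function for the inner loop.

    ``step(x, y, win, noise, *svals)`` returns ``(theta, omega_out,
    deltas)`` where ``deltas`` aligns with ``evolved_vars``.  Semantics are
    identical to :func:`evaluate_tree` on each tree.
    """

    __slots__ = ("genome", "evolved_vars", "uses_noise", "step", "n_state")

    def __init__(self, genome: Genome):
        self.genome = genome
        self.evolved_vars = genome.evolved_vars
        self.n_state = len(self.evolved_vars)
        names = {"x": "x", "y": "y", "win": "win", "noise": "noise"}
        for i, v in enumerate(self.evolved_vars):
            names[v] = f"v{i}"
        args = ["x", "y", "win", "noise"] + [f"v{i}" for i in range(self.n_state)]
        deltas = genome.delta_trees
        exprs = [
            _expr_source(genome.theta_tree.root, names),
            _expr_source(genome.omega_tree.root, names),
        ] + [_expr_source(deltas[v].root, names) for v in self.evolved_vars]
        src = "def _step({}):\n    return ({},)".format(
            ", ".join(args), ", ".join(exprs)
        )
        ns = {"_div": fdiv, "_nan": math.nan, "_inf": math.inf}
        exec(compile(src, "<genome>", "exec"), ns)
        self.step = ns["_step"]
        self.uses_noise = any("noise" in tree_variables(t.root) for t in genome.trees)
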