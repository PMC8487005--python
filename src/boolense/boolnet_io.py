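"""Read and write Boolean networks in the "targets, factors" text dialect.

One line per gene: ``gene, expression`` where the expression grammar is
limited to gene names, ``!`` (negation), ``&`` (conjunction), ``|``
(disjunction), parentheses, and the literals ``0``/``1``.  This is the
dialect understood by the BoolNet R package, so ground-truth and
reconstructed networks can be audited with independent tooling.

The writer emits a canonical disjunctive normal form whose minterms list the
function inputs in their stored order; the reader recovers input order from
first appearance.  Writing then reading a network reproduces it exactly
(same input order, same truth table).
"""

from __future__ import annotations

import json
import re
from itertools import product
from typing import Iterable

from .network import Attractor, BooleanFunction, BooleanNetwork, GeneUniverse

__all__ = [
    "function_to_expression",
    "expression_to_function",
    "write_network",
    "read_network",
    "network_to_lines",
    "network_from_lines",
    "attractor_report",
    "write_attractor_report",
]

_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_.:-]*|[01()!&|])")


def function_to_expression(f: BooleanFunction) -> str:
    """Render a truth table as a DNF expression over its inputs."""
    if f.is_constant:
        return str(f.table[0])
    ones = [i for i, b in enumerate(f.table) if b == 1]
    k = len(f.inputs)
    if not ones:
        # degenerate all-zero table: keep the inputs recoverable
        return " & ".join(["0", *f.inputs])
    if len(ones) == len(f.table):
        return " | ".join(["1", *f.inputs])
    terms = []
    for pattern in ones:
        lits = []
        for j, name in enumerate(f.inputs):
            bit = (pattern >> (k - 1 - j)) & 1
            lits.append(name if bit else f"!{name}")
        terms.append("(" + " & ".join(lits) + ")" if k > 1 else lits[0])
    return " | ".join(terms)


class _Parser:
    """Recursive-descent parser for the restricted Boolean expression grammar."""

    def __init__(self, text: str):
        self.tokens = self._tokenize(text)
        self.pos = 0
        self.genes: list[str] = []  # in order of first appearance

    @staticmethod
    def _tokenize(text: str) -> list[str]:
        tokens = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                if text[pos:].strip():
                    raise ValueError(f"cannot tokenize expression near {text[pos:]!r}")
                break
            tokens.append(m.group(1))
            pos = m.end()
        return tokens

    def _peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise ValueError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self._expr()
        if self._peek() is not None:
            raise ValueError(f"trailing tokens in expression: {self.tokens[self.pos:]}")
        return node

    def _expr(self):
        node = self._term()
        while self._peek() == "|":
            self._next()
            node = ("or", node, self._term())
        return node

    def _term(self):
        node = self._factor()
        while self._peek() == "&":
            self._next()
            node = ("and", node, self._factor())
        return node

    def _factor(self):
        tok = self._next()
        if tok == "!":
            return ("not", self._factor())
        if tok == "(":
            node = self._expr()
            if self._next() != ")":
                raise ValueError("unbalanced parentheses")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in ("&", "|", ")"):
            raise ValueError(f"unexpected token {tok!r}")
        if tok not in self.genes:
            self.genes.append(tok)
        return ("gene", tok)


def _eval_node(node, env: dict[str, int]) -> int:
    op = node[0]
    if op == "const":
        return node[1]
    if op == "gene":
        return env[node[1]]
    if op == "not":
        return 1 - _eval_node(node[1], env)
    if op == "and":
        return _eval_node(node[1], env) & _eval_node(node[2], env)
    if op == "or":
        return _eval_node(node[1], env) | _eval_node(node[2], env)
    raise AssertionError(op)


def expression_to_function(target: str, expression: str) -> BooleanFunction:
    """Parse an expression into a truth-table function.

    Inputs are the gene names in order of first appearance; the table is
    computed by evaluating the expression over all input patterns (first
    input = most significant bit).
    """
    parser = _Parser(expression)
    node = parser.parse()
    inputs = tuple(parser.genes)
    table = []
    for bits in product((0, 1), repeat=len(inputs)):
        env = dict(zip(inputs, bits))
        table.append(_eval_node(node, env))
    return BooleanFunction(target=target, inputs=inputs, table=tuple(table))


def network_to_lines(net: BooleanNetwork) -> list[str]:
    lines = ["targets, factors"]
    for f in net.functions:
        lines.append(f"{f.target}, {function_to_expression(f)}")
    return lines


def network_from_lines(lines: Iterable[str]) -> BooleanNetwork:
    functions = []
    names = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().replace(" ", "") == "targets,factors":
            continue
        target, _, expr = line.partition(",")
        target = target.strip()
        if not _:
            raise ValueError(f"malformed network line: {raw!r}")
        functions.append(expression_to_function(target, expr.strip()))
        names.append(target)
    universe = GeneUniverse(tuple(names))
    return BooleanNetwork(universe=universe, functions=tuple(functions))


def write_network(net: BooleanNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(network_to_lines(net)) + "\n")


def read_network(path) -> BooleanNetwork:
    with open(path) as fh:
        return network_from_lines(fh)


def attractor_report(attractors: Iterable[Attractor]) -> dict:
    """JSON-serializable attractor summary: states as 0/1 strings in universe order."""
    return {
        "attractors": [
            {
                "length": a.length,
                "states": ["".join(str(b) for b in s) for s in a.states],
            }
            for a in attractors
        ]
    }


def write_attractor_report(attractors: Iterable[Attractor], path) -> None:
    with open(path, "w") as fh:
        json.dump(attractor_report(attractors), fh, indent=1)
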