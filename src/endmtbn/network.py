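"""Core types for synchronous Boolean networks.

A :class:`BooleanNetwork` is an ordered list of named nodes, each with a
:class:`RegulatoryFunction` giving the node's next value as a function of
its regulators.  Update rules are compiled to truth tables at construction
time; the original expression strings are retained for text export.

State conventions (fixed throughout the package):

* a network state is either a length-``n`` binary vector in canonical node
  order, or the equivalent unsigned integer with node index 0 as the least
  significant bit;
* truth-table rows are ordered by reading the regulator tuple as a binary
  number with the first-listed regulator as the most significant bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expressions import (
    Expr,
    ExpressionError,
    compile_truth_table,
    format_expression,
    parse_expression,
)

__all__ = [
    "NODE_NAME_ALIASES",
    "normalize_node_name",
    "RegulatoryFunction",
    "BooleanNetwork",
    "NetworkError",
    "validate_network",
    "pack_state",
    "unpack_state",
    "evaluate_rule",
]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or unknown node names."""


#: Accepted alternative spellings, mapped to the canonical ASCII node name.
NODE_NAME_ALIASES: dict[str, str] = {
    "HIF1α": "HIF1a",
    "HIF1A": "HIF1a",
    "HIF1alpha": "HIF1a",
    "NFκB": "NFkB",
    "NF-κB": "NFkB",
    "NF-kB": "NFkB",
    "NFKB": "NFkB",
    "TGFβ": "TGFB",
    "TGFb": "TGFB",
    "TGFβR": "TGFBR",
    "TGFbR": "TGFBR",
    "β-catenin": "CTNNB",
    "beta-catenin": "CTNNB",
    "CTNNB1": "CTNNB",
    "PDGF-AB": "PDGF_AB",
    "PDGFAB": "PDGF_AB",
    "NPR1": "NRP1",  # frequent transposition of the neuropilin-1 symbol
}


def normalize_node_name(name: str) -> str:
    """Map alternative spellings (Greek letters, hyphens) to canonical form."""
    return NODE_NAME_ALIASES.get(name, name)


@dataclass(frozen=True)
class RegulatoryFunction:
    """Update rule of one node: a truth table over named regulators."""

    target: str
    regulators: tuple[str, ...]
    table: np.ndarray  # uint8, length 2**len(regulators), read-only
    expression: str

    def __post_init__(self):
        table = np.ascontiguousarray(self.table, dtype=np.uint8)
        table.setflags(write=False)
        object.__setattr__(self, "table", table)
        if len(self.regulators) != len(set(self.regulators)):
            raise NetworkError(
                f"rule for {self.target}: duplicate regulators {self.regulators}"
            )
        if table.shape != (1 << len(self.regulators),):
            raise NetworkError(
                f"rule for {self.target}: table length {table.size} != "
                f"2**{len(self.regulators)}"
            )
        if table.size and not np.isin(table, (0, 1)).all():
            raise NetworkError(f"rule for {self.target}: table entries must be 0/1")

    @classmethod
    def from_expression(cls, target: str, text: str) -> "RegulatoryFunction":
        expr = parse_expression(text)
        expr = _normalize_ast(expr)
        regulators = tuple(expr.variables())
        table = compile_truth_table(expr, regulators)
        return cls(
            target=normalize_node_name(target),
            regulators=regulators,
            table=table,
            expression=format_expression(expr),
        )

    @classmethod
    def constant(cls, target: str, value: int) -> "RegulatoryFunction":
        return cls(
            target=normalize_node_name(target),
            regulators=(),
            table=np.array([int(value)], dtype=np.uint8),
            expression=str(int(value)),
        )

    @property
    def k(self) -> int:
        return len(self.regulators)

    @property
    def is_identity_source(self) -> bool:
        """True for the identity rule on the node itself (a source node)."""
        return (
            self.regulators == (self.target,)
            and self.table[0] == 0
            and self.table[1] == 1
        )

    @property
    def is_constant(self) -> bool:
        return self.table.size == 1 or bool((self.table == self.table[0]).all())

    def __call__(self, regulator_values: Sequence[int]) -> int:
        row = 0
        for v in regulator_values:
            row = (row << 1) | (int(v) & 1)
        return int(self.table[row])

    def nonfunctional_regulators(self) -> list[str]:
        """Regulators whose value never changes the output (vacuous inputs)."""
        vacuous = []
        k = self.k
        rows = np.arange(1 << k, dtype=np.uint32)
        for j, reg in enumerate(self.regulators):
            bit = np.uint32(1 << (k - 1 - j))
            low = rows[(rows & bit) == 0]
            if (self.table[low] == self.table[low | bit]).all():
                vacuous.append(reg)
        return vacuous

    def matches_expression(self) -> bool:
        """Re-evaluate the stored expression and compare with the table."""
        expr = parse_expression(self.expression)
        recompiled = compile_truth_table(expr, self.regulators)
        return bool(np.array_equal(recompiled, self.table))


def _normalize_ast(expr: Expr) -> Expr:
    """Rewrite variable names in an AST to canonical spellings."""
    from .expressions import And, Const, Not, Or, Var

    if isinstance(expr, Var):
        return Var(normalize_node_name(expr.name))
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(_normalize_ast(expr.operand))
    if isinstance(expr, And):
        return And(tuple(_normalize_ast(op) for op in expr.operands))
    if isinstance(expr, Or):
        return Or(tuple(_normalize_ast(op) for op in expr.operands))
    raise TypeError(expr)


class BooleanNetwork:
    """A synchronous Boolean network: ordered nodes plus one rule per node."""

    def __init__(
        self,
        rules: Iterable[RegulatoryFunction],
        name: str = "network",
        metadata: Mapping[str, object] | None = None,
    ):
        self.rules: list[RegulatoryFunction] = list(rules)
        self.nodes: list[str] = [r.target for r in self.rules]
        self.name = name
        self.metadata: dict = dict(metadata or {})
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkError("duplicate node names")
        self._index = {name: i for i, name in enumerate(self.nodes)}
        for rule in self.rules:
            for reg in rule.regulators:
                if reg not in self._index:
                    raise NetworkError(
                        f"rule for {rule.target}: unknown regulator {reg!r}"
                    )

    # -- basic queries ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def node_index(self, name: str) -> int:
        name = normalize_node_name(name)
        try:
            return self._index[name]
        except KeyError:
            raise NetworkError(f"unknown node name {name!r}") from None

    def rule(self, name: str) -> RegulatoryFunction:
        return self.rules[self.node_index(name)]

    @property
    def source_nodes(self) -> list[str]:
        """Nodes whose rule is the identity on themselves (inputs)."""
        return [r.target for r in self.rules if r.is_identity_source]

    def is_source(self, name: str) -> bool:
        return self.rules[self.node_index(name)].is_identity_source

    # -- state conversions -----------------------------------------------

    def state_array(self, state) -> np.ndarray:
        """Coerce an int, sequence, or name->bit mapping to a bit vector."""
        if isinstance(state, (int, np.integer)):
            return unpack_state(int(state), self.n)
        if isinstance(state, Mapping):
            missing = [nd for nd in self.nodes if normalize_node_name(nd) not in
                       {normalize_node_name(k) for k in state}]
            if missing:
                raise NetworkError(f"state mapping missing nodes: {missing}")
            lookup = {normalize_node_name(k): v for k, v in state.items()}
            return np.array([int(lookup[nd]) & 1 for nd in self.nodes],
                            dtype=np.uint8)
        arr = np.asarray(state, dtype=np.uint8)
        if arr.shape != (self.n,):
            raise NetworkError(f"state length {arr.size} != {self.n}")
        return arr

    def state_int(self, state) -> int:
        if isinstance(state, (int, np.integer)):
            return int(state)
        return pack_state(self.state_array(state))

    def state_map(self, state) -> dict[str, int]:
        arr = self.state_array(state)
        return {name: int(bit) for name, bit in zip(self.nodes, arr)}

    # -- derived networks ------------------------------------------------

    def with_rules(self, replacements: Mapping[str, RegulatoryFunction],
                   name: str | None = None) -> "BooleanNetwork":
        """New network with some rules replaced (by target name)."""
        repl = {normalize_node_name(k): v for k, v in replacements.items()}
        for key in repl:
            if key not in self._index:
                raise NetworkError(f"unknown node name {key!r}")
        rules = [repl.get(r.target, r) for r in self.rules]
        return BooleanNetwork(rules, name=name or self.name,
                              metadata=dict(self.metadata))

    # -- provenance ------------------------------------------------------

    def checksum(self) -> str:
        """SHA-256 over node names, regulators, and truth tables."""
        digest = hashlib.sha256()
        for rule in self.rules:
            digest.update(rule.target.encode())
            digest.update(b"\0")
            digest.update(",".join(rule.regulators).encode())
            digest.update(b"\0")
            digest.update(rule.table.tobytes())
            digest.update(b"\1")
        return digest.hexdigest()

    def same_truth_tables(self, other: "BooleanNetwork") -> bool:
        """Semantic equality: same nodes, and rules equal as functions."""
        if self.nodes != other.nodes:
            return False
        for a, b in zip(self.rules, other.rules):
            if a.regulators != b.regulators:
                # compare as functions of the union of regulators
                union = tuple(dict.fromkeys(a.regulators + b.regulators))
                ta = _expand_table(a, union)
                tb = _expand_table(b, union)
                if not np.array_equal(ta, tb):
                    return False
            elif not np.array_equal(a.table, b.table):
                return False
        return True

    # -- JSON dump -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "nodes": self.nodes,
            "rules": [
                {
                    "target": r.target,
                    "regulators": list(r.regulators),
                    "expression": r.expression,
                }
                for r in self.rules
            ],
            "metadata": self.metadata,
            "checksum": self.checksum(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BooleanNetwork":
        payload = json.loads(text)
        rules = [
            RegulatoryFunction.from_expression(r["target"], r["expression"])
            for r in payload["rules"]
        ]
        return cls(rules, name=payload.get("name", "network"),
                   metadata=payload.get("metadata"))

    def __repr__(self) -> str:
        return (f"BooleanNetwork({self.name!r}, n={self.n}, "
                f"sources={len(self.source_nodes)})")


def _expand_table(rule: RegulatoryFunction, regulators: tuple[str, ...]) -> np.ndarray:
    """Truth table of *rule* re-expressed over a regulator superset."""
    k = len(regulators)
    rows = np.arange(1 << k, dtype=np.uint32)
    idx = np.zeros_like(rows)
    for reg in rule.regulators:
        j = regulators.index(reg)
        idx = (idx << 1) | ((rows >> (k - 1 - j)) & 1)
    return rule.table[idx]


def pack_state(bits: Sequence[int]) -> int:
    """Binary vector -> unsigned integer, node index 0 least significant."""
    value = 0
    for i, b in enumerate(bits):
        value |= (int(b) & 1) << i
    return value


def unpack_state(value: int, n: int) -> np.ndarray:
    """Unsigned integer -> binary vector of length *n*."""
    if value < 0 or value >= (1 << n):
        raise NetworkError(f"state integer {value} out of range for n={n}")
    return np.array([(value >> i) & 1 for i in range(n)], dtype=np.uint8)


def evaluate_rule(network: BooleanNetwork, node: str, state) -> int:
    """Apply node's update rule to the regulator values read from *state*."""
    rule = network.rules[network.node_index(node)]
    arr = network.state_array(state)
    return rule([arr[network.node_index(reg)] for reg in rule.regulators])


def validate_network(network: BooleanNetwork) -> list[str]:
    """Structural findings: vacuous regulators, unreferenced nodes, and
    expression/table disagreements.  Returns an empty list for a clean model.
    """
    findings: list[str] = []
    referenced: set[str] = set()
    for rule in network.rules:
        referenced.update(rule.regulators)
        for reg in rule.nonfunctional_regulators():
            findings.append(f"regulator {reg} non-functional for {rule.target}")
        try:
            if not rule.matches_expression():
                findings.append(
                    f"expression/table mismatch for {rule.target}"
                )
        except ExpressionError as exc:
            findings.append(f"unparseable expression for {rule.target}: {exc}")
    for node in network.nodes:
        # sinks (regulated but never regulating) are legitimate; flag only
        # nodes disconnected on both sides
        if node not in referenced and network.rule(node).k == 0:
            findings.append(f"node {node} is disconnected (constant, never a regulator)")
    return findings
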