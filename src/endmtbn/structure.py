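"""Signed functional-interaction graph and feedback-circuit analysis.

A regulator *j* of node *i* is a **functional activator** if some pair of
regulator configurations differing only in *j* raises ``f_i`` when *j*
goes from 0 to 1, and a **functional inhibitor** if some pair lowers it;
an edge witnessed in both directions is **dual**.  Because ``f_i`` depends
only on its own regulators, the scan runs over the rule's ``2**k`` truth
table rows rather than the full state space.

The identity self-loops of the source nodes are the formal encoding of a
constant microenvironment rather than a regulatory mechanism, so they are
excluded from the interaction graph by default (the headline edge count
refers to the regulatory interactions proper); pass
``include_source_self_loops=True`` to keep them.

A feedback circuit is an elementary directed cycle; its sign is negative
iff it traverses an odd number of inhibitions.  A circuit is flagged
*functional* when a single context — one assignment of the regulators
outside the circuit — simultaneously gives every circuit edge a sign
witness consistent with its sign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .network import BooleanNetwork

__all__ = [
    "SignedInteraction",
    "InteractionGraph",
    "Circuit",
    "CircuitBudgetError",
    "extract_interactions",
    "enumerate_circuits",
    "functional_circuits",
]

ACTIVATING = "activating"
INHIBITING = "inhibiting"
DUAL = "dual"


class CircuitBudgetError(RuntimeError):
    """Raised when circuit enumeration exceeds the configured cap."""


@dataclass(frozen=True)
class SignedInteraction:
    """A functional edge with stored, re-checkable witness rows.

    A witness is a truth-table row pair ``(row0, row1)`` of the target's
    rule differing only in the source regulator (0 in ``row0``, 1 in
    ``row1``) with the corresponding output change.
    """

    source: str
    target: str
    sign: str
    activation_witness: tuple[int, int] | None = None
    inhibition_witness: tuple[int, int] | None = None

    def check_witnesses(self, network: BooleanNetwork) -> bool:
        rule = network.rule(self.target)
        j = rule.regulators.index(self.source)
        bit = 1 << (rule.k - 1 - j)
        ok = True
        if self.activation_witness is not None:
            r0, r1 = self.activation_witness
            ok &= (r1 == r0 | bit) and not (r0 & bit) \
                and rule.table[r0] == 0 and rule.table[r1] == 1
        if self.inhibition_witness is not None:
            r0, r1 = self.inhibition_witness
            ok &= (r1 == r0 | bit) and not (r0 & bit) \
                and rule.table[r0] == 1 and rule.table[r1] == 0
        return bool(ok)


@dataclass
class InteractionGraph:
    """Signed directed graph of functional interactions (self-loops allowed)."""

    nodes: list[str]
    edges: list[SignedInteraction]

    def __len__(self) -> int:
        return len(self.edges)

    def edge(self, source: str, target: str) -> SignedInteraction | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(e.source, e.target, e.sign) for e in self.edges],
            columns=["source", "target", "sign"],
        )

    def to_dot(self) -> str:
        lines = ["digraph interactions {"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        style = {
            ACTIVATING: "[arrowhead=normal]",
            INHIBITING: "[arrowhead=tee, color=red]",
            DUAL: "[arrowhead=diamond, color=purple]",
        }
        for e in self.edges:
            lines.append(f'  "{e.source}" -> "{e.target}" {style[e.sign]};')
        lines.append("}")
        return "\n".join(lines)


def extract_interactions(
    network: BooleanNetwork, include_source_self_loops: bool = False
) -> InteractionGraph:
    """Scan every rule's truth table for activation/inhibition witnesses."""
    edges: list[SignedInteraction] = []
    for rule in network.rules:
        if rule.is_identity_source and not include_source_self_loops:
            continue
        k = rule.k
        rows = np.arange(1 << k, dtype=np.uint32)
        for j, reg in enumerate(rule.regulators):
            bit = np.uint32(1 << (k - 1 - j))
            low = rows[(rows & bit) == 0]
            high = low | bit
            delta = rule.table[high].astype(np.int8) - rule.table[low].astype(np.int8)
            act = np.flatnonzero(delta > 0)
            inh = np.flatnonzero(delta < 0)
            if act.size and inh.size:
                sign = DUAL
            elif act.size:
                sign = ACTIVATING
            elif inh.size:
                sign = INHIBITING
            else:
                continue  # vacuous regulator: no functional edge
            edges.append(
                SignedInteraction(
                    source=reg,
                    target=rule.target,
                    sign=sign,
                    activation_witness=(
                        (int(low[act[0]]), int(high[act[0]])) if act.size else None
                    ),
                    inhibition_witness=(
                        (int(low[inh[0]]), int(high[inh[0]])) if inh.size else None
                    ),
                )
            )
    return InteractionGraph(nodes=list(network.nodes), edges=edges)


@dataclass(frozen=True)
class Circuit:
    """An elementary feedback circuit with a sign assignment per edge.

    ``nodes`` lists the cycle in order, rotated to start at the smallest
    node name (rotation-invariant identity).  ``edge_signs[t]`` is the
    sign used for the edge nodes[t] -> nodes[t+1 mod m]; for a dual edge
    the circuit is enumerated once per sign assignment.
    """

    nodes: tuple[str, ...]
    edge_signs: tuple[str, ...]
    functional: bool | None = None

    @property
    def length(self) -> int:
        return len(self.nodes)

    @property
    def sign(self) -> str:
        negatives = sum(1 for s in self.edge_signs if s == INHIBITING)
        return "negative" if negatives % 2 else "positive"

    def edges(self) -> list[tuple[str, str, str]]:
        m = len(self.nodes)
        return [
            (self.nodes[t], self.nodes[(t + 1) % m], self.edge_signs[t])
            for t in range(m)
        ]


def _rotate_canonical(cycle: Sequence[str]) -> tuple[str, ...]:
    cycle = list(cycle)
    start = cycle.index(min(cycle))
    return tuple(cycle[start:] + cycle[:start])


def enumerate_circuits(
    graph: InteractionGraph, cap: int = 1_000_000
) -> list[Circuit]:
    """All elementary directed cycles, with per-edge sign assignments.

    Self-loops count as length-1 circuits.  Cycles through a dual edge are
    enumerated once per sign of that edge.
    """
    g = graph.to_networkx()
    sign_of = {(e.source, e.target): e.sign for e in graph.edges}
    circuits: list[Circuit] = []
    for cycle in nx.simple_cycles(g):
        nodes = _rotate_canonical(cycle)
        m = len(nodes)
        edge_sign_options = []
        for t in range(m):
            s = sign_of[(nodes[t], nodes[(t + 1) % m])]
            edge_sign_options.append(
                (ACTIVATING, INHIBITING) if s == DUAL else (s,)
            )
        for assignment in itertools.product(*edge_sign_options):
            circuits.append(Circuit(nodes=nodes, edge_signs=assignment))
            if len(circuits) > cap:
                raise CircuitBudgetError(
                    f"more than {cap} circuits; raise the cap to proceed"
                )
    circuits.sort(key=lambda c: (c.length, c.nodes))
    return circuits


def functional_circuits(
    network: BooleanNetwork,
    circuits: Iterable[Circuit],
    max_context_bits: int = 22,
) -> list[Circuit]:
    """Flag circuits that admit a single sign-consistent witness context.

    For each circuit, the *context variables* are the regulators of the
    circuit's nodes that are not themselves on the circuit.  The circuit
    is functional if some single assignment of the context variables lets
    every circuit edge exhibit a witness pair of its assigned sign, where
    circuit-node regulators other than the edge source are existentially
    quantified.
    """
    result = []
    for circuit in circuits:
        result.append(replace(circuit, functional=_is_functional(
            network, circuit, max_context_bits)))
    return result


def _is_functional(network: BooleanNetwork, circuit: Circuit,
                   max_context_bits: int) -> bool:
    cnodes = set(circuit.nodes)
    context_vars: list[str] = []
    for _, target, _ in circuit.edges():
        for reg in network.rule(target).regulators:
            if reg not in cnodes and reg not in context_vars:
                context_vars.append(reg)
    if len(context_vars) > max_context_bits:
        raise CircuitBudgetError(
            f"circuit {circuit.nodes}: context space 2**{len(context_vars)} "
            "exceeds the budget"
        )
    n_ctx = len(context_vars)
    ok = np.ones(1 << n_ctx, dtype=bool)
    for (source, target, sign), _ in zip(circuit.edges(), range(circuit.length)):
        rule = network.rule(target)
        k = rule.k
        j = rule.regulators.index(source)
        bit = np.uint32(1 << (k - 1 - j))
        rows = np.arange(1 << k, dtype=np.uint32)
        low = rows[(rows & bit) == 0]
        delta = rule.table[low | bit].astype(np.int8) - rule.table[low].astype(np.int8)
        want = 1 if sign == ACTIVATING else -1
        witness_rows = low[delta == want]
        if witness_rows.size == 0:
            return False
        # project witness rows onto the context variables of this rule;
        # regulators not in the context (circuit nodes) are existentially
        # quantified by the projection
        ctx_positions = [
            (context_vars.index(reg), k - 1 - jj)
            for jj, reg in enumerate(rule.regulators)
            if reg in context_vars
        ]
        # map each projection into the full context space
        edge_ok = np.zeros(1 << n_ctx, dtype=bool)
        if ctx_positions:
            full_ctx = np.arange(1 << n_ctx, dtype=np.uint32)
            sub = np.zeros_like(full_ctx)
            for local_bit, (ctx_idx, _) in enumerate(ctx_positions):
                sub |= ((full_ctx >> ctx_idx) & 1) << local_bit
            hit = np.zeros(1 << len(ctx_positions), dtype=bool)
            local_proj = np.zeros(witness_rows.shape, dtype=np.uint32)
            for local_bit, (ctx_idx, row_shift) in enumerate(ctx_positions):
                local_proj |= (((witness_rows >> row_shift) & 1) << local_bit).astype(
                    np.uint32
                )
            hit[local_proj] = True
            edge_ok = hit[sub]
        else:
            edge_ok[:] = True
        ok &= edge_ok
        if not ok.any():
            return False
    return bool(ok.any())
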