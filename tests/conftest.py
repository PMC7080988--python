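"""Shared fixtures: the bundled model, its atlas, the reference attractor
table for the EndMT-inducing microenvironment, toy networks, and a
brute-force attractor oracle used to validate the reduced engine."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import endmtbn as e

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

# ---------------------------------------------------------------------------
# reference data: the three period-4 attractors reached in the
# EndMT-inducing microenvironment (DLL4, TGFB, WNT5b, WNT7a, PDGF_AB
# present; HIF1a, FGF2 absent), 12 printed state columns in cycle order.

TABLE4_ENVIRONMENT = {
    "DLL4": 1, "FGF2": 0, "HIF1a": 0, "PDGF_AB": 1,
    "TGFB": 1, "WNT5b": 1, "WNT7a": 1,
}

TABLE4_ROWS = {
    "AP1":     [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "CTNNB":   [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "DLL4":    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "ETS1":    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "FGF2":    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "FLI1":    [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0],
    "GATA2":   [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0],
    "HIF1a":   [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "LEF1":    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "NFkB":    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "NOTCH":   [0, 1, 1, 0, 0, 0, 1, 1, 0, 1, 1, 0],
    "NRARP":   [0, 0, 1, 1, 1, 0, 0, 1, 0, 0, 1, 1],
    "NRP1":    [0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0],
    "PDGF_AB": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "SMAD1":   [0, 1, 1, 0, 0, 0, 1, 1, 1, 1, 1, 1],
    "SMAD2":   [0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0],
    "SMAD6":   [0, 0, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0],
    "SNAI1":   [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "SNAI2":   [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "STAT3":   [0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0],
    "TGFB":    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "TGFBR":   [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "TWIST1":  [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "VEGFA":   [0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0],
    "VEGFR2":  [0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0],
    "WNT5b":   [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "WNT7a":   [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "ZEB1":    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "ZEB2":    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
}


def table4_column(network: e.BooleanNetwork, col: int) -> np.ndarray:
    """Printed state column (0-based) as a bit vector in canonical order."""
    return np.array([TABLE4_ROWS[nd][col] for nd in network.nodes], dtype=np.uint8)


def table4_cycles(network: e.BooleanNetwork) -> list[list[int]]:
    """The three printed attractors as lists of packed states (cycle order)."""
    cols = [e.pack_state(table4_column(network, c)) for c in range(12)]
    return [cols[0:4], cols[4:8], cols[8:12]]


# ---------------------------------------------------------------------------
# brute-force oracle (independent of the reduced engine and of step_batch)


def brute_force_attractors(network: e.BooleanNetwork) -> set[tuple[int, ...]]:
    """Attractor cycles by direct simulation from every state.

    Uses per-node rule evaluation (the scalar path), so it shares no code
    with the vectorized engine it validates.  Returns canonical cycles
    (rotated to their smallest packed state).
    """
    n = network.n
    assert n <= 14, "oracle is exponential; keep fixtures small"

    def scalar_step(x: int) -> int:
        bits = network.state_array(x)
        y = 0
        for i, node in enumerate(network.nodes):
            y |= e.evaluate_rule(network, node, bits) << i
        return y

    succ = [scalar_step(x) for x in range(1 << n)]
    attractors: set[tuple[int, ...]] = set()
    for start in range(1 << n):
        seen: dict[int, int] = {start: 0}
        path = [start]
        x = start
        while True:
            x = succ[x]
            if x in seen:
                cycle = path[seen[x]:]
                k = cycle.index(min(cycle))
                attractors.add(tuple(cycle[k:] + cycle[:k]))
                break
            seen[x] = len(path)
            path.append(x)
    return attractors


def random_network(n_nodes: int, seed: int) -> e.BooleanNetwork:
    """A random Boolean network fixture (seeded, <= 3 regulators per node)."""
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    rules = []
    for i, name in enumerate(names):
        k = int(rng.integers(1, 4))
        regs = tuple(names[j] for j in rng.choice(n_nodes, size=k, replace=False))
        table = rng.integers(0, 2, size=1 << k).astype(np.uint8)
        expr = _table_to_expression(regs, table)
        rules.append(
            e.RegulatoryFunction(target=name, regulators=regs, table=table,
                                 expression=expr)
        )
    return e.BooleanNetwork(rules, name=f"random{n_nodes}_{seed}")


def _table_to_expression(regs: tuple[str, ...], table: np.ndarray) -> str:
    """Disjunctive normal form of a truth table (for export round trips)."""
    k = len(regs)
    ones = [r for r in range(1 << k) if table[r]]
    if not ones:
        return "0"
    if len(ones) == 1 << k:
        return "1"
    terms = []
    for row in ones:
        lits = []
        for j, reg in enumerate(regs):
            bit = (row >> (k - 1 - j)) & 1
            lits.append(reg if bit else f"!{reg}")
        terms.append("(" + " & ".join(lits) + ")")
    return " | ".join(terms)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def endmt() -> e.BooleanNetwork:
    return e.build_endmt_network()


@pytest.fixture(scope="session")
def wt_atlas(endmt) -> e.AttractorAtlas:
    return e.enumerate_attractors(endmt)


@pytest.fixture(scope="session")
def wt_report(endmt, wt_atlas):
    return e.classify_atlas(wt_atlas, e.ClassifierConfig())


@pytest.fixture(scope="session")
def table4_env(endmt) -> e.Environment:
    return e.Environment.from_assignment(endmt, TABLE4_ENVIRONMENT)


@pytest.fixture()
def toy3() -> e.BooleanNetwork:
    """A' = A (source), B' = A AND NOT C, C' = B."""
    return e.read_bnet("targets, factors\nA, A\nB, A & !C\nC, B\n", name="toy3")
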