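"""Synchronous update engine.

All nodes update simultaneously: ``x(t+1) = f(x(t))``.  Besides scalar
stepping, this module provides a vectorized step over packed integer
states (one ``uint64`` per state, node index 0 least significant) and
per-microenvironment successor maps.  Because the source nodes carry
identity rules, their bits are constants of the dynamics and the state
space decomposes exactly into ``2**s`` independent subspaces, one per
microenvironment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import BooleanNetwork, NetworkError

__all__ = [
    "Environment",
    "SuccessorMap",
    "Trajectory",
    "ConvergenceError",
    "step",
    "step_int",
    "step_batch",
    "simulate_to_attractor",
    "build_successor_map",
    "iter_environments",
]

DEFAULT_MAX_STEPS = 10_000


class ConvergenceError(RuntimeError):
    """Raised when a trajectory fails to close a cycle within max_steps."""


@dataclass(frozen=True)
class Environment:
    """Assignment of the source nodes; the microenvironment of a simulation.

    ``id`` encodes the assignment as an integer: bit *b* is the value of
    the *b*-th source node in canonical node order (first source = least
    significant bit).
    """

    sources: tuple[str, ...]
    assignment: tuple[int, ...]

    def __post_init__(self):
        if len(self.sources) != len(self.assignment):
            raise NetworkError("environment assignment length mismatch")

    @property
    def id(self) -> int:
        value = 0
        for b, bit in enumerate(self.assignment):
            value |= (int(bit) & 1) << b
        return value

    @classmethod
    def from_id(cls, network: BooleanNetwork, env_id: int) -> "Environment":
        sources = tuple(network.source_nodes)
        if not 0 <= env_id < (1 << len(sources)):
            raise NetworkError(f"environment id {env_id} out of range")
        return cls(sources, tuple((env_id >> b) & 1 for b in range(len(sources))))

    @classmethod
    def from_assignment(
        cls, network: BooleanNetwork, assignment: Mapping[str, int]
    ) -> "Environment":
        from .network import normalize_node_name

        sources = tuple(network.source_nodes)
        given = {normalize_node_name(k): int(v) & 1 for k, v in assignment.items()}
        missing = [s for s in sources if s not in given]
        extra = [k for k in given if k not in sources]
        if missing:
            raise NetworkError(f"environment must assign all source nodes; missing {missing}")
        if extra:
            raise NetworkError(f"environment assigns non-source nodes {extra}")
        return cls(sources, tuple(given[s] for s in sources))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.sources, self.assignment))

    def bitstring(self) -> str:
        return "".join(str(b) for b in self.assignment)


def iter_environments(network: BooleanNetwork) -> Iterable[Environment]:
    s = len(network.source_nodes)
    for env_id in range(1 << s):
        yield Environment.from_id(network, env_id)


# ---------------------------------------------------------------------------
# stepping


def step(network: BooleanNetwork, state) -> np.ndarray:
    """One synchronous update; returns the successor as a bit vector."""
    arr = network.state_array(state)
    out = np.empty_like(arr)
    for i, rule in enumerate(network.rules):
        out[i] = rule([arr[network.node_index(r)] for r in rule.regulators])
    return out


def step_int(network: BooleanNetwork, state: int) -> int:
    """One synchronous update on a packed integer state."""
    return int(step_batch(network, np.array([state], dtype=np.uint64))[0])


def step_batch(network: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Vectorized synchronous update over packed uint64 states."""
    states = np.asarray(states, dtype=np.uint64)
    out = np.zeros_like(states)
    index = network.node_index
    for i, rule in enumerate(network.rules):
        k = rule.k
        if k == 0:
            if rule.table[0]:
                out |= np.uint64(1 << i)
            continue
        row = np.zeros(states.shape, dtype=np.uint64)
        for j, reg in enumerate(rule.regulators):
            ri = index(reg)
            row |= ((states >> np.uint64(ri)) & np.uint64(1)) << np.uint64(k - 1 - j)
        bits = rule.table[row].astype(np.uint64)
        out |= bits << np.uint64(i)
    return out


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """A simulated path: transient prefix followed by the attractor cycle."""

    states: list[np.ndarray]
    transient_length: int
    attractor: "object"  # endmtbn.attractors.Attractor

    def to_frame(self, network: BooleanNetwork):
        import pandas as pd

        data = np.vstack(self.states)
        return pd.DataFrame(data, columns=network.nodes)

    def to_csv(self, network: BooleanNetwork, path) -> None:
        self.to_frame(network).to_csv(path, index_label="step")


def simulate_to_attractor(
    network: BooleanNetwork, state, max_steps: int = DEFAULT_MAX_STEPS
) -> Trajectory:
    """Iterate to the attractor, detecting cycle entry with a visited table.

    The returned trajectory runs from the initial state to the end of the
    first full traversal of the cycle.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    from .attractors import canonicalize

    x = network.state_int(state)
    seen: dict[int, int] = {x: 0}
    path = [x]
    for t in range(1, max_steps + 1):
        x = step_int(network, x)
        if x in seen:
            entry = seen[x]
            cycle = path[entry:]
            attractor = canonicalize(network, cycle)
            return Trajectory(
                states=[network.state_array(s) for s in path],
                transient_length=entry,
                attractor=attractor,
            )
        seen[x] = t
        path.append(x)
    raise ConvergenceError(f"no cycle detected within {max_steps} steps")


# ---------------------------------------------------------------------------
# per-environment successor maps


@dataclass
class SuccessorMap:
    """Successor function of the free (non-source) nodes in one environment.

    ``successors[i]`` is the free-node configuration reached in one step
    from free configuration ``i`` (bit *p* of ``i`` = value of the *p*-th
    free node in canonical order).
    """

    environment: Environment
    free_nodes: tuple[str, ...]
    successors: np.ndarray

    @property
    def size(self) -> int:
        return int(self.successors.size)


def build_successor_map(
    network: BooleanNetwork,
    environment: Environment,
    chunk_size: int = 1 << 20,
    max_states: int = 1 << 26,
) -> SuccessorMap:
    """Exhaustive one-step map of an environment's free-node subspace.

    Construction is chunked to bound peak memory.  Source bits of every
    successor equal the environment by construction (identity rules).
    """
    sources = tuple(network.source_nodes)
    if tuple(environment.sources) != sources:
        raise NetworkError("environment does not match the network's source nodes")
    free = [i for i, name in enumerate(network.nodes) if name not in sources]
    f = len(free)
    if 1 << f > max_states:
        raise MemoryError(
            f"free subspace 2**{f} exceeds the {max_states}-state budget; "
            "use the reduced attractor engine or raise max_states"
        )
    env_bits = np.uint64(0)
    for name, bit in environment.as_dict().items():
        if bit:
            env_bits |= np.uint64(1 << network.node_index(name))

    successors = np.empty(1 << f, dtype=np.uint64 if f > 31 else np.uint32)
    for start in range(0, 1 << f, chunk_size):
        stop = min(start + chunk_size, 1 << f)
        idx = np.arange(start, stop, dtype=np.uint64)
        full = np.full(idx.shape, env_bits, dtype=np.uint64)
        for p, node_pos in enumerate(free):
            full |= ((idx >> np.uint64(p)) & np.uint64(1)) << np.uint64(node_pos)
        nxt = step_batch(network, full)
        packed = np.zeros_like(idx)
        for p, node_pos in enumerate(free):
            packed |= ((nxt >> np.uint64(node_pos)) & np.uint64(1)) << np.uint64(p)
        successors[start:stop] = packed.astype(successors.dtype)
    return SuccessorMap(
        environment=environment,
        free_nodes=tuple(network.nodes[i] for i in free),
        successors=successors,
    )
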