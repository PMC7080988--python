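"""Robustness and perturbation protocols.

Four complementary protocols probe the model:

1. **Mutation scans** — clamping nodes to 0 (loss of function) or 1 (gain
   of function), re-enumerating all attractors, and comparing the set of
   represented cell-type classes against the wild type.
2. **Update-rule noise** — a population of model instances, each with one
   truth-table output bit flipped, summarizing the attractor counts per
   class.
3. **State noise sensitivity** — for each rule component, the fraction of
   random states whose one-step output changes when k bits of the input
   state are flipped.
4. **Cell-fate transitions** — instantaneous overwrites of the
   microenvironment ligands and the core endothelial identity factors,
   followed by free evolution to a (possibly different) attractor class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .attractors import AttractorAtlas, AttractorResolver, enumerate_attractors
from .classify import (
    NINE_CLASSES,
    ClassifierConfig,
    ClassificationReport,
    classify_atlas,
)
from .dynamics import step_batch
from .network import BooleanNetwork, NetworkError, RegulatoryFunction

__all__ = [
    "MutationSpec",
    "MutantReport",
    "SensitivityReport",
    "TransitionRecord",
    "DEFAULT_PERTURBATION_NODES",
    "apply_mutations",
    "scan_single_mutations",
    "double_mutant_analysis",
    "rule_flip_robustness",
    "rule_sensitivity",
    "perturbation_transitions",
]

#: Microenvironment ligands plus the core endothelial identity factors
#: probed in the cell-fate transition protocol.
DEFAULT_PERTURBATION_NODES = (
    "DLL4", "FGF2", "FLI1", "GATA2", "HIF1a",
    "PDGF_AB", "TGFB", "VEGFA", "WNT5b", "WNT7a",
)


@dataclass(frozen=True)
class MutationSpec:
    """A node clamp: loss of function (0) or gain of function (1)."""

    node: str
    kind: str  # "loss" | "gain"

    def __post_init__(self):
        if self.kind not in ("loss", "gain"):
            raise ValueError(f"kind must be 'loss' or 'gain', got {self.kind!r}")

    @property
    def clamp_value(self) -> int:
        return 0 if self.kind == "loss" else 1

    def __str__(self) -> str:
        return f"{self.node}{'-' if self.kind == 'loss' else '+'}"


def apply_mutations(
    network: BooleanNetwork, specs: Iterable[MutationSpec]
) -> BooleanNetwork:
    """Clamp each mutated node's rule to a constant; other rules untouched."""
    specs = list(specs)
    seen: dict[str, MutationSpec] = {}
    for spec in specs:
        node = network.nodes[network.node_index(spec.node)]
        if node in seen and seen[node].kind != spec.kind:
            raise NetworkError(f"conflicting mutations on {node}")
        seen[node] = spec
    replacements = {
        node: RegulatoryFunction.constant(node, spec.clamp_value)
        for node, spec in seen.items()
    }
    suffix = ",".join(str(s) for s in seen.values())
    mutant = network.with_rules(replacements, name=f"{network.name}[{suffix}]")
    mutant.metadata.setdefault("mutations", []).extend(str(s) for s in seen.values())
    return mutant


@dataclass
class MutantReport:
    """Classification of a mutant's attractor set against the wild type."""

    specs: tuple[MutationSpec, ...]
    n_attractors: int
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    label_counts: dict[str, int]
    qualitative_profile: frozenset[str]
    unchanged: bool
    lost_classes: frozenset[str]
    gained_classes: frozenset[str]

    @property
    def name(self) -> str:
        return "/".join(str(s) for s in self.specs)


def _mutant_report(
    network: BooleanNetwork,
    specs: Sequence[MutationSpec],
    config: ClassifierConfig,
    wild_profile: frozenset[str],
) -> MutantReport:
    mutant = apply_mutations(network, specs)
    atlas = enumerate_attractors(mutant)
    report = classify_atlas(atlas, config)
    profile = report.qualitative_profile
    return MutantReport(
        specs=tuple(specs),
        n_attractors=len(atlas),
        class_counts=report.nine_class_counts,
        class_fractions={c: report.fractions[c] for c in NINE_CLASSES},
        label_counts={g: report.counts.get(g, 0)
                      for g in ("EC", "MC", "Phalanx", "Stalk", "Tip", "EC&MC")},
        qualitative_profile=profile,
        unchanged=(profile == wild_profile),
        lost_classes=wild_profile - profile,
        gained_classes=profile - wild_profile,
    )


def scan_single_mutations(
    network: BooleanNetwork,
    config: ClassifierConfig | None = None,
    atlas: AttractorAtlas | None = None,
    nodes: Sequence[str] | None = None,
):
    """All single gain- and loss-of-function clamps (2 per node).

    Returns ``(reports, summary)``.  ``summary`` is a table with one row
    per nine-class ("loss of ..." rows) plus the wild-type row: the specs
    whose qualitative profile change loses that class, and the robustness
    (fraction of specs that keep it).
    """
    import pandas as pd

    config = config or ClassifierConfig()
    if atlas is None:
        atlas = enumerate_attractors(network)
    wild_profile = classify_atlas(atlas, config).qualitative_profile
    node_list = list(nodes) if nodes is not None else list(network.nodes)
    reports = []
    for node in node_list:
        for kind in ("loss", "gain"):
            reports.append(
                _mutant_report(network, [MutationSpec(node, kind)], config,
                               wild_profile)
            )
    n_specs = len(reports)
    rows = [
        {
            "effect": "wild type",
            "mutations": ", ".join(r.name for r in reports if r.unchanged),
            "count": sum(r.unchanged for r in reports),
            "robustness": sum(r.unchanged for r in reports) / n_specs,
        }
    ]
    for cls in NINE_CLASSES:
        losing = [r for r in reports if cls in r.lost_classes]
        rows.append(
            {
                "effect": f"loss of {cls}",
                "mutations": ", ".join(r.name for r in losing),
                "count": len(losing),
                "robustness": 1 - len(losing) / n_specs,
            }
        )
    return reports, pd.DataFrame(rows)


def double_mutant_analysis(
    network: BooleanNetwork,
    spec_pair: Sequence[MutationSpec],
    config: ClassifierConfig | None = None,
    wild_atlas: AttractorAtlas | None = None,
) -> MutantReport:
    """Full enumeration and classification under a simultaneous double clamp."""
    spec_pair = list(spec_pair)
    if len(spec_pair) != 2 or spec_pair[0].node == spec_pair[1].node:
        raise NetworkError("double mutant requires two distinct nodes")
    config = config or ClassifierConfig()
    if wild_atlas is None:
        wild_atlas = enumerate_attractors(network)
    wild_profile = classify_atlas(wild_atlas, config).qualitative_profile
    return _mutant_report(network, spec_pair, config, wild_profile)


# ---------------------------------------------------------------------------
# update-rule noise


def rule_flip_robustness(
    network: BooleanNetwork,
    config: ClassifierConfig | None = None,
    n_instances: int = 1000,
    seed: int = 42,
    sampling: str = "node-uniform",
):
    """Attractor-count distribution under single truth-table bit flips.

    Each instance picks a node (uniformly, or with probability proportional
    to its table size when ``sampling="row-uniform"``), flips one uniformly
    chosen output bit of its truth table, and re-enumerates + classifies.
    Returns ``(per_class_stats, raw_counts)``; ``raw_counts`` is an
    ``(n_instances, 9)`` array of per-class attractor counts.
    """
    import pandas as pd

    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if sampling not in ("node-uniform", "row-uniform"):
        raise ValueError("sampling must be 'node-uniform' or 'row-uniform'")
    config = config or ClassifierConfig()
    rng = np.random.default_rng(seed)
    table_sizes = np.array([r.table.size for r in network.rules], dtype=float)
    probs = None if sampling == "node-uniform" else table_sizes / table_sizes.sum()
    counts = np.zeros((n_instances, len(NINE_CLASSES)), dtype=np.int64)
    for inst in range(n_instances):
        node_i = int(rng.choice(network.n, p=probs))
        rule = network.rules[node_i]
        row = int(rng.integers(rule.table.size))
        flipped = rule.table.copy()
        flipped[row] ^= 1
        variant_rule = RegulatoryFunction(
            target=rule.target,
            regulators=rule.regulators,
            table=flipped,
            expression=f"flip(row={row}) of ({rule.expression})",
        )
        variant = network.with_rules({rule.target: variant_rule},
                                     name=f"{network.name}~flip")
        report = classify_atlas(enumerate_attractors(variant), config)
        counts[inst] = [report.counts[c] for c in NINE_CLASSES]
    stats = pd.DataFrame(
        {
            "mean": counts.mean(axis=0),
            "sd": counts.std(axis=0, ddof=1) if n_instances > 1 else 0.0,
            "min": counts.min(axis=0),
            "max": counts.max(axis=0),
        },
        index=list(NINE_CLASSES),
    )
    stats.attrs["seed"] = seed
    stats.attrs["n_instances"] = n_instances
    return stats, counts


# ---------------------------------------------------------------------------
# state-noise sensitivity


@dataclass
class SensitivityReport:
    """Per-component sensitivity to k-bit state flips.

    ``fractions[node][k]`` is the fraction of sampled states whose one-step
    output for that component changes when k uniformly chosen distinct
    input bits are flipped.
    """

    fractions: dict[str, dict[int, float]]
    n_samples: dict[int, int]
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.fractions).T.sort_index(axis=1)

    def max_sensitivity(self, k: int = 1) -> float:
        return max(v[k] for v in self.fractions.values())


def rule_sensitivity(
    network: BooleanNetwork,
    n_samples_1bit: int = 500_000,
    n_samples_kbit: int = 20_000,
    seed: int = 42,
    ks: Sequence[int] = tuple(range(1, 16)),
) -> SensitivityReport:
    """Monte Carlo sensitivity of each update-rule component.

    For each k, random states ``s`` are paired with ``s'`` differing in k
    distinct uniformly chosen bits; the sensitivity of component ``f_i``
    is the fraction of pairs with ``f(s)_i != f(s')_i``.
    """
    rng = np.random.default_rng(seed)
    n = network.n
    fractions: dict[str, dict[int, float]] = {node: {} for node in network.nodes}
    n_samples: dict[int, int] = {}
    for k in ks:
        if not 1 <= k <= n:
            raise ValueError(f"flip count {k} out of range 1..{n}")
        m = n_samples_1bit if k == 1 else n_samples_kbit
        n_samples[k] = m
        states = rng.integers(0, 1 << n, size=m, dtype=np.uint64)
        if k == 1:
            positions = rng.integers(0, n, size=(m, 1))
        else:
            scores = rng.random((m, n))
            positions = np.argpartition(scores, k - 1, axis=1)[:, :k]
        masks = np.bitwise_or.reduce(
            np.uint64(1) << positions.astype(np.uint64), axis=1
        )
        flipped = states ^ masks
        diff = step_batch(network, states) ^ step_batch(network, flipped)
        for i, node in enumerate(network.nodes):
            changed = (diff >> np.uint64(i)) & np.uint64(1)
            fractions[node][k] = float(changed.mean())
    return SensitivityReport(fractions=fractions, n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# cell-fate transitions


@dataclass(frozen=True)
class TransitionRecord:
    """Aggregated transitions from one nine-class to another.

    ``n_patterns`` counts the perturbation patterns that send at least one
    attractor of the source class to the destination class.  The invariant
    bits summarize the contributing patterns: nodes set active in all of
    them and nodes inactive in all of them.
    """

    source_class: str
    dest_class: str
    n_patterns: int
    always_active: tuple[str, ...]
    always_inactive: tuple[str, ...]


def perturbation_transitions(
    network: BooleanNetwork,
    atlas: AttractorAtlas | None = None,
    config: ClassifierConfig | None = None,
    perturb_nodes: Sequence[str] = DEFAULT_PERTURBATION_NODES,
    mode: str = "first",
):
    """Map cell-fate transitions under all perturbation patterns.

    Every attractor is perturbed by overwriting the ``perturb_nodes`` bits
    of a start state with each of the ``2**len(perturb_nodes)`` patterns
    (an instantaneous overwrite followed by free evolution; for source
    nodes this is equivalent to a sustained condition).  ``mode`` selects
    the start states of cyclic attractors: ``"first"`` uses the canonical
    first state; ``"all"`` perturbs every cycle state.

    Returns ``(records, matrix)`` where ``matrix`` is the 9x9 pattern-count
    table (source class x destination class).
    """
    import pandas as pd

    if mode not in ("first", "all"):
        raise ValueError("mode must be 'first' or 'all'")
    config = config or ClassifierConfig()
    if atlas is None or atlas.resolver is None:
        atlas = enumerate_attractors(network)
    resolver: AttractorResolver = atlas.resolver
    node_positions = [network.node_index(nd) for nd in perturb_nodes]
    p = len(node_positions)
    n_patterns = 1 << p

    report = classify_atlas(atlas, config)
    att_class = np.array(
        [NINE_CLASSES.index(ls.nine_class) for ls in report.label_sets]
    )

    clear_mask = np.uint64(~sum(1 << pos for pos in node_positions) & ((1 << network.n) - 1))
    patterns = np.arange(n_patterns, dtype=np.uint64)
    pattern_bits = np.zeros(n_patterns, dtype=np.uint64)
    for b, pos in enumerate(node_positions):
        pattern_bits |= ((patterns >> np.uint64(b)) & np.uint64(1)) << np.uint64(pos)

    starts: list[tuple[int, int]] = []  # (attractor id, packed start state)
    for aid, att in enumerate(atlas.attractors):
        states = att.states if mode == "all" else att.states[:1]
        for s in states:
            starts.append((aid, s))
    start_ids = np.array([aid for aid, _ in starts])
    start_states = np.array([s for _, s in starts], dtype=np.uint64)

    # (n_starts, n_patterns) grid of perturbed states, resolved in one call
    perturbed = (start_states[:, None] & clear_mask) | pattern_bits[None, :]
    dest = resolver.resolve(perturbed)
    dest_class = att_class[dest]  # (n_starts, n_patterns)

    # pattern -> (source class, dest class) incidence
    reachable = np.zeros((len(NINE_CLASSES), n_patterns, len(NINE_CLASSES)),
                         dtype=bool)
    src_class_per_start = att_class[start_ids]
    for src in range(len(NINE_CLASSES)):
        rows = dest_class[src_class_per_start == src]
        if rows.size == 0:
            continue
        for dst in range(len(NINE_CLASSES)):
            reachable[src, :, dst] = (rows == dst).any(axis=0)

    records: list[TransitionRecord] = []
    matrix = np.zeros((len(NINE_CLASSES), len(NINE_CLASSES)), dtype=int)
    pattern_matrix = patterns[:, None] >> np.arange(p, dtype=np.uint64)[None, :] & np.uint64(1)
    for src, src_name in enumerate(NINE_CLASSES):
        for dst, dst_name in enumerate(NINE_CLASSES):
            hit = reachable[src, :, dst]
            count = int(hit.sum())
            matrix[src, dst] = count
            if count == 0:
                continue
            bits = pattern_matrix[hit]
            always_on = bits.all(axis=0)
            always_off = ~bits.any(axis=0)
            records.append(
                TransitionRecord(
                    source_class=src_name,
                    dest_class=dst_name,
                    n_patterns=count,
                    always_active=tuple(
                        nd for nd, on in zip(perturb_nodes, always_on) if on
                    ),
                    always_inactive=tuple(
                        nd for nd, off in zip(perturb_nodes, always_off) if off
                    ),
                )
            )
    matrix_frame = pd.DataFrame(matrix, index=list(NINE_CLASSES),
                                columns=list(NINE_CLASSES))
    return records, matrix_frame
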