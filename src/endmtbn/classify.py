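"""Cell-type labelling of states and attractors, and trap-space estimation.

States are labelled by marker patterns:

* **EC** (endothelial): FLI1 and GATA2 active — the two transcription
  factors whose joint activity drives the canonical endothelial markers.
* **MC** (mesenchymal): ZEB1, ZEB2, TWIST1 and at least one of SNAI1/SNAI2
  active.
* **Phalanx** (quiescent barrier EC): EC markers present with NRP1, CTNNB,
  SNAI1 and SNAI2 all absent.
* **Tip** (leading migratory EC): FLI1, GATA2, NRP1 and ETS1 active.
* **Stalk** (trailing activated EC): FLI1 and GATA2 active, NRP1 absent,
  plus a positive activation marker.  The biological Stalk marker (JAG1)
  is not a network node, so it is proxied by its canonical-Wnt
  transcriptional driver; the default requires CTNNB and the predicate is
  configurable (see :class:`ClassifierConfig`).

A cyclic attractor carries a label only if every state of the cycle
does; this applies symmetrically to presence and absence markers.  The
five base labels overlap; they are dissected into nine disjoint classes
(the ``NINE_CLASSES`` partition) interpreted as cell types or behaviors.

The *trap space* of a class is the union of the basins of the attractors
carrying its label; its size is estimated by Monte Carlo over uniformly
random initial states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .attractors import Attractor, AttractorAtlas, AttractorResolver
from .expressions import compile_truth_table, parse_expression
from .network import BooleanNetwork, NetworkError

__all__ = [
    "BASE_LABELS",
    "NINE_CLASSES",
    "ClassifierConfig",
    "ClassLabelSet",
    "ClassificationReport",
    "TrapSpaceEstimate",
    "label_state",
    "label_attractor",
    "nine_class_from_base",
    "classify_atlas",
    "estimate_trap_spaces",
]

BASE_LABELS = ("EC", "MC", "Phalanx", "Stalk", "Tip")

#: The nine disjoint classes: not-EC-not-MC, EC only, Phalanx,
#: non-mesenchymal / mesenchymal Stalk, non-mesenchymal / mesenchymal Tip,
#: mesenchymal-and-EC only, and mesenchymal-not-EC (full transition).
NINE_CLASSES = (
    "nECsnMCs",
    "EConly",
    "Phalanx",
    "nMCStalk",
    "MCStalk",
    "nMCTip",
    "MCTip",
    "MCEConly",
    "MCsnECs",
)

STALK_MARKER_CHOICES = {
    "CTNNB&LEF1": "CTNNB & LEF1",
    "CTNNB": "CTNNB",
    "LEF1": "LEF1",
}


@dataclass
class ClassifierConfig:
    """Marker predicates (Boolean expressions over node names).

    ``stalk_marker`` selects the positive Stalk marker; ``extra_markers``
    adds user-defined labels evaluated with the same all-states rule.

    The default Stalk marker is CTNNB: among the candidate JAG1 proxies
    ({LEF1, CTNNB, CTNNB&LEF1}) it is the one whose classification matches
    the reference cell-type characteristics both on the wild type and
    across the single-mutation scan (CTNNB&LEF1 agrees on the wild type
    but makes LEF1 loss-of-function spuriously abolish the Stalk classes).
    """

    stalk_marker: str = "CTNNB"
    extra_markers: Mapping[str, str] = field(default_factory=dict)
    #: full replacement of the marker set (for non-EndMT networks); the
    #: nine-class machinery degrades gracefully when the five standard
    #: labels are absent (everything falls into nECsnMCs).
    markers: Mapping[str, str] | None = None

    def marker_expressions(self) -> dict[str, str]:
        if self.markers is not None:
            return dict(self.markers)
        try:
            stalk_pos = STALK_MARKER_CHOICES[self.stalk_marker]
        except KeyError:
            raise ValueError(
                f"stalk_marker must be one of {sorted(STALK_MARKER_CHOICES)}"
            ) from None
        markers = {
            "EC": "FLI1 & GATA2",
            "MC": "ZEB1 & ZEB2 & TWIST1 & (SNAI1 | SNAI2)",
            "Phalanx": "FLI1 & GATA2 & !NRP1 & !CTNNB & !SNAI1 & !SNAI2",
            "Stalk": f"FLI1 & GATA2 & !NRP1 & ({stalk_pos})",
            "Tip": "FLI1 & GATA2 & NRP1 & ETS1",
        }
        markers.update(self.extra_markers)
        return markers

    def compiled(self, network: BooleanNetwork) -> dict[str, tuple]:
        """Parse each marker into (node indices, truth table)."""
        compiled = {}
        for label, text in self.marker_expressions().items():
            expr = parse_expression(text)
            variables = tuple(expr.variables())
            for v in variables:
                network.node_index(v)  # raises for invalid node names
            table = compile_truth_table(expr, variables)
            compiled[label] = (
                tuple(network.node_index(v) for v in variables),
                table,
            )
        self._check_consistency(compiled)
        return compiled

    def _check_consistency(self, compiled) -> None:
        """Phalanx and MC must be mutually exclusive (checked exhaustively
        over the union of their marker variables)."""
        if "Phalanx" not in compiled or "MC" not in compiled:
            return
        (vars_p, table_p) = compiled["Phalanx"]
        (vars_m, table_m) = compiled["MC"]
        union = tuple(dict.fromkeys(vars_p + vars_m))
        for assignment in itertools.product((0, 1), repeat=len(union)):
            values = dict(zip(union, assignment))
            row_p = 0
            for v in vars_p:
                row_p = (row_p << 1) | values[v]
            row_m = 0
            for v in vars_m:
                row_m = (row_m << 1) | values[v]
            if table_p[row_p] and table_m[row_m]:
                raise NetworkError(
                    "inconsistent classifier: Phalanx and MC are jointly satisfiable"
                )


@dataclass(frozen=True)
class ClassLabelSet:
    """Base marker labels of an attractor plus its nine-class membership."""

    base: frozenset[str]
    nine_class: str


def _eval_marker(marker, states: np.ndarray) -> np.ndarray:
    """Evaluate one compiled marker on packed states (vectorized)."""
    variables, table = marker
    states = np.asarray(states, dtype=np.uint64)
    k = len(variables)
    row = np.zeros(states.shape, dtype=np.uint64)
    for j, node_i in enumerate(variables):
        row |= ((states >> np.uint64(node_i)) & np.uint64(1)) << np.uint64(k - 1 - j)
    return table[row].astype(bool)


def label_state(network: BooleanNetwork, state, config: ClassifierConfig | None = None,
                _compiled=None) -> frozenset[str]:
    """Marker labels satisfied by a single network state."""
    compiled = _compiled or (config or ClassifierConfig()).compiled(network)
    packed = np.array([network.state_int(state)], dtype=np.uint64)
    return frozenset(
        label for label, marker in compiled.items() if _eval_marker(marker, packed)[0]
    )


def label_attractor(network: BooleanNetwork, attractor: Attractor,
                    config: ClassifierConfig | None = None,
                    _compiled=None) -> ClassLabelSet:
    """Labels holding in *every* state of the cycle, plus the nine-class."""
    compiled = _compiled or (config or ClassifierConfig()).compiled(network)
    packed = np.asarray(attractor.states, dtype=np.uint64)
    base = frozenset(
        label
        for label, marker in compiled.items()
        if bool(_eval_marker(marker, packed).all())
    )
    return ClassLabelSet(base=base, nine_class=nine_class_from_base(base))


def nine_class_from_base(base: frozenset[str]) -> str:
    """Map a base label set to its disjoint nine-class.

    Tip and Stalk are mutually exclusive (NRP1); Phalanx excludes both MC
    (SNAI1/SNAI2) and, with the default Stalk marker, Stalk (CTNNB).  With
    a permissive Stalk marker a Phalanx state could also satisfy Stalk;
    Phalanx takes precedence so the partition stays disjoint.
    """
    ec, mc = "EC" in base, "MC" in base
    if not ec:
        return "MCsnECs" if mc else "nECsnMCs"
    if "Phalanx" in base:
        return "Phalanx"
    if "Tip" in base:
        return "MCTip" if mc else "nMCTip"
    if "Stalk" in base:
        return "MCStalk" if mc else "nMCStalk"
    return "MCEConly" if mc else "EConly"


# ---------------------------------------------------------------------------
# atlas-level classification


@dataclass
class ClassificationReport:
    """Counts and molecular signatures per label group and nine-class."""

    n_attractors: int
    label_sets: list[ClassLabelSet]
    group_members: dict[str, list[int]]
    counts: dict[str, int]
    fractions: dict[str, float]
    common_active: dict[str, frozenset[str]]
    common_inactive: dict[str, frozenset[str]]

    @property
    def nine_class_counts(self) -> dict[str, int]:
        return {c: self.counts[c] for c in NINE_CLASSES}

    @property
    def qualitative_profile(self) -> frozenset[str]:
        """Nine-classes represented by at least one attractor."""
        return frozenset(c for c in NINE_CLASSES if self.counts[c] > 0)

    def to_frame(self):
        import pandas as pd

        rows = []
        for group, members in self.group_members.items():
            rows.append(
                {
                    "group": group,
                    "attractors": len(members),
                    "fraction": self.fractions[group],
                    "common_active": ", ".join(sorted(self.common_active[group])),
                    "common_inactive": ", ".join(sorted(self.common_inactive[group])),
                }
            )
        return pd.DataFrame(rows)


def classify_atlas(atlas: AttractorAtlas,
                   config: ClassifierConfig | None = None) -> ClassificationReport:
    """Label every attractor; report counts and common on/off molecules.

    Groups reported: each base label, the EC∧MC intersection, and the nine
    disjoint classes.  For each group the common-active (common-inactive)
    set contains the nodes active (inactive) in every state of every
    member attractor.
    """
    network = atlas.network
    config = config or ClassifierConfig()
    compiled = config.compiled(network)
    label_sets = [
        label_attractor(network, att, _compiled=compiled) for att in atlas.attractors
    ]

    groups: dict[str, list[int]] = {name: [] for name in compiled}
    groups["EC&MC"] = []
    for c in NINE_CLASSES:
        groups[c] = []
    for aid, ls in enumerate(label_sets):
        for label in ls.base:
            groups[label].append(aid)
        if "EC" in ls.base and "MC" in ls.base:
            groups["EC&MC"].append(aid)
        # "Phalanx" names both a base label and its nine-class (the two
        # sets coincide); avoid appending the same attractor twice
        if ls.nine_class not in ls.base:
            groups[ls.nine_class].append(aid)

    n = len(atlas.attractors)
    counts = {g: len(members) for g, members in groups.items()}
    fractions = {g: (counts[g] / n if n else math.nan) for g in groups}
    common_active: dict[str, frozenset[str]] = {}
    common_inactive: dict[str, frozenset[str]] = {}
    for group, members in groups.items():
        if not members:
            common_active[group] = frozenset()
            common_inactive[group] = frozenset()
            continue
        all_on = np.ones(network.n, dtype=bool)
        all_off = np.ones(network.n, dtype=bool)
        for aid in members:
            bits = atlas.attractors[aid].state_arrays(network)
            all_on &= bits.all(axis=0)
            all_off &= ~bits.any(axis=0)
        common_active[group] = frozenset(
            nd for nd, on in zip(network.nodes, all_on) if on
        )
        common_inactive[group] = frozenset(
            nd for nd, off in zip(network.nodes, all_off) if off
        )
    return ClassificationReport(
        n_attractors=n,
        label_sets=label_sets,
        group_members=groups,
        counts=counts,
        fractions=fractions,
        common_active=common_active,
        common_inactive=common_inactive,
    )


# ---------------------------------------------------------------------------
# trap-space (basin-union) estimation


@dataclass
class TrapSpaceEstimate:
    """Monte Carlo estimate of trap-space sizes.

    ``fractions[g]`` is the fraction of sampled initial states whose
    attractor carries group ``g``; labels overlap, so fractions need not
    sum to one.  ``standard_errors`` are binomial.
    """

    fractions: dict[str, float]
    standard_errors: dict[str, float]
    n_samples: int
    seed: int

    def percent(self, group: str) -> float:
        return 100.0 * self.fractions[group]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "percent": {g: 100 * v for g, v in self.fractions.items()},
                "standard_error": self.standard_errors,
            }
        )


def estimate_trap_spaces(
    network: BooleanNetwork,
    config: ClassifierConfig | None = None,
    n_samples: int = 10_000_000,
    seed: int = 42,
    atlas: AttractorAtlas | None = None,
    batch_size: int = 1_000_000,
) -> TrapSpaceEstimate:
    """Sample uniform random initial states and classify their attractors.

    States are drawn uniformly from all ``2**n`` states (sources included),
    iterated to their attractor with the exact per-environment engine, and
    labelled; the fraction per label/class estimates the trap-space size.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    config = config or ClassifierConfig()
    if atlas is None or atlas.resolver is None:
        resolver = AttractorResolver(network)
        atlas = resolver.atlas()
    else:
        resolver = atlas.resolver
    report = classify_atlas(atlas, config)

    group_names = list(report.group_members)
    membership = np.zeros((len(atlas.attractors), len(group_names)), dtype=bool)
    for g, name in enumerate(group_names):
        membership[report.group_members[name], g] = True

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(group_names), dtype=np.int64)
    remaining = n_samples
    while remaining > 0:
        m = min(batch_size, remaining)
        states = rng.integers(0, 1 << network.n, size=m, dtype=np.uint64)
        ids = resolver.resolve(states)
        counts = np.bincount(ids, minlength=len(atlas.attractors))
        hits += counts @ membership
        remaining -= m

    fractions = {g: hits[i] / n_samples for i, g in enumerate(group_names)}
    ses = {
        g: math.sqrt(max(p * (1 - p), 0.0) / n_samples)
        for g, p in fractions.items()
    }
    return TrapSpaceEstimate(
        fractions=fractions, standard_errors=ses, n_samples=n_samples, seed=seed
    )
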