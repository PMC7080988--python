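"""The bundled 29-node endothelial-to-mesenchymal transition (EndMT) model.

The network couples the VEGF, HIF, NOTCH, FGF, TGF, WNT, and PDGF
signalling pathways to the transcription factors that maintain endothelial
identity (FLI1, GATA2, ETS1) and those that drive the mesenchymal program
(SNAI1, SNAI2, TWIST1, ZEB1, ZEB2, LEF1).  Seven ligand/condition nodes —
DLL4, FGF2, HIF1a, PDGF_AB, TGFB, WNT5b, WNT7a — carry identity rules and
encode the extracellular microenvironment: their joint assignment is a
constant of the dynamics, so the state space splits into 128 independent
microenvironments.

Node names use one canonical ASCII spelling (HIF1a, NFkB, TGFB, TGFBR,
CTNNB); Greek-letter and hyphenated variants are accepted on input.  The
source equations for ETS1 name a "VEGF2" input, which is not a node of the
model; it is read here as VEGFR2 (the VEGF receptor whose signalling
activates ETS1), and the substitution is recorded in the network metadata
rather than applied silently.
"""

from __future__ import annotations

from .network import BooleanNetwork, RegulatoryFunction

__all__ = ["ENDMT_NODES", "ENDMT_SOURCE_NODES", "ENDMT_RULES", "build_endmt_network"]


#: Update rules in canonical (alphabetical) node order.
ENDMT_RULES: dict[str, str] = {
    "AP1": "WNT5b | SMAD2",
    "CTNNB": "WNT5b | WNT7a",
    "DLL4": "DLL4",
    "ETS1": "VEGFR2 | FGF2 | ZEB2 | AP1",
    "FGF2": "FGF2",
    "FLI1": "FLI1 | GATA2 | HIF1a",
    "GATA2": "FLI1 | GATA2 | VEGFR2",
    "HIF1a": "HIF1a",
    "LEF1": "LEF1 | NRARP | SMAD2 | NFkB | CTNNB",
    "NFkB": "PDGF_AB",
    "NOTCH": "DLL4 & !NRARP",
    "NRARP": "NOTCH",
    "NRP1": "VEGFA & (ETS1 | GATA2) & !NOTCH",
    "PDGF_AB": "PDGF_AB",
    "SMAD1": "TGFBR & !SMAD6",
    "SMAD2": "TGFBR & !SMAD6 & NRP1",
    "SMAD6": "FLI1 & GATA2 & (NOTCH | SMAD1)",
    "SNAI1": "(HIF1a | STAT3 | CTNNB | AP1 | NFkB | SMAD2)"
             " & (NOTCH | CTNNB) & !TWIST1 & !SNAI1 & !SNAI2",
    "SNAI2": "!(SNAI1 & GATA2) & (SMAD2 | SNAI2 | TWIST1 | LEF1 | NOTCH)",
    "STAT3": "VEGFR2",
    "TGFB": "TGFB",
    "TGFBR": "TGFB & !FGF2",
    "TWIST1": "CTNNB | HIF1a",
    "VEGFA": "(!WNT5b & !TGFBR & (STAT3 | HIF1a)) | VEGFA",
    "VEGFR2": "VEGFA & !SNAI1 & !NOTCH & (FLI1 | GATA2 | ETS1)",
    "WNT5b": "WNT5b",
    "WNT7a": "WNT7a",
    "ZEB1": "SNAI2 | CTNNB | LEF1",
    "ZEB2": "HIF1a | ETS1 | SMAD2 | AP1 | SNAI1",
}

ENDMT_NODES: tuple[str, ...] = tuple(ENDMT_RULES)

ENDMT_SOURCE_NODES: frozenset[str] = frozenset(
    {"DLL4", "FGF2", "HIF1a", "PDGF_AB", "TGFB", "WNT5b", "WNT7a"}
)


def build_endmt_network() -> BooleanNetwork:
    """Build the 29-node EndMT network with its rules compiled verbatim."""
    rules = [
        RegulatoryFunction.from_expression(target, text)
        for target, text in ENDMT_RULES.items()
    ]
    net = BooleanNetwork(
        rules,
        name="EndMT",
        metadata={
            "substitutions": {
                "ETS1": "source-equation token 'VEGF2' read as VEGFR2"
            },
        },
    )
    assert set(net.source_nodes) == ENDMT_SOURCE_NODES
    return net
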