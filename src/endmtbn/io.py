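"""Read and write Boolean networks in the .bnet logical-model text format.

The dialect is the common ``targets, factors`` one: a header line followed
by one ``NODE, expression`` line per node, with ``!``/``&``/``|`` operators
and parentheses.  Round-tripping preserves truth tables exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import TextIO

from .expressions import ExpressionError
from .network import BooleanNetwork, NetworkError, RegulatoryFunction

__all__ = ["BnetParseError", "read_bnet", "write_bnet", "load_bnet", "dump_bnet"]


class BnetParseError(ValueError):
    """Syntax or reference error in a .bnet document, with line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_bnet(text: str, name: str = "network") -> BooleanNetwork:
    """Parse a .bnet document into a :class:`BooleanNetwork`.

    Node order follows the order of rule lines.  Every factor appearing in
    an expression must itself be declared as a target.
    """
    entries: list[tuple[str, str, int]] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            normalized = [part.strip().lower() for part in line.split(",")]
            if normalized == ["targets", "factors"]:
                header_seen = True
                continue
            # tolerate a missing header: fall through to rule parsing
            header_seen = True
        if "," not in line:
            raise BnetParseError("expected 'target, expression'", lineno)
        target, expression = line.split(",", 1)
        target = target.strip()
        if not target:
            raise BnetParseError("empty target name", lineno)
        entries.append((target, expression.strip(), lineno))
    if not entries:
        raise BnetParseError("no rules found", 1)

    rules = []
    for target, expression, lineno in entries:
        try:
            rules.append(RegulatoryFunction.from_expression(target, expression))
        except ExpressionError as exc:
            raise BnetParseError(str(exc), lineno) from exc

    declared = {rule.target for rule in rules}
    for rule, (_, _, lineno) in zip(rules, entries):
        for reg in rule.regulators:
            if reg not in declared:
                raise BnetParseError(
                    f"undeclared factor {reg!r} in rule for {rule.target}", lineno
                )
    try:
        return BooleanNetwork(rules, name=name)
    except NetworkError as exc:
        raise BnetParseError(str(exc), entries[0][2]) from exc


def write_bnet(network: BooleanNetwork) -> str:
    """Serialize a network as a .bnet document (one rule line per node)."""
    lines = ["targets, factors"]
    for rule in network.rules:
        lines.append(f"{rule.target}, {rule.expression}")
    return "\n".join(lines) + "\n"


def load_bnet(path: str | Path | TextIO) -> BooleanNetwork:
    if hasattr(path, "read"):
        return read_bnet(path.read())
    path = Path(path)
    return read_bnet(path.read_text(), name=path.stem)


def dump_bnet(network: BooleanNetwork, path: str | Path) -> None:
    Path(path).write_text(write_bnet(network))
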