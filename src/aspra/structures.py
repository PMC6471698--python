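"""Reading, validating and writing RNA secondary structures.

A secondary structure is a primary sequence together with a set of base
pairs ("weak interactions"), drawn as arcs over the backbone.  Two plain-text
formats are supported:

* **Arc-annotated sequence** -- two lines: the sequence (possibly empty) and a
  semicolon-separated list of 1-based pairs ``(i1,j1);(i2,j2);...``.
* **Extended dot-bracket notation** -- two lines of equal length: the sequence
  and a bracket string where matched pairs from distinct bracket families
  (``()``, ``[]``, ``{}``, ``<>``, ``Aa`` ... ``Zz``) encode arcs and dots mark
  unpaired positions.  Pseudoknots need at least two families.

Coordinates are 1-based and inclusive at both ends throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError, StructureError

#: Placeholder base used when only the structure (no sequence) is given.
PLACEHOLDER_BASE = "N"

_BASES = frozenset("ACGUN")

#: Bracket families usable in dot-bracket output/input, in assignment order.
BRACKET_FAMILIES: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
) + tuple((chr(ord("A") + i), chr(ord("a") + i)) for i in range(26))

_OPEN = {o: idx for idx, (o, _) in enumerate(BRACKET_FAMILIES)}
_CLOSE = {c: idx for idx, (_, c) in enumerate(BRACKET_FAMILIES)}


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA secondary structure: sequence plus a canonical tuple of arcs.

    Parameters
    ----------
    sequence:
        String over ``A, C, G, U`` (or the placeholder ``N`` in
        structure-only mode).  Its length fixes ``n``.
    arcs:
        Base pairs ``(i, j)`` with ``1 <= i < j <= n``; stored sorted.

    Invariants (enforced on construction): every arc encloses at least one
    nucleotide (``j - i >= 2``), every position is in at most one arc, and at
    least one arc is present (a bare sequence has no main pseudoloop and is
    rejected upstream of the grammar).
    """

    sequence: str
    arcs: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _BASES
        if bad:
            raise StructureError(f"invalid characters in sequence: {sorted(bad)!r}")
        n = len(seq)
        arcs = tuple(sorted((int(i), int(j)) for i, j in self.arcs))
        object.__setattr__(self, "arcs", arcs)
        if not arcs:
            raise StructureError(
                "structure has no weak interactions: at least one arc is required"
            )
        seen: set[int] = set()
        for i, j in arcs:
            if not (1 <= i <= n and 1 <= j <= n):
                raise StructureError(f"arc ({i},{j}) outside [1,{n}]")
            if j - i < 2:
                raise StructureError(
                    f"arc ({i},{j}) must enclose at least one nucleotide (j - i >= 2)"
                )
            for p in (i, j):
                if p in seen:
                    raise StructureError(f"position {p} occurs in more than one arc")
                seen.add(p)

    @property
    def n(self) -> int:
        """Length of the primary sequence."""
        return len(self.sequence)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for arc in self.arcs for p in arc)

    def is_paired(self, pos: int) -> bool:
        return pos in self.paired_positions

    def with_sequence(self, sequence: str) -> "SecondaryStructure":
        """Same arcs on a different primary sequence (must have equal length)."""
        if len(sequence) != self.n:
            raise StructureError("replacement sequence has a different length")
        return SecondaryStructure(sequence, self.arcs)


def structure_from_arcs(
    arcs, n: int | None = None, sequence: str | None = None
) -> SecondaryStructure:
    """Build a structure from bare arcs, with a placeholder sequence if needed."""
    arcs = tuple(tuple(a) for a in arcs)
    if sequence is not None:
        return SecondaryStructure(sequence, arcs)
    if n is None:
        n = max((j for _, j in arcs), default=0)
    return SecondaryStructure(PLACEHOLDER_BASE * n, arcs)


_PAIR_RE = re.compile(r"\(\s*(\d+)\s*,\s*(\d+)\s*\)")


def parse_arc_annotated(text: str) -> SecondaryStructure:
    """Parse the two-line arc-annotated sequence format.

    Line 1 is the sequence (may be empty: structure-only mode, in which case
    the length is taken as the largest arc endpoint and the sequence is filled
    with the placeholder base).  Line 2 lists the arcs in any order as
    ``(i1,j1);(i2,j2);...``.
    """
    lines = text.splitlines()
    while len(lines) < 2:
        lines.append("")
    seq = lines[0].strip()
    arc_text = lines[1].strip()
    arcs: list[tuple[int, int]] = []
    if arc_text:
        consumed = _PAIR_RE.sub("", arc_text).replace(";", "").strip()
        if consumed:
            raise ParseError(f"malformed arc list near {consumed!r}")
        for m in _PAIR_RE.finditer(arc_text):
            i, j = int(m.group(1)), int(m.group(2))
            if i >= j:
                raise ParseError(f"arc ({i},{j}): first index must be smaller")
            arcs.append((i, j))
    if not arcs:
        raise ParseError("no weak interactions given: empty structures are rejected")
    if seq:
        return SecondaryStructure(seq, tuple(arcs))
    return structure_from_arcs(arcs)


def write_arc_annotated(s: SecondaryStructure) -> str:
    """Serialise to the two-line arc-annotated format (canonical arc order)."""
    pairs = ";".join(f"({i},{j})" for i, j in s.arcs)
    return f"{s.sequence}\n{pairs}\n"


def parse_dot_bracket(text: str) -> SecondaryStructure:
    """Parse extended dot-bracket notation (sequence line + bracket line)."""
    lines = [ln for ln in (ln.strip() for ln in text.splitlines()) if ln]
    if len(lines) != 2:
        raise ParseError("expected exactly two non-empty lines: sequence + brackets")
    seq, db = lines
    if len(seq) != len(db):
        raise ParseError(
            f"sequence length {len(seq)} != structure length {len(db)}"
        )
    stacks: dict[int, list[int]] = {}
    arcs: list[tuple[int, int]] = []
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            fam = _CLOSE[ch]
            if not stacks.get(fam):
                raise ParseError(f"unbalanced {ch!r} at position {pos}")
            arcs.append((stacks[fam].pop(), pos))
        else:
            raise ParseError(f"unknown character {ch!r} at position {pos}")
    for fam, stack in stacks.items():
        if stack:
            o = BRACKET_FAMILIES[fam][0]
            raise ParseError(f"unbalanced {o!r} opened at position {stack[-1]}")
    if not arcs:
        raise ParseError("no weak interactions given: empty structures are rejected")
    return SecondaryStructure(seq, tuple(arcs))


def _cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return i < k < j < l or k < i < l < j


def write_dot_bracket(s: SecondaryStructure) -> str:
    """Serialise to dot-bracket, greedily assigning bracket families.

    Arcs are taken in canonical order and each is placed into the first family
    whose already-assigned arcs it does not cross, so every family's arcs form
    a well-nested set and the output parses back to the same structure.
    """
    assigned: list[list[tuple[int, int]]] = []
    family_of: dict[tuple[int, int], int] = {}
    for arc in s.arcs:
        for fam, members in enumerate(assigned):
            if not any(_cross(arc, m) for m in members):
                members.append(arc)
                family_of[arc] = fam
                break
        else:
            if len(assigned) >= len(BRACKET_FAMILIES):
                raise StructureError("structure needs more bracket families than available")
            assigned.append([arc])
            family_of[arc] = len(assigned) - 1
    chars = ["."] * s.n
    for (i, j), fam in family_of.items():
        o, c = BRACKET_FAMILIES[fam]
        chars[i - 1], chars[j - 1] = o, c
    return f"{s.sequence}\n{''.join(chars)}\n"
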