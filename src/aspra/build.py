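"""Unique grammar decomposition of a structure into its algebraic RNA tree.

Every secondary structure has exactly one derived tree of the regular tree
grammar over ``{⇄, ⊙, ⋈, ⋒, H}``.  The decomposition procedure, applied to
the main pseudoloop (the span between the first and last paired position),
is:

1. if the pseudoloop splits into two or more *concatenation blocks* (maximal
   groups of arcs with no arc spanning a boundary), emit left-associative
   ``⊙`` nodes with the unpaired linkers ``η`` between blocks;
2. otherwise take the hairpin ``α`` with the rightmost paired nucleotide;
   if ``α`` crosses a remaining arc, emit ``⋈`` with right child ``H(α)``
   and recurse on the remaining arcs (``k`` = relative position of ``α``'s
   left end inside the remaining pseudoloop's span);
3. if ``α`` crosses nothing it encloses everything left: emit ``⋒`` with
   right child ``H(α)`` and recurse on the arcs inside (``k`` = relative
   position of the inner pseudoloop's first paired position inside ``α``);
4. a single arc is a hairpin leaf ``H``.

The ``⇄`` root carries the unpaired head and tail.  The construction is
deterministic and runs in time linear in ``n`` plus the total arc length.
"""

from __future__ import annotations

from .algebra import (
    CONCAT_SYM,
    CROSS_SYM,
    NEST_SYM,
    ROOT_SYM,
    UNPAIRED,
    AlgebraicTerm,
    Concat,
    Cross,
    Hairpin,
    Nest,
    PseudoloopTerm,
    Root,
    annotate,
)
from .errors import StructureError
from .structures import SecondaryStructure

Arc = tuple[int, int]


def arcs_cross(a: Arc, b: Arc) -> bool:
    """Do two arcs cross (form a pseudoknot)?

    Ordering the arcs so that ``j' < j``, the pair crosses iff
    ``i' < i < j'`` — the later arc starts strictly inside the earlier one
    and ends strictly outside it.
    """
    (ip, jp), (i, j) = sorted((a, b), key=lambda arc: arc[1])
    return ip < i < jp


def rightmost_hairpin(arcs) -> Arc:
    """The arc with the rightmost paired nucleotide (unique: positions are disjoint)."""
    return max(arcs, key=lambda arc: arc[1])


def main_pseudoloop_bounds(s: SecondaryStructure) -> tuple[str, tuple[int, int], str]:
    """Head string, main pseudoloop span (lo, hi) and tail string of a structure."""
    paired = s.paired_positions
    lo, hi = min(paired), max(paired)
    return s.sequence[: lo - 1], (lo, hi), s.sequence[hi:]


def split_concatenation_blocks(
    arcs, sequence: str | None = None
) -> tuple[list[tuple[Arc, ...]], list[str]]:
    """Partition arcs into maximal concatenation blocks plus linker strings.

    A block boundary falls wherever no arc spans across it; the linker
    between consecutive blocks is the (possibly empty) run of unpaired
    positions separating them.  Linker strings are extracted from
    ``sequence`` when given, otherwise returned as empty placeholders.
    """
    ordered = sorted(arcs)
    blocks: list[list[Arc]] = []
    block_hi = -1
    for arc in ordered:
        if blocks and arc[0] < block_hi:
            blocks[-1].append(arc)
            block_hi = max(block_hi, arc[1])
        else:
            blocks.append([arc])
            block_hi = arc[1]
    linkers: list[str] = []
    for prev, nxt in zip(blocks, blocks[1:]):
        lo = max(j for _, j in prev) + 1
        hi = min(i for i, _ in nxt)  # exclusive
        linkers.append(sequence[lo - 1 : hi - 1] if sequence is not None else "")
    return [tuple(b) for b in blocks], linkers


def _hairpin(s: SecondaryStructure, arc: Arc) -> Hairpin:
    i, j = arc
    return Hairpin(s.sequence[i - 1 : j], i, j)


def _build(s: SecondaryStructure, arcs: tuple[Arc, ...]) -> PseudoloopTerm:
    blocks, linkers = split_concatenation_blocks(arcs, s.sequence)
    if len(blocks) > 1:
        term: PseudoloopTerm = _build(s, blocks[0])
        for eta, block in zip(linkers, blocks[1:]):
            term = Concat(term, eta, _build(s, block))
        return term
    if len(arcs) == 1:
        return _hairpin(s, arcs[0])
    alpha = rightmost_hairpin(arcs)
    rest = tuple(a for a in arcs if a != alpha)
    if any(arcs_cross(alpha, other) for other in rest):
        rest_lo = min(i for i, _ in rest)
        k = alpha[0] - rest_lo + 1
        return Cross(_build(s, rest), k, _hairpin(s, alpha))
    # no crossing and not a concatenation: alpha must enclose all the rest
    if not all(alpha[0] < i and j < alpha[1] for i, j in rest):
        raise StructureError("internal decomposition error: stray arc outside hairpin")
    inner_lo = min(i for i, _ in rest)
    k = inner_lo - alpha[0] + 1
    return Nest(_build(s, rest), k, _hairpin(s, alpha))


def build_algebraic_tree(s: SecondaryStructure) -> Root:
    """The unique algebraic RNA tree of a secondary structure."""
    head, _, tail = main_pseudoloop_bounds(s)
    return Root(head, _build(s, s.arcs), tail)


# ---------------------------------------------------------------------------
# yields and text serialisation
# ---------------------------------------------------------------------------

def tree_yield(term: AlgebraicTerm) -> str:
    """Left-to-right concatenation of a term's leaf labels.

    Hairpin leaves contribute their annotated strings, operator nodes their
    middle marker leaf (``(⊙,η)``, ``(⋈,k)``, ``(⋒,k)``), the root its
    unpaired head and tail.  The yield of a pseudoloop subterm is exactly the
    input accepted by :func:`aspra.algebra.pseudoloop_of_yield`.
    """
    if isinstance(term, Root):
        head = annotate(term.head, [False] * len(term.head))
        tail = annotate(term.tail, [False] * len(term.tail))
        return head + tree_yield(term.child) + tail
    if isinstance(term, Hairpin):
        return term.annotated
    if isinstance(term, Concat):
        eta = annotate(term.eta, [False] * len(term.eta))
        return f"{tree_yield(term.left)}({CONCAT_SYM},{eta}){tree_yield(term.right)}"
    if isinstance(term, Cross):
        return f"{tree_yield(term.left)}({CROSS_SYM},{term.k}){term.right.annotated}"
    if isinstance(term, Nest):
        return f"{tree_yield(term.left)}({NEST_SYM},{term.k}){term.right.annotated}"
    raise StructureError(f"not an algebraic term: {term!r}")


class _MarkerLeaf:
    """Middle operator-parameter leaf used only for serialisation."""

    __slots__ = ("text",)

    def __init__(self, text: str) -> None:
        self.text = text

    def tree_view(self, ascii_labels: bool):
        return self.text, ()


_ASCII = {ROOT_SYM: "ROOT", CONCAT_SYM: "CONCAT", CROSS_SYM: "CROSS", NEST_SYM: "NEST"}


def _sym(sym: str, ascii_labels: bool) -> str:
    return _ASCII[sym] if ascii_labels else sym


def _view(term, ascii_labels: bool):
    if hasattr(term, "tree_view"):
        return term.tree_view(ascii_labels)
    if isinstance(term, Root):
        head = annotate(term.head, [False] * len(term.head))
        tail = annotate(term.tail, [False] * len(term.tail))
        return _sym(ROOT_SYM, ascii_labels), (
            _MarkerLeaf(head),
            term.child,
            _MarkerLeaf(tail),
        )
    if isinstance(term, Concat):
        eta = annotate(term.eta, [False] * len(term.eta))
        marker = f"({_sym(CONCAT_SYM, ascii_labels)},{eta})"
        return _sym(CONCAT_SYM, ascii_labels), (term.left, _MarkerLeaf(marker), term.right)
    if isinstance(term, (Cross, Nest)):
        sym = CROSS_SYM if isinstance(term, Cross) else NEST_SYM
        marker = f"({_sym(sym, ascii_labels)},{term.k})"
        return _sym(sym, ascii_labels), (term.left, _MarkerLeaf(marker), term.right)
    if isinstance(term, Hairpin):
        return term.annotated, ()
    raise StructureError(f"cannot serialise {term!r}")


def tree_to_text(term, ascii_labels: bool = False) -> str:
    """Depth-first serialisation in the shape ``(~node-label~, [children])``.

    Works for algebraic terms, structural trees and alignment trees (any
    node exposing ``tree_view``).  Leaves serialise with an empty child list.
    """
    label, children = _view(term, ascii_labels)
    inner = ", ".join(tree_to_text(c, ascii_labels) for c in children)
    return f"(~{label}~, [{inner}])"
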