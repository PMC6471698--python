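"""Structural RNA trees: the primary-sequence-free abstraction.

A structural RNA tree is an ordered *binary* tree whose leaves are the arcs
of the structure, labelled ``H(start,stop)`` with absolute positions, and
whose interior nodes are labelled ``⊙`` (concatenation), ``⋒`` (nesting) or
``(⋈,h)`` (crossing).  The crossing count ``h`` is the number of hairpins in
the left child's pseudoloop that actually cross the right-child hairpin; it
distinguishes structures that share the same pattern of operator
applications but differ in how deeply the pseudoknot interleaves.

The abstraction drops the ⇄ root (head and tail), the middle
operator-parameter leaves and the nucleotide identities of the algebraic
tree; only the tree shape, the operators and the absolute hairpin positions
remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .algebra import CONCAT_SYM, CROSS_SYM, NEST_SYM, Concat, Cross, Hairpin, Nest, Root
from .build import arcs_cross, build_algebraic_tree
from .errors import StructureError
from .structures import SecondaryStructure

Arc = tuple[int, int]


@dataclass(frozen=True)
class HairpinLeaf:
    """Leaf ``H(start,stop)``: one arc at absolute 1-based positions."""

    start: int
    stop: int

    @property
    def arc(self) -> Arc:
        return (self.start, self.stop)

    @property
    def children(self) -> tuple:
        return ()

    def label(self, ascii_labels: bool = False) -> str:
        return f"H({self.start},{self.stop})"

    def tree_view(self, ascii_labels: bool):
        return self.label(ascii_labels), ()


@dataclass(frozen=True)
class OperatorNode:
    """Interior node labelled ``⊙``, ``⋒`` or ``(⋈,h)``; always two children."""

    op: str  # CONCAT_SYM | NEST_SYM | CROSS_SYM
    left: "StructuralTree"
    right: "StructuralTree"
    h: int | None = None

    def __post_init__(self) -> None:
        if self.op not in (CONCAT_SYM, NEST_SYM, CROSS_SYM):
            raise StructureError(f"unknown structural operator {self.op!r}")
        if self.op == CROSS_SYM:
            if self.h is None or self.h < 1:
                raise StructureError("a crossing node carries a count h >= 1")
        elif self.h is not None:
            raise StructureError("only crossing nodes carry a count h")

    @property
    def children(self) -> tuple:
        return (self.left, self.right)

    def label(self, ascii_labels: bool = False) -> str:
        if self.op == CROSS_SYM:
            name = "CROSS" if ascii_labels else CROSS_SYM
            return f"({name},{self.h})"
        if ascii_labels:
            return "CONCAT" if self.op == CONCAT_SYM else "NEST"
        return self.op

    def tree_view(self, ascii_labels: bool):
        return self.label(ascii_labels), self.children


StructuralTree = Union[HairpinLeaf, OperatorNode]


def crossing_count(left_hairpins, right: Arc) -> int:
    """How many arcs of a pseudoloop cross a given hairpin."""
    return sum(1 for arc in left_hairpins if arcs_cross(arc, right))


def _abstract(term) -> tuple[StructuralTree, list[Arc]]:
    if isinstance(term, Hairpin):
        return HairpinLeaf(term.start, term.stop), [term.arc]
    if isinstance(term, Concat):
        left, la = _abstract(term.left)
        right, ra = _abstract(term.right)
        return OperatorNode(CONCAT_SYM, left, right), la + ra
    if isinstance(term, (Cross, Nest)):
        left, la = _abstract(term.left)
        leaf = HairpinLeaf(term.right.start, term.right.stop)
        if isinstance(term, Cross):
            h = crossing_count(la, term.right.arc)
            if h < 1:
                raise StructureError("crossing node with no crossing hairpin")
            node = OperatorNode(CROSS_SYM, left, leaf, h=h)
        else:
            node = OperatorNode(NEST_SYM, left, leaf)
        return node, la + [term.right.arc]
    raise StructureError(f"not a pseudoloop term: {term!r}")


def abstract_to_structural(term: Root) -> StructuralTree:
    """Abstract an algebraic RNA tree (⇄ term) to its structural RNA tree."""
    if not isinstance(term, Root):
        raise StructureError("abstraction starts from a ⇄ root term")
    tree, _ = _abstract(term.child)
    return tree


def structural_tree(s: SecondaryStructure) -> StructuralTree:
    """Build the structural RNA tree of a structure (via its algebraic tree)."""
    return abstract_to_structural(build_algebraic_tree(s))


def leaves(tree: StructuralTree) -> list[HairpinLeaf]:
    """Leaves in left-to-right order."""
    if isinstance(tree, HairpinLeaf):
        return [tree]
    return [leaf for child in tree.children for leaf in leaves(child)]


def n_nodes(tree: StructuralTree) -> int:
    return 1 + sum(n_nodes(c) for c in getattr(tree, "children", ()))
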