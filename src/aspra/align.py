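"""Ordered-tree alignment of structural RNA trees and the ASPRA distance.

An alignment of two ordered labelled trees is a tree (in general a forest)
of label *pairs*: ``(a,b)`` is a replacement, ``(a,-)`` a deletion and
``(-,b)`` an insertion, the pair ``(-,-)`` being forbidden.  Deleting the
gap components on either side must recover the two input trees.  The ASPRA
distance between two secondary structures is the minimum total score of an
alignment of their structural RNA trees under the scoring ``σ_s``:

========================================  =============
pair                                      score
========================================  =============
``(⋈,h)`` vs ``(⋈,h')``                   ``c_m·|h-h'|``
operator vs different operator            ``o_r``
operator vs gap                           ``o_di``
hairpin vs hairpin                        ``0``
hairpin vs operator                       ``+∞``
hairpin vs gap                            ``h_di``
========================================  =============

Identical operator labels score 0 (the standard edit convention, so that a
tree is at distance 0 from itself); hairpin positions are ignored because
the measure is deliberately independent of the primary sequence.  The unit
``c_m`` is meant to be much smaller than the other constants: a crossing
mismatch is a local difference between two nodes carrying the *same*
operator.  Defaults are ``c_m=1`` and ``o_r=o_di=h_di=100``.

The optimal alignment is found with the classical dynamic program over
ordered forests (Jiang-style), which for binary trees runs in time
proportional to the product of the two tree sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .build import tree_to_text
from .errors import StructureError
from .structural import HairpinLeaf, OperatorNode, StructuralTree, structural_tree
from .structures import SecondaryStructure

#: Gap symbol used in alignment pairs.
GAP = "-"

INF = math.inf


@dataclass(frozen=True)
class ScoreConfig:
    """The σ_s score constants (all finite and non-negative).

    c_m
        unit cost of a crossing-count mismatch between two ``(⋈,h)`` nodes;
    o_r
        cost of replacing an operator with a different one;
    o_di
        cost of deleting or inserting an operator node;
    h_di
        cost of deleting or inserting a hairpin leaf.
    """

    c_m: float = 1.0
    o_r: float = 100.0
    o_di: float = 100.0
    h_di: float = 100.0

    def __post_init__(self) -> None:
        for name in ("c_m", "o_r", "o_di", "h_di"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise StructureError(f"score constant {name} must be finite and >= 0")
            object.__setattr__(self, name, v)

    @classmethod
    def from_file(cls, path) -> "ScoreConfig":
        """Read ``key=value`` lines (keys c_m, o_r, o_di, h_di; '#' comments)."""
        values: dict[str, float] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise StructureError(f"malformed score line {raw.strip()!r}")
                key, val = (part.strip() for part in line.split("=", 1))
                if key not in ("c_m", "o_r", "o_di", "h_di"):
                    raise StructureError(f"unknown score constant {key!r}")
                values[key] = float(val)
        return cls(**values)


def score_pair(a, b, cfg: ScoreConfig) -> float:
    """σ_s on a single alignment pair; operands are tree nodes or :data:`GAP`."""
    if a is GAP and b is GAP:
        raise StructureError("the pair (-,-) is not allowed in an alignment")
    if a is GAP or b is GAP:
        node = b if a is GAP else a
        return cfg.h_di if isinstance(node, HairpinLeaf) else cfg.o_di
    a_leaf, b_leaf = isinstance(a, HairpinLeaf), isinstance(b, HairpinLeaf)
    if a_leaf and b_leaf:
        return 0.0
    if a_leaf != b_leaf:
        return INF  # hairpin against operator never conserves the term shape
    if a.op == b.op:
        if a.h is not None:  # two crossing nodes: local mismatch of h
            return cfg.c_m * abs(a.h - b.h)
        return 0.0
    return cfg.o_r


@dataclass(frozen=True)
class AlignedNode:
    """A node of the alignment tree: a pair of labels plus aligned children."""

    a: object  # StructuralTree node or GAP
    b: object
    children: tuple = ()

    def label(self, ascii_labels: bool = False) -> str:
        la = self.a if self.a is GAP else self.a.label(ascii_labels)
        lb = self.b if self.b is GAP else self.b.label(ascii_labels)
        return f"({la},{lb})"

    def tree_view(self, ascii_labels: bool):
        return self.label(ascii_labels), self.children


@dataclass(frozen=True)
class AlignmentResult:
    """Distance plus one optimal alignment forest (deterministic traceback)."""

    distance: float
    forest: tuple[AlignedNode, ...]

    def to_text(self, ascii_labels: bool = False) -> str:
        return ", ".join(tree_to_text(node, ascii_labels) for node in self.forest)


def align_trees(t1: StructuralTree, t2: StructuralTree,
                cfg: ScoreConfig | None = None) -> AlignmentResult:
    """Optimal alignment of two structural RNA trees under σ_s.

    Dynamic program over ordered forests.  When several alignments are
    optimal the traceback prefers replacement over deletion over insertion,
    and earlier splits over later ones; the distance itself is unique.
    """
    cfg = cfg or ScoreConfig()
    memo: dict = {}

    def key(f, g):
        return (tuple(id(x) for x in f), tuple(id(x) for x in g))

    def gap_all(forest, side):
        cost, out = 0.0, []
        for node in forest:
            sub_cost, sub = gap_all(node.children, side)
            pair = AlignedNode(node, GAP, sub) if side == "a" else AlignedNode(GAP, node, sub)
            cost += sub_cost + score_pair(*((node, GAP) if side == "a" else (GAP, node)), cfg)
            out.append(pair)
        return cost, tuple(out)

    def best(f, g):
        k = key(f, g)
        hit = memo.get(k)
        if hit is not None:
            return hit
        if not f and not g:
            result = (0.0, ())
        elif not g:
            result = gap_all(f, "a")
        elif not f:
            result = gap_all(g, "b")
        else:
            a, rest_f = f[0], f[1:]
            b, rest_g = g[0], g[1:]
            cand_cost, cand_forest = INF, ()
            # replacement (a,b)
            s = score_pair(a, b, cfg)
            if s < INF:
                c1, f1 = best(a.children, b.children)
                c2, f2 = best(rest_f, rest_g)
                cand_cost = s + c1 + c2
                cand_forest = (AlignedNode(a, b, f1),) + f2
            # deletion (a,-): a's children align with a prefix of g
            s = score_pair(a, GAP, cfg)
            for split in range(len(g) + 1):
                c1, f1 = best(a.children, g[:split])
                c2, f2 = best(rest_f, g[split:])
                total = s + c1 + c2
                if total < cand_cost:
                    cand_cost = total
                    cand_forest = (AlignedNode(a, GAP, f1),) + f2
            # insertion (-,b): b's children align with a prefix of f
            s = score_pair(GAP, b, cfg)
            for split in range(len(f) + 1):
                c1, f1 = best(f[:split], b.children)
                c2, f2 = best(f[split:], rest_g)
                total = s + c1 + c2
                if total < cand_cost:
                    cand_cost = total
                    cand_forest = (AlignedNode(GAP, b, f1),) + f2
            result = (cand_cost, cand_forest)
        memo[k] = result
        return result

    distance, forest = best((t1,), (t2,))
    return AlignmentResult(distance, forest)


def aspra_distance(s1: SecondaryStructure, s2: SecondaryStructure,
                   cfg: ScoreConfig | None = None) -> float:
    """ASPRA distance between two secondary structures.

    Builds both algebraic RNA trees, abstracts them to structural RNA trees
    and returns the minimum σ_s alignment score.  Non-negative, symmetric,
    zero on identical structures; not a metric (no triangle inequality).
    """
    return align_trees(structural_tree(s1), structural_tree(s2), cfg).distance


# ---------------------------------------------------------------------------
# brute-force oracle (test cross-check)
# ---------------------------------------------------------------------------

def _count(forest) -> int:
    return sum(1 + _count(n.children) for n in forest)


def enumerate_alignments_oracle(t1: StructuralTree, t2: StructuralTree,
                                cfg: ScoreConfig | None = None,
                                max_nodes: int = 8) -> float:
    """Minimum σ_s score by exhaustive enumeration of all alignment forests.

    Independent of the dynamic program: generates every legal alignment
    forest of the two trees and scores each by summing σ_s over its pairs.
    Exponential — only for tiny trees (≤ ``max_nodes`` nodes each).
    """
    cfg = cfg or ScoreConfig()
    if _count((t1,)) > max_nodes or _count((t2,)) > max_nodes:
        raise StructureError("oracle is exhaustive; trees too large")

    def gen(f, g):
        if not f and not g:
            yield ()
            return
        if f:
            a, rest_f = f[0], f[1:]
            for split in range(len(g) + 1):
                for sub in gen(a.children, g[:split]):
                    for rest in gen(rest_f, g[split:]):
                        yield (AlignedNode(a, GAP, sub),) + rest
        if g:
            b, rest_g = g[0], g[1:]
            for split in range(len(f) + 1):
                for sub in gen(f[:split], b.children):
                    for rest in gen(f[split:], rest_g):
                        yield (AlignedNode(GAP, b, sub),) + rest
        if f and g:
            for sub in gen(f[0].children, g[0].children):
                for rest in gen(f[1:], g[1:]):
                    yield (AlignedNode(f[0], g[0], sub),) + rest

    def total(forest):
        return sum(
            score_pair(n.a, n.b, cfg) + total(n.children) for n in forest
        )

    return min(total(forest) for forest in gen((t1,), (t2,)))
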