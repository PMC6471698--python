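"""The pseudoloop algebra: concatenation, crossing and nesting.

A *pseudoloop* is a bounded, pairing-annotated run of nucleotides
``(a1•, aN•)⟨a2 ... a(N-1)⟩`` whose first and last bases are paired (closed by
a fictitious "pseudoweak" interaction).  Every secondary structure without
head and tail is a pseudoloop, and any pseudoloop can be built from simple
hairpins with three binary operators:

* ``P1 ⊙_η P2`` — *concatenation*: P2 follows P1 after a (possibly empty)
  run ``η`` of unpaired linker nucleotides.  Always well defined, because the
  operands share no nucleotides.
* ``P1 ⋈_k P2`` — *crossing*: P2 overlaps the suffix of P1 starting at P1's
  internal position ``k`` and runs past its end (a pseudoknot).
* ``P1 ⋒_k P2`` — *nesting*: P1 is embedded inside P2 starting at P2's
  internal position ``k``.

Crossing and nesting overlay shared nucleotides; the pairing states merge
pointwise (unpaired+unpaired → unpaired, paired+unpaired → paired) and the
overlay is *well defined* only if no shared nucleotide is paired on both
sides — paired+paired is the undefined state ⊥ and raises
:class:`~aspra.errors.NotWellDefinedError`.  A mismatch of the shared
nucleotide letters or of the length conditions is a different kind of
failure and raises :class:`~aspra.errors.StructureError`.

Algebraic RNA trees are terms over the signature
``{⇄, ⊙, ⋈, ⋒, H}``; their leaves carry annotated nucleotide strings such as
``A•C∘C∘U•`` (``•`` paired, ``∘`` unpaired) and their yields use the operator
markers ``(⊙,η)``, ``(⋈,k)`` and ``(⋒,k)`` between operand substrings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .errors import NotWellDefinedError, ParseError, StructureError

PAIRED = "•"
UNPAIRED = "∘"

CONCAT_SYM = "⊙"
CROSS_SYM = "⋈"
NEST_SYM = "⋒"
ROOT_SYM = "⇄"


def merge_states(s: bool, t: bool) -> bool:
    """Merge two pairing states of a shared nucleotide.

    ``False`` is unpaired (∘), ``True`` is paired (•).  Both paired is the
    ⊥ case: the nucleotide would carry two weak interactions.
    """
    if s and t:
        raise NotWellDefinedError("shared nucleotide paired on both sides (⊥)")
    return s or t


class Pseudoloop:
    """Immutable pairing-annotated nucleotide run with paired bounds."""

    __slots__ = ("nucleotides",)

    def __init__(self, nucleotides) -> None:
        nucs = tuple((str(b), bool(p)) for b, p in nucleotides)
        if len(nucs) < 3:
            raise StructureError("a pseudoloop has at least three nucleotides")
        if not (nucs[0][1] and nucs[-1][1]):
            raise StructureError("pseudoloop bounds must be paired (•)")
        object.__setattr__(self, "nucleotides", nucs)

    def __setattr__(self, *_):  # pragma: no cover - immutability guard
        raise AttributeError("Pseudoloop is immutable")

    def __len__(self) -> int:
        return len(self.nucleotides)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pseudoloop) and self.nucleotides == other.nucleotides

    def __hash__(self) -> int:
        return hash(self.nucleotides)

    @property
    def letters(self) -> str:
        return "".join(b for b, _ in self.nucleotides)

    @property
    def states(self) -> tuple[bool, ...]:
        return tuple(p for _, p in self.nucleotides)

    @property
    def annotated(self) -> str:
        """Flat annotated string, e.g. ``A•C∘C∘U•`` (bounds included)."""
        return "".join(b + (PAIRED if p else UNPAIRED) for b, p in self.nucleotides)

    def __str__(self) -> str:
        body = "".join(
            b + (PAIRED if p else UNPAIRED) for b, p in self.nucleotides[1:-1]
        )
        first, last = self.nucleotides[0][0], self.nucleotides[-1][0]
        return f"({first}{PAIRED},{last}{PAIRED})⟨{body}⟩"

    def __repr__(self) -> str:
        return f"Pseudoloop({self.annotated!r})"

    @classmethod
    def from_annotated(cls, text: str) -> "Pseudoloop":
        return cls(parse_annotated(text))

    @classmethod
    def hairpin(cls, letters: str) -> "Pseudoloop":
        """A simple hairpin: paired bounds, all-unpaired interior."""
        if len(letters) < 3:
            raise StructureError("a hairpin encloses at least one nucleotide")
        states = [True] + [False] * (len(letters) - 2) + [True]
        return cls(zip(letters, states))


def parse_annotated(text: str) -> list[tuple[str, bool]]:
    """Parse an annotated string like ``A•C∘C∘U•`` into (base, paired) pairs."""
    out: list[tuple[str, bool]] = []
    it = iter(text)
    for base in it:
        mark = next(it, None)
        if mark not in (PAIRED, UNPAIRED):
            raise ParseError(f"annotated string malformed near {base!r}")
        out.append((base, mark == PAIRED))
    return out


def annotate(letters: str, paired_states) -> str:
    return "".join(
        b + (PAIRED if p else UNPAIRED) for b, p in zip(letters, paired_states)
    )


# ---------------------------------------------------------------------------
# the three operators
# ---------------------------------------------------------------------------

def concatenate(p1: Pseudoloop, eta: str, p2: Pseudoloop) -> Pseudoloop:
    """``P1 ⊙_η P2``: append P2 after P1 with the unpaired linker η.

    η is given as a plain nucleotide string; its bases are unpaired by
    definition.  Concatenation is always well defined.
    """
    linker = [(c, False) for c in eta]
    return Pseudoloop(list(p1.nucleotides) + linker + list(p2.nucleotides))


def crossing(p1: Pseudoloop, k: int, p2: Pseudoloop) -> Pseudoloop:
    """``P1 ⋈_k P2``: overlay P2 on P1's suffix starting at position k.

    Preconditions: ``2 <= k <= N-1``; P2 must end past P1
    (``M + k - 1 > N``); the overlapped letters must agree
    (``b_1 .. b_{N-k+1} = a_k .. a_N``).  The overlap's pairing states merge
    pointwise; a paired+paired clash raises ``NotWellDefinedError``.
    """
    n, m = len(p1), len(p2)
    if not 2 <= k <= n - 1:
        raise StructureError(f"crossing position k={k} outside [2,{n - 1}]")
    if m + k - 1 <= n:
        raise StructureError(
            f"crossing condition (1) violated: M+k-1={m + k - 1} must exceed N={n}"
        )
    if p2.letters[: n - k + 1] != p1.letters[k - 1:]:
        raise StructureError("crossing condition (2) violated: shared nucleotides differ")
    out: list[tuple[str, bool]] = []
    for z in range(1, m + k):  # 1-based result positions, length M+k-1
        if z < k:
            out.append(p1.nucleotides[z - 1])
        elif z > n:
            out.append(p2.nucleotides[z - k])
        else:
            base, s = p1.nucleotides[z - 1]
            _, t = p2.nucleotides[z - k]
            out.append((base, merge_states(s, t)))
    return Pseudoloop(out)


def nesting(p1: Pseudoloop, k: int, p2: Pseudoloop) -> Pseudoloop:
    """``P1 ⋒_k P2``: embed P1 inside P2 starting at P2's position k.

    Preconditions: ``2 <= k <= M-2``; P1 fits strictly inside P2
    (``k + N - 1 < M``); P1's letters equal ``b_k .. b_{k+N-1}``.  States in
    the embedded window merge as for crossing.
    """
    n, m = len(p1), len(p2)
    if not 2 <= k <= m - 2:
        raise StructureError(f"nesting position k={k} outside [2,{m - 2}]")
    if k + n - 1 >= m:
        raise StructureError(
            f"nesting condition (1) violated: k+N-1={k + n - 1} must be below M={m}"
        )
    if p1.letters != p2.letters[k - 1 : k + n - 1]:
        raise StructureError("nesting condition (2) violated: shared nucleotides differ")
    out: list[tuple[str, bool]] = []
    for z in range(1, m + 1):
        if z < k or z > k + n - 1:
            out.append(p2.nucleotides[z - 1])
        else:
            base, t = p2.nucleotides[z - 1]
            _, s = p1.nucleotides[z - k]
            out.append((base, merge_states(t, s)))
    return Pseudoloop(out)


# ---------------------------------------------------------------------------
# algebraic terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hairpin:
    """Leaf term ``H(x1 ω x2)``: one arc plus its enclosed run.

    ``letters`` is the plain nucleotide string from the arc's start to its
    stop; bounds are paired and the interior is all-unpaired at leaf level
    (inner pairings are reintroduced by the operators).  ``start``/``stop``
    are the absolute 1-based positions of the arc.
    """

    letters: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if len(self.letters) < 3:
            raise StructureError("hairpin body ω must be non-empty")
        if self.stop - self.start != len(self.letters) - 1:
            raise StructureError("hairpin positions inconsistent with its length")

    @property
    def annotated(self) -> str:
        states = [True] + [False] * (len(self.letters) - 2) + [True]
        return annotate(self.letters, states)

    @property
    def arc(self) -> tuple[int, int]:
        return (self.start, self.stop)


@dataclass(frozen=True)
class Concat:
    """Interior term ``⊙(left, (⊙,η), right)`` with unpaired linker η."""

    left: "PseudoloopTerm"
    eta: str
    right: "PseudoloopTerm"


@dataclass(frozen=True)
class Cross:
    """Interior term ``⋈(left, (⋈,k), H)``; the right child is a hairpin."""

    left: "PseudoloopTerm"
    k: int
    right: Hairpin

    def __post_init__(self) -> None:
        if not isinstance(self.right, Hairpin):
            raise StructureError("the right child of ⋈ must be a hairpin leaf")
        if self.k < 2:
            raise StructureError("crossing parameter k must be at least 2")


@dataclass(frozen=True)
class Nest:
    """Interior term ``⋒(left, (⋒,k), H)``; the right child is the enclosing hairpin."""

    left: "PseudoloopTerm"
    k: int
    right: Hairpin

    def __post_init__(self) -> None:
        if not isinstance(self.right, Hairpin):
            raise StructureError("the right child of ⋒ must be a hairpin leaf")
        if self.k < 2:
            raise StructureError("nesting parameter k must be at least 2")


@dataclass(frozen=True)
class Root:
    """Top term ``⇄(η1, T, η2)``: unpaired head, main pseudoloop, unpaired tail."""

    head: str
    child: "PseudoloopTerm"
    tail: str


PseudoloopTerm = Union[Hairpin, Concat, Cross, Nest]
AlgebraicTerm = Union[Root, PseudoloopTerm]


def evaluate_pseudoloop(term: PseudoloopTerm) -> Pseudoloop:
    """Bottom-up application of the operators to a pseudoloop subterm."""
    if isinstance(term, Hairpin):
        return Pseudoloop.hairpin(term.letters)
    if isinstance(term, Concat):
        return concatenate(evaluate_pseudoloop(term.left), term.eta,
                           evaluate_pseudoloop(term.right))
    if isinstance(term, Cross):
        return crossing(evaluate_pseudoloop(term.left), term.k,
                        Pseudoloop.hairpin(term.right.letters))
    if isinstance(term, Nest):
        return nesting(evaluate_pseudoloop(term.left), term.k,
                       Pseudoloop.hairpin(term.right.letters))
    raise StructureError(f"not a pseudoloop term: {term!r}")


def evaluate_term(term: Root) -> str:
    """Evaluate a full ⇄ term to the annotated sequence of its structure.

    Returns the pairing-annotated primary sequence, e.g.
    ``A∘A•G•...U∘``: the head and tail are unpaired, the body is the
    flattened pseudoloop obtained by applying the operators bottom-up.
    """
    if not isinstance(term, Root):
        raise StructureError("evaluate_term expects a ⇄ root term")
    body = evaluate_pseudoloop(term.child)
    head = annotate(term.head, [False] * len(term.head))
    tail = annotate(term.tail, [False] * len(term.tail))
    return head + body.annotated + tail


# ---------------------------------------------------------------------------
# yield strings: the pseudoloop-builder p and the grammar predicate c
# ---------------------------------------------------------------------------

_Item = tuple  # ("seg", annotated) | ("op", symbol, param)


def _tokenize_yield(u: str) -> list[_Item]:
    items: list[_Item] = []
    i, n = 0, len(u)
    seg_start = i
    while i < n:
        if u[i] == "(":
            if i > seg_start:
                items.append(("seg", u[seg_start:i]))
            close = u.find(")", i)
            if close < 0:
                raise ParseError("unterminated operator marker in yield string")
            inner = u[i + 1 : close]
            if "," not in inner:
                raise ParseError(f"malformed operator marker ({inner})")
            sym, param = inner.split(",", 1)
            if sym not in (CONCAT_SYM, CROSS_SYM, NEST_SYM):
                raise ParseError(f"unknown operator {sym!r} in yield string")
            items.append(("op", sym, param))
            i = close + 1
            seg_start = i
        else:
            i += 1
    if i > seg_start:
        items.append(("seg", u[seg_start:i]))
    if not items:
        raise ParseError("empty yield string")
    return items


def _segment_pseudoloop(annotated: str) -> Pseudoloop:
    return Pseudoloop.from_annotated(annotated)


def _linker_letters(param: str) -> str:
    # η in a (⊙,η) marker may be annotated ("G∘") or plain ("G"), possibly empty
    if UNPAIRED in param or PAIRED in param:
        nucs = parse_annotated(param)
        if any(p for _, p in nucs):
            raise ParseError("concatenation linker η must be unpaired")
        return "".join(b for b, _ in nucs)
    return param


def _parse_items(items: list[_Item]) -> Pseudoloop:
    """Backtracking parse of a tokenised yield.

    The top operator of a yield string is not always its rightmost marker
    (a concatenation's right operand may itself contain operators), so
    candidate splits are tried right-to-left and validated by the operators'
    own length/letter preconditions; the split produced by the grammar always
    validates.  A ⊥ arising on an otherwise structurally valid split is
    remembered and re-raised if no split succeeds.
    """
    if len(items) == 1:
        kind, payload = items[0][0], items[0][1]
        if kind != "seg":
            raise ParseError("yield string must start and end with a hairpin segment")
        return _segment_pseudoloop(payload)
    bottom: NotWellDefinedError | None = None
    # case: u' (⋈|⋒, k) x1 ω x2 -- rightmost marker with a trailing hairpin
    if (
        items[-1][0] == "seg"
        and items[-2][0] == "op"
        and items[-2][1] in (CROSS_SYM, NEST_SYM)
    ):
        sym, param = items[-2][1], items[-2][2]
        try:
            k = int(param)
        except ValueError as exc:
            raise ParseError(f"operator parameter {param!r} is not a position") from exc
        op = crossing if sym == CROSS_SYM else nesting
        try:
            left = _parse_items(items[:-2])
            return op(left, k, _segment_pseudoloop(items[-1][1]))
        except NotWellDefinedError as exc:
            bottom = exc
        except StructureError:
            pass
    # case: u' (⊙, η) u'' -- try each concatenation marker, right to left
    for idx in range(len(items) - 2, 0, -1):
        item = items[idx]
        if item[0] != "op" or item[1] != CONCAT_SYM:
            continue
        try:
            left = _parse_items(items[:idx])
            right = _parse_items(items[idx + 1 :])
            return concatenate(left, _linker_letters(item[2]), right)
        except NotWellDefinedError as exc:
            bottom = bottom or exc
        except StructureError:
            continue
    if bottom is not None:
        raise bottom
    raise ParseError("yield string has no valid decomposition")


def pseudoloop_of_yield(u: str) -> Pseudoloop:
    """The pseudoloop-builder ``p``: evaluate a yield string to a pseudoloop.

    ``p(x1 ω x2) = (x1,x2)⟨ω⟩``; ``p(u' (o,k) x1 ω x2) = p(u') o_k (x1,x2)⟨ω⟩``
    for ``o ∈ {⋈,⋒}``; ``p(u' (⊙,η) u'') = p(u') ⊙_η p(u'')``.  Raises
    ``NotWellDefinedError`` if the encoded overlay pairs a nucleotide twice.
    """
    return _parse_items(_tokenize_yield(u))


def well_formed(u: str) -> bool:
    """The grammar predicate ``c``: is the yield's operator chain well defined?"""
    try:
        pseudoloop_of_yield(u)
    except NotWellDefinedError:
        return False
    return True
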