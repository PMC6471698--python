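"""Seeded random structures and small worked-example structures.

The worked examples are tiny structures whose decompositions are known by
hand; they exercise every operator and both crossing counts and are used
throughout the test suite and the documentation.  The random generator
produces valid structures with a controllable propensity for pseudoknots so
that properties (round-trips, pseudoknot characterisation, alignment
invariants) can be checked without any external data.
"""

from __future__ import annotations

import random

from .errors import StructureError
from .structures import SecondaryStructure, structure_from_arcs

_SEQ_18 = "AAGACCUGCACGCUAGUU"

#: name -> (sequence or None, n, arcs)
_EXAMPLES: dict[str, tuple[str | None, int, tuple[tuple[int, int], ...]]] = {
    # one hairpin nested in another, k = 2
    "nested_hairpins": (_SEQ_18, 18, ((2, 14), (3, 13))),
    # two hairpins side by side, linked by the unpaired G at position 8
    "concatenated_hairpins": (_SEQ_18, 18, ((4, 7), (9, 12))),
    # the full 18-mer pseudoknot: concatenation, two nestings and a crossing
    "pseudoknot_18mer": (_SEQ_18, 18, ((2, 14), (3, 13), (4, 7), (9, 12), (8, 17))),
    # rightmost hairpin crosses exactly one of the other two
    "knot_one_crossing": (None, 19, ((2, 9), (4, 13), (11, 18))),
    # rightmost hairpin crosses both of the other two
    "knot_two_crossings": (None, 17, ((2, 9), (4, 13), (7, 16))),
    # synthetic companion to pseudoknot_18mer: a pure nesting chain whose
    # rightmost hairpin crosses all three others (root (⋈,3)); its distance
    # from pseudoknot_18mer is c_m + o_di + h_di
    "knot_three_crossings": (None, 18, ((2, 14), (3, 13), (4, 12), (8, 17))),
}

EXAMPLE_NAMES = tuple(_EXAMPLES)


def example_structure(name: str) -> SecondaryStructure:
    """One of the named worked-example structures (see :data:`EXAMPLE_NAMES`)."""
    try:
        seq, n, arcs = _EXAMPLES[name]
    except KeyError:
        raise StructureError(
            f"unknown example {name!r}; choose from {', '.join(_EXAMPLES)}"
        ) from None
    return structure_from_arcs(arcs, n=n, sequence=seq)


def random_structure(n: int, m: int, crossing_prob: float = 0.0,
                     seed: int = 0) -> SecondaryStructure:
    """A seeded random secondary structure with ``m`` arcs on ``n`` bases.

    Arcs are sampled by rejection: candidate pairs on free positions with at
    least one enclosed nucleotide are always accepted when they cross no
    existing arc, and accepted with probability ``crossing_prob`` when they
    do.  ``crossing_prob = 0`` therefore yields a pseudoknot-free structure;
    higher values yield increasingly interleaved ones.  The same seed always
    gives the same structure.
    """
    if not 0.0 <= crossing_prob <= 1.0:
        raise StructureError("crossing_prob must lie in [0, 1]")
    if m < 1 or n < 2 * m + 1:
        raise StructureError(f"infeasible parameters: need n >= 2m+1, got n={n}, m={m}")
    rng = random.Random(seed)
    for _ in range(64):  # full restarts if sampling paints itself into a corner
        free = list(range(1, n + 1))
        arcs: list[tuple[int, int]] = []
        failed = False
        for _ in range(m):
            for _attempt in range(500):
                i, j = sorted(rng.sample(free, 2))
                if j - i < 2:
                    continue
                crosses = any(
                    a < i < b < j or i < a < j < b for a, b in arcs
                )
                if crosses and rng.random() >= crossing_prob:
                    continue
                arcs.append((i, j))
                free.remove(i)
                free.remove(j)
                break
            else:
                failed = True
                break
        if not failed:
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            return SecondaryStructure(seq, tuple(arcs))
    raise StructureError(
        f"could not place {m} arcs on {n} bases with crossing_prob={crossing_prob}"
    )
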