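"""The grammar decomposition: unique algebraic RNA trees."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aspra import (
    Concat,
    Cross,
    Hairpin,
    Nest,
    Root,
    arcs_cross,
    build_algebraic_tree,
    evaluate_term,
    example_structure,
    main_pseudoloop_bounds,
    random_structure,
    rightmost_hairpin,
    split_concatenation_blocks,
    structure_from_arcs,
    tree_to_text,
    tree_yield,
)
from aspra.algebra import PAIRED, UNPAIRED


def annotation_of(s):
    paired = s.paired_positions
    return "".join(
        base + (PAIRED if pos in paired else UNPAIRED)
        for pos, base in enumerate(s.sequence, start=1)
    )


def collect(term, kind):
    if isinstance(term, Root):
        return collect(term.child, kind)
    found = [term] if isinstance(term, kind) else []
    for attr in ("left", "right"):
        child = getattr(term, attr, None)
        if child is not None and not isinstance(child, Hairpin):
            found += collect(child, kind)
        elif isinstance(child, Hairpin) and kind is Hairpin:
            found.append(child)
    return found


class TestMainPseudoloop:
    def test_head_and_tail_of_18mer(self, knot_18mer):
        head, span, tail = main_pseudoloop_bounds(knot_18mer)
        assert (head, span, tail) == ("A", (2, 17), "U")

    def test_full_span_arc(self):
        s = structure_from_arcs([(1, 5)], n=5)
        assert main_pseudoloop_bounds(s) == ("", (1, 5), "")

    def test_inner_arc(self):
        s = structure_from_arcs([(3, 7)], n=10)
        head, _, tail = main_pseudoloop_bounds(s)
        assert (len(head), len(tail)) == (2, 3)


class TestBlocks:
    def test_two_blocks_with_linker_g(self, knot_18mer):
        blocks, linkers = split_concatenation_blocks(
            [(4, 7), (9, 12)], knot_18mer.sequence
        )
        assert blocks == [((4, 7),), ((9, 12),)]
        assert linkers == ["G"]

    def test_18mer_main_span_is_one_block(self, knot_18mer):
        blocks, _ = split_concatenation_blocks(knot_18mer.arcs, knot_18mer.sequence)
        assert len(blocks) == 1

    def test_three_hairpins_build_left_associative(self):
        s = structure_from_arcs([(1, 4), (5, 8), (9, 12)], n=12)
        term = build_algebraic_tree(s).child
        assert isinstance(term, Concat)
        assert isinstance(term.left, Concat)  # ((H1 ⊙ H2) ⊙ H3)
        assert isinstance(term.right, Hairpin)


class TestCrossPredicate:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((11, 18), (4, 13), True),
            ((11, 18), (2, 9), False),
            ((2, 14), (3, 13), False),  # nested
            ((2, 5), (7, 10), False),  # disjoint
        ],
    )
    def test_examples(self, a, b, expected):
        assert arcs_cross(a, b) is expected
        assert arcs_cross(b, a) is expected

    def test_rightmost_hairpin(self, knot_18mer):
        assert rightmost_hairpin(knot_18mer.arcs) == (8, 17)
        assert rightmost_hairpin([(2, 9), (4, 13), (11, 18)]) == (11, 18)
        assert rightmost_hairpin([(1, 5)]) == (1, 5)


class TestDecomposition:
    def test_18mer_step_by_step(self, knot_18mer):
        tree = build_algebraic_tree(knot_18mer)
        assert (tree.head, tree.tail) == ("A", "U")
        crossings = collect(tree, Cross)
        nestings = collect(tree, Nest)
        concats = collect(tree, Concat)
        assert [c.k for c in crossings] == [7]
        assert sorted(n.k for n in nestings) == [2, 2]
        assert [c.eta for c in concats] == ["G"]
        assert tree_yield(tree) == (
            "A∘A•C∘C∘U•(⊙,G∘)C•A∘C∘G•(⋒,2)G•A∘C∘C∘U∘G∘C∘A∘C∘G∘C•"
            "(⋒,2)A•G∘A∘C∘C∘U∘G∘C∘A∘C∘G∘C∘U•(⋈,7)G•C∘A∘C∘G∘C∘U∘A∘G∘U•U∘"
        )

    def test_nested_pair_nesting_k2(self):
        tree = build_algebraic_tree(example_structure("nested_hairpins"))
        term = tree.child
        assert isinstance(term, Nest)
        assert term.k == 2
        assert term.right.arc == (2, 14)

    def test_single_arc_is_a_hairpin_leaf(self):
        tree = build_algebraic_tree(structure_from_arcs([(1, 5)], n=5))
        assert isinstance(tree.child, Hairpin)

    def test_evaluation_reproduces_the_18mer_annotation(self, knot_18mer):
        assert evaluate_term(build_algebraic_tree(knot_18mer)) == annotation_of(
            knot_18mer
        )
        paired = {
            pos
            for pos, mark in enumerate(
                evaluate_term(build_algebraic_tree(knot_18mer))[1::2], start=1
            )
            if mark == PAIRED
        }
        assert paired == {2, 3, 4, 7, 8, 9, 12, 13, 14, 17}


class TestSerialisation:
    def test_structural_leaf_format(self):
        from aspra.structural import HairpinLeaf

        assert tree_to_text(HairpinLeaf(2, 9)) == "(~H(2,9)~, [])"

    def test_children_in_order_and_deterministic(self, knot_18mer):
        tree = build_algebraic_tree(knot_18mer)
        text = tree_to_text(tree)
        assert text == tree_to_text(build_algebraic_tree(knot_18mer))
        assert text.index("(⋒,2)") < text.index("(⋈,7)")

    def test_ascii_fallback(self, knot_18mer):
        text = tree_to_text(build_algebraic_tree(knot_18mer), ascii_labels=True)
        assert "CROSS" in text and "NEST" in text and "CONCAT" in text
        assert "⋈" not in text

    def test_serialisation_parses_back_injectively(self):
        texts = set()
        for seed in range(20):
            s = random_structure(n=30, m=5, crossing_prob=0.5, seed=seed)
            text = tree_to_text(build_algebraic_tree(s))
            shape = parse_tree_text(text)
            assert render(shape) == text  # lossless parse-back
            texts.add(text)
        assert len(texts) == 20  # distinct structures, distinct serialisations


def parse_tree_text(text):
    """Minimal reader for the (~label~, [children]) shape (test-only)."""
    pos = 0

    def node():
        nonlocal pos
        assert text[pos : pos + 2] == "(~"
        pos += 2
        end = text.index("~, [", pos)
        label = text[pos:end]
        pos = end + 4
        children = []
        while text[pos] != "]":
            children.append(node())
            if text[pos : pos + 2] == ", ":
                pos += 2
        pos += 2  # "])"
        return (label, tuple(children))

    out = node()
    assert pos == len(text)
    return out


def render(shape):
    label, children = shape
    return f"(~{label}~, [{', '.join(render(c) for c in children)}])"


@given(
    m=st.integers(min_value=1, max_value=12),
    crossing_prob=st.sampled_from([0.0, 0.3, 0.8]),
    seed=st.integers(min_value=0, max_value=2**20),
)
@settings(max_examples=80, derandomize=True, deadline=None)
def test_round_trip_and_pseudoknot_characterisation(m, crossing_prob, seed):
    """Leaf arcs equal input arcs; evaluation restores the pairing; a
    crossing node appears iff some arc pair crosses."""
    s = random_structure(n=60, m=m, crossing_prob=crossing_prob, seed=seed)
    tree = build_algebraic_tree(s)
    assert sorted(h.arc for h in collect(tree, Hairpin)) == list(s.arcs)
    assert evaluate_term(tree) == annotation_of(s)
    has_cross = bool(collect(tree, Cross))
    any_crossing_pair = any(
        arcs_cross(a, b) for i, a in enumerate(s.arcs) for b in s.arcs[i + 1 :]
    )
    assert has_cross == any_crossing_pair


def test_build_scales_to_long_nested_helices():
    """Linear-time construction: a deep helix stack builds without fuss."""
    m = 300
    arcs = [(i, 2 * m + 2 - i) for i in range(1, m + 1)]
    s = structure_from_arcs(arcs, n=2 * m + 2)
    tree = build_algebraic_tree(s)
    assert len(collect(tree, Nest)) == m - 1
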