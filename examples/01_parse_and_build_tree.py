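"""Parse a pseudoknotted structure and build its algebraic RNA tree.

The 18-mer below carries five base pairs; pair (8,17) reaches from inside
the nested stem out into the tail region, crossing (2,14) and (3,13) — a
pseudoknot.  The unique grammar decomposition expresses the whole structure
as hairpins combined by concatenation (⊙), nesting (⋒) and crossing (⋈).
"""

from aspra import build_algebraic_tree, parse_arc_annotated, tree_to_text, tree_yield

s = parse_arc_annotated("AAGACCUGCACGCUAGUU\n(2,14);(3,13);(4,7);(9,12);(8,17)\n")
tree = build_algebraic_tree(s)

print("head:", tree.head, " tail:", tree.tail)
print("yield:", tree_yield(tree))
print("tree:", tree_to_text(tree))

# The yield spells out the decomposition left to right: two small hairpins
# concatenated with linker G, nested twice (k=2) into the enclosing stems,
# and finally crossed (k=7) by the hairpin spanning positions 8-17.
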