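"""Abstract algebraic RNA trees to structural RNA trees.

Two structures can apply the crossing operator in the same pattern yet
interleave differently; the crossing count h at each ⋈ node records how many
hairpins of the left pseudoloop the right hairpin actually crosses.
"""

from aspra import structure_from_arcs, structural_tree, tree_to_text

one = structure_from_arcs([(2, 9), (4, 13), (11, 18)], n=19)
two = structure_from_arcs([(2, 9), (4, 13), (7, 16)], n=17)

print("one crossing :", tree_to_text(structural_tree(one)))
print("two crossings:", tree_to_text(structural_tree(two)))

# Both trees have the same shape, but the roots read (⋈,1) and (⋈,2): in the
# first structure the rightmost hairpin crosses only (4,13), in the second it
# crosses both (2,9) and (4,13).
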