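# aspra

Algebraic tree representation and structural comparison of RNA secondary
structures with **arbitrary pseudoknots**.

## The problem

RNA secondary structures are routinely compared through their tree
representation — but the classical tree encoding breaks down as soon as two
base pairs cross (a pseudoknot), which excludes many biologically important
structures from tree-based comparison. This package implements an algebraic
language in which *every* secondary structure, knotted or not, has a unique
tree: hairpin loops are the atomic operands, and three binary operators over
*pseudoloops* (bounded, pairing-annotated nucleotide runs) combine them:

- **concatenation** `P1 ⊙_η P2` — P2 follows P1 after an unpaired linker η;
- **nesting** `P1 ⋒_k P2` — P1 is embedded inside hairpin-closed P2 at
  position k;
- **crossing** `P1 ⋈_k P2` — P2 overlaps P1's suffix from position k and
  runs past its end (this is what a pseudoknot looks like algebraically).

Nesting and crossing overlay shared nucleotides; they are *well defined*
only if no nucleotide ends up in two base pairs (the ⊥ rule). A regular
tree grammar over `{⇄, ⊙, ⋈, ⋒, H}` with these operators yields exactly one
derived tree per structure — the **algebraic RNA tree** — and a structure is
pseudoknotted iff its tree contains a ⋈ node.

For comparison, the algebraic tree is abstracted to a **structural RNA
tree**: a binary tree with interior labels `⊙`, `⋒`, `(⋈,h)` and leaves
`H(start,stop)`, where `h` counts how many hairpins of the left pseudoloop
the right hairpin crosses. The **ASPRA distance** between two structures is
the minimum score of an ordered-tree alignment of their structural trees
under the scoring σ_s:

| pair                    | score        |
|-------------------------|--------------|
| `(⋈,h)` vs `(⋈,h′)`     | `c_m·|h−h′|` |
| operator vs different operator | `o_r` |
| operator vs gap         | `o_di`       |
| hairpin vs hairpin      | `0`          |
| hairpin vs operator     | `+∞`         |
| hairpin vs gap          | `h_di`       |

Hairpin positions score 0 so the measure is independent of the primary
sequence; defaults `c_m=1`, `o_r=o_di=h_di=100` keep crossing-count
mismatches a strictly local, cheap difference. The distance is symmetric and
zero on identical structures, but not a metric (no triangle inequality).

## Worked example

```python
from aspra import (parse_arc_annotated, build_algebraic_tree, tree_yield,
                   structural_tree, tree_to_text, aspra_distance,
                   structure_from_arcs)

s = parse_arc_annotated("AAGACCUGCACGCUAGUU\n(2,14);(3,13);(4,7);(9,12);(8,17)\n")
print(tree_yield(build_algebraic_tree(s)))
# A∘A•C∘C∘U•(⊙,G∘)C•A∘C∘G•(⋒,2)G•A∘C∘C∘U∘G∘C∘A∘C∘G∘C•(⋒,2)A•G∘A∘C∘C∘U∘G∘C∘A∘C∘G∘C∘U•(⋈,7)G•C∘A∘C∘G∘C∘U∘A∘G∘U•U∘

one = structure_from_arcs([(2, 9), (4, 13), (11, 18)], n=19)
two = structure_from_arcs([(2, 9), (4, 13), (7, 16)], n=17)
print(tree_to_text(structural_tree(one)))
# (~(⋈,1)~, [(~(⋈,1)~, [(~H(2,9)~, []), (~H(4,13)~, [])]), (~H(11,18)~, [])])
print(aspra_distance(one, two))
# 1.0
```

Reading the yield: the 18-mer decomposes into two small hairpins joined by
the unpaired linker `G`, nested twice (both at relative position `k=2`) into
the enclosing stems, and finally crossed at `k=7` by the hairpin spanning
positions 8–17 — the pseudoknot. The two three-arc structures differ only in
how deeply the rightmost hairpin interleaves (`h=1` vs `h=2` at the root),
so their distance is exactly one crossing-mismatch unit, `c_m·|1−2| = 1`.
Structures whose operator skeletons differ score in the hundreds instead.

More narrative walk-throughs live in `examples/`; each script prints its
results with a note on what they mean.

## Command line

```sh
aspra tree structure.aas --kind structural        # print the tree
aspra distance one.aas two.aas                    # print the distance
aspra generate --n 40 --m 6 --crossing-prob 0.5 --seed 1 --out-prefix rnd
```

Inputs are two-line files: either sequence + dot-bracket string (pseudoknots
use extra bracket families `[] {} <> Aa…Zz`) or sequence + arc list
`(i1,j1);(i2,j2);…` (sequence line may be empty). Score constants can be
overridden with `--config` (a `key=value` file for `c_m, o_r, o_di, h_di`).

## Layout

- `src/aspra/structures.py` — formats, validation, the `SecondaryStructure` type
- `src/aspra/algebra.py` — pseudoloops, the three operators, yields, predicate *c*
- `src/aspra/build.py` — the unique grammar decomposition into algebraic trees
- `src/aspra/structural.py` — abstraction to structural RNA trees
- `src/aspra/align.py` — σ_s, the alignment DP, the ASPRA distance, a brute-force oracle
- `src/aspra/synthetic.py` — seeded random structures and worked-example fixtures
- `src/aspra/cli.py` — the thin command-line layer
- `docs/methods.md` — models, conventions, numerical choices, limitations
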