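# Methods

## Data model and conventions

A secondary structure is a sequence over `A,C,G,U` (or the placeholder `N`
when only the structure is known) plus a set of arcs `(i,j)`, 1-based and
inclusive at both ends. Validation enforces the biology the algebra relies
on: every position sits in at most one arc, and every arc encloses at least
one nucleotide (`j − i ≥ 2`) — a pair with an empty interior has no hairpin
body and is rejected. Structures with zero arcs are rejected as well: the
grammar's axiom always produces a main pseudoloop, so there is nothing to
decompose. Arcs are stored canonically sorted, making parsing independent of
input order.

Since the distance ignores nucleotide identity, structure-only input is
accepted: an absent sequence is replaced by a run of `N`. Dot-bracket
output assigns bracket families `() [] {} <> Aa…Zz` greedily — each arc goes
to the first family it does not cross — which guarantees every family is
well nested and the output re-parses to the same structure.

## The operators

Pseudoloops are stored as immutable runs of (base, paired?) with paired
bounds. Concatenation simply splices its operands around an unpaired
linker. Crossing and nesting overlay a shared region; the pairing states
merge pointwise (`∘+∘→∘`, `•+∘→•`, `∘+•→•`) and `•+•` is the undefined
state ⊥. Two failure modes are deliberately distinct exception types: a
violated length condition or a mismatch of shared nucleotide letters is a
*structural* error (the operands simply do not fit), while ⊥ is the
*well-definedness* failure (the overlay would give a nucleotide two base
pairs). Tests discriminate the two.

The crossing definition is implemented with the shared region
`b₁…b_{N−k+1} = a_k…a_N` and the post-overlap states taken from
`t_{z−k+1}`; these index choices are the ones that reproduce the worked
`⋈₇` overlay character-for-character, which the suite asserts. Bounds are
always paired and participate in the merge like any other position.

## Unique decomposition

`build_algebraic_tree` follows the deterministic procedure: identify the
main pseudoloop (first to last paired position; what precedes/follows is
the unpaired head/tail on the ⇄ root), then recursively

1. split into maximal concatenation blocks (no arc spans a boundary) and
   fold them left-associatively with the unpaired linkers η;
2. otherwise pick the hairpin α with the rightmost paired nucleotide: if it
   crosses a remaining arc, emit `⋈` with `k` = α's left end relative to the
   remaining pseudoloop's span; if not, α must enclose everything left
   (asserted at run time) and `⋒` is emitted with `k` = the inner
   pseudoloop's first paired position relative to α;
3. a single arc is a hairpin leaf.

`k` is computed as `(absolute left endpoint) − (span start) + 1` in both
cases; both printed worked values (`k=7` for the crossing, `k=2` for the
nestings) come out of this one formula. Hairpin leaves carry an
all-unpaired interior — pairings inside are reintroduced by the operators
during evaluation — plus absolute start/stop. The grammar's constant K (a
maximum hairpin length, needed only to keep the grammar's alphabet finite)
is intentionally not enforced.

Construction is linear in `n` plus total arc length and recursion depth is
bounded by the arc count, comfortable for any realistic molecule.

## Yield strings

Term yields use the markers `(⊙,η)`, `(⋈,k)`, `(⋒,k)` between annotated
operand substrings, and `pseudoloop_of_yield` implements the three-case
builder `p` with the predicate `c` (`well_formed`) on top. A raw yield
string does not always determine its parse: when a concatenation's right
operand is itself compound, the rightmost marker is not the top operator.
The parser therefore backtracks over candidate splits (rightmost
crossing/nesting first, then concatenation markers right to left) and lets
the operators' own length and shared-letter preconditions reject wrong
splits; the grammar-generated split always validates. On placeholder-only
sequences the letter check is vacuous and disambiguation rests on the
length conditions alone — for adversarial hand-written yields (as opposed
to yields of built trees) this is a known soft spot, and the coherence
property `p(yield(t)) = evaluate(t)` is exercised on randomly lettered
structures where the letter check has full power.

## Abstraction and crossing counts

The structural tree drops the ⇄ root, the head/tail, the operator-parameter
leaves and all nucleotide identity; hairpins become `H(start,stop)`. Each
`⋈` node is annotated with `h`, the number of hairpins in its left child's
pseudoloop that cross the right-child hairpin (two arcs cross iff, ordered
so `j′<j`, `i′<i<j′`). `h` is computed during a single depth-first visit
that returns each subtree's hairpin list, and `h ≥ 1` is asserted — a
crossing node whose hairpin crosses nothing would contradict the
decomposition. The abstraction is the only code path for structural trees
(always via the algebraic tree), so the two representations cannot drift
apart.

## Alignment

The distance uses the classical ordered-forest alignment recurrences: at
each step the leftmost roots are replaced together, or one is deleted (its
children aligning with a prefix of the other forest's trees), or inserted
(symmetrically). The implementation memoises on contiguous sibling
intervals, giving the usual product-of-sizes behaviour for binary trees.
`+∞` (hairpin vs operator) is `math.inf`: sum-safe and never selected when
a finite alignment exists, which one always does via gaps.

Scoring follows σ_s with one sharpening: "replace operator" (`o_r`) applies
to *distinct* operator labels, identical labels scoring 0 — the standard
edit convention, and required for a tree to be at distance 0 from itself.
Two crossing nodes always use the `c_m·|h−h′|` rule regardless of h; a
crossing node against `⊙` or `⋒` scores `o_r` with h ignored, since the
crossing-count rule is local to pairs of crossing nodes. Default constants
are `c_m=1`, `o_r=o_di=h_di=100`: integer scores avoid rounding issues and
keep a crossing mismatch three orders of magnitude below a true edit, so
the two effects never trade against each other in practice.

When several alignments are optimal the traceback deterministically prefers
replacement over deletion over insertion and earlier splits over later
ones; the distance itself is unique. Output is in general a forest (e.g.
when both roots are gapped); projecting out either gap component recovers
the corresponding input tree, which the suite checks.

An exhaustive enumerator of all legal alignment forests serves as an
independent oracle; the DP is cross-checked against it on hundreds of
random tree pairs of up to six nodes (beyond that the enumeration
explodes, which is exactly why the DP exists).

## Synthetic data

The random generator draws `m` arcs on `n` bases by rejection sampling:
candidates need free endpoints and `j−i ≥ 2`; a candidate crossing an
existing arc is accepted with probability `crossing_prob`, so `0` yields
pseudoknot-free structures and higher values increasingly interleaved ones.
Sequences are uniform random `ACGU`; everything is deterministic per seed.
Property tests run at `n ≤ 60`, `m ≤ 15` across `crossing_prob ∈
{0, 0.3, 0.8}` — small enough to iterate hundreds of structures quickly,
large enough to exercise every operator combination. The generator emulates
arc *topology* only: no thermodynamics, no helix stacking statistics, no
base-pair composition bias. Passing tests therefore certify the algebra,
the decomposition and the distance on arbitrary arc arrangements, not any
claim about distributions of real RNA structures.

The bundled worked-example structures reproduce the hand-checkable
decompositions used throughout the docs and tests. One of them,
`knot_three_crossings`, is a synthetic reconstruction: a companion to the
18-mer pseudoknot whose structural tree has root `(⋈,3)` above a pure
nesting chain, so that its distance from the 18-mer is exactly
`c_m + o_di + h_di` (one crossing-count unit, one operator deletion, one
hairpin deletion) for *any* score constants — the suite asserts the
identity under two unrelated configurations.

## Known limitations

- Arbitrary hand-written yield strings over a single-letter alphabet may
  parse ambiguously (see above); yields produced from trees are safe.
- The alignment is global; local or multiple forest alignment and affine
  gap models are out of scope.
- Tree text output serialises; parsing the text format back is provided
  only as test scaffolding, not API.
- The distance is not a metric: the triangle inequality can fail, as is
  inherent to alignment-based tree distances.
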