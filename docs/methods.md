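# Methods

## Problem and representation

The package matches the annotated secondary-structure elements (SSEs) of
an atomic model to the axis "sticks" a detector finds in a
medium-resolution cryo-EM density map. Each element is represented by a
single directed segment: first-to-last Cα for a model helix/strand,
first-to-last axis point for a stick. This deliberately discards internal
curvature; for a model helix the first Cα also lies off the helical axis,
and no axis re-estimation is attempted — endpoints are used as traced.
Segment direction is an artifact of trace order (a detector may walk a rod
either way), so every downstream feature must be insensitive to start/end
swaps; this is why the angle feature uses |cos θ| by default
(`angle_mode="signed"` restores the raw cosine for users whose traces have
a meaningful orientation).

## Feature graphs

For one side's set of segments, three complete weighted graphs are built
(angle, midpoint Euclidean distance, relative length). All three weights
are invariant under rotation and translation of the whole set, which is
the property that makes the model frame and the map frame comparable
without any registration step. Angle and RL are additionally
scale-invariant; ED scales linearly with a global scale factor. Each
adjacency matrix is symmetric with an exactly-zero diagonal, and
off-diagonal entries are non-negative (they can be exactly zero — e.g.
orthogonal segments under the angle feature — which is why zero is not
treated as an error).

## Row scoring

Row *i* of the model-side matrix (length m−1) and row *j* of the map-side
matrix (length n−1) describe different, as-yet-unmatched neighbours, so
positional comparison is meaningless. The default alignment sorts both
rows in descending order and zero-pads the shorter to the common length —
each row becomes a permutation-invariant geometric profile. This is the
package's single most consequential design choice: the alternative
(`row_alignment="truncate_sorted"`) truncates the longer sorted row
instead, and both are exposed because neither is canonical.

Two scorers compare aligned rows:

* **BD** (default mode `normalized`): each row is rescaled to sum to 1 and
  BD = −ln Σₖ √(pₖ qₖ). This is the classical Bhattacharyya distance; it
  is ≥ 0, zero iff the normalized rows coincide, symmetric, and invariant
  to positive rescaling of either row (which makes the unbounded ED rows
  comparable across differently-sized proteins). When the Bhattacharyya
  coefficient underflows to 0 the distance is capped at `bd_max = 745`,
  just below −ln of the smallest positive double. A `literal` mode
  computes −ln Σₖ raₖ·rcₖ on the raw rows — the unnormalized inner-product
  variant — for comparison; it is unbounded and may be negative, and is
  not the default precisely because it lacks the [0, ∞) distance
  semantics.
* **MAC**: (ra·rc)² / ((ra·ra)(rc·rc)) ∈ [0, 1], equal to 1 iff the rows
  are proportional. Scale-invariant by construction.

An all-zero row profile (a node with no geometric context) is an error
rather than a silent 0/0.

## Candidate assignment

Each feature's m×n score matrix is resolved into a one-to-one
correspondence of size min(m, n) by exact linear assignment
(`scipy.optimize.linear_sum_assignment`), maximizing total MAC or
minimizing total BD. Ties between equally-optimal assignments are broken
toward the lexicographically smallest pair list (lowest a_index, then
c_index); the exact tie-break refinement — iteratively fixing each row to
the smallest column that preserves the optimal total — costs O(m·n) extra
assignment solves and therefore runs only for min(m, n) ≤ 12, the regime
where exact score ties realistically occur (hand-built or constant
matrices). For larger continuous-score instances exact ties have measure
zero and the solver's deterministic output is used directly. A `greedy`
mode (repeatedly take the best remaining entry) exists purely as an
ablation baseline, and an exhaustive brute-force enumerator (min(m, n) ≤ 8)
serves as an independent oracle in the tests. Unmatched elements, present
whenever m ≠ n, are simply absent from the set — the correspondence is not
assumed to be a bijection.

## Voting fusion (SimVA)

The three candidate sets are fused in three stages. Unanimous pairs
(present in all three) are accepted first, then pairs present in two of
three sets over still-free indices, then the principle of least conflict:
among candidate pairs over free indices (pool = union of the three sets,
recomputed every iteration so pairs missed by both voting stages remain
reachable), accept the pair sharing an index with the fewest other pool
pairs; iterate to exhaustion. All tie-breaks are total orders (vote count,
then score under the active scorer's polarity — pair score being its mean
across the candidate sets that contain it — then lowest indices), so the
fusion is deterministic. A consequence worth knowing: with three injective
candidate sets, two distinct pairs that each hold ≥ 2 votes can never
share an index (pigeonhole over three sets), so majority-stage conflicts
cannot actually arise through the pipeline; the resolution rule is
implemented defensively. PLC is iterated to exhaustion rather than run
once — the single-pass alternative leaves free elements unmatched and was
rejected because the pool-union design exists precisely to extend
coverage.

## Evaluation

Confusion is counted per model-side element i = 1..m: TP if predicted to
match its true partner, TN if correctly left unmatched, FP if matched
wrongly (including when no true partner exists), FN if left unmatched
despite having one. The four metrics are reported as percentages;
F-measure is the harmonic mean of precision and sensitivity computed on
the fractional values and then scaled. Zero-denominator ratios are
reported as 0 and flagged rather than raised, since an empty prediction is
a legitimate (if useless) output.

## Synthetic benchmark generator

The generator emulates the *geometry* of the matching problem, not the
density map itself. A layout of n segments has lengths uniform in
[8, 40] Å (≈ 5–27-residue helices at a 1.5 Å/residue rise), uniformly
random orientations, and midpoints uniform in a ball of radius
6·n^(1/3) Å so packing density is roughly size-independent. The map side
is derived by a random rigid motion (the two frames are unrelated),
optional isotropic Gaussian endpoint jitter, random end-trimming (sticks
are systematically shorter than their SSEs), dropping a fraction of
sticks (missed detections), appending spurious sticks drawn from the same
geometry distribution (hallucinated detections), and shuffling the order
so index coincidence can never masquerade as skill.

What the generator does **not** model: correlated SSE packing (sheets of
parallel strands, helix bundles), detector error correlated with stick
length or map resolution, curved rods, and strand-specific detection
rates. Passing the synthetic suite therefore demonstrates the method's
geometric core — invariance, scoring, assignment and fusion — not its
accuracy on any particular experimental map.

With zero noise the map side is exactly a rigid-transformed shuffled copy,
the peer graphs are identical up to relabeling, every true pair scores
MAC = 1 / BD = 0, and the pipeline must recover the native correspondence
exactly; this is the primary smoke test. Under detection errors alone
(10% dropped + 2 spurious at n = 20) there is a structural accuracy
ceiling: every candidate injection covers all m model elements, so PLC
assigns everything and each dropped-partner element is a forced false
positive (ceiling 90% at these settings); measured fused accuracy sits
around 76–81% depending on scorer and seeds, roughly ten points above the
per-feature candidates, mirroring the fusion gain the method is built
for.

## Numerical choices

* Degenerate segments (length ≤ 10⁻⁶ Å) are rejected at construction.
* Rigid-motion invariance is asserted to 10⁻⁹ in tests; feature math is
  plain double precision.
* BD cap 745 (see above); cosine clipped to [−1, 1] before use.
* Assignment tie-break tolerance: 10⁻⁹ relative to the largest |cost|.
* Problem sizes exercised by the test suite and acceptance script — up to
  65 model SSEs vs 54 sticks, 20-seed repetitions at n = 20, 10 seeds at
  n = 65 — were chosen to bracket the sizes the method targets while
  keeping a full run in seconds.

## Known limitations

* Helix endpoints are Cα positions, not axis points, so model and map
  segments for the same helix differ systematically by ~2.3 Å of radial
  offset at each end; at medium resolution this is below the feature
  scales that drive matching, and no correction is applied.
* The candidate-construction rule (global linear assignment) is one
  defensible choice among several; published accuracies obtained with a
  different (unstated) rule are not directly comparable.
* All elements are treated identically regardless of helix/strand kind;
  kind is carried as metadata only.
* Multi-chain models require an explicit chain selection; chains are never
  merged.
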