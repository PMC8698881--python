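# ssematch

Finding which secondary-structure element (SSE) of an atomic model
corresponds to which density rod in a medium-resolution (~4–10 Å) cryo-EM
map. At that resolution a map shows the positions and orientations of
α-helices and β-strands but not the backbone, so detectors (SSETracer,
SSEhunter, …) emit a set of axis "sticks" with no labels. Pinning each
annotated model SSE to its stick is the anchor step for placing Cα atoms
and building an initial backbone; `ssematch` automates it.

## Method

Both sides are reduced to 3D segments: a model SSE *i* becomes the vector
from its first to its last Cα (HVᵢ), a stick becomes the vector between
the ends of its axis trace (SVᵢ). Each side's set of m (model) or n (map)
vectors is then turned into three complete weighted graphs whose edge
weights are pairwise features:

* **angle** — |cos θ| between the two segment directions,
* **ED** — Euclidean distance between segment midpoints (Å),
* **RL** — relative length |Lᵢ − Lⱼ| / (Lᵢ + Lⱼ),

all invariant under rigid motion, so the model and map graphs are directly
comparable even though the two frames are unrelated. Row *i* of a graph's
adjacency matrix is a geometric signature of node *i*; rows from the two
sides are aligned (sorted descending, zero-padded) and scored with either

* **BD** — Bhattacharyya distance, −ln Σₖ √(pₖ qₖ) on the normalized rows
  (0 = identical), or
* **MAC** — modal assurance criterion, (rᵢ·rⱼ)² / ((rᵢ·rᵢ)(rⱼ·rⱼ))
  (1 = proportional),

giving one m×n score matrix per feature. Exact linear assignment
(Hungarian) turns each into a one-to-one candidate correspondence, and the
three candidates are fused by **SimVA**: unanimous voting, then majority
voting, then the principle of least conflict (repeatedly accept the
remaining candidate pair that shares an index with the fewest other
remaining candidate pairs). Predictions are scored against a known truth
with per-element TP/TN/FP/FN and accuracy / precision / sensitivity /
F-measure.

## Worked example

Everything runs on synthetic benchmarks, no downloads. Generate a 10-SSE
model whose "map" lost one stick and gained one spurious rod, match, and
score:

```sh
ssematch simulate --n 10 --seed 7 --drop-fraction 0.1 --spurious-count 1 --out-dir demo
ssematch match demo/model.pdb demo/sticks.txt --chain A --out-dir demo/out
ssematch evaluate demo/out/correspondence.tsv demo/native.tsv --m 10
```

which prints

```
wrote synthetic case (m=10, n=10) to demo
matched 10 of 10 model SSEs (unanimous 4, majority 6, PLC 0) -> demo/out
tp      tn      fp      fn      accuracy        precision       sensitivity     f_measure
9       0       1       0       90.00   90.00   100.00  94.74
```

Four pairs were agreed by all three features, six more by two of three;
nine of the ten assignments are correct. The one error is forced: the
model SSE whose stick was dropped has no right answer, and matching it to
anything counts as a false positive. `demo/out/` holds the final
correspondence TSV (`a_index  c_index  score`), the three per-feature
candidate sets and a report with per-pair stage provenance.

The same pipeline is available as a library:

```python
from ssematch import NoiseSpec, RunConfig, generate_case, match_vector_sets, evaluate

case = generate_case(20, NoiseSpec(drop_fraction=0.1, spurious_count=2, seed=0))
result = match_vector_sets(case.set_a, case.set_c, RunConfig(scorer="MAC"))
print(evaluate(result.final, case.native, m=len(case.set_a)))
```

Real inputs work the same way: an annotated PDB file (HELIX/SHEET records
plus Cα coordinates) on the model side, and a stick file (one `x y z`
axis point per line, blank line between sticks — or a pseudo-atom PDB with
one chain per stick via `--stick-format pdb`) on the map side.

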