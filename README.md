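# fpsim

Dense binary fingerprint formats and fast Tanimoto/Tversky similarity
search.

Molecular similarity search — "find every compound whose fingerprint is at
least 0.7 similar to this query", or "find its 1000 nearest neighbors" —
is a workhorse of cheminformatics, sitting under virtual screening,
neighbor tables and clustering (the Taylor–Butina sparse similarity matrix
is just an N×N threshold search). fpsim implements the full stack for
people who work with fingerprints as data:

* the **FPS** text format (hex fingerprint + id per line, `#`-prefixed
  header metadata, gzip transparent) and a chunked binary **FPB** format
  with lazy, memory-mapped loading;
* a popcount-sorted in-memory **fingerprint arena** with **BitBound**
  pruning: a hit at threshold *t* against a query of popcount *A* must
  have popcount *B* in [*A·t*, *A/t*], so whole popcount bins are skipped;
* **threshold** and **k-nearest** search (heap and counting-sort
  variants), streaming FPS file-scan search, multiquery and symmetric
  N×N modes, with Tanimoto `c/(A+B−c)` or Tversky
  `c/(α(A−c)+β(B−c)+c)` scoring;
* command-line tools `fpsim simsearch | fpcat | sdf2fps`;
* a synthetic fingerprint generator and a benchmark task suite with
  deterministic candidate-count instrumentation.

All accept/reject decisions use exact integer arithmetic: thresholds are
carried as the exact rational `p/q` of their double value, candidates are
accepted iff `c ≥ ⌈T(A+B)/(1+T)⌉` (one integer compare per candidate, no
division), and Tversky weights are scaled by 10,000 to integers so
self-similarity is exactly 1.0. Floating point appears only in reported
scores.

## Worked example

Generate a synthetic 166-bit MACCS-like data set, then search it with one
of its own fingerprints as the query:

```sh
$ python -c "
from fpsim.synthetic import SyntheticSpec, generate_fps
generate_fps(SyntheticSpec(num_bits=166, count=1000, density=0.25, seed=7),
             'demo.fps')"
$ head -3 demo.fps
#FPS1
#num_bits=166
#type=Synthetic/1 model=uniform density=0.25 seed=7

$ fpsim simsearch demo.fps \
    --query 04450a117020020a40c3c22a9002c0001080410821 --k-nearest 5
Query1	5	SYN0007	1.000	SYN0463	0.303	SYN0093	0.288	SYN0031	0.271	SYN0242	0.258
```

One line per query: the query id, the hit count, then alternating hit id /
score pairs (three decimals). The query here is record `SYN0007` itself,
so the best hit scores exactly 1.000; the remaining neighbors of a random
uniform set cluster around ~0.3, the background similarity level at this
density. (Hit order is descending score, ties by ascending position.)

The same search through the library:

```python
from fpsim import read_fps, build_arena, knearest_search, hex_decode

with read_fps("demo.fps") as reader:
    arena = build_arena(list(reader), reader.metadata)
query = hex_decode("04450a117020020a40c3c22a9002c0001080410821")
for i, score in knearest_search(arena, query, 5):
    print(arena.ids[i], round(score, 3))
```

`threshold_search(arena, query, 0.7)` returns every target at or above
0.7; `symmetric_matrix_search(arena, "threshold", {"threshold": 0.7})`
returns the sparse symmetric all-pairs matrix (diagonal excluded) as a
`scipy.sparse.csr_matrix`. `fpsim fpcat a.fps b.fps -o merged.fpb`
converts and merges between FPS, FPS.gz and FPB.

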