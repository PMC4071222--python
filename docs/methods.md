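# Methods

`seqbic` discovers order-preserving biclusters in real-valued expression
matrices by sequential pattern mining. This note records the model, the
algorithmic choices, the defaults and their rationale, what the synthetic
benchmark does and does not show, and known limitations.

## Model

A bicluster is a pair (I, J) of row and column subsets together with a
linear order π over J such that every row of I, restricted to J, is
monotone along π. Two readings of "monotone" are supported:

* **xor** — strictly increasing between tie groups, equal within a tie
  group (the strict order-preserving model);
* **or** — non-decreasing: equality and increase are interchangeable.

Order-preserving coherence subsumes constant, additive (shifting) and
multiplicative (scaling) row effects, which is why this bicluster type is
attractive for expression modules: co-regulated genes preserve the ranking
of conditions even when their absolute levels differ.

The search reduces biclustering to sequential pattern mining (SPM). Each
row is mapped to a sequence of itemsets over its column indexes: columns
are sorted by (discretized) value, columns with equal symbols co-occur in
one itemset, and increasing symbols form precedences. A frequent sequential
pattern then maps directly to a bicluster: its supporting rows are I, its
distinct items are J, and the pattern's itemset order is π. The support
threshold θ is the minimum number of rows; the minimum item count δ is the
minimum number of columns. Closed patterns (no super-pattern with equal
support) are the default representation because they correspond to maximal
biclusters — biclusters that cannot be extended without losing rows or
columns.

## Mapping

* **Normalization**: z-scoring per row (default), column or matrix. The
  zero-mean property is required for the symmetric (sign-flip) search and
  makes symmetric discretization meaningful. Constant units are centered
  only.
* **Discretization**: equal-width, equal-depth, Gaussian cut-off (default)
  or Poisson cut-off bins; the Poisson option requires a fitted rate ≥ 3
  and otherwise falls back to the Gaussian with a warning. Default alphabet
  size is ⌊m/4⌋ clamped to [2, 20]. A raw-value mode orders exact values
  with no discretization (ties are exact equality); it yields perfect
  biclusters but no noise tolerance.
* **Noise relaxation**: a cell whose value lies within 10% of its bin's
  width from a boundary also receives the adjacent bin's symbol (the
  items-boundary problem). A centroid-distance variant assigns every symbol
  whose centroid is within a user threshold.
* **Missing values**: *restrictive* removes the cell from its row's
  sequence; *relaxed* lets the column co-occur at every position (plus one
  virtual position at each end — a missing column may precede, follow or
  tie with anything, but never splits two observed positions); and
  *delta-replacement* assigns the symbols whose centroids lie within δ of a
  row-statistic estimate (row median by default, at most the 4 nearest
  symbols).
* **Outliers**: optional |z| masking (off by default; threshold 3 when on).

## Mining

The miner is a prefix-projection (pattern-growth) search. Rows mapped from
a matrix are *item-indexable*: each column occurs a small bounded number of
times, so a row is fully described by the itemset index ("rank") at which
each column sits. The compiled kernel encodes the feasible ranks of the
pattern's current itemset as one 64-bit mask per active row; growing the
pattern is then two bit operations per candidate (sequence extension:
ranks above the smallest feasible rank; itemset extension: mask
intersection). This exact feasible-set propagation supports multi-symbol
cells and wildcard (relaxed-missing) columns without special cases. Rows
whose suffix cannot reach δ items are dropped from projections, which keeps
supports exact because only patterns with ≥ δ items are emitted. Candidate
items are restricted by anti-monotonicity (dropping an item of a frequent
pattern leaves a frequent pattern), and candidate counting abandons a
candidate once the remaining rows cannot lift it to θ.

Under the **or** behavior the kernel mines monotone chains of distinct
columns with non-decreasing ranks. Co-occurrence itemsets are not
enumerated separately: under the or reading a tie satisfies a chain, so the
flat chain over the same columns has at least the co-occurrence pattern's
support and derives the same bicluster. Closedness is computed within this
chain family. A pure-Python miner with the textbook semantics (arbitrary
itemset patterns, or-expanded databases) handles small inputs and anchors
the equivalence tests; an exhaustive enumeration oracle guards both on tiny
instances.

Exhaustive order-preserving search is combinatorial: once θ falls below the
chance level of short random chains, the frequent-pattern space explodes.
Every mining call therefore carries a **node budget** (default 4,000,000
search nodes). A support level whose search exceeds the budget is treated
as unminable and the scheduler keeps the previous level's solution. This is
the package's principled replacement for an arbitrary absolute support
floor: the effective floor adapts to each data set's chance structure.

**Support schedule.** θ starts at 0.5 and decays by 10% per step until the
solution holds 50 non-similar biclusters, the raw (pre-closing) solution
exceeds 50 biclusters, coverage reaches 10% of the matrix cells, the
absolute support would fall below 4 rows, or the node budget is exhausted.
The raw-count stop matters: exhaustive order-preserving search transitions
sharply from "only real modules are frequent" to "random chains flood the
output" as θ falls, and a raw solution past the size target is the signal
that the transition has begun. Steps that emit no pattern (θ far above any
module's size) descend three decay steps at once; this cannot change the
stopping point because the stopping rules only react to non-empty
solutions, and an accelerated step that lands in the explosion is retried
at single-step resolution.

## Closing

Derived biclusters are post-processed in this order:

1. **Significance filtering** (each scheduler iteration): a bicluster with
   L columns and support σ in an n×m matrix over K symbols is kept only if
   the expected number of random column chains of that length reaching
   that support, E = perm(m, L) · P(Binomial(n, p_L) ≥ σ), stays below
   0.5, where p_L is the single-row match probability of a fixed chain
   (C(K+L−1, L)/K^L under or; C(K, L)/K^L under xor; 1/L! for raw-value
   ordering). This is the statistical-significance filter that guards an
   exhaustive search against chance patterns.
2. **Representative selection** (each scheduler iteration): candidates are
   ranked by column count then support — long patterns are preferred
   because a spurious long order-preserving pattern is combinatorially
   implausible, so they carry the least row pollution. A candidate is
   suppressed when (a) its row overlap with a kept bicluster reaches 40%
   of the smaller row set, (b) half its rows are already covered by the
   union of kept biclusters, or (c) 30% of its rows lie inside a kept
   bicluster with more columns (a side view of an already-described
   module). At most the solution-size target (50) survive.
3. **Merging** (default 80% overlap of the smaller bicluster, measured on
   cell area; a row-set mode is available): best-pair-first greedy with a
   consensus permutation (columns ordered by mean symbol over the merged
   rows — a Borda count; exact majority relations can be intransitive). A
   homogeneity guard (mean row violation fraction ≤ 0.25 against the
   consensus) stops unrelated modules from chaining into one block through
   shared rows.
4. **Extension** (statistical, on by default): candidate *columns* are
   inserted at their best slot and screened against a Monte-Carlo null
   that shuffles the candidate down the rows and repeats the best-slot
   search, at a Bonferroni-corrected threshold (a false column poisons the
   permutation and later costs genuine rows); candidate *rows* are
   screened against the permutation null of their own symbol multiset —
   exact enumeration up to 8 present columns, 10,000-draw Monte-Carlo
   beyond — at α = 0.01 per candidate, uncorrected. Columns are tested
   before rows because a longer permutation sharpens the row test. Row
   correction is deliberately absent: at benchmark scale a Bonferroni row
   threshold admits only violation-free rows, which defeats the purpose of
   extension (recovering noise-displaced members); a few false rows cost
   little row-set Jaccard. The relaxed-support strategy (re-mine at
   θ(1−f) and merge) is also provided.
5. **Row/column filtering** (default homogeneity 0.75): iteratively remove
   the worst-offending row or column until every one agrees with π on at
   least 75% of its evaluated pairs; a bicluster that would fall under 2
   rows or δ columns is discarded.
6. **Final selection and containment filtering**: significance and
   representative selection run again on the closed solution, duplicates
   and biclusters contained in larger ones are removed; the result is an
   antichain.

## Symmetries

Anti-correlated rows (sign-flipped expression) join a bicluster through a
per-row factor c ∈ {−1, +1}. The search runs one iteration per alignment
column: rows are multiplied by ±1 so that column becomes non-negative, the
plain pipeline runs on the corrected matrix, and discovered biclusters
carry the sign vector restricted to their rows. An identity iteration (no
flips) runs first, so the result is a superset of the plain search after
deduplication; iterations whose canonical sign vector (global flips
identified, first row fixed positive) was already processed are skipped.
Sign mirroring maps symbol k to |Σ|−1−k; with an odd alphabet the middle
symbol is its own mirror image by the symmetric cut-off construction.

## Synthetic benchmark

The generator plants k order-preserving (or multiplicative) biclusters in
an i.i.d. background — uniform on (−1, 1) or standard normal — with
row/column counts drawn uniformly from per-setting ranges. Four presets
cover 100×30 (2 planted), 500×50 (3), 1000×75 (5) and 2000×100 (8). Row
and column picks are independent across biclusters, so plantings overlap;
later plantings overwrite earlier values in shared cells, which erodes the
earlier bicluster where they cross. Per-row values are sorted background
draws placed along a hidden permutation; additive noise is uniform within
±`noise_factor` × (domain range) per cell, with `noise_factor` capped at
0.10 ("up to ±10% of the domain range" — experiments spread the level of
their replicate instances evenly over [0, 0.10]). A `replace_rate` option
substitutes that fraction of all cells with fresh background draws (the
corruption used to probe the closing extensions); `missing_rate` blanks
cells uniformly; `symmetry_rate` negates that fraction of each bicluster's
rows before noise.

What the benchmark does not emulate: correlated (heteroscedastic or
row-dependent) noise, dependence between modules and background, realistic
expression marginals (library-size or intensity effects), and replicate
structure. Passing recovery tests therefore shows that the search and
closing machinery work as designed under the stated noise model, not that
modules of any particular real data set will be recovered.

Two properties of the generator bound the attainable match scores well
below 1 even for a perfect method: overlapping plantings overwrite one
another (the hidden list still credits the overwritten rows to the earlier
bicluster), and per-cell additive noise at the ±10% ceiling breaks the
within-row ordering of adjacent planted values whose gap is below the
noise amplitude, so a sizable fraction of planted rows genuinely no longer
follow their module's full ordering. The recovery experiments' scores
should be read against that ceiling; the noise sweep (instances at levels
spread over [0, 10%]) makes the dependence visible.

## Experiment problem sizes

The packaged experiments (`seqbic repro`, `scripts/acceptance.py`, the
acceptance tests) run at reduced replication: 3 instances per setting for
recovery (500×50 and 1000×75), 3 instances for the missing-value baseline,
2 for the extension study, and the per-setting mining parameters listed in
`experiments.SETTING_PARAMS` (20 symbols; δ one below the smallest planted
column count; 10 symbols for the missing-value study, following the
original protocol of that comparison). The extension study runs on the
1000×75 setting with a 20-symbol alphabet. The missing-value and extension
studies measure completeness of recovery rather than solution compactness,
so they raise the raw-solution-size stop to 400 (coarse alphabets make
each planted module spawn dozens of equally legitimate sub-patterns, and
the comparison protocol's 50-bicluster stop would end the schedule before
the smaller modules' support level). Each instance's support schedule,
node budget and seeds derive deterministically from the master seed.

## Numerical and tie-breaking choices

* Canonical itemset form: columns sorted by index; pattern output sorted by
  (support desc, item count desc, lexicographic) for determinism.
* Relative θ converts to an absolute count by ceiling.
* Consensus permutations group columns whose mean symbols differ by less
  than 1e−12.
* All randomness (generator, Monte-Carlo nulls) flows from explicit seeds;
  derived sub-seeds come from `numpy.random.SeedSequence` spawning.
* Degenerate inputs: empty databases mine to empty lists; all-missing rows
  are dropped with a log notice; constant units are centered but not
  scaled.

## Limitations

* The column-oriented (vertical) search for very wide matrices (m ≫ n) is
  not implemented; the dynamic parameterization logs a notice and the
  row-oriented search is used. Order-preserving biclusters on columns can
  still be mined by transposing the input.
* The or-behavior fast path mines monotone chains (see above); textbook
  or-semantics with explicit co-occurrence patterns are available through
  the pure-Python engine for small inputs.
* Bit-mask encoding supports up to 62 ranks per row; raw-value ordering of
  matrices with more than ~60 columns falls back to the slower engine.
* Statistical extension tests are screening devices, not calibrated
  inference: the column null conditions on the observed column values, the
  row null on the observed row multiset, and no multiplicity correction is
  applied by default.
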