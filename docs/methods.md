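# Methods

## Model and test

Let F1 and F2 be two motif libraries (sets of genomic intervals, BED-style
0-based half-open coordinates). Two intervals co-localize when their
overlap length is at least `min_overlap` bases (default 1). The test metric
for each hypothesis is the number of **distinct** motifs of the counted
feature with at least one qualifying overlap in the other — not the number
of overlapping pairs and not base-level coverage. The pair count is
symmetric under feature exchange; the distinct-motif counts are not, and
their divergence is informative exactly when motifs of one feature nest
inside the other (many short motifs per long region).

Two one-sided hypotheses are evaluated:

* **H01**: the count of F1 motifs inside F2 exceeds chance;
* **H02**: the count of F2 motifs inside F1 exceeds chance.

"Chance" is an empirical null: simulated libraries in which each motif is
re-placed at a uniformly random genome position (optionally composition-
matched, below). With N simulated replicates, the Monte-Carlo p-value is

```
p = (1 + #{null metric >= observed metric}) / (1 + N)
```

The add-one form bounds p in `[1/(N+1), 1]` and counts ties against
rejection, so the test is valid (never anti-conservative) at any N. The
default N = 100 replicates resolves p down to ~0.01; raise it if smaller
p-values are needed. Verdicts: both p ≤ α ⇒ `colocalization_reciprocal`;
exactly one ⇒ `cooccurrence_one_sided` with direction; neither ⇒ `none`.
α defaults to 0.05.

### Which feature is simulated

`TestConfig.simulate` controls the null:

* `"f1"` (default) or `"f2"`: one designated feature is re-placed and
  **both** metrics are recomputed against each replicate. This matches the
  situation where one feature (e.g. broad damage peaks) is the natural
  candidate for re-placement while the other (a dense, sequence-defined
  motif track) is held fixed.
* `"both"`: each hypothesis re-places the feature whose motifs it counts,
  the fully bi-directional style appropriate when the two features are of
  the same data type.

The choice matters for diagnostics of nested data. In the nested scenario
(clusters of k short motifs per long host, hosts hit at chance frequency),
re-placing the *short* feature is what exposes the signature — the
query-count metric rejects while the host-count metric stays at chance.
Re-placing the hosts instead would move the null away from the clustered
queries and make both metrics reject, hiding the asymmetry. The package's
asymmetry checks therefore simulate the short feature.

## Property-informed simulation

Re-placing motifs uniformly preserves lengths but destroys sequence
composition. When both features prefer a composition class (the motivating
case: 8-oxo-dG is oxidised guanine, and many non-B DNA motifs are G-rich),
a length-only null understates the chance overlap and produces false
positives. The simulator therefore optionally preserves the guanine
fraction of each motif:

* **Placement domain.** Valid starts are all positions where the interval
  fits; in genome-wide mode the chromosome is chosen with probability
  proportional to its number of valid starts, so placement is uniform over
  positions, not over chromosomes. `within_chromosome=True` restricts each
  motif to its template's chromosome.
* **%G.** Guanine fraction is counted on the plus-strand reference
  (`composition="G"`, default, appropriate for guanine-specific damage);
  `"GC"` switches to G+C. Non-ACGT characters count toward interval length
  but never toward G, and candidates with more than
  `max_non_acgt_fraction` (default 0.1) ambiguous bases are rejected,
  which keeps placements out of assembly gaps.
* **Dynamic tolerance.** A candidate is accepted when
  |%G(candidate) − %G(template)| ≤ tolerance. The tolerance starts at
  `start` (default 0.02) and increases by `step` (default 0.02) after
  every `attempts_per_level` (default 100) consecutive rejections, capped
  at `max_tolerance` (default 1.0). At the cap the %G constraint is
  vacuous, so only the non-ACGT filter can reject; if even that exhausts a
  level, any in-bounds candidate is accepted. Escalation therefore
  *structurally* excludes infinite loops. Motifs accepted at the cap are
  flagged in the per-motif report, which records template %G, simulated
  %G, final tolerance and flag status; for every unflagged motif the
  reported final tolerance is a hard bound on the %G error.
* **Simulation pool.** Candidates that pass the placement filters but miss
  the current tolerance are cached under a (length, %G bin) key, with bin
  width equal to `step` (bins at the resolution of the acceptance
  tolerance) and a per-key cap of 128 entries to bound memory. Each motif
  consults the pool before drawing fresh candidates; entries are consumed
  without replacement, so a pooled placement is never issued twice in a
  run. The pool is an efficiency device only: with it disabled the
  simulated %G distribution is statistically indistinguishable on matched
  seeds, but more fresh candidates must be drawn (both properties are
  under test).

Defaults `start = step = 0.02` sit at the fidelity end of the
efficiency–fidelity trade-off: tight enough that a bimodal motif %G
distribution survives simulation visibly intact, loose enough that typical
libraries simulate without escalating more than one or two levels.

Simulated motifs within a replicate may overlap each other and the
original motifs; forbidding self-overlap would make dense libraries
infeasible to place and is not required by the test's logic.

### Seeding and reproducibility

All randomness flows from user-visible integer seeds. Each module derives
its generators as `default_rng([seed, module_salt, k])` with a distinct
salt per module, so passing the same seed to the data generator and to the
test can never make a simulation replicate collide with the observed data
(an earlier revision without salts had exactly that failure: replicate
`r = 1` of a run seeded like the generator reproduced the observed library
bit-for-bit and corrupted the null's upper tail). In length-only mode each
replicate r is drawn in one vectorised pass from `(seed, r)` and is
independently reproducible; in %G-matched mode the shared pool carries
cache state across replicates, so individual replicates are reproducible
only as part of the whole run, which remains deterministic from the seed.

## Subtype post-test

For a query library partitioned into subtypes, co-localization strength is
the **normalized overlap proportion**: overlapped-pivot-count / pivot-size
(`by_pivot`) or overlapped-subtype-count / subtype-size (`by_subtype`).
For each unordered subtype pair the observed statistic is the difference
of proportions; the null reshuffles subtype labels over the pair's pooled
motifs, preserving sizes, and the two-sided p-value is
`(1 + #{|null| ≥ |observed|}) / (1 + n_permutations)` (default n = 100).
Labels are permuted within each pair, not jointly across all subtypes.
Benjamini–Hochberg q-values are reported across the pair matrix; the
direction of every difference is in the observed sign.

Because the statistic is a difference of counts on a lattice, ties between
permuted and observed values are common, and the reported p-value is
deliberately conservative on them (the two-sided fold doubles the tie
mass). The exact-calibration property — under exchangeable subtypes the
permutation rank is uniform — is verified in the test suite through the
randomized probability integral transform of the rank, alongside a
one-sided check that the reported p-value rejects at most nominally.

`compare_subtypes_with_pivot_resimulation` additionally draws a fresh
property-informed simulation of the pivot library for every permutation
iteration (a permutation-plus-bootstrap null); observed proportions are
still computed against the real pivot, the permutation stream is shared
with the plain variant, and the output is flagged `resimulated_pivot`.

## Overlap counting

Counting is a sorted-array sweep per chromosome. A pivot `[ps, pe)` has a
qualifying partner at threshold t iff some query satisfies `qs ≤ pe − t`
and `qe ≥ ps + t` (and both lengths ≥ t); with queries sorted by start and
a prefix maximum over their ends this is one vectorised `searchsorted` per
pivot array. Pair counts use inclusion–exclusion on the two sorted
coordinate arrays; the two subtracted sets can intersect only when
`t > (pivot_length + 3) / 2`, a regime handled by an explicit per-pivot
correction. Equivalence with the all-pairs brute force over random
instances and thresholds is enforced in the acceptance suite.
Stratified counts assign each overlapped pivot motif to the annotation
class with the largest overlap, ties broken by annotation file order;
pivots touching no annotation land in `unannotated`.

## Synthetic data

The generator emulates the statistical structure the method operates on:

* **Genome**: i.i.d. nucleotides at a background %G (default 0.25, the
  unbiased value), with optional composition islands overwritten at their
  own %G — the confounder scenario uses 40 × 5 kb islands at %G 0.6 on a
  1 Mb background, the two-peak scenario a 12.5%-G background with 30%-G
  islands, mirroring the bimodal %G structure reported for oxidative
  damage regions (peaks near 12.5% and 30%).
* **Features**: a host feature of long regions (default scenario
  200 × 500 b) and a query feature of short motifs (500 × 25 b), the two
  length scales that make reciprocal testing necessary. Lengths can be
  fixed, two-valued, or lognormal by median.
* **Planted co-localization**: a fraction ρ of query motifs is placed
  uniformly *inside* uniformly chosen hosts; nesting factor k places them
  in clusters of k per host. Cluster hosts are drawn **with replacement**
  so that the number of distinct hosts receiving clusters follows the same
  collision process as independent placement of the cluster seeds — this
  is what makes the k = 10 scenario leave the host-count metric at chance
  while inflating the query-count metric k-fold.
* **Subtypes**: per-subtype (count, length, ρ), concatenated with labels.

What the generator does *not* emulate: chromatin or repeat structure,
peak-caller artifacts (width jitter, summit bias), assembly gaps, or
correlated motif spacing. Passing tests therefore demonstrate the
statistical machinery — calibration, power, confounder control — under the
model's own assumptions, not robustness to every artifact of real peak
data.

One exchangeability subtlety the test suite respects: the planted count
`round(ρ·n)` is deterministic, so two subtypes generated with equal ρ > 0
are *not* exchangeable with their label permutation (the observed
difference is under-dispersed relative to the permutation null);
exchangeable fixtures use ρ = 0, where motifs are i.i.d.

## Numerical choices and edge cases

* Empty pivot library: overlap metric undefined ⇒ error; empty query:
  zero metrics with a warning. Degenerate tests with zero observed overlap
  in both directions return verdict `none` (p = 1 allowed).
* Thresholds for coverage profiles must be strictly increasing; the
  resulting count sequence is non-increasing by construction.
* %G comparisons use an absolute slack of 1e-12 to keep float rounding
  from breaking tolerance checks at bin edges.
* `gc_mode_count` (used by the dual-peak checks) counts runs of histogram
  bins (width 0.05) holding ≥ 10% of the sample; it presumes peaks
  separated by more than one bin with a valley below threshold, which is
  the regime the scenarios construct.
* BED writing reproduces coordinates bit-exactly; when a library has
  subtype labels but no names, labels are written into the BED name
  column, the same convention the `compare` command reads back.

## Problem sizes

The shipped test and acceptance configurations use 1 Mb single-chromosome
genomes, host/query libraries of 150–500 motifs, N = 99 simulation
replicates and 99 permutations, with 20–200 datasets per calibration
check. These sizes put Monte-Carlo rates well inside their binomial
acceptance bands while keeping the whole suite fast on a single CPU;
the method itself has no intrinsic scale limits beyond memory for the
genome and O((n+m) log) per overlap count.

## Known limitations

* %G is the only matched composition trait; dinucleotide content, repeat
  class and masking tracks are out of scope (the non-ACGT filter is the
  only gap handling).
* Strand is ignored in overlap computation.
* The %G-matched null is exchangeable with observed data only to the
  extent that observed placements are composition-driven; features placed
  by mechanisms the simulator does not model (e.g. distance to replication
  origins) can still confound.
* p-value resolution is `1/(N+1)`; headline claims below 0.01 need more
  replicates than the default 100.
* The pairwise subtype test does not provide an omnibus
  all-subtypes-at-once comparison.
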