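# Methods

## Model and assumptions

`intronsim` treats a set of homologous introns as the leaves of a guide tree
whose internal nodes are unobserved ancestral sequences. Evolution along
each branch is reduced to two event types: point substitution and
contiguous block indels. The two simulators differ only in the sign of the
length trajectory — mutation-and-deletion (MD) shrinks from a long root
ancestor, mutation-and-insertion (MI) grows from a short one — and share all
other machinery. Deliberate simplifications:

* no selection, no rate heterogeneity across sites, no context-dependent
  mutation;
* one contiguous indel block per event, at a uniformly chosen internal
  position or junction (the simplest model consistent with "a number of
  bases per event");
* substitutions inside one event hit distinct sites; across events a site
  may be hit again (event counts, not distinct-site counts, are budgeted);
* the `GT`/`AG` termini are protected from all events after the root
  ancestor is capped, so every simulated molecule keeps splice-site
  structure throughout (a flag on the core operators can lift this).

## Parameters

| parameter | units | default / range | role |
|---|---|---|---|
| `L_AS1` | bases | MD 4000–7000, MI 10–40 | length of the root ancestor |
| `L_AS12` | bases | MD 2000–2750, MI 110–140 | length of the last ancestor |
| `M_1` | subs / unit branch length | 200–800 | per-edge budget `round(M_1·b)` |
| `L_I/D` | bases / event | e.g. 31–50 | block size drawn uniformly per indel event |
| `M_I/D` | bases / event | e.g. 11–50 | substitutions drawn uniformly per mutation event |
| `R` | — | 1.5 | transition probability `R/(R+1)` per substitution |

Intermediate ancestor lengths are linearly interpolated in backbone index
between `L_AS1` and `L_AS12`, then a repair pass clamps each ancestor
between its parent (monotonicity) and one base beyond its most constraining
leaf child. A parameterisation is valid only if every direct ancestor ends
strictly longer (MD) / shorter (MI) than each of its leaf children; with the
default tree this bounds `L_AS12 ≥ 2000` for MD (the longest leaf is 1975)
and `L_AS12 ≤ 140` for MI (the interpolated ancestor above the 112-base
leaf then stays below 112). The schedule is pluggable (`plan_stages`
accepts a callable) because only the endpoint lengths are externally
prescribed; linear-in-index is the simplest schedule satisfying all stated
inequalities.

Branch alternation starts with mutation, then indel, reading the two event
types in their conventional order; final partial draws are capped by the
remaining budget rather than redrawn, which makes leaf lengths exact for
every seed.

## The synthetic guide tree

The default fixture is a ladder-like (caterpillar) rooted display: basal
trifurcation with two leaves, one leaf per intermediate ancestor, a
terminal cherry; 14 leaves and 12 ancestors. Three leaf lengths anchor the
printed extremes and the worked example (112, 376, 1975); the worked-example
leaf descends from AS_2, the shortest leaf from AS_9, the longest from the
last ancestor AS_12, which is what makes the validity bounds above bind the
way they do. The other eleven lengths are drawn uniformly on [150, 1850] so
every seed passes both models' validity checks; branch lengths are drawn
uniformly on [0.05, 0.60], the magnitude range typical of trees of
fast-evolving non-coding sequence. The fixture emulates the *shape* of a
real reference tree, not any particular branch-length estimates, so absolute
attribute values (especially `D̄` and `R_K2+I` of generated sets, which are
sensitive to per-edge substitution loads and to alignment saturation) are
not comparable to values measured on real introns; the tests therefore
check structural and statistical properties, not published attribute means.

Because no real intron sequences ship with the package, the
perturbation-reference workflow uses a synthetic stand-in
(`experiment.synthetic_reference`): one deletion-model run plays the role
of the observed sequence set, and its own inferred tree is the reference
topology. An unperturbed control then scores the full 2N topology points
and has zero attribute variance, which is the property the tests pin down.

## Attribute pipeline

* **Alignment** (builtin backend): deterministic progressive alignment — a
  k-mer (k = 6) distance matrix, average-linkage guide tree, and
  profile–profile Needleman–Wunsch merges under integer sum-of-pairs
  scoring (match +1, mismatch −1, gap −2 per site; gap columns cost 2 per
  base faced). Scores are summed, not averaged, so the dynamic programme is
  exact in integer arithmetic and the traceback (diagonal > up > left on
  ties) is fully deterministic. Input order is canonicalised by sorting ids,
  making the alignment order-invariant. `backend="mafft"` shells out to
  MAFFT when present; the builtin is the default and the one used by tests.
* **K2P statistics**: per pair, transition/transversion difference
  proportions P and Q over sites where both rows carry a base;
  `d = −½ln((1−2P−Q)√(1−2Q))`, ts/tv ratio `d_s/d_v` with
  `d_s = −½ln(1−2P−Q) + ¼ln(1−2Q)` and `d_v = −½ln(1−2Q)`. Pairs with
  non-positive log arguments are flagged undefined: excluded from `D̄`
  (count reported) and imputed as twice the largest defined distance for
  tree inference. The set-level ratio pools site counts across pairs before
  applying the formula — per-pair ratios are numerically unstable when
  `d_v ≈ 0`. An optional invariant-sites flag drops fully conserved columns
  first; it is off by default since "+I" estimators differ between desktop
  phylogenetics packages and none is replicated here.
* **Bootstrap SE**: 500 column resamples by default; the replicate mean
  distance is computed from per-pair site-class count matrices by a single
  matrix product, and the SE is the sample SD across replicates. Fixed
  seeds make it reproducible; column duplication shrinks it by ~1/√2,
  which the tests verify.
* **Tree inference**: neighbor joining (scikit-bio) on the K2P matrix,
  negative branch lengths clamped to zero, displayed rooted at the internal
  node adjacent to the outgroup leaf (default: lexicographically smallest
  label). NJ is a deterministic distance-based stand-in for a full ML
  search; the topology *score*, not the search engine, is the quantity of
  interest, and the inference backend is swappable.
* **Topology score**: both trees are ladderized by a fixed convention
  (larger clade first; ties by smallest descendant leaf label) so the
  drawing is unique. Per leaf: +1 for matching branch form — straight when
  the leaf row is within half a row of its parent's row, otherwise L-shape
  (below) or inverted-L (above) — and +1 for matching relative location
  (the leaf immediately above; the top leaf matches only the top).

## Experimental layer

The L16(4^5) array is constructed from two GF(4) digits (columns a, b, a+b,
a+2b, a+3b), which guarantees single-column and pairwise balance; both are
verified exhaustively in tests. The factor tables of the two models assign
its levels; the row numbering (tests 1–16) is internal to this package.
Per-run seeds are derived as
`crc32(master_seed, test_id, replicate)`, recorded in every output row, so
any table is a pure function of its master seed. Per-run failures are
recorded in an `error` column rather than aborting a screen.

Statistics follow the conventional desktop workflow: pooled-variance
independent t tests (Welch available behind a flag), all-main-effects fixed ANOVA
(residual df `16r − 16` at r replicates), Duncan's multiple range test with
least significant ranges from the studentized range distribution at
protection level `(1−α)^(p−1)` (harmonic-mean n under imbalance), and
significance stars at 0.1 / 0.05 / 0.01.

## Numerical choices and degenerate inputs

* Budget rounding is round-half-up on `M_1 · b`.
* Integer draws from parameter ranges are uniform inclusive.
* Mutation events on very short sequences are capped by the number of
  mutable internal positions; a branch that can make no progress raises
  rather than looping.
* Zero-variance t-test inputs with equal means return t = 0, p = 1; a
  constant ANOVA response returns F = 0 for every factor; Duncan never
  splits identical groups.
* A single-column alignment returns SE 0 with a warning; an all-identical
  set yields `D̄ = 0`, SE 0, and an undefined (NaN) pooled ratio.

## Problem sizes used by the test suite

The default screen in the field workflow is 16 tests × 10 replicates per
model. The shipped test suite exercises the same code paths at reduced
sizes chosen for quick iteration — e.g. a 2-replicate screen (32 rows), a
6-leaf tree for orchestration determinism checks, 200-replicate bootstraps
in some property tests — while the acceptance script and the headline tests
run the full 14-leaf configuration.

## Known limitations

* Attribute values on the synthetic fixture are not comparable to values
  measured on real intron sets: they depend on the reference tree's branch
  lengths, on the real sequences, and on the internals of whichever
  alignment/ML software measured them.
* The builtin aligner is a plain linear-gap progressive aligner; it is not
  MUSCLE and makes no claim of matching its output column-for-column.
* NJ replaces ML tree search; topologies of highly saturated sets depend on
  the imputation rule for undefined distances.
* Mixed regimes (gain and loss in one run) are out of scope by design: each
  run is purely MD or purely MI, mirroring the hypothesis test the
  methodology implements.
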