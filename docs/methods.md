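# Methods

## The Kappa index of coincidence on a single sequence

The classical Kappa test compares two equal-length texts and counts
positionwise coincidences. `promkic` applies it to one DNA sequence by
comparing the sequence with each of its own shifted suffixes. For a
sequence *A* of length *L* and shift *u* ∈ {1, …, L−1}, let *B* be the
suffix of *A* starting at offset *u*, running to the end of *A* (so
|B| = L−u), and count positions *i* with A[i] = B[i]. The per-shift
coincidence percentage is 100·matches/(L−u); the statistic is the mean
over all L−1 shifts, rounded to two decimals. Only the final value is
rounded; per-shift percentages are kept at full precision.

Boundary convention: the suffix at shift *u* runs through the *end* of
the sequence. This is the only convention under which every shift
compares equal-length sequences, the loop is well defined for all *u*
(no empty suffix), and a homopolymer scores exactly 100.

Properties (all property-tested): values lie in [0,100]; the statistic
is invariant under alphabet relabeling and under reversal; i.i.d.
equiprobable DNA has expectation 25 (match probability 1/4 at every
shift); inserting homopolymer tracts raises it. An independent
brute-force oracle that enumerates every (i, i+u) pair verifies the
implementation exhaustively for all sequences up to length 8 and on
10,000 random sequences up to length 200.

**Ambiguous bases.** N never counts as a coincidence (not even against
another N) and enters neither the C+G nor the A+T tallies, but still
occupies window positions, keeping the per-shift denominators stable.
Sequences with >10% N are flagged (`PromoterSequence.high_n`).
Composition of an all-N sequence is an error.

## C+G coordinates

`CG_TOT = 100·(C+G)/(A+T+C+G)` over the whole segment (N excluded
from both tallies). The window value is, in the default *relative*
mode, `CG_SW = CG_TOT · (C+G)_SW / (A+T+C+G)_SW`, which never exceeds
`CG_TOT`; the *absolute* mode is the plain window percentage. Relative
mode is the default because the pattern archetypes are defined on it:
it encodes the segment-level composition into the x-axis scale, so
AT-rich and CG-rich promoters occupy visibly different x-ranges.

## Patterns and rasters

A profile is one (CG_SW, Kappa IC) point per window, in 5′→3′ order;
window count is ⌊(L−w)/step⌋+1 with w = 30, step = 1 by default.
Coordinates are 0-based half-open internally; TSS-relative coordinates
appear only at I/O boundaries (a −499..+100 segment has its TSS at
offset 500).

The pattern is the point cloud plus its center of weight (arithmetic
mean point). Rasterization maps each point onto a fixed
[0,100]×[0,100] frame — shared by all patterns so they are
pixel-comparable — at 348×268 = 93,264 pixels by default, the input
size of the classifier retina. Pixel mapping:
`col = floor(x/100·(width−1))`, `row = floor((1−y/100)·(height−1))`
(y inverted so high Kappa IC is at the top). Count mode increments a
pixel per point; binarized mode sets it to 1.

`pattern_distance` is the normalized L1 distance between binarized
rasters (count rasters are binarized first): bounded in [0,1],
symmetric, 0 iff the set-pixel sets coincide. It quantifies *shape*
difference, deliberately ignoring point multiplicity.

## The classifier

A one-vs-rest linear perceptron with ten output units over the
93,264-pixel retina.

**Input encoding.** The count raster is smoothed with an isotropic
Gaussian (σ = 5 px by default) and L2-normalized. The smoothing gives
every pattern point a finite receptive footprint — two same-class
promoters occupy the same *regions* of pattern space but almost never
the same exact pixels, so raw single-pixel rasters do not generalize;
the normalization makes scoring exactly invariant to any positive
scaling of the raster intensities.

**Training.** Classic multiclass perceptron updates from zero weights:
on a misclassification, the true class's weight vector gains the input
(learning rate 0.1) and the wrongly winning class's loses it; biases
move by ±lr. Inputs are centered on the training-set mean during
updates; the mean is folded into the stored bias afterwards
((x−μ)·W + b ≡ x·W + (b−μ·W)), so a stored model is a plain affine
scorer and an all-zero raster scores exactly the bias vector. Training
is epoch-capped (1,000) with early stop at zero errors; the seed
drives only the per-epoch shuffle, so training is fully deterministic.
The per-epoch training accuracy is logged on the model.

The model keeps two weight sets: the **final iterate**, which on a
linearly separable training set attains 100% training accuracy
(perceptron convergence) and therefore memorizes training exemplars
exactly, and the **averaged perceptron** (running average over all
update steps, computed with the standard lazy accumulator), which is
the default for scoring because the average of the mistake-driven
trajectory generalizes measurably better to held-out promoters.

**Scores.** "Match score" is the raw activation; "match percentage"
min-max normalizes the ten scores to [0,100] per pattern (the best
class is always 100; if all scores tie, all are 100). Exact argmax
ties break alphabetically for determinism. A pattern is
**transitional** when best − runner-up match percentage < 5 points
(strict inequality; threshold configurable). Convex 50/50 mixtures of
rasters from two classes are flagged transitional several times more
often than pure exemplars.

## Synthetic promoter generator

Each of the ten classes has a generative recipe over 600 nt segments
(TSS at offset 500). A background is drawn i.i.d. from a composition
with a target A+T fraction (or, for ATCG-less, from alternating
composition blocks), then structural elements are placed uniformly at
random without overlap (rejection sampling; an impossible budget
raises an error): scattered short homopolymer tracts, a central tandem
block of mixed short tracts, ≥30 nt spike tracts near the TSS, and
composition-depletion blocks written as tandem tracts of the retained
base pair. Tandem-block tract bases are laid down as a shuffled
balanced multiset so the block's composition stays at its target.

Defaults (the package's concrete instantiation of the qualitative
class architectures; "short" tracts are 3–8 nt unless noted, "long"
30–60 nt, placed within ±200 nt of the TSS):

| class         | background A+T | scattered short tracts | other elements |
|---------------|----------------|------------------------|----------------|
| AT_based      | 0.65           | 20 × poly(dA/dT)       | — |
| CG_based      | 0.35           | 20 × poly(dC/dG)       | — |
| ATCG_compact  | 0.50           | —                      | tandem block of 6 mixed tracts |
| ATCG_balanced | 0.50           | 12 AT + 12 CG, 5–12 nt | — |
| ATCG_middle   | 0.50           | 2 AT + 2 CG            | tandem block of 28 mixed tracts, 8–16 nt |
| ATCG_less     | blocks 0.65/0.35 (60 nt) | —            | — |
| AT_less       | 0.45           | 16 CG + 4 AT           | one CG-depleted 30–60 nt block near TSS |
| CG_less       | 0.55           | 16 AT + 4 CG           | one AT-depleted 30–60 nt block near TSS |
| AT_spike      | 0.55           | 6 AT                   | one ≥30 nt poly(dA) or poly(dT) run near TSS |
| CG_spike      | 0.45           | 6 CG                   | one ≥30 nt poly(dC) or poly(dG) run near TSS |

Every generated sequence passes an independent structural audit
(run-length scan for spike tracts, windowed composition scan for
depletion blocks, overall A+T within 5 points of the recipe's analytic
expectation) that shares no bookkeeping with the generator.

Balanced labeled sets derive per-sequence seeds from a master seed
(`make_fixture_set`); the canonical training scale is 20 per class =
200 patterns, with an equally sized held-out set.

**Mutation model.** Uniform per-site substitution at a given rate;
replacements always differ from the original base, so rate 1 changes
every site and the expected Hamming distance is rate·L. Indel-driven
class transitions are outside the mutator; intermediates are instead
exercised with interpolated rasters.

**What the generator does not emulate.** Real promoters have
positional structure (core-promoter elements, CpG islands with
characteristic spatial extent, nucleosome-driven periodicities),
dinucleotide/trinucleotide repeat families beyond homopolymers, and
class-internal substructure. Passing tests therefore demonstrate that
the pipeline recovers architectures of the kinds described, not that
real promoter collections would sort with the same accuracy.

## Aggregation analyses

- **Density maps** bin centers of weight on [0,100]² (default bin 1
  point, half-open bins, boundary values to the higher bin, 100.0 into
  the top bin). Totals are conserved.
- **Overlap** of two maps is Σ min of the normalized histograms —
  bounded, symmetric, 1 iff identical, and equal to 1 − total-variation
  distance (verified against an independent TV computation). It is the
  package's quantitative reading of "shared surface" between
  superposed distributions.
- **Proportion tables** row-normalize class counts per group to
  percentages; the transposed view gives each class's distribution
  over groups.
- **Expected vs observed** compares a subset's class shares with
  reference shares; ratio observed/expected, with absent classes
  flagged (ratio 0). Under i.i.d. subsampling ratios concentrate at 1.
- **Pairwise relations** correlate two class columns across groups
  (Pearson); tags: complementary (r ≤ −0.5), proportional (r ≥ 0.5),
  none; zero-variance columns are reported as undefined rather than
  tagged. Thresholds are declared conventions.
- **TATA scan** matches an IUPAC consensus (default TATAWAW) on the
  forward strand within an inclusive TSS-relative region (default
  −40..−19, the canonical TATA-box placement); a hit must lie entirely
  inside the region. A promoter is TATA-containing iff it has ≥1 hit.
  Real-data TATA fractions depend strongly on the motif and window
  chosen, so these defaults are configurable.

## Numerical and design choices

- Rounding: only the final Kappa IC value is rounded (2 decimals),
  matching the statistic's definition; CG values are unrounded.
- Profile computation shares shift comparisons across overlapping
  windows (cumulative-sum sliding counts), and is tested to agree
  exactly with the single-window path.
- Raster resolution 348×268 interprets the classifier's 93,264-unit
  retina; axis bounds are fixed, never data-dependent.
- Transitional threshold 5 points, correlation thresholds ±0.5, N
  flag at 10%: declared conventions, configurable at call sites.
- Strand: sequences are used as given; no reverse-complement
  normalization.
- Problem sizes in the test suite and acceptance script (200-pattern
  training, 200 held out, 100 interpolations, 50 mutants, 100,000
  null windows) are the package's canonical desk-scale experiment
  sizes.

## Known limitations

- The ten class labels are defined *by construction* through the
  synthetic recipes; no claim is made that they coincide with any
  manual labeling of real promoter databases.
- The perceptron is linear; classes made separable only by nonlinear
  pixel interactions would need a richer scorer.
- Relative CG compresses the x-axis for AT-rich segments, which is
  intentional (it is what makes the archetypes comparable) but means
  absolute composition differences inside one segment are attenuated.
- The TATA defaults will not reproduce any particular published
  TATA-containing fraction on real data; they are a scanning
  convention.
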