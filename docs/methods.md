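# Methods

## Data model and labeling

Every activity record is keyed by the experimental-condition triple
(*bt*, *me*, *at*).  Measure kinds are a closed vocabulary {IC50, Ki, Kd}
and assay types {B, F}; unknown tokens are rejected at load time rather
than silently grouped.  Labels come from per-measure potency cutoffs in nM
(defaults IC50: 100, Ki: 300, Kd: 300, all configurable): active ⇔ value ≤
cutoff.  Censored values are used only when conclusive — "<v" at or below
the cutoff is active, ">v" at or above it is inactive; the contradictory
cases ("<v" above the cutoff, ">v" below it) are excluded and reported,
never guessed.  Duplicate (compound, condition) records with the same label
collapse to the first occurrence; duplicates with *conflicting* labels are
removed entirely and reported, because majority-voting contradictory
measurements would fabricate data.

Splitting is two-stage and seeded: the external-validation set is drawn
first (default 30% of all rows), then the test set from the remainder
(default 20%), leaving the sub-training set.  Set sizes use
nearest-integer rounding, ties up; at N = 1892 / 0.30 / 0.20 this yields
1059 / 265 / 568.  The split RNG is a documented NumPy generator, so
identical seeds give identical partitions of *this* implementation;
member-for-member agreement with other tools' seeded splits is not a goal.

## Box–Jenkins moving-average descriptors

Averages avg(Dᵢ)ₑ are arithmetic means over training-set actives (the
sub-training and test rows together; the external set contributes to
neither the averages nor the model), keyed per single ontology element
rather than per full triple — each raw column yields exactly three
modified columns.  The transform is a pure function: the fitted average
table is applied unchanged to test, external and screening rows.  An
element value with no training actives has no average; transforming such a
row is a hard error by default, with an optional global-active-mean
fallback for screening libraries that probe rare conditions.  Two
consequences are used as invariants in the tests: per element value, the
active Δ-means are exactly zero; and additive condition offsets on raw
descriptors are fully absorbed.

## The linear discriminant

Fisher's two-class direction w ∝ S_w⁻¹(μ₊ − μ₋) with pooled within-class
covariance.  The default intercept puts the boundary at the pooled class-
mean midpoint (equal priors); a class-frequency variant adds ln(n₊/n₋).
Classification is the sign of the affine score, with score = 0 mapped to
−1.  Goodness of fit uses the Wilks λ of the one-dimensional discriminant
scores (within-group over total sum of squares — equivalent to the
determinant form for two groups), F = ((1−λ)/λ)(N−p−1)/p, and the
F(p, N−p−1) upper tail.  Standardized coefficients are
|wᵢ · SDᵢ(training)|, reported sorted descending for importance plots.
Singular pooled covariances raise an error naming the collinear columns
(rank-revealing QR).  Sample statistics use ddof = 1 throughout (variance
cutoff, standardized coefficients, AD statistics).

Pretreatment removes columns with sample variance < 0.001, then scans the
survivors left to right and drops any later column with |r| > 0.95 against
an already-retained one (first-retained-wins, the common QSAR convention).

## Feature selection

*Stepwise*: enter the candidate minimizing the model Wilks λ when its
partial-F p-value (F = (N−2−k)(1−Λp)/Λp on (1, N−2−k) df, Λp the ratio of
full to reduced λ) is below p-to-enter (0.05); after each entry remove,
worst first, any included feature whose F-to-remove p-value exceeds
p-to-remove (0.05); stop at 10 features or no qualifying candidate.  A
visited-state set guards against enter/remove cycles.

*SFS*: greedy forward, scoring a refit model by training accuracy or
AUROC; stops on no strict improvement; ties break to the lower column
index.

*GA*: a genome is a variable-length list of column indices (one gene per
equation term), initial sizes uniform on {2..10}, fitness the multivariate
Wilks λ of the subset.  Each generation keeps the 30 fittest of 100,
refills by uniform crossover of random survivor pairs, and mutates each
gene with probability 0.3 by swapping in a random unused column; the best
subset over 20 independent runs wins, fully reproducible from one seed.  A
per-*column* bit-flip at 0.3 would randomize ~a third of a 150-column mask
every generation and could not respect the 10-descriptor cap, so the
gene-slot representation is used.  The generation budget (not externally
prescribed) defaults to 100.

## PS3M refinement

Candidate pools rank all pretreated modified columns by Euclidean distance
to each model descriptor over the modeling rows, computed on the stored
column values (a standardize-first switch exists because ED is
scale-sensitive; off by default).  Candidates with ED ≤ 1e−8 (effective
duplicates) and columns already in the model are excluded; the top m = 10
per descriptor give at most m·p alternatives per round.  Each alternative
is refit on the sub-training rows; it is eligible only if its sub-training
MCC has not dropped below the current reference's, and the eligible
alternative with the best mean of sub-training and test MCC is accepted
only on strict improvement.  Ties break by smaller ED, then lexicographic
name, making the search order irrelevant.  The trace therefore has
strictly increasing mean MCC and non-decreasing sub-training MCC;
termination is bounded by max_rounds (default 50).  The test set acts as a
calibration set; external rows are never visible.  Model size is
preserved — substitutions only.

## Validation battery

Sn, Sp, Acc, F1 are percentages from the standard definitions; MCC uses
the 0-on-zero-denominator convention.  Accrnd divides the full sum
(TP+FN)(TP+FP) + (TN+FN)(TN+FP) by N² — the form that reproduces every
published value it is checked against.  AUROC is the rank-based
Mann–Whitney statistic with ties counted ½ (scikit-learn), with ROC points
from a unique-score threshold sweep.

Yc-randomization permutes the (label, bt, me, at) tuples jointly across
rows (independent permutations available), recomputes the average table
and modified block, refits the same feature set on the sub-training rows,
and averages Wilks λ and sub-training accuracy over runs (default 100).
The randomized refits use class-frequency priors: with the signal
destroyed, such a discriminant degenerates to predicting the majority
class, which is the correct no-information accuracy baseline — an
equal-priors boundary would drift toward a 50/50 split and understate the
baseline.

The applicability domain is the standardization approach: zᵢ =
|xᵢ − meanᵢ|/SDᵢ over the model descriptors with training statistics; all
zᵢ ≤ 3 → inside, min zᵢ > 3 → outlier, otherwise inside iff mean(z) +
1.28·SD(z) ≤ 3 (sample SD).  Threshold and multiplier are configurable.

## Screening and similarity search

Screening expands a library across every covered condition (n·k rows),
recenters with the model's averages, scores, classifies (+1 ⇔ score > 0;
no margin thresholding) and AD-flags each row.  Pan-hits need ≥ 4 active
conditions of 7 and, by default, no outlier condition; the AD filter is
applied jointly with the activity count.  Isoform-selective hits need ≥
min_active on-target active conditions and zero off-target ones.

Similarity search encodes structures as circular fingerprints of diameter
4 (Morgan radius 2) folded to 2048 bits (configurable; the bit length is
not externally prescribed).  A match requires Tanimoto *strictly* greater
than the 0.3 cutoff.  Per-query mean activities floor left-censored
("<x") values at 100 nM; ">"-censored records are excluded from means with
a warning (their contribution is undefined).  Queries rank by match count
descending.

## Synthetic fixtures

The generator emulates exactly the structure the transform and the
discriminant assume: class-conditional Gaussian descriptors, a
standardized mean separation of `effect_size` (default 2.0) on the
informative columns, per-(condition, column) N(0, condition_shift) offsets
(default SD 1.0) that the recentering must absorb, and pure-noise columns
elsewhere.  Defaults: 600 compounds, the seven (me, at, bt) combinations
of the reference two-isoform dataset, 3 informative + 50 noise columns,
35% actives (the approximate active fraction of that dataset).  Activity
values in nM are drawn on the correct side of the default cutoffs so the
labeling stage reproduces the planted classes.  What the fixture does
*not* model: correlated descriptor blocks, heavy-tailed or discrete
descriptors, activity cliffs, and any structure–descriptor consistency
(the bundled SMILES are only parseable structures for fingerprint tests) —
so green tests demonstrate correctness of the machinery, not real-data
performance.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 600 compounds, Yc at 5–20 runs,
the GA at reduced budgets (population 40, 10–12 generations, 2 runs), and
the screening-expansion check at the full 6538 × 7 = 45,766 rows; these
sizes were chosen so the whole suite completes in well under a minute
while every behavioral property remains sharply testable.  Degenerate
inputs are errors, not silent defaults: empty split partitions, all
columns pretreated away, single-class fits, zero-variance scores, missing
AD statistics.  Determinism: all randomness flows through seeded NumPy
generators (GA runs use spawned `SeedSequence` children), and refitting
with identical inputs is byte-identical.

## Known limitations

No descriptor computation (matrices come from an external engine), no
structure standardization beyond SMILES parse validation, no multi-class
discriminant, no probability calibration, no bootstrap confidence
intervals, and the non-linear learner comparison is out of scope (the
pipeline exposes the pretreated blocks, so plugging in external
classifiers is straightforward).  The packaged reference equation carries
coefficients only — it scores pre-modified rows but cannot recenter raw
descriptors, because its average table was never published.
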