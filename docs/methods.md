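# Methods

## The problem

Supervised frame-by-frame behavior classifiers (JAABA-style) return a
real-valued confidence score for every video frame of every animal.
Benchmarking such a classifier against human annotation is complicated by
the fact that the "ground truth" is itself graded and variable: two
trained observers disagree on a substantial fraction of bouts of even
"stereotypical" *Drosophila* social behaviors (wing extension, lunge,
headbutt), and each observer attaches a 1–3 confidence grade to every
bout.  `ethobench` implements the complete evaluation pipeline for this
setting: combined-annotation construction, classifier bout
post-processing, bout/frame matching, confidence-stratified
precision/recall, and a permutation null for the association between
human confidence and classifier confidence.

## Combined human annotation

Frames are 1-based and intervals inclusive; a bout's length is
`end − start + 1` frames, one frame being `1000/fps` ms (16.7 ms at the
60 fps used throughout, displayed as 17 ms).

Two observers' bouts for the same (movie, fly, behavior) are merged by
the union operation whenever they share at least one frame.  The combined
score of a matched pair is the sum of the two 1–3 confidences (a 1–6
scale); a region annotated by one observer keeps that observer's
confidence (1–3).  When one observer splits a region that the other
annotated as one bout, each cross-observer overlapping pair yields its
own *score record*, and the maximum record is the region's
*representative score*.  Chains of overlaps (A₁–B₁–A₂) are collapsed into
a single region by connected components of the overlap graph; the
score-record rule above (one record per cross-observer overlapping pair)
is the natural generalization, is symmetric in the observers, and reduces
exactly to the split-bout rule when only one observer splits.  This
chained case is a genuine design choice: nothing forces a particular
grid-counting for it, and it is rare in practice.

Score-distribution summaries (the 4×4 observer-confidence grid, the
fraction of scores 4–6, the one-observer fraction) count score records,
not merged regions, so a split region contributes one count per record.
The raw region count is reported alongside so either denominator can be
recovered.

Frame-based combined annotation assigns every frame the sum of the
confidences of the (at most one per observer) bouts covering it, 0–6.

## Classifier bout smoothing

A frame is "on" when its score is **strictly** greater than the detection
threshold (so exact-boundary scores are reproducibly "off").  Maximal
"off" runs no longer than `max_gap` frames flanked by "on" frames on both
sides are filled — gap filling precedes the length filter, edge gaps are
never filled, and an over-long gap is never filled partially.  Maximal
"on" runs of at least `min_bout_len` frames become classifier bouts.  The
per-bout average score is the mean of the *original* scores over the bout,
filled frames included.  `max_gap` is always an explicit parameter: the
smoothing procedure itself places no bound on fillable gaps, the bound is
part of the parameter search space.

`min_bout_len` is derived from the human annotations as the largest L
such that at least a `keep_fraction` (default 0.98) of human bouts have
duration ≥ L, i.e. the filter eliminates only bouts shorter than at least
98% of the manually annotated bouts.  The grid search over
(threshold, max_gap, min_bout_len) ranks parameter combinations by
recall × precision, descending, with deterministic ties broken by
ascending parameter values; undefined objectives (no positive bouts at
all) rank last.  The headline detection threshold is 0.1.

## Matching and metrics

Bout matching is human-bout-referenced.  A human bout overlapped (≥ 1
frame) by any classifier bout is one true positive regardless of how many
classifier bouts touch it; its average classifier score is the mean frame
score over the union of all matched classifier-bout frames.  A classifier
bout that overlaps k human bouts yields k true positives, each carrying
that bout's single average score; a classifier bout may therefore
contribute to several TPs, and each human bout is processed independently
against the classifier bouts it overlaps.  A human bout with no overlap is
a false negative; a *virtual* classifier bout spanning the full human
extent supplies its average score (the source description of this virtual
bout's length is ambiguous — there is no classifier bout to intersect —
so the full human extent is used).  A classifier bout with no overlap is a
false positive with human score 0.  TP/FN records carry the region's
representative score.

Precision is TP/(TP+FP) and recall TP/(TP+FN).  An undefined ratio is
propagated as a distinguished `None`, never silently 0 or 1.
Confidence-stratified recall bins TP/FN records by representative score;
empty bins are omitted, not zero-filled.  False-positive rates per pair
type are reported as FP bouts per minute of evaluated video (minutes
summed per movie, not per fly track) — the normalization is not dictated
by the matching conventions, so raw counts and minutes are emitted too.

Frame matching uses raw thresholded scores (strict >, consistent with
bout detection), not smoothed bouts; a frame is TP when above threshold
and covered by a combined score ≥ 1.

## Permutation null and statistics

The null hypothesis is that combined human scores carry no information
about average classifier scores.  Each of `n_reps` (default 50) shuffled
replicates permutes the observed 1–6 scores uniformly across the TP∪FN
bouts — the multiset of scores, hence the proportion of every score
category, is preserved exactly, not just in expectation — while false
positives stay at 0 and all classifier-score fields are untouched.
Replicate r uses a generator seeded `base_seed + r`, so the whole series
is reproducible bit for bit.

The observed Kruskal–Wallis statistic (tie-corrected; the all-tied
degenerate case is reported as H = 0, p = 1) is compared with the 50
shuffled statistics, and per-score "recall" rates are recomputed inside
every replicate and summarized by a t-based 95% confidence interval:
m ± t₀.₀₂₅(n−1)·s/√n with s the sample standard deviation (so s/√n is the
standard error; treating s itself as the standard error would divide by
√n twice).  n is taken from the supplied replicate count.  Pairwise
two-sided Mann–Whitney U tests between neighboring score groups use the
exact distribution when the combined sample is ≤ 12 without ties and the
tie-corrected normal approximation otherwise, with a Bonferroni divisor
equal to the number of pairs actually tested (critical value 0.01).
Violin summaries use a Gaussian KDE with Scott's bandwidth rule (the
original plotting tool's default is unspecified); widths scale by group
count relative to the largest group.

Note that the t interval is a confidence interval for the *mean* shuffled
recall — roughly √n_reps narrower than the spread of a single null draw —
so a single observed replicate can fall outside it even under the null.
Calibration checks therefore average the observed recall over independent
seeds before comparing it with the (equally averaged) interval.

## The generative model

The synthetic generator produces the statistical structure the pipeline
assumes so every stage is testable without video:

* **Movies**: fly pairs at 60 fps in male–male, male–female and
  female–female combinations (default two 5-minute movies per type, two
  flies each).
* **Ground truth**: per behavior, bouts arrive at a pair-type-specific
  rate (lunges 3/min in male–male pairs only; headbutts 3/min
  predominantly in female–female pairs; wing extensions 4/min mostly in
  male–female pairs) with log-normal durations — median 5 frames (83 ms)
  for lunges, 4 frames (67 ms) for headbutts, and a heavy-tailed
  median-30-frame distribution (σ = 1.1) for wing extensions.  Bouts are
  placed uniformly without overlap, two empty frames apart at minimum.
* **Salience**: each truth bout carries a latent S ~ Uniform(0,1) (a Beta
  alternative is available) that drives *both* observers and the
  classifier — encoding the interpretation that variability in the
  behavior itself, not annotation noise, is what both respond to.
* **Observers**: each of two observers independently detects a bout with
  probability logistic(a₀ + a₁S), a₀ = 0.3, a₁ = 3.0 — calibrated by
  numerical integration so that ~27% of combined bouts are annotated by a
  single observer, inside the 25–35% range reported for trained
  annotators.  Confidence 1–3 thresholds S plus per-observer Gaussian
  noise (sd 0.15) at 1/3 and 2/3, with optional per-observer threshold
  offsets (the relative use of confidence levels is discretionary to each
  observer).  Bout boundaries are jittered (sd 1 frame) but clipped so an
  annotation always overlaps its truth bout and never its neighbors.
* **Score tracks**: on-bout level b₀ + b₁S with AR(1) noise (φ = 0.8,
  sd 0.05), off-bout AR(1) baseline near 0.02, plus Poisson-placed
  half-sine distractor bumps (0.4/min, amplitude 0.35) that create
  controllable false-positive pressure.  The defaults b₀ = 0.02,
  b₁ = 0.35 put low-salience bouts at the 0.1 detection threshold, which
  reproduces the characteristic confidence-stratified recall of the
  benchmarked classifiers: recall ≈ 0.4 for combined score 1 rising to
  ≈ 0.97 at score 6.  b₁ = 0 severs the coupling and produces null data
  (for null-condition checks the constant on-bout level is raised to the
  coupled model's mean, b₀ = 0.25, so recall stays high but uniform).

Four RNG streams (truth, observer A, observer B, scores) are spawned from
the single seed, so changing one component's parameters leaves the other
draws identical, and every dataset is byte-reproducible.

### What the generator does *not* emulate

* Salience is independent of bout duration, whereas in the study longer
  wing extensions tended to receive higher scores.  Consequently the
  generator does not reproduce the study's finding that frame-level
  agreement exceeds bout-level agreement; its frame-level one-observer
  fraction is *higher* than the bout-level one.
* Union merging widens combined bouts by roughly one frame per side
  relative to the truth durations, so combined medians read ~1 frame
  above the configured medians (e.g. 100 ms instead of 83 ms for lunges).
* No fly trajectories, tracker features or video are simulated; feature
  tables for z-score profiling tests are simple Gaussians shifted on
  annotated frames.

Passing tests on synthetic data therefore demonstrate the correctness and
calibration of the *pipeline*, not properties of any particular real
classifier or annotator pool.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at modest sizes chosen
to keep per-score bins populated while staying fast: the full study
default is six 5-minute movies (≈ 160 annotated bouts across the three
behaviors); calibration checks use a single 8-minute two-fly movie of
lunges (≈ 50 combined bouts) repeated over 40–200 seeds.  Exact-boundary
behavior everywhere uses strict `>` against the threshold.  CSV floats
are written with the shortest round-trippable representation and read
with round-trip precision, so read∘write is the identity field for field.

## Known limitations

* Exactly two observers are supported, as in the study design; more
  raise an unsupported-input error.
* The false-positive-rate normalization (per movie-minute) is one
  reasonable choice among several; raw counts are always emitted.
* The Mann–Whitney exact path is limited to small untied samples;
  elsewhere the normal approximation with tie correction is used.
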