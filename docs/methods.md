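# Methods

## Survey generation (truth lists)

A simulated survey is a timeline of `duration_s` = 180 s divided into
`interval_s` = 3 s recording intervals (60 intervals). Each of the ten
roster species contributes a `clip_s` = 4 s vocalization clip a random
number of times, drawn independently per species from the discrete uniform
on [`count_low`, `count_high`] = [1, 4]. The clip multiset is shuffled
uniformly, the remaining white-noise time (180 − 4·n seconds) is divided
over the n+1 gaps by uniform stick-breaking (equivalently Dirichlet(1,…,1)),
and onsets are laid down cumulatively. Consequences: clips never overlap,
may be exactly consecutive, and any clip arrangement of a given multiset is
equally likely. A clip's *truth interval* is the interval containing its
onset; the 4-s clip may spill into the next interval, which the ±1-interval
scoring window absorbs.

The uniform-count rule implies 25 clips per survey in expectation (range
10–40). The reference experiment reports an empirical mean of 18.4 (range
12–25) under the nominally identical rule; the two are incompatible and
cannot both be emulated. The generator follows the stated rule and exposes
`count_low`/`count_high` so other count regimes can be configured; the
empirical mean is deliberately **not** a calibration target.

Worst-case feasibility (`n_species · count_high · clip_s ≤ duration_s`) is
validated at configuration time, so generation cannot fail mid-batch. The
per-species count bounds are an invariant of *generated* schedules;
handcrafted schedules (used heavily in tests) are validated only for
timeline consistency, because fixed clip layouts are legitimate inputs to
the scorer regardless of what distribution could have produced them.

Randomness: one root seed; survey *i* uses the sub-stream
`SeedSequence(seed, spawn_key=(i,))`, so batches are reproducible and
prefix-stable (generating 3 surveys yields the same first 3 as generating
5). Campaigns key sub-streams by (scenario, survey, stage).

## Observer model

The original experiment used human volunteers; this package replaces them
with the minimal stochastic model that produces every error category the
scoring rule classifies:

* `p_detect[s]` — probability of detecting a played clip of species *s*
  (misses become false negatives);
* `confusion[s, r]` — row-stochastic probability of reporting *r* given a
  detected clip of *s* (off-diagonals become false positives for *r* and
  false negatives for *s*);
* `jitter` — probability mass on interval offsets {−1, 0, +1} for the
  reported interval, clamped at the grid edges (timers do not wrap);
* `spurious_rate` — per-interval probability of a clip-less detection,
  default 0 (the false-positive definition used here covers only
  misidentified or mistimed real clips).

ISO: each clip is an independent Bernoulli/categorical draw. DDO (removal
design, at most one record per clip): the primary observer's draw comes
first; if the primary detects, one primary-role record is emitted, and a
misidentification is replaced by the correct species with probability κ
(`DDOConfig.collaboration`) when the secondary observer independently
detected *and* correctly identified the clip — attribution stays with the
primary, matching the field protocol in which collaboration may fix the
identity but not the detection credit. If the primary misses and the
secondary detects, a secondary-role record is emitted from the secondary's
confusion row. The model gives the secondary no correction channel of its
own, and exactly one identification is attributed per clip. Within a DDO
scenario the two profiles swap primary/secondary roles on alternating
surveys.

Closed-form per-clip outcome probabilities (used as the enumeration oracle
in tests; equal profiles, detection p, diagonal c): a detection is
misidentified with probability (1−c) under ISO, and under DDO the expected
misidentified fraction among detections is (1−c)(2 − p − p·c·κ)/(2 − p) ≤
(1−c), strictly for κ > 0 — the mechanism by which the removal design
lowers false-positive rates.

### Default calibrated profiles

The reference experiment quantifies no observer parameters, so the defaults
were solved once from the closed forms above to place the four simulated
arms near the reference scenario rates, and then frozen:

| profile | p_detect | confusion diagonal | κ | implied ISO / DDO misID fraction |
|---|---|---|---|---|
| expert | 0.95 | 0.905 | 0.80 | 0.095 / 0.033 |
| naive  | 0.90 | 0.51  | 0.49 | 0.490 / 0.390 |

Jitter is {−1: 0.08, 0: 0.84, +1: 0.08} for both. Off-diagonal confusion
mass is spread over the other nine species with heavier weights on the
similar-sounding pairs (longspur→lark 8×, lark→longspur 2.5×,
curlew→killdeer 6×, killdeer→curlew 2×, the two sparrows 3× each way),
reproducing the asymmetric confusion structure seen in field data.

Scored rates from dense default schedules run slightly below the implied
misidentification fractions (e.g. expert ISO ≈ 0.09 rather than 0.095)
because a misidentified report is occasionally rescued by an unrelated
unmatched clip of the reported species that happens to fall inside the
window — a real property of window-based scoring, not an artifact. The
defaults are not adjusted for it.

## Scoring

For each clip the *allowable window* is its truth interval plus one 3-s
interval on either side (9 s total). A detection is **correct** iff it is
assigned one-to-one to an unmatched clip of its reported species whose
truth interval is within ±1 of the reported interval. Assignment processes
detections in time order and gives each the *earliest* unmatched candidate
clip. Because a clip at interval i is eligible exactly for detections at
i−1…i+1, candidate sets are intervals and this earliest-deadline-first
greedy attains the maximum achievable number of correct matches (standard
exchange argument; verified exhaustively against a maximum-bipartite-
matching oracle on small instances). A same-interval-first preference is
*not* optimal — clips at intervals {1,2} with detections at {2,3} yield one
match instead of two — and is not used.

Every unassigned detection is a false positive with a cause:
`misidentification` if some unmatched clip of a different species lies in
its window, else `out_of_window`. Misidentification attribution picks the
nearest such clip (smaller |offset|, then earlier clip), preferring clips
not already blamed, so confusion counts approximate one-per-source-clip.
Unmatched clips split into misidentification sources and pure
nondetections; per species, false negatives = all its unmatched clips, and
the accounting identity observed − truth = FP − FN holds exactly by
construction (asserted on every scoring call). Scoring ignores observer
roles: DDO surveys are scored on the union record set.

Attribution is a reconstruction: with dense schedules two unmatched clips
can share a window and a false positive can be blamed on the wrong one.
The parameter-recovery analysis therefore uses a sparse design (one clip
per species per survey) where attribution is identifiable; recovered
misidentification fractions then sit within Monte-Carlo error of the
generating matrix.

## Statistics

* **Rates.** r = FP/detections; SE = √(r(1−r)/n). This binomial SE
  reproduces all five printed scenario "SD" values of the reference table
  at 3 d.p., which is how that column is interpreted here.
* **Saturated logistic regression.** Two binary factors, four cells — the
  MLE is closed-form in the cell odds: intercept odds a/(N−a) of the
  reference cell (expert DDO), main-effect odds ratios vs the reference,
  interaction = ratio of odds ratios. Each term's SE is exp(√Σ 1/k) over
  its 2/4/8 constituent counts (delta-method Wald SE of the log estimate,
  exponentiated; reproduces the printed SE column). Closed form vs an
  iteratively fitted binomial GLM agrees to ≤1e−6 relative (property-tested
  over random tables). A zero cell makes the fit undefined; the function
  refuses rather than silently applying a continuity correction.
* **Confidence intervals.** Wald on the log-odds scale by default
  (estimate × exp(±1.96·log SE)). The printed reference CIs are wider than
  Wald; the `ci_method="profile"` option computes profile-likelihood
  intervals by root-finding on the profile deviance (χ²₁ cutoff, remaining
  coefficients re-maximized by BFGS at each fixed value) and reproduces the
  printed CI bounds exactly at 3 d.p.
* **Percent reduction.** 100·(r_ISO − r_DDO)/r_ISO, computed after rounding
  both rates to 3 decimals (default) because the reference reductions
  (66.3%, 20.4%) are printed-precision arithmetic; unrounded inputs give
  66.0%. Pass `rounding=None` for exact arithmetic.
* **Per-species rates.** Same estimator per species with a normal 95% CI
  truncated to [0,1]; zero detections yield NaN (undefined), and zero
  observed FPs collapse the approximate CI to [0,0] — a known boundary
  limitation of the Wald interval, flagged rather than patched.

The detection-weighted mean of the four scenario rates equals the pooled
rate exactly (an identity on counts, kept as a test).

## Problem sizes

Distributional checks use 1,000 schedules (occurrence-count goodness of
fit), ~11,000 clips (confusion recovery), and 100 surveys per arm (DDO vs
ISO contrast) — sizes at which the Monte-Carlo error of every checked
quantity is several times smaller than the effects being verified. The
reference-table reproduction is exact arithmetic on counts and needs no
simulation.

## Known limitations

* The observer model is memoryless: no fatigue, learning, inter-observer
  heterogeneity beyond the two profiles, and no distance/volume/visual
  effects — all present in field data. Passing tests validate the
  simulator/scorer/statistics loop, not human behaviour.
* Spurious (clip-less) detections default to off; with `spurious_rate > 0`
  their false positives are classified `out_of_window` unless an unmatched
  clip happens to be nearby.
* Misidentification attribution (and hence the confusion matrix and the
  nondetection/misID split of unmatched clips) is exact only when windows
  rarely collide; dense schedules blur it, as quantified above. Total FP
  counts and rates are unaffected.
* The count-rule/empirical-mean inconsistency of the reference experiment
  is surfaced, not resolved.
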