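# Methods

`mobisias` turns raw phone GPS traces into semantic mobility features and
predicts Social Interaction Anxiety Scale (SIAS) scores from them. This
note documents the models and procedures, the parameters that matter, what
the synthetic cohort generator does and does not emulate, and the design
choices made where the design was genuinely open.

## SIAS scoring

The SIAS has 20 items rated 0–4; the total ranges 0–80 and the clinical
cutoff of 34 splits participants into high/low social-anxiety groups. The
cutoff is a parameter (`cutoff=34` throughout).

## Stay-point clustering

Fixes arrive in time order (nominal interval 150 s). A running cluster
absorbs any fix within `d` metres of its arithmetic-mean centroid
(haversine distance, sphere radius 6 371 000 m). A single far fix is parked
as a *pending location* so a lone GPS glitch inside a stay is discarded; a
second consecutive far fix closes the cluster — emitted as a *stay* if its
wall-clock span exceeds `t` — and restarts clustering from the pending fix.
Defaults `d = 60 m`, `t = 600 s`. The end of the stream flushes the open
cluster; without that flush the last stay of every trace would be lost.

Two readings in the source algorithm sketch are ambiguous and were
resolved as follows: the inner distance test after the cluster is rebuilt
from the pending fix compares against the *new* fix (the only reading that
makes the branch meaningful), and cluster duration is the wall-clock span
minus excised long internal gaps (the alternative — summing inter-sample
intervals — double-counts nothing but behaves erratically with sparse
sampling).

### Gaps

Any inter-fix interval above the detection threshold (default 5 min) is a
gap. Gaps of 5–30 min are *resolvable*: if the flanking intervals carry the
same semantic class they are merged into one interval (the participant
presumably never moved); otherwise the gap is labeled `Transition`. Gaps
over 30 min are *removable*: the span is excluded from the analysis
entirely — clusters are split at them and every downstream denominator
omits them. A gap with only one flank (at a trace boundary) is removed,
the conservative choice. The field's gap definitions are not fully
consistent (a 10-minute "minimum gap" definition coexists with the
5–30 min resolution rule); both thresholds are configuration parameters
and the defaults follow the operational rule.

## Semantic labeling

Stays are matched to a place map (places with circular footprints and raw
tags from a closed vocabulary: house, education, leisure, food,
supermarket, religious, service). Matching order: footprint containment
(nearest centroid, ties by smallest place id) → nearest place within a
75 m match radius → out-of-town marker if beyond the town radius → nearest
place regardless. `Home` is the house-tagged place accumulating the most
stay time between 10 pm and 9 am over the whole study (study-cumulative
rather than per-night — the per-night variant is noisier and was not
described precisely enough to prefer); other houses map to `OtherHouses`.
Stays beyond the town radius are `OutOfTown` regardless of tag. Food and
Supermarket stay separate classes deliberately: they move in opposite
directions with social anxiety. Timelines are cut at local midnight;
time before the first and after the last fix of a day is *unobserved* and
excluded from denominators.

## Daily features (204 per day)

* 40 staying-time fractions: 10 classes × 4 epochs (daily 0–24 h, morning
  8 am–4 pm, evening 4 pm–12 am, night 12 am–8 am). The fraction
  denominator is the epoch length minus removed and unobserved time; an
  unmeasurable fraction is imputed 0 with a parallel observed-mask that is
  never fed to the model.
* 80 visit-distribution occupancies: 10 classes × 8 three-hour bins.
* 1 location entropy: Shannon entropy (natural log) of time shares across
  semantic classes, `Transition` excluded. Entropy is computed over
  classes, not distinct places, matching how the associations are framed;
  the log base is a convention and natural log is used.
* 81 transition counts: ordered pairs of the 9 non-Transition classes,
  unidirectional. Intervening `Transition` intervals are skipped; removed
  spans break adjacency; a same-class pair counts only when the two places
  differ (so `Leisure → Leisure` means two distinct leisure venues
  back-to-back, which is a real and informative event).
* 1 weekend flag and 1 day-of-week ordinal (Monday = 0).

The canonical feature count in the source material (220) cannot be
reconstructed from its stated components; this package's documented schema
is the 204 above.

Separately from the model features, an Epanechnikov kernel density
(K(u) = 0.75(1−u²), Silverman bandwidth, wrapped at 24 h) estimates
visit-time distributions for descriptive plots.

## Association analysis

Pearson correlations (two-sided p from the t transform with n−2 df) between
SIAS and per-participant means of daily staying minutes (per class, per
epoch, per day type), entropy, and transition counts; Welch unpaired
t-tests for high-vs-low group comparisons of mean daily minutes (the
pooled-variance test is a flag). No multiple-testing correction by default,
matching the exploratory framing; Benjamini–Hochberg is available as an
option. Table filters (|r| > 0.2 with p < .05 for staying-time tables,
p < .01 for the transition table) are parameters, because the source
material states them inconsistently.

## Hierarchical SIAS prediction

The main method (OM) trains one MLP — two hidden layers of 100 tanh units —
on daily feature vectors; every day inherits its participant's SIAS total
(regression) or group (classification). Prediction aggregates one candidate
per day: a 7% trimmed mean for regression (floor(0.07·n) dropped per tail,
which trims nothing at n ≤ 14 — stated plainly), majority vote with a
seeded random tie-break for classification. Candidates and final scores
are clipped to [0, 80].

Training details are design choices: Adam, learning rate 1e-3, at most 500
epochs with early stopping on a 10% validation split (patience 12), L2
penalty 1e-4, features standardized with training-fold statistics, and the
regression target standardized as well (the raw 0–80 scale is far from a
fresh network's output range and stalls small-sample training). For
classification the minority class is oversampled to balance (seeded): the
cohort skews roughly 2:1 low, and with balanced validation folds an
unweighted daily classifier's biased votes would be amplified by the
majority vote. Both adjustments apply identically to all methods.

Baselines share the architecture. BM1 aggregates the same daily features
over the study period (means of staying fractions, occupancy bins, entropy
and transition counts, plus weekday/weekend staying means) into one vector
per participant; flags provide slimmer variants. BM2 concatenates a fixed
number of daily vectors (default 14, zero-padded with an observed-day-count
column) and projects onto principal components fitted on training
participants only (components capped below the training-set size).
Separate networks are trained for regression and classification.

### Evaluation

Leave-one-participant-out CV holds all of a participant's days out
together. The balanced 10-fold scheme draws equal numbers of high and low
participants per validation fold — exactly 12+12 when the cohort supports
it, otherwise `min(n_high, n_low) // 10` per class, with leftover
participants always training. Balanced test folds are what make accuracy
interpretable (a no-signal cohort scores 0.5). Metrics: fold-mean RMSE for
regression; fold-mean accuracy and pooled F-1 (high class positive — the
averaging convention was unstated) for classification. Standardization,
oversampling, PCA and weights are always functions of the training fold;
fold memberships are recorded in the report so leakage is checkable
structurally. The learning curve re-evaluates using only each
participant's first k days.

## Synthetic cohort generator

No real GPS cohort is distributed, so the generator emulates the study
conditions: 228 students (size configurable; the analyses here use 200 for
tractability), 14 days starting on a Monday, SIAS totals from a truncated
normal (mean 29.91, SD 9.1, range 11–54), fixes every 150 s with isotropic
Gaussian jitter (σ = 10 m, well under d = 60 m so clustering is exercised,
not defeated), straight-line transitions at walking/bike/driving speed by
distance, and a campus place map whose extent grows with the number of
places so a minimum 180 m separation stays satisfiable.

Each participant gets a *weekly routine template* drawn once: which
activities happen on which day of week, at which habitual places, with
daily gamma duration noise, occasional skipped items, and (for erratic
participants) unplanned extra outings. This rigid-weekly-routine regime is
realistic for students and is the regime in which per-day modeling has
enough signal per day to be competitive.

Expected dwell minutes shift linearly with standardized SIAS (z):
more evening home time (implicitly, by crowding out), less evening/weekend
leisure (slopes −10/−18 min per z, concentrated on Friday/Saturday evenings
via day-of-week weights), a small opposite shift of weekend leisure into
mornings, less food and friends'-house time, more supermarket, religious
and service time, more weekend out-of-town trips, fewer distinct routine
places (the entropy mechanism), and day-to-day routine variability that
shrinks with SIAS (a mean-one lognormal day factor whose σ falls with z) —
rigid routines for anxious participants. Slopes are sized to the order of
the published group differences; they are directional emulation, not a fit.
Between-participant random intercepts keep correlations strong but not
degenerate. Missing data: Poisson gap starts (0.3/day) with mixed
durations spanning all three regimes, plus a 15% chance a day is "patchy"
(phone off and on all day, most of it removed).

What the generator does **not** emulate: real place geometry and footprint
shapes, sensing-quality correlation with behavior, within-stay movement,
non-stationarity across the study, demographic structure, and any
calibrated effect magnitudes. Passing tests therefore show the pipeline
recovers what the generator put in — directions and orderings — not that
real cohorts behave this way.

Ground truth (true stays with classes, transition intervals, injected
gaps) is recorded for every simulated day, so clustering and labeling are
tested against a known answer.

## Numerical and degenerate-input conventions

Distances are haversine on a 6 371 km sphere; local displacements use a
tangent-plane approximation (sub-metre error at these scales). Undefined
correlations (zero variance, n < 3) are NaN and flagged, never silently
dropped. Ties: place matching and home inference break ties by smallest
place id; majority-vote ties by a seeded uniform draw. Empty aggregation
inputs raise. All randomness flows from `numpy` `SeedSequence` spawns, so a
(config, seed) pair reproduces a cohort bit-for-bit.

## Known limitations

* The gap thresholds and home rule follow one of several defensible
  readings; both are configurable.
* The trimmed mean is inert for studies of ≤ 14 days (floor semantics).
* On this generator the aggregated baseline (BM1) attains slightly lower
  regression RMSE than the hierarchical method: with days exchangeable
  given a participant's latent state, participant-mean features are
  near-sufficient, so averaging features before fitting beats averaging
  per-day predictions for a continuous target. The hierarchical method
  matches or beats BM1 on balanced classification accuracy and is the only
  method that is incremental and robust to unbalanced day counts.
* Entropy's weekend correlation with SIAS is weaker than its weekday one
  in generated cohorts (weekend diversity gains and losses partly cancel).
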