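# Methods

This note documents the models and procedures implemented in `forumdyn`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

An event log is a table of view/post events `(event_id, user_id, post_id,
category_id, event_type, timestamp)`.  Timestamps are stored and compared
in UTC at second resolution; input without an explicit timezone offset is
rejected rather than guessed.  Categories carry a COPINE severity grade in
1–10; the derived segment is `NonSexual` for grades 1–6 and `Sexual` for
7–10.  Cumulative descriptive series are binned by UTC calendar day, with
days lacking events carried forward, so the final value of each series
equals the corresponding total count.

## Session segmentation

A session is a maximal run of one user's events in which every gap between
consecutive events is below the inactivity threshold (default 60 minutes).
The boundary convention is *gap ≥ threshold starts a new session* ("inactive
for an hour or more"); it is configurable.  Views and posts are pooled by
default — a session is a run of interactions of any kind — and a type
filter is exposed.  Single-event sessions have duration 0 and are included
in all statistics; no exclusion rule is applied.  The inter-event-time
histogram uses base-10 logarithmic bins from 1 minute to 60 days.

Ties in timestamps keep input order (stable sort), so segmentation is
deterministic.

## Periodicity classification

Each user's events are aggregated into a 168-bin hour-of-week histogram
(Monday 00:00 UTC = bin 0; counts, not rates).  The classifier computes the
discrete Fourier power spectrum of this histogram and compares the three
candidate harmonics at 7, 14 and 28 cycles/week (periods 24 h, 12 h, 6 h).
The dominant candidate is accepted when

1. the profile has at least `min_events` events (default 50),
2. its power is at least `dominance_ratio` (default 2.0) times the
   next-largest candidate power, and
3. its power is at least `min_power_fraction` (default 0.05) of the total
   non-constant spectral power;

otherwise the user is classified as having no dominant rhythm.  Ties in
candidate power go to the longer period, the weaker claim.

Two numerical points deserve comment.  First, the power-fraction threshold
is calibrated to *bursty* logs: a user whose events arrive in sessions of
~13 events deposits large clumps into single bins, which spreads broadband
power across all 83 non-constant frequencies.  Even a strongly rhythmic
user then concentrates only a few percent of total power in one harmonic
(measured on generator output: rhythmic users reach a median candidate
share of ~0.066 against ~0.028 for arrhythmic users).  The default 0.05 —
roughly eight times the mean per-frequency share — balances detection and
false alarms in that regime; smooth, non-bursty streams (e.g. a plain
Poisson process with a daily rate modulation) concentrate most of their
power in the planted harmonic and pass easily.

Second, per-user detectability is limited by the number of *sessions*, not
events: all events of a session land at essentially one phase of the
candidate rhythm, so the spectral signal-to-noise ratio grows linearly with
the session count.  Below roughly 20 sessions the planted period of a
strongly modulated user is not reliably identifiable by any threshold
choice; recovery tests therefore condition on users with ≥ 40 sessions,
where measured recovery exceeds 95%.  At desk scale (8 weeks, median ~330
views ≈ 25 sessions) a substantial fraction of genuinely rhythmic users is
classified "none"; this is a property of the data volume, not a bug, and
the population census should be read accordingly.

## Preference clustering and entropy

Users with at least `min_views` views (default 100 — the activity filter
threshold is not externally given, so it is an exposed parameter) are
embedded by their category view *shares*.  Shares rather than raw counts
remove activity-volume confounding, so clusters reflect where attention
goes, not how much of it there is.  K-means (scikit-learn, `n_init`
restarts, seeded) supplies assignments and the inertia curve over
k = 2…15.

The cluster count is chosen by the elbow rule, operationalised as the k
maximising the centered second difference I(k−1) − 2·I(k) + I(k+1) of the
inertia curve, ties toward smaller k.  A flat or linear curve has no elbow;
the smallest candidate is returned with a degeneracy flag.  This is the
simplest curvature rule consistent with "choose k where the marginal
variance gain collapses"; on curves with a genuine knee (large, roughly
even gains up to the true cluster count, little after) it selects the knee.

Preference breadth is Shannon entropy in bits, H = −Σ p log₂ p with
0·log 0 = 0, bounded by [0, log₂ M] for M categories.  Base 2 is a
convention; all comparisons are within-pipeline, so the base affects scale
only.

## Relative-risk category network

From view events only, the stage builds per-category distinct-consumer
sets.  For categories i, j with C_ij shared consumers out of N viewing
users and prevalences (distinct-consumer *counts*) P_i, P_j:

    RR_ij = C_ij · N / (P_i · P_j)

With counts, this equals the lift (C_ij/N) / ((P_i/N)(P_j/N)), so RR = 1 is
exactly independence of the two audiences.  One edge is created per
unordered pair with C_ij ≥ 1.  Filtering removes edges with RR < 1 (the
boundary RR = 1 is kept) and then nodes left isolated; the operation is
idempotent.  "Core" is operationalised as the maximum k-core of the
filtered, unweighted graph; per-node coreness is exported alongside so
other centrality readings remain possible.  No multiple-testing correction
is applied to the RR cut — a deliberate reproduction of the analysed
procedure, and a known statistical limitation: with ~2,200 candidate pairs,
some RR ≥ 1 edges are noise.

## Synthetic generator

The generator emulates, per user:

- **Activity volume**: target view counts are lognormal (default median
  330, σ = 1.0) — a heavy tail with a minority of highly active users.
- **Preferences**: 8 archetypes in a uniform mixture.  Every archetype
  spends `core_overlap` = 0.35 of its mass on one *shared* profile over the
  high-severity (Sexual) categories — this plants the dense co-consumption
  core — and the rest on its own disjoint block of low-severity categories
  (blocks assigned round-robin, so archetypes are pairwise well separated
  and the inertia curve has its knee at 8).  Three archetypes draw their
  block profile with low Dirichlet concentration (0.6: narrow, spiky
  preferences) and five with high (2.0: broad), which orders mean member
  entropy narrow < broad.  Individual users draw their weights from a
  Dirichlet centred on the archetype profile with total concentration 60;
  together with the profile sparsity this calibrates the mean number of
  distinct categories viewed to ≈ 20.
- **Rhythms**: each user is assigned a period (24/12/6 h or none; default
  mix 0.55/0.20/0.10/0.15) and a uniform random phase.  Session *start
  times* follow an inhomogeneous Poisson process with rate ∝
  1 + a·cos(2πt/T + φ), a = 0.9 by default, realised by thinning.  The
  rhythm is imposed on session starts, not individual events — the simplest
  mechanism that produces periodic weekly profiles.
- **Sessions**: the number of events in a session is 1 + NegBin(r = 2.5,
  mean = 12); within-session gaps are lognormal (μ = 0.579, σ = 1.2 in
  log-minutes) truncated strictly below the 60-minute threshold, and
  consecutive sessions are separated by strictly more than 60 minutes by
  construction.  Segmentation with the one-hour rule therefore recovers the
  generated sessions *exactly*, giving an exact oracle for that stage.  The
  negative-binomial size law (rather than a plain geometric) is what makes
  the three duration statistics jointly attainable: with geometric counts
  the duration distribution is near-exponential, and no parameter choice
  reaches 85% of sessions ≥ 10 min while keeping 25% ≥ 60 min; the
  calibrated law yields mean ≈ 42 min, S(10) ≈ 0.85, S(60) ≈ 0.24.
- **Posts**: a producer_fraction (0.2) of users post; posts per producer
  are geometric with mean 10 (many small producers, a long tail), realised
  by relabelling that many of the user's events.

Per-user session rates are set so activity spans the whole 8-week window,
floored at one session per `session_gap_mean_hours` (6 h).  All draws flow
from seeded `numpy.random.Generator` instances; identical seeds give
byte-identical logs.  Ground truth (archetypes, periods, session counts) is
returned for tests and never read by the pipeline.

**What the generator does not emulate**: forum text or reply structure,
user–user social ties, category birth/death over time, non-stationary
growth (the real system grew explosively over a year), weekday/weekend
asymmetries, or producer/consumer overlap statistics beyond a configurable
producer fraction.  Passing tests show the pipeline's stages are correct
and well calibrated on logs with this structure; they do not certify
behaviour on real data with features outside it.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `gap_threshold_min` | 60 min | session inactivity threshold |
| `min_events` | 50 | periodicity: minimum events per profile |
| `dominance_ratio` | 2.0 | periodicity: dominant vs runner-up power |
| `min_power_fraction` | 0.05 | periodicity: dominant share of non-DC power |
| `min_views` | 100 | clustering: activity filter |
| `k_range` | 2–15 | clustering: candidate cluster counts |
| `restarts` | 10 | k-means restarts per k |
| `rr_min` | 1.0 | network: edge filter threshold |
| `n_users` / window | 500 / 8 weeks | generator desk scale |

Desk-scale sizes (500 users for calibration statistics, 1,000 for the
elbow analysis, ≥ 5,000 sessions for duration statistics) were chosen as
the package's working problem sizes; all statistics quoted above are
recomputed at run time by the test suite and `scripts/acceptance.py`, never
hard-coded.

## Known limitations

- RR edges carry no confidence intervals; the RR ≥ 1 cut is a point
  estimate filter (documented extension, not implemented).
- The elbow rule is a heuristic; on curves without a distinct knee it
  degrades to the flagged smallest-k fallback.
- Periodicity classification at low session counts is information-limited
  (see above); census fractions at desk scale undercount true rhythmicity.
- The entropy summary uses plain Shannon entropy of view shares; no
  normalisation for the number of available categories is applied.
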