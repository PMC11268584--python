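# forumdyn

Behavioural analysis of timestamped forum event logs: session segmentation,
activity-rhythm classification, content-preference clustering, and a
relative-risk category co-consumption network with severity-based
core–periphery segmentation.

The package targets the kind of data produced by law-enforcement seizures of
illicit-content forums: an anonymised log of *view* and *post* events (user,
post, category, timestamp) plus a table grading each content category on the
10-level COPINE severity scale (grades 1–6 "NonSexual", 7–10 "Sexual").
Because such data is restricted, the package ships a calibrated synthetic
generator that reproduces the behavioural statistics reported for this kind
of forum, so every stage of the pipeline is testable end to end.  **No
content of any kind is ever represented — only opaque integer ids, event
types, timestamps and severity grades.**

## Methods at a glance

- **Sessions.** A session is a maximal run of one user's events with all
  consecutive gaps below an inactivity threshold; a gap Δt ≥ 60 min starts a
  new session.  The stage reports mean duration and survival fractions
  P(duration ≥ 10 min), P(duration ≥ 60 min), plus a log-binned inter-event
  time histogram.
- **Rhythms.** Each user's events are binned into a 168-bin hour-of-week
  profile.  The discrete Fourier power at the harmonics of 24 h, 12 h and
  6 h decides the dominant period, guarded by an event-count floor, a 2×
  dominance ratio over the runner-up harmonic, and a minimum share of total
  non-constant spectral power.
- **Preference clusters.** Users are embedded by their category view shares
  (row-normalised counts), clustered with k-means; k is chosen by the elbow
  rule (maximum second difference of the inertia curve over k = 2…15).
  Preference breadth is Shannon entropy H = −Σ p·log₂ p of the share vector.
- **Category network.** Categories are linked when the same user viewed
  both; edges are weighted by relative risk
  RR_ij = C_ij · N / (P_i · P_j), where C_ij counts users viewing both
  categories, P_i, P_j are per-category distinct-consumer counts and N is
  the number of viewing users.  Edges with RR < 1 are dropped, isolated
  nodes removed, and the maximum k-core of the remaining graph is profiled
  by COPINE segment.

See `docs/methods.md` for the full model description, parameter table and
limitations.

## Worked example

```bash
forumdyn generate --seed 42 --out events.csv --categories categories.csv --truth truth.json
# wrote 211065 events for 500 users

printf 'events_path: events.csv\ncategories_path: categories.csv\noutput_dir: out\nseed: 42\n' > pipeline.yaml
forumdyn run --config pipeline.yaml
```

`out/report.json` from that run contains (abridged):

```
sessions:      16449 sessions, mean duration 41.5 min,
               P(>=10 min) = 0.848, P(>=60 min) = 0.235
clusters:      selected_k = 8
network:       67 nodes, 1204 edges after the RR >= 1 filter,
               maximum k-core at k = 27 with segment fractions
               Sexual 0.825 / NonSexual 0.175
descriptives:  500 users, 210247 views, 818 posts, 67 categories
```

Reading these numbers: the one-hour rule segments the log into sessions
whose duration statistics match the behavioural profile the generator is
calibrated to (mean ≈ 40 min; ≈ 85% of sessions at least 10 min; ≈ 25% at
least an hour).  The elbow rule recovers the eight planted preference
archetypes.  In the filtered co-consumption network the densest core is
dominated by high-severity ("Sexual") categories while low-severity
categories sit at the periphery — the structure the generator plants via a
shared high-severity consumption profile.

Each stage is also available separately (`forumdyn sessions|temporal|
clusters|network`) and as library functions (`forumdyn.sessions`,
`forumdyn.temporal`, `forumdyn.content_clusters`,
`forumdyn.category_network`, `forumdyn.synthetic_data`).

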