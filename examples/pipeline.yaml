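# Default pipeline configuration.  Generate inputs first:
#   forumdyn generate --seed 42 --out events.csv --categories categories.csv
events_path: events.csv
categories_path: categories.csv
output_dir: out
session_threshold_min: 60.0
periodicity_min_events: 50
periodicity_dominance_ratio: 2.0
periodicity_min_power_fraction: 0.05
min_views: 100
k: auto
k_range: [2, 15]
restarts: 10
rr_min: 1.0
seed: 42
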