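import numpy as np
import pandas as pd
import pytest

from forumdyn import event_log as ev


def make_events(rows):
    """Build a sorted event frame from (user_id, minutes, event_type, category_id)
    tuples; timestamps are offsets from a fixed UTC origin."""
    origin = pd.Timestamp("2014-02-03T00:00:00Z")
    df = pd.DataFrame(
        {
            "event_id": range(1, len(rows) + 1),
            "user_id": [r[0] for r in rows],
            "post_id": [1000 + i for i in range(len(rows))],
            "category_id": [r[3] if len(r) > 3 else 1 for r in rows],
            "event_type": [r[2] if len(r) > 2 else ev.VIEW for r in rows],
            "timestamp": [origin + pd.Timedelta(minutes=float(r[1])) for r in rows],
        }
    )
    return df.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)


@pytest.fixture(scope="session")
def default_population():
    """One default-config population, shared across tests (read-only)."""
    from forumdyn import synthetic_data as syn

    cfg = syn.default_config()
    return cfg, syn.generate_population(cfg, seed=101)


@pytest.fixture(scope="session")
def default_log(default_population):
    """One default-config event log + ground truth, shared across tests."""
    from forumdyn import synthetic_data as syn

    cfg, pop = default_population
    events, truth = syn.generate_events(pop, cfg, seed=202)
    return cfg, pop, events, truth
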