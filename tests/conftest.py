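import numpy as np
import pandas as pd
import pytest

import mrdcyte as m
from mrdcyte.simulate import simulate_reference_samples


@pytest.fixture(scope="session")
def tree():
    return m.default_gate_tree()


@pytest.fixture(scope="session")
def small_sample():
    """50k-event BM sample with a 1% blast spike (pinned LAIP+ clone)."""
    from mrdcyte.simulate import spikein_sample_config
    cfg = spikein_sample_config(50_000, 0.01, seed=1)
    return m.simulate_sample(cfg)


@pytest.fixture(scope="session")
def reference_results(tree):
    """Five gated non-leukemic reference samples."""
    refs = simulate_reference_samples(5, 50_000, seed=3)
    return [m.gate_events(s, tree) for s in refs]


@pytest.fixture(scope="session")
def ranges(reference_results):
    return m.build_reference_ranges(reference_results)


@pytest.fixture(scope="session")
def default_cohort():
    return m.simulate_cohort(m.CohortConfig(seed=11))


def make_event(channels: dict, panel=None) -> "m.EventMatrix":
    """Single-event matrix with the given channel values (others zero)."""
    base = {ch: 0.0 for ch in m.default_panel()}
    base.update(channels)
    return m.EventMatrix(pd.DataFrame([base]), None, "single")
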