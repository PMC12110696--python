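from datetime import date

import numpy as np
import pytest

from flowmrd import drift_monitor, synthcyto


@pytest.fixture(scope="session")
def small_sample():
    """One mixed specimen with a 1% classic-CLL clone, 20k events."""
    spec = synthcyto.SampleSpec(sample_id="fix-1", specimen_type="BM",
                                n_events=20_000, mrd_fraction=0.01, seed=11)
    return synthcyto.generate_sample(spec)


@pytest.fixture(scope="session")
def reference_cohort():
    """Eight low-burden reference specimens for drift-model fitting."""
    return [
        synthcyto.generate_sample(
            synthcyto.SampleSpec(sample_id=f"ref-{i}", n_events=6_000,
                                 mrd_fraction=0.001, seed=100 + i))
        for i in range(8)
    ]


@pytest.fixture(scope="session")
def drift_model(reference_cohort):
    return drift_monitor.fit_reference(reference_cohort, n_sub=2_000, seed=7)


@pytest.fixture
def day():
    return date(2024, 6, 3)
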