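import numpy as np
import pytest

from mtcn import (
    SimulationConfig,
    batch_correct,
    estimate_cohort,
    generate_cohort,
)


@pytest.fixture(scope="session")
def demo_cohort():
    """A mid-size synthetic cohort with every signal planted."""
    cfg = SimulationConfig(n_patients=80, frac_wgs=0.4)
    return generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def demo_pipeline(demo_cohort):
    """(cohort, corrected estimates, meta records, per-cancer-type fits)."""
    meta = demo_cohort.meta_records()
    ests = estimate_cohort(
        demo_cohort.read_count_records(), meta, demo_cohort.purity_records()
    )
    ests, fits = batch_correct(ests, meta)
    return demo_cohort, ests, meta, fits


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
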