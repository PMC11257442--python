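import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import perichrom as pc

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_layout():
    return pc.GenomeLayout(("chrA", "chrB"), (100_000, 53_000))


@pytest.fixture(scope="session")
def small_truth():
    """2 x 25-Mb synthetic genome (5,000 10-kb bins), default effects."""
    cfg = pc.SynthConfig(seed=11, n_chromosomes=2, chrom_length_bp=25_000_000)
    return pc.generate_truth(cfg)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return pc.simulate_counts(small_truth)


def make_track(layout, bin_size, values, meta=None):
    return pc.BinnedTrack(layout, bin_size,
                          {c: np.asarray(v, dtype=float) for c, v in values.items()},
                          dict(meta or {}))
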