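import numpy as np
import pytest

from immunoscore.reference import MARKER_REGION_PAIRS, ReferenceDistribution


def make_reference(values) -> ReferenceDistribution:
    """Reference with the same sorted sequence for all four (marker, region)."""
    seq = np.sort(np.asarray(values, dtype=float))
    return ReferenceDistribution({key: seq.copy() for key in MARKER_REGION_PAIRS})


@pytest.fixture
def step_ref():
    """100-point reference over {10, 20, 30, 40}: percentiles in steps of 25."""
    return make_reference(np.repeat([10.0, 20.0, 30.0, 40.0], 25))


@pytest.fixture
def grid_ref():
    """1000 distinct densities 1..1000: percentile(d) = d/10 for integer d."""
    return make_reference(np.arange(1, 1001, dtype=float))


def random_survival_data(rng, n, hazard_scale=0.05, censor_high=40.0,
                         round_times=False):
    """Exponential times with uniform censoring; optional ties via rounding."""
    t = rng.exponential(1.0 / hazard_scale, size=n)
    c = rng.uniform(1.0, censor_high, size=n)
    times = np.minimum(t, c)
    if round_times:
        times = np.ceil(times)  # force heavy ties
    events = t <= c
    return times, events
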