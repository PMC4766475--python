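import numpy as np
import pytest

from hrvlines import EventSpec, RRSeries, SynthSpec, generate, normalize_global


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def random_series_corpus(rng):
    """Random positive RR series with assorted lengths and orders.

    A shared corpus for the closure / projection-oracle / scale-invariance
    sweeps: (series, order) pairs with lengths spanning 10 to 5000.
    """
    corpus = []
    for _ in range(1000):
        m = int(rng.integers(10, 5001))
        n = int(rng.integers(2, 11))
        if m < 2 * n:
            m = 2 * n
        intervals = rng.lognormal(mean=np.log(0.8), sigma=0.2, size=m)
        corpus.append((RRSeries(intervals=intervals), n))
    return corpus


@pytest.fixture
def flat_pair_record():
    """Flat 0.8 s baseline, one compensated ectopic pair at beats 53-54."""
    spec = SynthSpec(
        M=105,
        mean_rr=0.8,
        noise_sd=0.0,
        resp_amplitude=0.0,
        events=(EventSpec("ectopic_pair", 52, 0.2, 2),),
        seed=0,
    )
    rr, log = generate(spec)
    return rr, log


@pytest.fixture
def hf_like_normalized():
    """A stochastic record with frequent ectopy, globally normalized."""
    events = tuple(
        EventSpec("ectopic_pair", i, 0.3, 2) for i in range(40, 2900, 75)
    )
    spec = SynthSpec(M=3000, noise_sd=0.035, ar_coefficient=0.5, events=events, seed=7)
    rr, _ = generate(spec)
    return normalize_global(rr)
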