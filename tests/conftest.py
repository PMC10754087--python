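import numpy as np
import pytest

from molspan.photons import PhotonStream


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic draws
    # regardless of execution order
    return np.random.default_rng(20240915)


def make_stream(times_s, channels=None, duration=None, sources=None):
    """Build a PhotonStream from arrival times in seconds."""
    times_s = np.asarray(times_s, dtype=float)
    order = np.argsort(times_s)
    times_s = times_s[order]
    n = times_s.size
    ch = np.zeros(n, np.uint8) if channels is None else np.asarray(channels, np.uint8)[order]
    src = np.zeros(n, np.uint8) if sources is None else np.asarray(sources, np.uint8)[order]
    return PhotonStream(
        np.round(times_s * 1e12).astype(np.int64),
        ch,
        np.zeros(n, np.uint16),
        src,
        duration if duration is not None else (times_s[-1] if n else 1.0),
    )


@pytest.fixture(scope="session")
def poisson_stream():
    """Stationary Poisson stream, 20 kHz for 10 s, two channels."""
    r = np.random.default_rng(777)
    n = r.poisson(20_000 * 10)
    t = np.sort(r.uniform(0, 10.0, n))
    ch = r.integers(0, 2, n)
    return make_stream(t, ch, duration=10.0)
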