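import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chipem.formats import ReadAlignment
from chipem.read_model import default_distribution

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chipseq_dist():
    return default_distribution("chipseq")


@pytest.fixture(scope="session")
def chipexo_dist():
    return default_distribution("chipexo")


def reads_for_event(rng, pos, n, dist, chrom="chr1"):
    """Reads whose 5' ends follow ``dist`` around a single event."""
    offs = rng.choice(dist.support, size=n, p=dist.prob_plus)
    plus = rng.random(n) < 0.5
    return [
        ReadAlignment(chrom, int(pos + o) if pl else int(pos - o), "+" if pl else "-")
        for o, pl in zip(offs, plus)
    ]


@pytest.fixture
def make_event_reads():
    return reads_for_event
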