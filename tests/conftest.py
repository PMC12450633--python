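import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hepacre.intervals import GenomicInterval
from hepacre.synthetic import SyntheticConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_config():
    """Scaled-down study conditions: 200 peaks per condition, 30 planted
    promoters and 25 planted enhancers in the disease state."""
    return SyntheticConfig(seed=7, n_atac_peaks=200, cells_per_cluster=50,
                           n_genes=400)


def random_intervals(rng, n, chroms=("chr1", "chr2", "chr3"),
                     span=100_000, max_len=500):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + length, f"iv{i}"))
    return out


def brute_force_match(queries, subjects, min_bp=1):
    """All-pairs overlap oracle, vectorised over the subject axis."""
    if not subjects:
        return [False] * len(queries)
    s_chrom = np.array([s.chrom for s in subjects])
    s_start = np.array([s.start for s in subjects])
    s_end = np.array([s.end for s in subjects])
    flags = []
    for q in queries:
        ov = np.minimum(s_end, q.end) - np.maximum(s_start, q.start)
        flags.append(bool(((s_chrom == q.chrom) & (ov >= min_bp)).any()))
    return flags
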