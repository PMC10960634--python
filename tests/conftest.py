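import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mocolo as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_genome() -> m.Genome:
    """Two short chromosomes with known composition."""
    return m.Genome({"chr1": "GGGGGAAAAA", "chr2": "ACGTACGTACGTACGT"})


@pytest.fixture(scope="session")
def toy_world():
    """A 300 kb uniform-composition genome with host/query features."""
    syn = m.make_genome(
        m.GenomeSpec(chromosome_length=300_000, background_g=0.25), seed=11
    )
    f1, f2 = m.make_features(
        syn, m.FeatureSpec(150, 400), m.FeatureSpec(300, 25), rho=0.0, seed=11
    )
    return syn, f1, f2


def random_library(
    rng: np.random.Generator,
    n: int,
    max_len: int = 40,
    chrom_len: int = 10_000,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
) -> m.MotifLibrary:
    """Uniform random intervals for oracle comparisons."""
    c = rng.choice(chroms, size=n).astype(object)
    lens = rng.integers(1, max_len, size=n)
    starts = np.array([rng.integers(0, chrom_len - L + 1) for L in lens])
    return m.MotifLibrary.from_arrays(c, starts, starts + lens)


def brute_force_metrics(
    pivot: m.MotifLibrary, query: m.MotifLibrary, min_overlap: int
) -> tuple[int, int]:
    """All-pairs oracle for (n_pivot_overlapped, n_pairs)."""
    n_overlapped = 0
    n_pairs = 0
    for a in pivot:
        hits = sum(
            1 for b in query if m.overlap_length(a, b) >= min_overlap
        )
        n_pairs += hits
        n_overlapped += hits > 0
    return n_overlapped, n_pairs
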