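import numpy as np
import pytest

from minibulkcna import GenomeBins, RatioProfile, make_genome


def make_bins(n_by_chrom: dict[str, int], gc: float | None = 0.45, seed: int = 0) -> GenomeBins:
    """Small bin set for unit tests; gc constant or seeded in [0.3, 0.6]."""
    rng = np.random.default_rng(seed)
    chroms, starts, ends, gcs = [], [], [], []
    for chrom, n in n_by_chrom.items():
        chroms.extend([chrom] * n)
        starts.extend(range(0, n * 1_000_000, 1_000_000))
        ends.extend(range(1_000_000, (n + 1) * 1_000_000, 1_000_000))
        if gc is None:
            gcs.extend(rng.uniform(0.3, 0.6, size=n))
        else:
            gcs.extend([gc] * n)
    return GenomeBins(chroms, starts, ends, gcs)


def profile_from_values(x_by_chrom: dict[str, np.ndarray], sample_id: str = "s") -> RatioProfile:
    """RatioProfile over constant-GC bins holding the given values."""
    bins = make_bins({c: len(v) for c, v in x_by_chrom.items()})
    x = np.concatenate([np.asarray(v, dtype=float) for v in x_by_chrom.values()])
    return RatioProfile(sample_id=sample_id, bins=bins, x=x, mask=np.ones(len(x), bool))


@pytest.fixture(scope="session")
def small_genome() -> GenomeBins:
    """Fast 24-chromosome test genome (~620 bins)."""
    return make_genome(scale=0.2, seed=1)


@pytest.fixture(scope="session")
def full_genome() -> GenomeBins:
    """Full-scale genome (~3,100 one-megabase bins)."""
    return make_genome(scale=1.0, seed=1)
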