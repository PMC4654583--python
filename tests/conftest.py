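import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dualmut.genome import GenomeModel
from dualmut.intervals import FeatureTrack
from dualmut.variants import VariantSet


@pytest.fixture
def toy_genome() -> GenomeModel:
    """Two tiny chromosomes for interval/oracle tests."""
    return GenomeModel([("chr1", 100_000), ("chr2", 50_000)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_track(rng, genome, name="t", n=50, max_len=2000) -> FeatureTrack:
    rows = []
    for chrom, length in genome.chromosomes:
        starts = rng.integers(0, length - max_len, size=n)
        lens = rng.integers(1, max_len, size=n)
        rows.extend((chrom, int(s), int(min(s + l, length))) for s, l in zip(starts, lens))
    return FeatureTrack(name, rows)


def per_bp_mask(track: FeatureTrack, chrom: str, length: int) -> np.ndarray:
    """Independent per-bp membership oracle built from the raw intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in track.intervals(chrom):
        mask[s:e] = True
    return mask


def per_bp_coverage(track: FeatureTrack, chrom: str, start: int, end: int) -> int:
    return int(per_bp_mask(track, chrom, end)[start:end].sum())


def variants_from_positions(chrom, pos, kind="disease", **kw) -> VariantSet:
    return VariantSet.from_arrays([chrom] * len(pos), np.asarray(pos), kind, **kw)
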