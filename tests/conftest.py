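import numpy as np
import pytest

from xregenrich import (
    AnnotationTrack,
    ChromosomeModel,
    GenomicInterval,
    RegionSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_model():
    return ChromosomeModel("chrX", 1_000_000)


def random_intervals(rng, n, length=10_000, max_width=300, chrom="chrX"):
    """n random valid intervals on a small chromosome."""
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [GenomicInterval(chrom, int(s), int(s + w)) for s, w in zip(starts, widths)]


def random_track(rng, n, name="t", length=10_000, max_width=300, element_class="other"):
    ivs = random_intervals(rng, n, length=length, max_width=max_width)
    return AnnotationTrack(
        name, element_class, tuple((f"e{i:05d}", iv) for i, iv in enumerate(ivs))
    )


def brute_force_overlap_ids(track, regions):
    """All-pairs oracle: ids of elements sharing >= 1 base with any region."""
    hits = set()
    for eid, iv in track.elements:
        for reg in regions:
            if (
                iv.chrom == reg.chrom
                and iv.start < reg.end
                and reg.start < iv.end
            ):
                hits.add(eid)
                break
    return hits
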