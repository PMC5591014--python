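import numpy as np
import pytest

from contactscape import (
    CutterScheme, FragmentMap, RestrictionFragment, ViewpointSpec,
)


@pytest.fixture
def scheme():
    return CutterScheme()


def toy_fragment_map(lengths, chrom="chr1", blind=None):
    """FragmentMap built from explicit fragment lengths."""
    edges = np.concatenate([[0], np.cumsum(lengths)])
    blind = blind or [True] * len(lengths)
    frags = [
        RestrictionFragment(chrom, int(edges[i]), int(edges[i + 1]), i, blind[i])
        for i in range(len(lengths))
    ]
    return FragmentMap({chrom: frags})


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def small_map():
    return toy_fragment_map([100] * 50)


@pytest.fixture
def small_viewpoint(small_map):
    frag = small_map.locate_fragment("chr1", 2500)
    return ViewpointSpec("vp", "chr1", (frag.start + frag.end) // 2, frag.index,
                         exclusion_radius_fragments=2)
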