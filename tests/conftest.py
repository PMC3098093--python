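import numpy as np
import pytest

from zftarget.core import PoolConfig, SiteDataset, TargetSite


@pytest.fixture
def tiny_pools():
    return PoolConfig(("GGG", "GAA"), ("GAA", "GCC", "GGG"), ("GCC",))


@pytest.fixture
def separable_dataset():
    """Position 1 perfectly determines the class (G-start active, T-start inactive)."""
    actives = ["GGGGGGGGG", "GAAGAAGAA", "GCCGCCGCC", "GTTGTTGTT", "GGAGGAGGA",
               "GACGACGAC"]
    inactives = ["TTTTTTTTT", "TAATAATAA", "TCCTCCTCC", "TGGTGGTGG", "TTATTATTA",
                 "TCGTCGTCG"]
    sites = [TargetSite(s, "active") for s in actives]
    sites += [TargetSite(s, "inactive") for s in inactives]
    return SiteDataset("separable", sites)


@pytest.fixture
def four_site_dataset():
    """Hand-checkable 2+2 dataset used for posterior arithmetic."""
    return SiteDataset(
        "four",
        [
            TargetSite("GGGGGGGGG", "active"),
            TargetSite("GGGGGGGGT", "active"),
            TargetSite("TTTTTTTTT", "inactive"),
            TargetSite("TTTTTTTTG", "inactive"),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


def random_site(rng) -> str:
    return "".join(rng.choice(list("GACT"), size=9))
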