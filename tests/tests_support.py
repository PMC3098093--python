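"""Shared helpers for the test suite."""

from zftarget.core import SiteDataset, TargetSite


def random_dataset(rng, n: int) -> SiteDataset:
    """Random labeled 9-mer dataset with both classes guaranteed present."""
    sites = []
    for i in range(n):
        seq = "".join(rng.choice(list("GACT"), size=9))
        label = "active" if rng.random() < 0.6 else "inactive"
        sites.append(TargetSite(seq, label, id=f"r{i}"))
    sites[0] = TargetSite(sites[0].sequence, "active", id="r0")
    sites[1] = TargetSite(sites[1].sequence, "inactive", id="r1")
    return SiteDataset("random", sites)
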