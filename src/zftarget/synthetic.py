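"""Synthetic labeled 9-mer datasets with a thymine-dependent activity model.

The generator emulates the statistical structure of validated OPEN target
datasets: candidate sites drawn from the per-position triplet pools, and an
activity label whose probability falls with the site's thymine content —
the dominant compositional difference between experimentally active and
inactive sites.  The activity model is logistic:

    P(active | site) = sigmoid(b0 + bT * countT(site)
                               + sum_p bonus[p][base at p])

with intercept ``b0``, thymine coefficient ``bT`` (negative for realistic
behavior), and an optional 9 x 4 positional bonus matrix.  When a target
active fraction is requested (validated datasets run ~79% active), ``b0``
is solved by bisection so the expected fraction over the sampled sites
matches it.

This is a synthetic ground-truth model for testing the surrounding
machinery; it makes no claim about OPEN selection chemistry or bacterial
two-hybrid fold-activation values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from zftarget.core import PoolConfig, SiteDataset, TargetSite, default_pool_config
from zftarget.encodings import BASE_ORDER
from zftarget.target_space import enumerate_half_sites


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic site generator.

    Defaults mirror the conditions of validated-site datasets: pool-drawn
    candidates, a clearly negative thymine effect, and ~79% active labels.
    """

    pools: Optional[PoolConfig] = None
    n: int = 135
    seed: int = 1
    intercept: float = 0.0
    thymine_coefficient: float = -1.0
    positional_bonus: Optional[np.ndarray] = None  # (9, 4) added to the logit
    target_active_fraction: Optional[float] = 0.79

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.pools is None:
            self.pools = default_pool_config()
        if self.positional_bonus is not None:
            self.positional_bonus = np.asarray(self.positional_bonus, float)
            if self.positional_bonus.shape != (9, 4):
                raise ValueError("positional_bonus must be a 9 x 4 matrix")
        if self.target_active_fraction is not None and not (
            0.0 < self.target_active_fraction < 1.0
        ):
            raise ValueError("target_active_fraction must be in (0, 1)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _logit_terms(sequences: list[str], config: SyntheticConfig) -> np.ndarray:
    """Per-site logit excluding the intercept."""
    terms = np.array(
        [config.thymine_coefficient * s.count("T") for s in sequences]
    )
    if config.positional_bonus is not None:
        for i, s in enumerate(sequences):
            terms[i] += sum(
                config.positional_bonus[p][BASE_ORDER.index(b)]
                for p, b in enumerate(s)
            )
    return terms


def _solve_intercept(terms: np.ndarray, target: float) -> float:
    """Bisection for b0 s.t. mean sigmoid(b0 + terms) == target."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if _sigmoid(mid + terms).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def sample_sites(config: SyntheticConfig) -> SiteDataset:
    """Draw n unlabeled sites uniformly (with replacement) from the pool product."""
    rng = np.random.default_rng(config.seed)
    pool = enumerate_half_sites(config.pools)
    idx = rng.integers(0, len(pool), size=config.n)
    sites = [TargetSite(pool[i], "unknown", id=f"syn{k}") for k, i in enumerate(idx)]
    return SiteDataset(name=f"synthetic-n{config.n}-seed{config.seed}", sites=sites)


def label_sites(sites: SiteDataset, config: SyntheticConfig) -> SiteDataset:
    """Assign Bernoulli activity labels under the logistic model."""
    sequences = [s.sequence for s in sites.sites]
    terms = _logit_terms(sequences, config)
    b0 = config.intercept
    if config.target_active_fraction is not None:
        b0 = _solve_intercept(terms, config.target_active_fraction)
    probs = _sigmoid(b0 + terms)
    # labeling stream is independent of the sampling stream
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    draws = rng.random(len(sequences))
    labeled = [
        TargetSite(
            s.sequence,
            "active" if d < p else "inactive",
            id=s.id,
            source=s.source,
        )
        for s, p, d in zip(sites.sites, probs, draws)
    ]
    return SiteDataset(name=sites.name, sites=labeled)


def generate_dataset(config: SyntheticConfig) -> SiteDataset:
    """Sample and label in one call."""
    return label_sites(sample_sites(config), config)


def generate_benchmark(
    config: SyntheticConfig, n_train: int = 135, n_test: int = 140
) -> tuple[SiteDataset, SiteDataset]:
    """Two sequence-disjoint labeled datasets from one generative model.

    Mirrors a cross-validation set plus a completely independent test set.
    Sites within each split may repeat, but no sequence appears in both.
    """
    pool = enumerate_half_sites(config.pools)
    if n_train + n_test > len(pool):
        raise ValueError(
            f"pool of {len(pool)} distinct sites cannot supply disjoint "
            f"splits of {n_train} + {n_test}"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pool))
    train_seqs = [pool[i] for i in order[:n_train]]
    test_seqs = [pool[i] for i in order[n_train : n_train + n_test]]

    def build(seqs: list[str], tag: str, stream: int) -> SiteDataset:
        ds = SiteDataset(
            name=f"synthetic-{tag}-seed{config.seed}",
            sites=[TargetSite(s, "unknown", id=f"{tag}{i}") for i, s in enumerate(seqs)],
        )
        sub = SyntheticConfig(
            pools=config.pools,
            n=len(seqs),
            seed=int(np.random.SeedSequence([config.seed, stream]).generate_state(1)[0] % (2**31)),
            intercept=config.intercept,
            thymine_coefficient=config.thymine_coefficient,
            positional_bonus=config.positional_bonus,
            target_active_fraction=config.target_active_fraction,
        )
        return label_sites(ds, sub)

    return build(train_seqs, "train", 2), build(test_seqs, "test", 3)
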