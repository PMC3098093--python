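"""OPEN target-space enumeration, methylation exclusion, and ZFN scanning.

A full zinc finger nuclease (ZFN) site consists of two 9-bp half-sites in
inverted orientation around a 5-7 bp spacer: in forward-strand coordinates
the span is left(9) + spacer + right(9), and the two zinc finger arrays
actually bind reverse_complement(left) and right (both half-sites point
5'-ends-inward so the FokI domains can dimerize over the spacer).  This
construction is strand-closed, so scanning one strand suffices.

Sites containing a dam (GATC) or dcm (CCAGG/CCTGG, i.e. CCWGG) motif are
excluded: they are methylated in the E. coli host of the bacterial
two-hybrid selection, which blocks zinc finger binding.  The motif set is
closed under reverse complement, so a forward-strand substring search
covers both strands.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from zftarget.classifiers import (
    ClassifierConfig,
    NaiveBayesModel,
    confidence_score,
    nb_posterior,
)
from zftarget.core import PoolConfig, SequenceRecord, TargetSite, reverse_complement
from zftarget.encodings import encode_site

METHYLATION_MOTIFS = ("GATC", "CCAGG", "CCTGG")
DEFAULT_SPACERS = frozenset({5, 6, 7})
HALF_SITE_LENGTH = 9
MIN_FULL_SITE = 2 * HALF_SITE_LENGTH + min(DEFAULT_SPACERS)  # 23


@dataclass(frozen=True)
class ZFNHit:
    """One candidate ZFN full site found on the forward strand.

    ``start`` is 0-based half-open internally; reports print 1-based.
    ``half_site_1`` is the reverse complement of the left 9-bp window (the
    site bound by the upstream array); ``half_site_2`` is the right window.
    """

    contig: str
    start: int
    spacer_length: int
    full_site: str
    left_window: str
    right_window: str
    half_site_1: str
    half_site_2: str
    posterior_1: Optional[float] = None
    posterior_2: Optional[float] = None
    confidence_1: Optional[int] = None
    confidence_2: Optional[int] = None

    @property
    def span(self) -> int:
        return 2 * HALF_SITE_LENGTH + self.spacer_length


@dataclass(frozen=True)
class TargetSpaceSummary:
    n_enumerable: int
    n_methylation_excluded: int
    n_targetable: int
    n_predicted_active: Optional[int]
    n_zfn_pairs: int
    n_zfn_pairs_unordered: int


def enumerate_half_sites(pools: PoolConfig) -> list[str]:
    """All 9-mers in the pool product pos1 x pos2 x pos3, lexicographic."""
    sites = [
        a + b + c
        for a, b, c in itertools.product(
            sorted(pools.triplets_pos1),
            sorted(pools.triplets_pos2),
            sorted(pools.triplets_pos3),
        )
    ]
    sites.sort()
    return sites


def methylation_excluded(site: str) -> bool:
    """True iff the 9-mer contains a dam/dcm motif on either strand.

    The motif set {GATC, CCAGG, CCTGG} is reverse-complement closed (GATC
    is self-complementary, CCAGG <-> CCTGG), so one-strand search covers
    both strands.
    """
    return any(m in site for m in METHYLATION_MOTIFS)


def summarize_target_space(
    pools: PoolConfig,
    model: Optional[NaiveBayesModel] = None,
    threshold: float = 0.5,
) -> TargetSpaceSummary:
    """Enumerate, methylation-filter, optionally classify; count ZFN pairs.

    ZFN pair counts are ordered (n^2) — every ordered combination of two
    targetable half-sites at a fixed spacer length — with the physically
    deduplicated unordered count n(n+1)/2 reported alongside.
    """
    sites = enumerate_half_sites(pools)
    excluded = sum(1 for s in sites if methylation_excluded(s))
    targetable = [s for s in sites if not methylation_excluded(s)]
    n_targetable = len(targetable)
    n_active: Optional[int] = None
    if model is not None:
        n_active = 0
        for seq in targetable:
            p = nb_posterior(model, encode_site(TargetSite(seq), model.kind))
            if p >= threshold:
                n_active += 1
    n_for_pairs = n_active if n_active is not None else n_targetable
    return TargetSpaceSummary(
        n_enumerable=len(sites),
        n_methylation_excluded=excluded,
        n_targetable=n_targetable,
        n_predicted_active=n_active,
        n_zfn_pairs=n_for_pairs**2,
        n_zfn_pairs_unordered=n_for_pairs * (n_for_pairs + 1) // 2,
    )


def scan_sequence(
    record: SequenceRecord,
    pools: Optional[PoolConfig] = None,
    spacers: Iterable[int] = DEFAULT_SPACERS,
    model: Optional[NaiveBayesModel] = None,
    min_confidence: Optional[int] = None,
    threshold: float = 0.5,
    filter_methylation: bool = True,
) -> list[ZFNHit]:
    """Slide over the forward strand and report candidate ZFN full sites.

    For each spacer length s, every window left(9)+spacer(s)+right(9) is
    decomposed; the candidate half-sites are reverse_complement(left) and
    right.  A hit is kept iff both half-sites are in the pool product (when
    pools are given), neither contains a methylation motif (when
    ``filter_methylation``), and — when a model is given — both confidence
    scores reach ``min_confidence`` (if set).  Windows containing N are
    skipped.  Scanning one strand is sufficient because the construction is
    strand-closed.
    """
    spacers = sorted(set(spacers))
    bad = [s for s in spacers if s not in DEFAULT_SPACERS]
    if bad:
        raise ValueError(f"invalid spacer length(s) {bad}; allowed: 5, 6, 7")
    if not spacers:
        raise ValueError("spacer set must be non-empty")
    pool_members = set(enumerate_half_sites(pools)) if pools is not None else None
    seq = record.sequence
    hits: list[ZFNHit] = []
    for spacer in spacers:
        span = 2 * HALF_SITE_LENGTH + spacer
        for start in range(0, len(seq) - span + 1):
            window = seq[start : start + span]
            if "N" in window:
                continue
            left = window[:HALF_SITE_LENGTH]
            right = window[-HALF_SITE_LENGTH:]
            half1 = reverse_complement(left)
            half2 = right
            if pool_members is not None and (
                half1 not in pool_members or half2 not in pool_members
            ):
                continue
            if filter_methylation and (
                methylation_excluded(half1) or methylation_excluded(half2)
            ):
                continue
            posterior_1 = posterior_2 = None
            conf_1 = conf_2 = None
            if model is not None:
                posterior_1 = nb_posterior(
                    model, encode_site(TargetSite(half1), model.kind)
                )
                posterior_2 = nb_posterior(
                    model, encode_site(TargetSite(half2), model.kind)
                )
                conf_1 = confidence_score(posterior_1)
                conf_2 = confidence_score(posterior_2)
                if min_confidence is not None and (
                    conf_1 < min_confidence or conf_2 < min_confidence
                ):
                    continue
            hits.append(
                ZFNHit(
                    contig=record.id,
                    start=start,
                    spacer_length=spacer,
                    full_site=window,
                    left_window=left,
                    right_window=right,
                    half_site_1=half1,
                    half_site_2=half2,
                    posterior_1=posterior_1,
                    posterior_2=posterior_2,
                    confidence_1=conf_1,
                    confidence_2=conf_2,
                )
            )
    hits.sort(key=lambda h: (h.start, h.spacer_length))
    return hits


HIT_COLUMNS = (
    "contig",
    "start",
    "spacer_length",
    "full_site",
    "half_site_1",
    "half_site_2",
    "posterior_1",
    "posterior_2",
    "confidence_1",
    "confidence_2",
)


def write_hit_report(hits: Sequence[ZFNHit], path: str | Path) -> None:
    """TSV hit report; ``start`` is printed 1-based, full site 5'->3' forward."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HIT_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.contig,
                    h.start + 1,
                    h.spacer_length,
                    h.full_site,
                    h.half_site_1,
                    h.half_site_2,
                    "" if h.posterior_1 is None else repr(h.posterior_1),
                    "" if h.posterior_2 is None else repr(h.posterior_2),
                    "" if h.confidence_1 is None else h.confidence_1,
                    "" if h.confidence_2 is None else h.confidence_2,
                ]
            )


def read_hit_report(path: str | Path) -> list[dict]:
    """Parse a hit report back into dicts (coordinates back to 0-based)."""
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for row in reader:
            row["start"] = int(row["start"]) - 1
            row["spacer_length"] = int(row["spacer_length"])
            for key in ("posterior_1", "posterior_2"):
                row[key] = float(row[key]) if row[key] else None
            for key in ("confidence_1", "confidence_2"):
                row[key] = int(row[key]) if row[key] else None
            rows.append(row)
    return rows
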