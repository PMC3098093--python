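"""Base-composition analytics for labeled target-site datasets.

These summaries expose the sequence biases that separate active from
inactive sites — most prominently that thymine at any within-triplet
position depresses the chance that OPEN yields a binding array:

* mean whole-site base counts per class;
* mean per-within-triplet-position base counts per class;
* a 9 x 4 percent-difference matrix (logo-style): for each of the nine
  site positions and each base, the percentage-point difference between
  the base's frequency among active sites and among all sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from zftarget.core import SiteDataset
from zftarget.encodings import BASE_ORDER, encode_base_counts, encode_positional


def _filtered(dataset: SiteDataset, label: Optional[str]) -> SiteDataset:
    if label is None:
        return dataset
    return dataset.subset(label)  # type: ignore[arg-type]


def mean_base_counts(
    dataset: SiteDataset, label: Optional[str] = None
) -> np.ndarray:
    """Mean (G, A, C, T) occurrences per site over the (filtered) dataset."""
    sub = _filtered(dataset, label)
    if not sub.sites:
        raise ValueError(f"no sites match filter {label!r}")
    counts = np.array([encode_base_counts(s).values for s in sub.sites], float)
    return counts.mean(axis=0)


def positional_mean_counts(
    dataset: SiteDataset, label: Optional[str] = None
) -> np.ndarray:
    """3 x 4 mean counts: within-triplet position (1st/2nd/3rd) by base."""
    sub = _filtered(dataset, label)
    if not sub.sites:
        raise ValueError(f"no sites match filter {label!r}")
    counts = np.array([encode_positional(s).values for s in sub.sites], float)
    return counts.mean(axis=0).reshape(3, 4)


def _position_frequencies(dataset: SiteDataset) -> np.ndarray:
    """9 x 4 base frequencies per site position (proportions, unsmoothed)."""
    freq = np.zeros((9, 4))
    for site in dataset.sites:
        for p, base in enumerate(site.sequence):
            freq[p, BASE_ORDER.index(base)] += 1
    return freq / len(dataset.sites)


def percent_difference_matrix(dataset: SiteDataset) -> np.ndarray:
    """9 x 4 matrix of 100 * (freq(base at pos | active) - freq(base at pos | all)).

    Positive entries mark bases favored at that position in active sites;
    each row sums to zero because both frequency tables are proper
    distributions over the four bases.
    """
    active = dataset.subset("active")
    if not active.sites:
        raise ValueError("dataset has no active sites")
    return 100.0 * (_position_frequencies(active) - _position_frequencies(dataset))


@dataclass
class CompositionReport:
    mean_base_counts: dict[str, np.ndarray]          # class -> (4,)
    positional_mean_counts: dict[str, np.ndarray]    # class -> (3, 4)
    percent_difference: np.ndarray                   # (9, 4)


def composition_report(dataset: SiteDataset) -> CompositionReport:
    """All three composition analyses for the active and inactive classes."""
    classes = [c for c in ("active", "inactive") if dataset.count(c) > 0]
    return CompositionReport(
        mean_base_counts={c: mean_base_counts(dataset, c) for c in classes},
        positional_mean_counts={
            c: positional_mean_counts(dataset, c) for c in classes
        },
        percent_difference=percent_difference_matrix(dataset),
    )


def write_composition(report: CompositionReport, path: str | Path) -> None:
    """Long-format TSV: analysis, class, position, base, value."""
    lines = ["analysis\tclass\tposition\tbase\tvalue"]
    for cls, vec in report.mean_base_counts.items():
        for b, v in zip(BASE_ORDER, vec):
            lines.append(f"mean_base_counts\t{cls}\t.\t{b}\t{v!r}")
    for cls, mat in report.positional_mean_counts.items():
        for g in range(3):
            for b, v in zip(BASE_ORDER, mat[g]):
                lines.append(f"positional_mean_counts\t{cls}\t{g + 1}\t{b}\t{v!r}")
    for p in range(9):
        for b, v in zip(BASE_ORDER, report.percent_difference[p]):
            lines.append(f"percent_difference\tactive_vs_all\t{p + 1}\t{b}\t{v!r}")
    Path(path).write_text("\n".join(lines) + "\n")
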