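"""Feature encodings of 9-bp target sites.

Three representations, all reading the site 5'->3':

* ``identity`` — the 9 nucleotide identities themselves (categorical).
* ``base_counts`` — 4 integers: occurrences of G, A, C, T in the site.
* ``positional_base_counts`` — 12 integers, 3 groups of 4: how often each
  base occupies the 1st, 2nd and 3rd position within a triplet subsite.

Base order is fixed as (G, A, C, T) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

from zftarget.core import SiteDataset, TargetSite

BASE_ORDER = "GACT"
EncodingKind = Literal["identity", "base_counts", "positional_base_counts"]
ENCODING_KINDS = ("identity", "base_counts", "positional_base_counts")


@dataclass(frozen=True)
class FeatureVector:
    kind: EncodingKind
    values: tuple

    def __post_init__(self) -> None:
        if self.kind == "identity":
            if len(self.values) != 9 or any(v not in BASE_ORDER for v in self.values):
                raise ValueError(f"identity vector must be 9 bases: {self.values}")
        elif self.kind == "base_counts":
            if len(self.values) != 4 or sum(self.values) != 9:
                raise ValueError(f"base counts must be 4 ints summing to 9: {self.values}")
        elif self.kind == "positional_base_counts":
            if len(self.values) != 12:
                raise ValueError(f"positional counts must have 12 entries: {self.values}")
            for g in range(3):
                group = self.values[4 * g : 4 * g + 4]
                if sum(group) != 3:
                    raise ValueError(f"triplet-position group {g + 1} must sum to 3: {group}")
        else:
            raise ValueError(f"unknown encoding kind {self.kind!r}")


def encode_identity(site: TargetSite) -> FeatureVector:
    """One categorical attribute per position, 5'->3'."""
    return FeatureVector("identity", tuple(site.sequence))


def decode_identity(vector: FeatureVector) -> str:
    if vector.kind != "identity":
        raise ValueError(f"cannot decode kind {vector.kind!r}")
    return "".join(vector.values)


def encode_base_counts(site: TargetSite) -> FeatureVector:
    """Occurrences of each base in the whole site, order (G, A, C, T)."""
    seq = site.sequence
    return FeatureVector("base_counts", tuple(seq.count(b) for b in BASE_ORDER))


def encode_positional(site: TargetSite) -> FeatureVector:
    """Occurrences of each base at each within-triplet position.

    Group ``g`` (0-based) counts how often each base is the (g+1)-th base of
    a triplet subsite, i.e. over site positions {g+1, g+4, g+7}.
    """
    seq = site.sequence
    values = []
    for g in range(3):
        column = seq[g::3]  # the g-th base of each of the 3 triplets
        values.extend(column.count(b) for b in BASE_ORDER)
    return FeatureVector("positional_base_counts", tuple(values))


_ENCODERS = {
    "identity": encode_identity,
    "base_counts": encode_base_counts,
    "positional_base_counts": encode_positional,
}


def encode_site(site: TargetSite, kind: EncodingKind) -> FeatureVector:
    try:
        encoder = _ENCODERS[kind]
    except KeyError:
        raise ValueError(f"unknown encoding kind {kind!r}") from None
    return encoder(site)


def encode_dataset(
    dataset: SiteDataset, kind: EncodingKind
) -> list[tuple[FeatureVector, str]]:
    """Encode every site, preserving order; returns (vector, label) pairs."""
    if kind not in _ENCODERS:
        raise ValueError(f"unknown encoding kind {kind!r}")
    encoder = _ENCODERS[kind]
    return [(encoder(site), site.label) for site in dataset.sites]


def attribute_names(kind: EncodingKind) -> list[str]:
    """Header names for feature-table export."""
    if kind == "identity":
        return [f"p{i}" for i in range(1, 10)]
    if kind == "base_counts":
        return [f"count_{b}" for b in BASE_ORDER]
    if kind == "positional_base_counts":
        return [f"t{g}_{b}" for g in range(1, 4) for b in BASE_ORDER]
    raise ValueError(f"unknown encoding kind {kind!r}")


def attribute_domains(kind: EncodingKind) -> list[tuple]:
    """Per-attribute value domains, used by the Naive Bayes model.

    Counts are treated as discrete categorical values of bounded arity
    (0-9 for whole-site counts, 0-3 for positional counts), not as
    continuous quantities.
    """
    if kind == "identity":
        return [tuple(BASE_ORDER)] * 9
    if kind == "base_counts":
        return [tuple(range(10))] * 4
    if kind == "positional_base_counts":
        return [tuple(range(4))] * 12
    raise ValueError(f"unknown encoding kind {kind!r}")
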