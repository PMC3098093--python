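"""Domain types and I/O: 9-bp target sites, site tables, FASTA, pool configs.

A *target site* is a 9-bp DNA sequence read 5'->3' on the strand bound by a
three-finger zinc finger array; it decomposes into three 3-bp triplet
subsites (positions 1-3, 4-6, 7-9), one per finger.  Triplet *pools* are the
per-position sets of triplets for which pre-built OPEN finger pools exist.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import yaml
from Bio import SeqIO

SITE_ALPHABET = frozenset("GACT")
FASTA_ALPHABET = frozenset("ACGTN")
SITE_LENGTH = 9
TRIPLET_LENGTH = 3

Label = Literal["active", "inactive", "unknown"]
VALID_LABELS = ("active", "inactive", "unknown")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class TargetSite:
    """A 9-bp candidate zinc finger target with an optional activity label.

    "active" means the OPEN selection yielded at least one zinc finger
    array binding this site (>= 3-fold activation in the bacterial
    two-hybrid reporter); "inactive" means no selected array bound it;
    "unknown" marks unlabeled candidates (e.g. scan output).
    """

    sequence: str
    label: Label = "unknown"
    id: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != SITE_LENGTH:
            raise ValueError(
                f"sequence length {len(self.sequence)} != {SITE_LENGTH}: "
                f"{self.sequence!r}"
            )
        for pos, base in enumerate(self.sequence, start=1):
            if base not in SITE_ALPHABET:
                raise ValueError(
                    f"invalid base {base!r} at position {pos} in {self.sequence!r}"
                )
        if self.label not in VALID_LABELS:
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def triplets(self) -> tuple[str, str, str]:
        """The three 3-bp subsites, 5'-most first."""
        s = self.sequence
        return (s[0:3], s[3:6], s[6:9])


@dataclass
class SiteDataset:
    """An ordered collection of target sites.

    Order is preserved because cross-validation folds are indexed by
    position in the list.
    """

    name: str
    sites: list[TargetSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def count(self, label: Label) -> int:
        return sum(1 for s in self.sites if s.label == label)

    def subset(self, label: Label) -> "SiteDataset":
        return SiteDataset(
            name=f"{self.name}[{label}]",
            sites=[s for s in self.sites if s.label == label],
        )

    def require_both_classes(self) -> None:
        if self.count("active") < 1 or self.count("inactive") < 1:
            raise ValueError(
                f"dataset {self.name!r} needs at least one active and one "
                f"inactive site (got {self.count('active')} active, "
                f"{self.count('inactive')} inactive)"
            )


def _validate_triplet(triplet: str) -> None:
    if len(triplet) != TRIPLET_LENGTH:
        raise ValueError(f"triplet length {len(triplet)} != 3: {triplet!r}")
    for base in triplet:
        if base not in SITE_ALPHABET:
            raise ValueError(f"invalid base {base!r} in triplet {triplet!r}")


@dataclass(frozen=True)
class PoolConfig:
    """Per-position triplet pools: which 3-bp subsites OPEN can target.

    Position 1 is the 5'-most triplet of the 9-bp site.
    """

    triplets_pos1: tuple[str, ...]
    triplets_pos2: tuple[str, ...]
    triplets_pos3: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, pool in self.pools.items():
            if not pool:
                raise ValueError(f"{name} pool is empty")
            for t in pool:
                _validate_triplet(t)
            if len(set(pool)) != len(pool):
                dupes = sorted({t for t in pool if pool.count(t) > 1})
                raise ValueError(f"duplicate triplets in {name}: {dupes}")

    @property
    def pools(self) -> dict[str, tuple[str, ...]]:
        return {
            "pos1": self.triplets_pos1,
            "pos2": self.triplets_pos2,
            "pos3": self.triplets_pos3,
        }

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (
            len(self.triplets_pos1),
            len(self.triplets_pos2),
            len(self.triplets_pos3),
        )

    @property
    def n_products(self) -> int:
        a, b, c = self.sizes
        return a * b * c


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence to be scanned (uppercased; N allowed for gaps)."""

    id: str
    sequence: str
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        for pos, base in enumerate(self.sequence, start=1):
            if base not in FASTA_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: invalid character {base!r} at "
                    f"position {pos}"
                )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    for pos, base in enumerate(seq, start=1):
        if base not in FASTA_ALPHABET:
            raise ValueError(f"invalid character {base!r} at position {pos}")
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_label(token: str, row: int) -> Label:
    token = token.strip().lower()
    if token == "" or token == "unknown":
        return "unknown"
    if token in ("active", "inactive"):
        return token  # type: ignore[return-value]
    raise ValueError(f"row {row}: unknown label token {token!r}")


def read_sites(path: str | Path, dialect: str = "auto") -> SiteDataset:
    """Read a headered TSV/CSV site table into a :class:`SiteDataset`.

    The table must have a ``sequence`` column; ``label`` and ``id`` are
    optional.  Labels are matched case-insensitively; a missing label column
    (or empty cell) yields ``unknown``.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "auto":
        header = text.splitlines()[0] if text.splitlines() else ""
        dialect = "tsv" if "\t" in header or "," not in header else "csv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    delim = "\t" if dialect == "tsv" else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None or "sequence" not in [
        f.strip().lower() for f in reader.fieldnames
    ]:
        raise ValueError(f"{path}: missing required 'sequence' column")
    fieldmap = {f.strip().lower(): f for f in reader.fieldnames}
    sites: list[TargetSite] = []
    for i, row in enumerate(reader, start=2):  # header is row 1
        seq = (row[fieldmap["sequence"]] or "").strip().upper()
        if len(seq) != SITE_LENGTH:
            raise ValueError(f"row {i}: sequence length {len(seq)} != 9")
        label = _normalize_label(row.get(fieldmap.get("label", ""), "") or "", i)
        site_id = (row.get(fieldmap.get("id", ""), "") or "").strip() or None
        try:
            sites.append(TargetSite(seq, label, site_id))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return SiteDataset(name=path.stem, sites=sites)


def write_sites(dataset: SiteDataset, path: str | Path) -> None:
    """Write a site table as headered TSV (sequence, label, id).

    Round-trips losslessly through :func:`read_sites`.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sequence", "label", "id"])
        for site in dataset.sites:
            writer.writerow([site.sequence, site.label, site.id or ""])


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file, uppercasing sequences."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        records.append(
            SequenceRecord(id=rec.id, sequence=seq, description=rec.description or None)
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_pool_config(path: str | Path) -> PoolConfig:
    """Read a YAML pool configuration with triplet lists pos1/pos2/pos3."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: pool config must be a mapping")
    pools = {}
    for key in ("pos1", "pos2", "pos3"):
        if key not in doc:
            raise ValueError(f"{path}: missing pool list {key!r}")
        raw = doc[key]
        if not isinstance(raw, list):
            raise ValueError(f"{path}: {key} must be a list of triplets")
        pools[key] = tuple(str(t).strip().upper() for t in raw)
    return PoolConfig(pools["pos1"], pools["pos2"], pools["pos3"])


def default_pool_config() -> PoolConfig:
    """The shipped placeholder pool configuration (sizes 26/21/23).

    All 16 GNN triplets plus provisional TNN choices per position; the true
    published pool identities are not public, so this file stands in for
    them with the correct list sizes only.
    """
    ref = resources.files("zftarget") / "data" / "default_pools.yaml"
    with resources.as_file(ref) as p:
        return read_pool_config(p)
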