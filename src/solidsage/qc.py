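"""Tag library quality control.

Raw SAGE tag libraries contain two artifact classes that must be removed
before mapping: tags lacking the 5' CATG anchor (products of random adaptor
ligation, uninformative for abundance) and tags whose 3' end runs into the
poly(A)+ tail of the cDNA (long terminal A runs that cannot be mapped).
Tags surviving both filters are the "potential mappable" tags.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from ._util import round_half_away
from .reference import ANCHOR, TAG_LENGTH

_VALID_CHARS = frozenset("ACGTN")

#: terminal A runs longer than this are treated as poly(A) runoff
MAX_TRAILING_A = 10


@dataclass
class RawTagLibrary:
    """A multiset of 27-base tags from one sequencing library."""

    sample: str
    replicate: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate number must be >= 1")
        for tag, count in self.counts.items():
            if len(tag) != TAG_LENGTH:
                raise ValueError(
                    f"tag {tag!r} has length {len(tag)}, expected {TAG_LENGTH}"
                )
            if set(tag) - _VALID_CHARS:
                raise ValueError(f"tag {tag!r} contains non-nucleotide characters")
            if count < 1:
                raise ValueError(f"tag {tag!r} has non-positive count {count}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def name(self) -> str:
        return f"{self.sample}:{self.replicate}"

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[str], sample: str = "sample", replicate: int = 1
    ) -> "RawTagLibrary":
        return cls(sample, replicate, dict(Counter(sequences)))

    @classmethod
    def from_tsv(
        cls, path: str | Path, sample: str = "sample", replicate: int = 1
    ) -> "RawTagLibrary":
        """Read a library from TSV (tag<TAB>count) or one-tag-per-line text."""
        counts: Counter[str] = Counter()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("tag", "tag_seq"):
                    continue
                if len(parts) == 1:
                    counts[parts[0]] += 1
                else:
                    counts[parts[0]] += int(parts[1])
        return cls(sample, replicate, dict(counts))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["tag", "count"])
            for tag in sorted(self.counts):
                writer.writerow([tag, self.counts[tag]])


@dataclass
class QCReport:
    """Per-library filtering accounting (tag-count units).

    Invariants: ``total = with_anchor + removed_no_anchor`` and
    ``with_anchor = after_polya + removed_polya``.  ``after_polya`` is the
    potential-mappable count.  Tags containing N cannot be mapped reliably
    and are tallied inside ``removed_no_anchor`` (sub-count
    ``removed_ambiguous``) unless they end in a disqualifying A run.
    """

    sample: str
    replicate: int
    total: int
    with_anchor: int
    after_polya: int
    removed_no_anchor: int
    removed_polya: int
    removed_ambiguous: int = 0

    def __post_init__(self) -> None:
        if self.total != self.with_anchor + self.removed_no_anchor:
            raise ValueError("QC accounting violated: anchor stage does not conserve")
        if self.with_anchor != self.after_polya + self.removed_polya:
            raise ValueError("QC accounting violated: poly-A stage does not conserve")


def has_anchor(tag: str) -> bool:
    """True iff the tag begins with the NlaIII cleavage site CATG.

    The filter is a strict prefix test: a CATG elsewhere in the tag does not
    rescue it.
    """
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} bases, got {len(tag)}")
    return tag.startswith(ANCHOR)


def trailing_a_run(tag: str) -> int:
    """Length of the maximal terminal run of A at the 3' end."""
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} bases, got {len(tag)}")
    n = len(tag)
    return n - len(tag.rstrip("A"))


def filter_library(lib: RawTagLibrary) -> tuple[RawTagLibrary, QCReport]:
    """Apply both QC filters; keep tags with the anchor and <=10 terminal As."""
    kept: dict[str, int] = {}
    removed_no_anchor = removed_polya = removed_ambiguous = 0
    for tag, count in lib.counts.items():
        if not has_anchor(tag):
            removed_no_anchor += count
        elif trailing_a_run(tag) > MAX_TRAILING_A:
            removed_polya += count
        elif "N" in tag:
            removed_no_anchor += count
            removed_ambiguous += count
        else:
            kept[tag] = count
    total = lib.total
    report = QCReport(
        sample=lib.sample,
        replicate=lib.replicate,
        total=total,
        with_anchor=total - removed_no_anchor,
        after_polya=total - removed_no_anchor - removed_polya,
        removed_no_anchor=removed_no_anchor,
        removed_polya=removed_polya,
        removed_ambiguous=removed_ambiguous,
    )
    return RawTagLibrary(lib.sample, lib.replicate, kept), report


def mapped_fraction(
    mapped_count: int, potential_mappable: int, decimals: int = 0
) -> float | int:
    """Mapped tags as a percent of potential-mappable tags.

    Report convention: integer percent for the plant partition, one decimal
    for the fungal partition (``decimals=1``).
    """
    if potential_mappable <= 0:
        raise ValueError("potential_mappable must be positive")
    return round_half_away(100.0 * mapped_count / potential_mappable, decimals)


def write_qc_reports(reports: Iterable[QCReport], path: str | Path) -> None:
    """Write a QC accounting table with one row per library."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "sample",
                "replicate",
                "total_tags",
                "tags_with_nlaiii_site",
                "tags_after_polya_removal",
                "removed_no_anchor",
                "removed_polya",
            ]
        )
        for r in reports:
            writer.writerow(
                [
                    r.sample,
                    r.replicate,
                    r.total,
                    r.with_anchor,
                    r.after_polya,
                    r.removed_no_anchor,
                    r.removed_polya,
                ]
            )
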