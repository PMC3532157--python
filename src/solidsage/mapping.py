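"""Strand-aware, mismatch-tolerant tag mapping against a two-part reference.

Matching is anchored: a tag can only align where the reference carries a
CATG site with at least 23 downstream bases, on either strand.  The anchor
must match exactly; the mismatch budget (default 2) applies to the 23
non-anchor bases.  Each distinct tag is assigned its minimal-mismatch hits
and partitioned as plant, fungal, ambiguous (equal best distance in both
partitions) or unmapped.  Quantification is per distinct tag sequence
("one tag = one transcript"): a tag hitting several transcripts within one
partition keeps a single count, annotated with all best hits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._util import revcomp
from .qc import QCReport, RawTagLibrary, mapped_fraction
from .reference import ANCHOR, TAG_LENGTH, ReferenceSet, Transcript, catg_positions

SENSE = "sense"
ANTISENSE = "antisense"
STRAND_UNKNOWN = "unknown"

PARTITIONS = ("plant", "fungal", "ambiguous", "unmapped")

DEFAULT_BUDGET = 2

# base encoding for vectorized Hamming distance; N encoded so that it
# mismatches every tag base
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _ENCODE[buf].reshape(len(seqs), -1)


@dataclass(frozen=True)
class MappingHit:
    """Placement of a tag at one anchored reference site.

    ``position`` is the 0-based anchor offset on the searched strand
    (the transcript as given for sense hits, its reverse complement for
    antisense hits).
    """

    tag_seq: str
    transcript_id: str
    position: int
    strand: str
    mismatches: int
    origin: str


@dataclass
class TagAssignment:
    """Best-distance partition assignment for one distinct tag."""

    tag: str
    partition: str
    hits: list[MappingHit]
    best_mismatches: int | None


def candidate_sites(transcript: Transcript) -> list[tuple[int, str]]:
    """All anchored candidate sites on both strands of a transcript.

    Returns (0-based anchor offset, strand) pairs for every CATG occurrence
    with at least 23 downstream bases, on the given sequence (sense) and on
    its reverse complement (antisense).
    """
    sites: list[tuple[int, str]] = []
    for strand, seq in ((SENSE, transcript.seq), (ANTISENSE, revcomp(transcript.seq))):
        for pos in catg_positions(seq):
            if pos + TAG_LENGTH <= len(seq):
                sites.append((pos, strand))
    return sites


def match_tag(tag: str, site_window: str, budget: int = DEFAULT_BUDGET) -> int | None:
    """Mismatch count between a tag and an anchored window, or None over budget.

    The anchor is exact by construction; the Hamming distance is taken over
    the 23 non-anchor positions.
    """
    if len(tag) != TAG_LENGTH or len(site_window) != TAG_LENGTH:
        raise ValueError("tag and window must both be 27 bases")
    if not site_window.startswith(ANCHOR):
        raise ValueError("site window must begin with CATG")
    mismatches = sum(
        a != b for a, b in zip(tag[len(ANCHOR) :], site_window[len(ANCHOR) :])
    )
    return mismatches if mismatches <= budget else None


class ReferenceIndex:
    """Anchored-window index over both strands of a reference set.

    Holds every candidate 27-mer window (as encoded 23-base suffixes, the
    anchor being shared) together with its transcript, position, strand and
    origin, ready for vectorized Hamming search.
    """

    def __init__(self, refset: ReferenceSet):
        self.refset = refset
        suffixes: list[str] = []
        meta: list[tuple[str, int, str, str, bool]] = []
        for t in refset:
            for pos, strand in candidate_sites(t):
                seq = t.seq if strand == SENSE else revcomp(t.seq)
                window = seq[pos : pos + TAG_LENGTH]
                suffixes.append(window[len(ANCHOR) :])
                meta.append((t.id, pos, strand, t.origin, t.oriented))
        self._suffixes = _encode(suffixes)
        self._meta = meta
        self._origin_is_plant = np.array(
            [m[3] == "plant" for m in meta], dtype=bool
        )

    @property
    def n_sites(self) -> int:
        return len(self._meta)

    def hit(self, tag: str, site_index: int, mismatches: int) -> MappingHit:
        tid, pos, strand, origin, oriented = self._meta[site_index]
        return MappingHit(
            tag_seq=tag,
            transcript_id=tid,
            position=pos,
            strand=strand if oriented else STRAND_UNKNOWN,
            mismatches=mismatches,
            origin=origin,
        )


def map_tags(
    tags: Sequence[str],
    refset: ReferenceSet | ReferenceIndex,
    budget: int = DEFAULT_BUDGET,
    block_size: int = 512,
) -> dict[str, TagAssignment]:
    """Map distinct QC-passed tags, returning best-hit assignments.

    The result is independent of tag input order: each tag is assigned
    purely from its own distance profile against the index.
    """
    index = refset if isinstance(refset, ReferenceIndex) else ReferenceIndex(refset)
    for tag in tags:
        if len(tag) != TAG_LENGTH or not tag.startswith(ANCHOR):
            raise ValueError(f"tag {tag!r} is not a QC-passed anchored 27-mer")

    assignments: dict[str, TagAssignment] = {}
    tag_list = list(dict.fromkeys(tags))
    if index.n_sites == 0:
        for tag in tag_list:
            assignments[tag] = TagAssignment(tag, "unmapped", [], None)
        return assignments

    encoded = _encode([t[len(ANCHOR) :] for t in tag_list])
    windows = index._suffixes
    plant_mask = index._origin_is_plant
    for start in range(0, len(tag_list), block_size):
        block = encoded[start : start + block_size]
        # (b, W) pairwise Hamming distance over the 23 non-anchor bases
        dist = (block[:, None, :] != windows[None, :, :]).sum(axis=2, dtype=np.int16)
        for i in range(block.shape[0]):
            tag = tag_list[start + i]
            row = dist[i]
            best = int(row.min())
            if best > budget:
                assignments[tag] = TagAssignment(tag, "unmapped", [], None)
                continue
            best_idx = np.flatnonzero(row == best)
            hits = [index.hit(tag, int(j), best) for j in best_idx]
            any_plant = bool(plant_mask[best_idx].any())
            any_fungal = bool((~plant_mask[best_idx]).any())
            if any_plant and any_fungal:
                partition = "ambiguous"
            elif any_plant:
                partition = "plant"
            else:
                partition = "fungal"
            assignments[tag] = TagAssignment(tag, partition, hits, best)
    return assignments


@dataclass
class MappingTable:
    """Per-library mapping outcome: assignments plus partition tallies.

    Tallies are in tag-count units and sum to the QC-passed library total.
    """

    sample: str
    replicate: int
    assignments: dict[str, TagAssignment]
    tallies: dict[str, int]

    @property
    def name(self) -> str:
        return f"{self.sample}:{self.replicate}"

    def partition_counts(self, lib: RawTagLibrary, partition: str) -> dict[str, int]:
        """Counts of this library's tags assigned to one partition."""
        return {
            tag: count
            for tag, count in lib.counts.items()
            if self.assignments[tag].partition == partition
        }


def tabulate(
    assignments: dict[str, TagAssignment], lib: RawTagLibrary
) -> MappingTable:
    """Build a MappingTable for one library from shared tag assignments."""
    tallies = {
        "plant_mapped": 0,
        "fungal_mapped": 0,
        "ambiguous": 0,
        "unmapped": 0,
    }
    key = {
        "plant": "plant_mapped",
        "fungal": "fungal_mapped",
        "ambiguous": "ambiguous",
        "unmapped": "unmapped",
    }
    for tag, count in lib.counts.items():
        tallies[key[assignments[tag].partition]] += count
    return MappingTable(lib.sample, lib.replicate, assignments, tallies)


def map_library(
    lib: RawTagLibrary,
    refset: ReferenceSet | ReferenceIndex,
    budget: int = DEFAULT_BUDGET,
) -> MappingTable:
    """Map one QC-passed library against the two-part reference."""
    assignments = map_tags(list(lib.counts), refset, budget=budget)
    return tabulate(assignments, lib)


def mapping_rates(table: MappingTable, qc_report: QCReport) -> dict[str, object]:
    """Plant and fungal mapped tags as percent of potential mappable."""
    if qc_report.after_polya != sum(table.tallies.values()):
        raise ValueError(
            "mapping tallies do not conserve the QC-passed total for "
            f"{table.name}: {sum(table.tallies.values())} vs {qc_report.after_polya}"
        )
    return {
        "sample": table.sample,
        "replicate": table.replicate,
        "plant_mapped": table.tallies["plant_mapped"],
        "plant_pct": mapped_fraction(
            table.tallies["plant_mapped"], qc_report.after_polya
        ),
        "fungal_mapped": table.tallies["fungal_mapped"],
        "fungal_pct": mapped_fraction(
            table.tallies["fungal_mapped"], qc_report.after_polya, decimals=1
        ),
    }


def write_hits(
    tables: Iterable[MappingTable] | MappingTable, path: str | Path
) -> None:
    """Write per-tag best hits as TSV (1-based positions, report convention)."""
    if isinstance(tables, MappingTable):
        tables = [tables]
    seen: set[str] = set()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["tag", "transcript_id", "position_1based", "strand", "mismatches", "origin", "partition"]
        )
        for table in tables:
            for tag, assignment in table.assignments.items():
                if tag in seen:
                    continue
                seen.add(tag)
                for hit in assignment.hits:
                    writer.writerow(
                        [
                            tag,
                            hit.transcript_id,
                            hit.position + 1,
                            hit.strand,
                            hit.mismatches,
                            hit.origin,
                            assignment.partition,
                        ]
                    )
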