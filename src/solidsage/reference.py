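"""Reference transcript sets and the in-silico NlaIII digest.

SAGE-style tag counting represents each transcript by a single fixed-length
tag anchored at the most 3' NlaIII recognition site (5'-CATG-3').  Tags here
are 27 bp: the 4-base anchor plus 23 downstream bases.  This module loads
reference transcript FASTA files, labels each record with its origin
(plant host or fungal endophyte), and computes the canonical tag each
transcript is expected to produce.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO

TAG_LENGTH = 27
ANCHOR = "CATG"
DOWNSTREAM = TAG_LENGTH - len(ANCHOR)  # 23 bases after the anchor

ORIGINS = ("plant", "fungal")
_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class Transcript:
    """An oriented reference sequence with an origin label.

    ``oriented`` records whether the 5'->3' mRNA orientation is known; only
    oriented references support antisense calls downstream.
    """

    id: str
    seq: str
    origin: str
    oriented: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        if self.origin not in ORIGINS:
            raise ValueError(
                f"transcript {self.id!r}: origin must be one of {ORIGINS}, "
                f"got {self.origin!r}"
            )
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """A collection of transcripts forming the two-part mapping database."""

    transcripts: list[Transcript]
    provenance: str = ""
    _by_id: dict[str, Transcript] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, Transcript] = {}
        for t in self.transcripts:
            if t.id in by_id:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            by_id[t.id] = t
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def get(self, transcript_id: str) -> Transcript:
        return self._by_id[transcript_id]

    def count_by_origin(self) -> dict[str, int]:
        counts = {origin: 0 for origin in ORIGINS}
        for t in self.transcripts:
            counts[t.origin] += 1
        return counts

    @staticmethod
    def merge(*sets: "ReferenceSet") -> "ReferenceSet":
        transcripts = [t for s in sets for t in s.transcripts]
        provenance = " + ".join(s.provenance for s in sets if s.provenance)
        return ReferenceSet(transcripts, provenance=provenance)


@dataclass(frozen=True)
class CanonicalTag:
    """The 27-mer a transcript contributes to the tag catalog.

    ``tag_start`` is the 0-based offset of the CATG anchor; it is the most
    3' occurrence with at least 23 downstream bases and no ambiguity codes
    inside the window.
    """

    transcript_id: str
    tag_seq: str
    tag_start: int

    def __post_init__(self) -> None:
        if len(self.tag_seq) != TAG_LENGTH:
            raise ValueError(f"tag must be {TAG_LENGTH} bases, got {len(self.tag_seq)}")
        if not self.tag_seq.startswith(ANCHOR):
            raise ValueError(f"tag must begin with {ANCHOR}: {self.tag_seq}")


def load_fasta(path: str | Path, origin: str, oriented: bool = True) -> ReferenceSet:
    """Load a multi-FASTA of reference transcripts with a single origin label.

    Sequences are uppercased and U is converted to T.  Empty files,
    duplicate ids and non-nucleotide characters raise ``ValueError`` naming
    the offending record.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        transcripts.append(Transcript(record.id, seq, origin, oriented=oriented))
    if not transcripts:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceSet(transcripts, provenance=f"{path.name} ({origin})")


def extract_tag(transcript: Transcript) -> Optional[CanonicalTag]:
    """Extract the canonical 27-bp tag anchored at the most 3' NlaIII site.

    Returns ``None`` when the transcript has no usable site.  If the most 3'
    CATG has fewer than 23 downstream bases (possible for truncated
    references; intact cDNAs carry a poly-A tail that supplies downstream
    sequence), the next eligible CATG upstream is used.  Windows containing
    N are skipped the same way, since tags are observed sequences and
    ambiguity codes cannot be counted.
    """
    seq = transcript.seq
    pos = seq.rfind(ANCHOR)
    while pos != -1:
        window = seq[pos : pos + TAG_LENGTH]
        if len(window) == TAG_LENGTH and "N" not in window:
            return CanonicalTag(transcript.id, window, pos)
        pos = seq.rfind(ANCHOR, 0, pos)
    return None


@dataclass
class TagCatalog:
    """Canonical tags per transcript plus the transcripts that yielded none."""

    tags: dict[str, CanonicalTag]
    tagless: list[str]

    def __len__(self) -> int:
        return len(self.tags)

    @property
    def fraction_tagless(self) -> float:
        total = len(self.tags) + len(self.tagless)
        return len(self.tagless) / total if total else 0.0

    def to_tsv(self, path: str | Path, tagless_path: str | Path | None = None) -> None:
        """Write the catalog (1-based anchor coordinates, report convention)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["transcript_id", "tag_seq", "tag_start_1based"])
            for tag in self.tags.values():
                writer.writerow([tag.transcript_id, tag.tag_seq, tag.tag_start + 1])
        if tagless_path is not None:
            with open(tagless_path, "w") as fh:
                for tid in self.tagless:
                    fh.write(tid + "\n")


def digest_reference(refset: ReferenceSet) -> TagCatalog:
    """Run the in-silico NlaIII digest over a reference set."""
    if len(refset) == 0:
        raise ValueError("reference set is empty")
    tags: dict[str, CanonicalTag] = {}
    tagless: list[str] = []
    for transcript in refset:
        tag = extract_tag(transcript)
        if tag is None:
            tagless.append(transcript.id)
        else:
            tags[transcript.id] = tag
    return TagCatalog(tags, tagless)


def reference_summary(contig_count: int, singleton_count: int) -> int:
    """Unigene count: non-redundant contigs plus singletons."""
    if contig_count < 0 or singleton_count < 0:
        raise ValueError("counts must be non-negative")
    return contig_count + singleton_count


def catg_positions(seq: str) -> list[int]:
    """All 0-based CATG occurrence starts in ``seq`` (non-overlapping by nature)."""
    positions = []
    pos = seq.find(ANCHOR)
    while pos != -1:
        positions.append(pos)
        pos = seq.find(ANCHOR, pos + 1)
    return positions
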