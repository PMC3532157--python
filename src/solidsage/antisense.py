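"""Antisense transcript detection from tag directionality.

Because SAGE tags are strand-specific, a tag that maps to the reverse
complement of an oriented reference transcript is evidence of antisense
transcription.  For each transcript with any antisense hit this module
aggregates sense and antisense abundances (mean normalized values across
replicates) and expresses their relation as a 1:N ratio, N being the
rounded sense/antisense quotient.  The antisense tag need not be the
reverse complement of the sense canonical tag: the two strands generally
anchor at different CATG sites, so pairing is per transcript.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._util import round_half_away
from .mapping import ANTISENSE, SENSE, TagAssignment


@dataclass
class SenseAntisensePair:
    """Aggregated sense/antisense abundance for one transcript."""

    transcript_id: str
    sense_abundance: float
    antisense_abundance: float
    ratio_n: int | None
    antisense_only: bool

    @property
    def ratio_label(self) -> str:
        return f"1:{self.ratio_n}" if self.ratio_n is not None else "antisense-only"


def ratio(sense: float, antisense: float) -> int:
    """N in the 1:N sense:antisense abundance ratio (ties away from zero)."""
    if antisense <= 0:
        raise ValueError("antisense abundance must be positive")
    return round_half_away(sense / antisense)


def pair_tags(
    assignments: dict[str, TagAssignment],
    mean_abundance: pd.Series,
    partition: str | None = None,
) -> list[SenseAntisensePair]:
    """Pair sense and antisense tag abundances per transcript.

    ``mean_abundance`` maps tag -> mean normalized abundance (TMM or
    percent); only tags present in it contribute.  A tag whose best hits
    touch several transcripts contributes its full abundance to each (counts
    are never split).  Transcripts with antisense but no sense signal are
    emitted flagged ``antisense_only``.  Hits with unknown strand
    (non-oriented references) are ignored.
    """
    sense_by_transcript: dict[str, float] = {}
    anti_by_transcript: dict[str, float] = {}
    for tag, abundance in mean_abundance.items():
        assignment = assignments.get(tag)
        if assignment is None or not assignment.hits:
            continue
        if partition is not None and assignment.partition != partition:
            continue
        for strand, bucket in ((SENSE, sense_by_transcript), (ANTISENSE, anti_by_transcript)):
            for tid in {h.transcript_id for h in assignment.hits if h.strand == strand}:
                bucket[tid] = bucket.get(tid, 0.0) + float(abundance)

    pairs = []
    for tid in sorted(anti_by_transcript):
        anti = anti_by_transcript[tid]
        if anti <= 0:
            continue
        sense = sense_by_transcript.get(tid, 0.0)
        pairs.append(
            SenseAntisensePair(
                transcript_id=tid,
                sense_abundance=sense,
                antisense_abundance=anti,
                ratio_n=ratio(sense, anti) if sense > 0 else None,
                antisense_only=sense == 0.0,
            )
        )
    pairs.sort(key=lambda p: p.antisense_abundance, reverse=True)
    return pairs


def write_pairs(pairs: list[SenseAntisensePair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["transcript_id", "sense_abundance", "antisense_abundance", "ratio"]
        )
        for p in pairs:
            writer.writerow(
                [
                    p.transcript_id,
                    f"{p.sense_abundance:.6g}",
                    f"{p.antisense_abundance:.6g}",
                    p.ratio_label,
                ]
            )
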