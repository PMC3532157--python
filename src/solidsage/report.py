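"""Run-level summary tables and consistency checks.

Assembles the per-replicate QC accounting, reference composition, DE
summary (with optional category table), fungal top-N ranking and antisense
table into a TSV bundle plus one human-readable text summary.  Every
derived number is recomputed from the upstream artifacts at build time and
cross-checked; violations raise instead of silently drifting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .antisense import write_pairs
from .qc import mapped_fraction
from .quantify import category_summary
from .workflow import StudyResult

logger = logging.getLogger(__name__)


class ReportConsistencyError(RuntimeError):
    """An internal cross-check between report tables failed."""


@dataclass
class RunReport:
    """The assembled report tables for one pipeline run."""

    qc_table: pd.DataFrame
    reference_table: pd.DataFrame
    de_table: pd.DataFrame
    category_table: pd.DataFrame | None
    fungal_top_table: pd.DataFrame
    antisense_table: pd.DataFrame
    summary_text: str


def _check(condition: bool, message: str) -> None:
    logger.info("consistency check: %s -> %s", message, "ok" if condition else "FAIL")
    if not condition:
        raise ReportConsistencyError(message)


def build_report(
    result: StudyResult,
    categories: pd.DataFrame | None = None,
    top_n: int = 20,
) -> RunReport:
    """Assemble all summary tables from a StudyResult.

    ``categories`` optionally maps DE tags to annotation labels (columns
    ``tag`` and ``category``); directions are derived from the signed fold
    changes of the significant tags.
    """
    qc_rows = []
    for report, table in zip(result.qc_reports, result.mapping_tables):
        _check(
            report.total == report.with_anchor + report.removed_no_anchor,
            f"QC anchor-stage conservation for {report.sample}:{report.replicate}",
        )
        _check(
            report.with_anchor == report.after_polya + report.removed_polya,
            f"QC poly-A-stage conservation for {report.sample}:{report.replicate}",
        )
        _check(
            sum(table.tallies.values()) == report.after_polya,
            f"mapping partition conservation for {table.name}",
        )
        plant_pct = mapped_fraction(table.tallies["plant_mapped"], report.after_polya)
        fungal_pct = mapped_fraction(
            table.tallies["fungal_mapped"], report.after_polya, decimals=1
        )
        qc_rows.append(
            {
                "sample": report.sample,
                "replicate": report.replicate,
                "total_tags": report.total,
                "tags_with_nlaiii_site": report.with_anchor,
                "tags_after_polya_removal": report.after_polya,
                "plant_mapped_tags": table.tallies["plant_mapped"],
                "plant_mapped_pct": plant_pct,
                "fungal_mapped_tags": table.tallies["fungal_mapped"],
                "fungal_mapped_pct": fungal_pct,
                "ambiguous_tags": table.tallies["ambiguous"],
                "unmapped_tags": table.tallies["unmapped"],
            }
        )
    qc_table = pd.DataFrame(qc_rows)

    origin_counts = result.refset.count_by_origin()
    reference_table = pd.DataFrame(
        [
            {"origin": "plant", "transcripts": origin_counts["plant"]},
            {"origin": "fungal", "transcripts": origin_counts["fungal"]},
            {"origin": "total", "transcripts": len(result.refset)},
        ]
    )
    _check(
        origin_counts["plant"] + origin_counts["fungal"] == len(result.refset),
        "reference partition counts sum to total",
    )

    de_table = result.de_results.reset_index()
    significant = de_table[de_table["significant"]]

    category_table = None
    if categories is not None:
        labelled = significant[["tag", "fold_change"]].merge(
            categories, on="tag", how="left"
        )
        labelled["direction"] = ["up" if f > 0 else "down" for f in labelled["fold_change"]]
        category_table = category_summary(labelled[["tag", "category", "direction"]])

    fungal_top_table = result.rank_result.top(top_n).reset_index(names="tag")

    antisense_rows = [
        {
            "transcript_id": p.transcript_id,
            "sense_abundance": p.sense_abundance,
            "antisense_abundance": p.antisense_abundance,
            "ratio": p.ratio_label,
        }
        for p in result.antisense_pairs
    ]
    antisense_table = pd.DataFrame(
        antisense_rows,
        columns=["transcript_id", "sense_abundance", "antisense_abundance", "ratio"],
    )

    n_sig = len(significant)
    n_up = int((significant["fold_change"] > 0).sum())
    n_down = n_sig - n_up
    lines = [
        "SOLiD-SAGE pipeline run summary",
        "===============================",
        "",
        f"Libraries analyzed: {len(result.qc_reports)}",
        f"Reference: {origin_counts['plant']} plant + {origin_counts['fungal']} fungal transcripts",
        "",
        "Per-replicate accounting (total / with NlaIII site / potential mappable / plant% / fungal%):",
    ]
    for row in qc_rows:
        lines.append(
            f"  {row['sample']} rep {row['replicate']}: "
            f"{row['total_tags']:,} / {row['tags_with_nlaiii_site']:,} / "
            f"{row['tags_after_polya_removal']:,} / {row['plant_mapped_pct']}% / "
            f"{row['fungal_mapped_pct']}%"
        )
    lines += [
        "",
        f"Differentially expressed plant tags (P<0.05): {n_sig} "
        f"({n_up} up-regulated, {n_down} down-regulated in the infected sample)",
        f"Abundant fungal tags (>= {result.rank_result.threshold}% of fungal mapped): "
        f"{result.rank_result.count}, together {result.rank_result.total_share:.1f}% "
        f"of fungal mapped tags",
        f"Transcripts with antisense evidence: {len(result.antisense_pairs)}",
    ]
    summary_text = "\n".join(lines) + "\n"

    return RunReport(
        qc_table=qc_table,
        reference_table=reference_table,
        de_table=de_table,
        category_table=category_table,
        fungal_top_table=fungal_top_table,
        antisense_table=antisense_table,
        summary_text=summary_text,
    )


def write_report(report: RunReport, result: StudyResult, outdir: str | Path) -> None:
    """Write the TSV bundle and the text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.qc_table.to_csv(outdir / "qc_table.tsv", sep="\t", index=False)
    report.reference_table.to_csv(outdir / "reference_table.tsv", sep="\t", index=False)
    report.de_table.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    if report.category_table is not None:
        report.category_table.to_csv(outdir / "category_summary.tsv", sep="\t", index=False)
    report.fungal_top_table.to_csv(outdir / "fungal_top.tsv", sep="\t", index=False)
    report.antisense_table.to_csv(outdir / "antisense.tsv", sep="\t", index=False)
    write_pairs(result.antisense_pairs, outdir / "antisense_pairs.tsv")
    (outdir / "summary.txt").write_text(report.summary_text)
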