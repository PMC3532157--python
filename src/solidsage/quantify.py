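"""Normalization, differential expression and summary arithmetic.

Plant tag counts are normalized to tags per million mapped tags (TMM in the
SAGE sense: simple per-million library scaling, not the trimmed-mean-of-M
normalization of count-based DE packages).  Fungal counts are normalized to
percent of fungal mapped tags, which suits the small fungal partition.
Differential expression between the endophyte-free (E-) and infected (E+)
samples uses an unpaired two-sided pooled-variance t-test on normalized
values across biological triplicates, at raw P<0.05 with no multiple-testing
correction by default (a correction option exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away
from .mapping import MappingTable
from .qc import RawTagLibrary

DEFAULT_ALPHA = 0.05


def normalize_tpm(count: float, mapped_total: float) -> float:
    """Tags per million mapped tags."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    return 1e6 * count / mapped_total


def percent_of_mapped(count: float, partition_total: float) -> float:
    """Count as a percent of the partition's mapped tags."""
    if partition_total <= 0:
        raise ValueError("partition_total must be positive")
    return 100.0 * count / partition_total


@dataclass
class ExpressionMatrix:
    """Raw and normalized per-replicate values for one partition.

    Rows are distinct tags, columns are replicate libraries named
    ``sample:replicate``.  ``mapped_totals`` holds the per-replicate
    partition totals used as normalization denominators; the other
    partition and ambiguous tags are excluded from them.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame
    mapped_totals: pd.Series
    unit: str  # "tpm" or "percent"

    def group_columns(self, sample: str) -> list[str]:
        return [c for c in self.counts.columns if c.split(":")[0] == sample]

    def mean_normalized(self, sample: str | None = None) -> pd.Series:
        cols = self.group_columns(sample) if sample else list(self.normalized.columns)
        return self.normalized[cols].mean(axis=1)


def build_expression(
    tables: Sequence[MappingTable],
    libs: Sequence[RawTagLibrary],
    partition: str,
) -> ExpressionMatrix:
    """Assemble the expression matrix for one partition across libraries.

    ``partition`` is "plant" (normalized to TMM) or "fungal" (normalized to
    percent of fungal mapped tags).
    """
    if partition not in ("plant", "fungal"):
        raise ValueError("partition must be 'plant' or 'fungal'")
    tally_key = f"{partition}_mapped"
    columns: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for table, lib in zip(tables, libs):
        if (table.sample, table.replicate) != (lib.sample, lib.replicate):
            raise ValueError("mapping tables and libraries are misaligned")
        columns[table.name] = table.partition_counts(lib, partition)
        totals[table.name] = table.tallies[tally_key]
    counts = pd.DataFrame(columns).fillna(0).astype(int)
    counts = counts.sort_index()
    mapped_totals = pd.Series(totals, dtype=float)
    if partition == "plant":
        normalized = counts / mapped_totals * 1e6
        unit = "tpm"
    else:
        normalized = counts / mapped_totals * 100.0
        unit = "percent"
    return ExpressionMatrix(counts, normalized, mapped_totals, unit)


def unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided unpaired Student's t-test (pooled variance by default).

    Degenerate inputs: if both groups have zero variance and equal means the
    result is (0, 1); if both have zero variance and unequal means the
    difference is exact under the model, returned as (signed inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = b.mean() - a.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff)) * float("inf"), 0.0
    na, nb = len(a), len(b)
    if equal_var:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def fold_change(mean_ctrl: float, mean_trt: float) -> float:
    """Signed fold change of E+ (treated) relative to E- (control).

    +R means R-fold up in the treated sample, -R means R-fold down; equal
    means give +1.  Zero-mean sides must be floored by the caller (see
    ``de_scan``); both-zero input is undefined.
    """
    if mean_ctrl < 0 or mean_trt < 0:
        raise ValueError("means must be non-negative")
    if mean_ctrl == 0 and mean_trt == 0:
        raise ValueError("fold change undefined when both means are zero")
    if mean_ctrl == 0 or mean_trt == 0:
        raise ValueError("zero-mean side must be floored before fold_change")
    if mean_trt >= mean_ctrl:
        return mean_trt / mean_ctrl
    return -mean_ctrl / mean_trt


def de_scan(
    matrix: ExpressionMatrix,
    ctrl_sample: str,
    trt_sample: str,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-tag t-tests on normalized values between two samples.

    Returns a DataFrame indexed by tag with group means, signed fold change,
    t, p-value and a significance flag, sorted by p.  Zero group means are
    replaced by half the smallest nonzero normalized value in the matrix
    (pseudo-floor, flagged in ``floored``) before the fold change.  With
    ``correction="bonferroni"`` the flag uses Bonferroni-adjusted p-values;
    the default is raw P<alpha.
    """
    ctrl_cols = matrix.group_columns(ctrl_sample)
    trt_cols = matrix.group_columns(trt_sample)
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need at least 2 replicates per sample")
    ctrl = matrix.normalized[ctrl_cols].to_numpy()
    trt = matrix.normalized[trt_cols].to_numpy()
    nonzero = matrix.normalized.to_numpy()
    nonzero = nonzero[nonzero > 0]
    floor = 0.5 * nonzero.min() if nonzero.size else np.nan

    rows = []
    for i, tag in enumerate(matrix.normalized.index):
        a, b = ctrl[i], trt[i]
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if mean_a == 0.0 and mean_b == 0.0:
            continue  # untestable: tag absent from both groups
        t, p = unpaired_t(a, b, equal_var=equal_var)
        fa = mean_a if mean_a > 0 else floor
        fb = mean_b if mean_b > 0 else floor
        rows.append(
            {
                "tag": tag,
                "mean_ctrl": mean_a,
                "mean_trt": mean_b,
                "fold_change": fold_change(fa, fb),
                "t": t,
                "p_value": p,
                "floored": mean_a == 0.0 or mean_b == 0.0,
                "degenerate": not np.isfinite(t),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "tag",
            "mean_ctrl",
            "mean_trt",
            "fold_change",
            "t",
            "p_value",
            "floored",
            "degenerate",
        ],
    ).set_index("tag")
    if correction == "bonferroni":
        adjusted = np.minimum(result["p_value"] * len(result), 1.0)
        result["significant"] = adjusted < alpha
    elif correction is None:
        result["significant"] = result["p_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return result.sort_values("p_value")


@dataclass
class RankResult:
    """Abundant-tag ranking: tags at or above the abundance threshold."""

    table: pd.DataFrame  # columns: mean_percent, cumulative_percent
    threshold: float

    @property
    def count(self) -> int:
        return len(self.table)

    @property
    def total_share(self) -> float:
        return float(self.table["mean_percent"].sum())

    def top(self, n: int) -> pd.DataFrame:
        return self.table.head(n)


def abundance_rank(mean_percents: pd.Series, threshold: float = 0.01) -> RankResult:
    """Rank tags by mean percent-of-mapped abundance.

    Keeps tags whose mean percent is at or above ``threshold`` (default
    0.01% of the fungal mapped tags), in descending order, with the
    cumulative share.
    """
    kept = mean_percents[mean_percents >= threshold].sort_values(ascending=False)
    table = pd.DataFrame(
        {
            "mean_percent": kept,
            "cumulative_percent": kept.cumsum(),
        }
    )
    return RankResult(table, threshold)


def gene_capture(unique_tags: int, gene_count: int) -> int:
    """Percent of annotated genes with at least one mapped tag."""
    if gene_count <= 0:
        raise ValueError("gene_count must be positive")
    return round_half_away(100.0 * unique_tags / gene_count)


def gene_content(base_genes: int, ploidy_factor: int) -> int:
    """Crude gene-content estimate: diploid relative's gene count x ploidy."""
    if base_genes <= 0 or ploidy_factor <= 0:
        raise ValueError("inputs must be positive")
    return base_genes * ploidy_factor


def coverage_estimate(unigenes: int, base_genes: int, ploidy_factor: int) -> int:
    """Percent of the estimated gene content covered by the unigene set."""
    if unigenes <= 0 or base_genes <= 0 or ploidy_factor <= 0:
        raise ValueError("inputs must be positive")
    return round_half_away(100.0 * unigenes / gene_content(base_genes, ploidy_factor))


NO_MATCH_CATEGORY = "No match"


def category_summary(labelled: pd.DataFrame) -> pd.DataFrame:
    """Per-category counts and percents of DE tags, split up/down.

    ``labelled`` needs columns ``tag``, ``category`` and ``direction``
    ("up"/"down").  Unlabelled tags (NaN or empty category) are counted
    under a "No match" category.  Percents are of the direction total,
    rounded half away from zero; a Total row closes the table.
    """
    df = labelled.copy()
    if not {"tag", "category", "direction"} <= set(df.columns):
        raise ValueError("labelled frame needs tag, category, direction columns")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"unknown directions: {sorted(bad)}")
    df["category"] = df["category"].fillna(NO_MATCH_CATEGORY)
    df.loc[df["category"].astype(str).str.strip() == "", "category"] = NO_MATCH_CATEGORY
    totals = df["direction"].value_counts().to_dict()
    up_total = totals.get("up", 0)
    down_total = totals.get("down", 0)

    rows = []
    for category, group in df.groupby("category", sort=True):
        up_n = int((group["direction"] == "up").sum())
        down_n = int((group["direction"] == "down").sum())
        rows.append(
            {
                "category": category,
                "up_n": up_n,
                "up_pct": round_half_away(100.0 * up_n / up_total) if up_total else 0,
                "down_n": down_n,
                "down_pct": round_half_away(100.0 * down_n / down_total)
                if down_total
                else 0,
            }
        )
    summary = pd.DataFrame(
        rows, columns=["category", "up_n", "up_pct", "down_n", "down_pct"]
    )
    total_row = pd.DataFrame(
        [
            {
                "category": "Total",
                "up_n": up_total,
                "up_pct": 100 if up_total else 0,
                "down_n": down_total,
                "down_pct": 100 if down_total else 0,
            }
        ]
    )
    return pd.concat([summary, total_row], ignore_index=True)
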