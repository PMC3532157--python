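"""Synthetic references and tag libraries with known ground truth.

The generator emulates the structure of a mixed host/endophyte SAGE
experiment: two transcript populations (plant and fungal) with poly-A
tails; a fungal share of a few percent of the mapped tags, present only in
the infected sample; a log-normal plant abundance distribution and a
strongly skewed (Zipf) fungal distribution whose top transcript takes a
configurable share (~10% by default); a configurable set of truly
differentially expressed plant tags across 3+3 biological replicates with
multiplicative within-group noise; antisense transcription at set
sense:antisense ratios; artifact tags lacking the CATG anchor; poly-A
runoff tags; and per-base substitution errors on the 23 non-anchor bases.

Libraries are drawn by multinomial sampling at fixed library size, matching
the counting nature of SAGE.  Identical seeds give identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from ._util import revcomp
from .qc import MAX_TRAILING_A, RawTagLibrary, trailing_a_run
from .reference import (
    ANCHOR,
    TAG_LENGTH,
    ReferenceSet,
    TagCatalog,
    Transcript,
    digest_reference,
    extract_tag,
)

SAMPLE_EMINUS = "Eminus"
SAMPLE_EPLUS = "Eplus"

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic experiment."""

    seed: int = 0
    # reference structure
    n_plant_transcripts: int = 1050
    n_fungal_transcripts: int = 200
    length_mean: float = 500.0
    length_sd: float = 150.0
    length_min: int = 120
    gc_fraction: float = 0.5
    polya_tail: int = 30
    # library structure
    library_size: int = 100_000
    replicates: int = 3
    fungal_fraction: float = 0.02
    # abundance models
    plant_lognorm_mu: float = 0.0
    plant_lognorm_sigma: float = 1.0
    fungal_top_share: float = 0.10
    # differential expression (plant)
    n_de: int = 50
    de_fold: float = 4.0
    within_group_cv: float = 0.2
    # antisense transcription: fungal abundance rank -> true sense:antisense 1:R
    antisense_ranks: dict[int, float] = field(default_factory=lambda: {1: 9.0, 4: 87.0})
    # artifacts and errors
    no_anchor_rate: float = 0.30
    polya_runoff_rate: float = 0.002
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("fungal_fraction", "no_anchor_rate", "polya_runoff_rate",
                     "error_rate", "gc_fraction", "fungal_top_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.no_anchor_rate + self.polya_runoff_rate >= 1.0:
            raise ValueError("artifact rates must leave room for real tags")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per sample")
        if self.n_de > self.n_plant_transcripts:
            raise ValueError("n_de cannot exceed n_plant_transcripts")
        if self.de_fold < 1.0:
            raise ValueError("de_fold must be >= 1")
        for rank in self.antisense_ranks:
            if not 1 <= rank <= self.n_fungal_transcripts:
                raise ValueError(f"antisense rank {rank} out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "antisense_ranks" in raw and raw["antisense_ranks"] is not None:
            raw["antisense_ranks"] = {
                int(k): float(v) for k, v in raw["antisense_ranks"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SimulatedTruth:
    """Ground truth for one simulated study.

    ``categories`` has one row per true tag species with its transcript,
    origin, strand and per-sample sampling probability (within the
    transcript-derived portion of a library).  ``de_table`` lists the truly
    DE plant tags with signed fold changes; ``antisense_table`` the
    configured antisense transcripts with their true 1:R ratios.
    """

    categories: pd.DataFrame
    de_table: pd.DataFrame
    antisense_table: pd.DataFrame

    def null_plant_tags(self) -> list[str]:
        cat = self.categories
        mask = (cat["origin"] == "plant") & (cat["strand"] == "sense")
        null = cat.loc[mask, "tag"]
        return sorted(set(null) - set(self.de_table["tag"]))

    def fungal_rank_order(self) -> list[str]:
        """Fungal transcript ids by true sense abundance, descending."""
        cat = self.categories
        sense = cat[(cat["origin"] == "fungal") & (cat["strand"] == "sense")]
        ordered = sense.sort_values("prob_eplus", ascending=False)
        return list(ordered["transcript_id"])


def _zipf_exponent(n: int, top_share: float) -> float:
    """Exponent s with max_i i^-s / sum_i i^-s == top_share for i=1..n."""
    if n == 1:
        return 1.0
    if top_share <= 1.0 / n:
        return 0.0

    def gap(s: float) -> float:
        weights = np.arange(1, n + 1, dtype=float) ** -s
        return weights[0] / weights.sum() - top_share

    return float(brentq(gap, 1e-9, 50.0))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _passes_qc(tag: str) -> bool:
    return trailing_a_run(tag) <= MAX_TRAILING_A and "N" not in tag


def _antisense_window(seq: str, forbidden: set[str]) -> str | None:
    """A QC-passable anchored 27-mer on the reverse complement, or None."""
    rc = revcomp(seq)
    pos = rc.rfind(ANCHOR)
    while pos != -1:
        window = rc[pos : pos + TAG_LENGTH]
        if len(window) == TAG_LENGTH and _passes_qc(window) and window not in forbidden:
            return window
        pos = rc.rfind(ANCHOR, 0, pos)
    return None


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceSet, TagCatalog]:
    """Generate plant and fungal reference transcripts with poly-A tails.

    Every emitted transcript is rejection-sampled to yield a canonical tag
    that survives QC, and transcripts hosting simulated antisense
    transcription additionally carry an anchored site on their reverse
    complement.  The returned catalog is the digest of the reference and
    serves as tag-level truth.
    """
    rng = np.random.default_rng([config.seed, 1])
    used_tags: set[str] = set()
    transcripts: list[Transcript] = []
    antisense_hosts = {rank - 1 for rank in config.antisense_ranks}
    tail = "A" * config.polya_tail

    specs = [("plant", i, False) for i in range(config.n_plant_transcripts)] + [
        ("fungal", i, i in antisense_hosts) for i in range(config.n_fungal_transcripts)
    ]
    for origin, i, needs_antisense in specs:
        prefix = "PT" if origin == "plant" else "FT"
        tid = f"{prefix}{i + 1:05d}"
        while True:
            length = max(config.length_min, int(round(rng.normal(config.length_mean, config.length_sd))))
            seq = _random_sequence(rng, length, config.gc_fraction) + tail
            tag = extract_tag(Transcript(tid, seq, origin))
            if tag is None or not _passes_qc(tag.tag_seq) or tag.tag_seq in used_tags:
                continue
            if needs_antisense and _antisense_window(seq, used_tags | {tag.tag_seq}) is None:
                continue
            used_tags.add(tag.tag_seq)
            transcripts.append(Transcript(tid, seq, origin))
            break
    refset = ReferenceSet(transcripts, provenance=f"simulated (seed={config.seed})")
    return refset, digest_reference(refset)


def build_truth(
    config: SimulationConfig, refset: ReferenceSet, catalog: TagCatalog
) -> SimulatedTruth:
    """Assign abundances, DE effects and antisense species to the reference."""
    rng = np.random.default_rng([config.seed, 2])
    plant_ids = [t.id for t in refset if t.origin == "plant"]
    fungal_ids = [t.id for t in refset if t.origin == "fungal"]

    # plant: log-normal abundances; DE transcripts get group-specific means
    plant_w = rng.lognormal(config.plant_lognorm_mu, config.plant_lognorm_sigma, len(plant_ids))
    de_idx = rng.choice(len(plant_ids), size=config.n_de, replace=False)
    folds = np.array(
        [config.de_fold if k % 2 == 0 else -config.de_fold for k in range(config.n_de)]
    )
    w_eminus = plant_w.copy()
    w_eplus = plant_w.copy()
    for idx, fold in zip(de_idx, folds):
        if fold > 0:
            w_eplus[idx] = plant_w[idx] * fold
        else:
            w_eplus[idx] = plant_w[idx] / -fold
    p_eminus = w_eminus / w_eminus.sum()
    p_eplus_plant = w_eplus / w_eplus.sum()

    # fungal: Zipf sense abundances plus antisense satellites at 1:R
    n_f = len(fungal_ids)
    s = _zipf_exponent(n_f, config.fungal_top_share)
    sense_w = np.arange(1, n_f + 1, dtype=float) ** -s
    anti_rows: list[tuple[int, str, float]] = []  # (rank, transcript_id, weight)
    for rank, r in sorted(config.antisense_ranks.items()):
        anti_rows.append((rank, fungal_ids[rank - 1], sense_w[rank - 1] / r))
    fungal_total = sense_w.sum() + sum(w for _, _, w in anti_rows)
    q_sense = sense_w / fungal_total
    q_anti = {tid: w / fungal_total for _, tid, w in anti_rows}

    rows = []
    forbidden = set(t.tag_seq for t in catalog.tags.values())
    antisense_records = []
    f = config.fungal_fraction
    for tid, pm, pp in zip(plant_ids, p_eminus, p_eplus_plant):
        rows.append(
            {
                "tag": catalog.tags[tid].tag_seq,
                "transcript_id": tid,
                "origin": "plant",
                "strand": "sense",
                "prob_eminus": pm,
                "prob_eplus": (1 - f) * pp,
            }
        )
    for tid, q in zip(fungal_ids, q_sense):
        rows.append(
            {
                "tag": catalog.tags[tid].tag_seq,
                "transcript_id": tid,
                "origin": "fungal",
                "strand": "sense",
                "prob_eminus": 0.0,
                "prob_eplus": f * q,
            }
        )
    for rank, tid, _w in anti_rows:
        window = _antisense_window(refset.get(tid).seq, forbidden)
        assert window is not None  # guaranteed by simulate_reference
        forbidden.add(window)
        rows.append(
            {
                "tag": window,
                "transcript_id": tid,
                "origin": "fungal",
                "strand": "antisense",
                "prob_eminus": 0.0,
                "prob_eplus": f * q_anti[tid],
            }
        )
        antisense_records.append(
            {
                "rank": rank,
                "transcript_id": tid,
                "true_ratio": config.antisense_ranks[rank],
                "sense_tag": catalog.tags[tid].tag_seq,
                "antisense_tag": window,
            }
        )
    categories = pd.DataFrame(rows)
    de_table = pd.DataFrame(
        {
            "transcript_id": [plant_ids[i] for i in de_idx],
            "tag": [catalog.tags[plant_ids[i]].tag_seq for i in de_idx],
            "fold": folds,
        }
    ).sort_values("transcript_id", ignore_index=True)
    antisense_table = pd.DataFrame(
        antisense_records,
        columns=["rank", "transcript_id", "true_ratio", "sense_tag", "antisense_tag"],
    )
    return SimulatedTruth(categories, de_table, antisense_table)


def _apply_errors(
    counts: dict[str, int], rate: float, rng: np.random.Generator
) -> dict[str, int]:
    """Per-base substitution errors over the 23 non-anchor positions."""
    if rate <= 0:
        return dict(counts)
    k = TAG_LENGTH - len(ANCHOR)
    p_any = 1.0 - (1.0 - rate) ** k
    # conditional number of errors given at least one (truncated binomial)
    from scipy.stats import binom

    ms = np.arange(1, 6)
    pmf = binom.pmf(ms, k, rate)
    pmf = pmf / pmf.sum()
    out: dict[str, int] = {}
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for tag, count in counts.items():
        n_err = rng.binomial(count, p_any)
        if count - n_err > 0:
            out[tag] = out.get(tag, 0) + (count - n_err)
        if n_err == 0:
            continue
        suffix = tag[len(ANCHOR) :]
        n_by_m = rng.multinomial(n_err, pmf)
        for m, reps in zip(ms, n_by_m):
            for _ in range(reps):
                pos = rng.choice(k, size=m, replace=False)
                chars = list(suffix)
                shifts = rng.integers(1, 4, size=m)
                for p, sh in zip(pos, shifts):
                    chars[p] = "ACGT"[(base_index[chars[p]] + sh) % 4]
                mutated = ANCHOR + "".join(chars)
                out[mutated] = out.get(mutated, 0) + 1
    return out


def _no_anchor_tags(n: int, rng: np.random.Generator) -> list[str]:
    """Random 27-mers whose 5' end is not CATG (adaptor-ligation artifacts)."""
    if n == 0:
        return []
    arr = rng.integers(0, 4, size=(n, TAG_LENGTH))
    tags = []
    anchor = ANCHOR
    for row in arr:
        tag = "".join(_BASES[row])
        while tag.startswith(anchor):
            tag = "".join(_BASES[rng.integers(0, 4, size=TAG_LENGTH)])
        tags.append(tag)
    return tags


def simulate_library(
    config: SimulationConfig,
    truth: SimulatedTruth,
    sample: str,
    replicate: int,
) -> RawTagLibrary:
    """Draw one replicate library by multinomial sampling.

    Within-group biological variability is multiplicative gamma noise (mean
    1, CV ``within_group_cv``).  Plant tag species vary independently;
    fungal species share a single factor per replicate, emulating
    replicate-to-replicate differences in fungal biomass (transcript
    proportions within the fungus are kept stable, so percent-of-mapped
    normalization cancels the biomass factor).  Artifact tags and
    substitution errors are layered on top of the transcript-derived tags.
    """
    if sample not in (SAMPLE_EMINUS, SAMPLE_EPLUS):
        raise ValueError(f"unknown sample {sample!r}")
    sample_idx = 0 if sample == SAMPLE_EMINUS else 1
    rng = np.random.default_rng([config.seed, 3, sample_idx, replicate])

    prob_col = "prob_eminus" if sample == SAMPLE_EMINUS else "prob_eplus"
    probs = truth.categories[prob_col].to_numpy(copy=True)
    tags = truth.categories["tag"].to_numpy()
    live = probs > 0
    probs = probs[live]
    live_tags = tags[live]
    is_plant = (truth.categories["origin"].to_numpy() == "plant")[live]
    cv = config.within_group_cv
    if cv > 0:
        shape = 1.0 / cv**2
        noise = np.ones(probs.size)
        noise[is_plant] = rng.gamma(shape, cv**2, size=int(is_plant.sum()))
        noise[~is_plant] = rng.gamma(shape, cv**2)  # shared biomass factor
        probs = probs * noise
    probs = probs / probs.sum()

    a, b = config.no_anchor_rate, config.polya_runoff_rate
    n_noanchor, n_runoff, n_real = rng.multinomial(
        config.library_size, [a, b, 1.0 - a - b]
    )

    counts_arr = rng.multinomial(n_real, probs)
    counts = {
        tag: int(c) for tag, c in zip(live_tags, counts_arr) if c > 0
    }
    counts = _apply_errors(counts, config.error_rate, rng)

    # poly-A runoff: a real anchored tag whose 3' end ran into the tail
    if n_runoff:
        source = rng.choice(tags, size=n_runoff)
        for src in source:
            run = int(rng.integers(MAX_TRAILING_A + 1, TAG_LENGTH - len(ANCHOR) + 1))
            tag = src[: TAG_LENGTH - run] + "A" * run
            counts[tag] = counts.get(tag, 0) + 1
    for tag in _no_anchor_tags(int(n_noanchor), rng):
        counts[tag] = counts.get(tag, 0) + 1
    return RawTagLibrary(sample, replicate, counts)


@dataclass
class SimulatedStudy:
    """A complete synthetic experiment: reference, truth and libraries."""

    config: SimulationConfig
    refset: ReferenceSet
    catalog: TagCatalog
    truth: SimulatedTruth
    libraries: list[RawTagLibrary]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full 3+3 experiment defined by ``config``."""
    refset, catalog = simulate_reference(config)
    truth = build_truth(config, refset, catalog)
    libraries = [
        simulate_library(config, truth, sample, rep)
        for sample in (SAMPLE_EMINUS, SAMPLE_EPLUS)
        for rep in range(1, config.replicates + 1)
    ]
    return SimulatedStudy(config, refset, catalog, truth, libraries)


def export_truth(truth: SimulatedTruth, outdir: str | Path) -> None:
    """Write the truth tables as TSV (lossless, schema-stable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.categories.to_csv(outdir / "truth_categories.tsv", sep="\t", index=False)
    truth.de_table.to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    truth.antisense_table.to_csv(outdir / "truth_antisense.tsv", sep="\t", index=False)


def load_truth(outdir: str | Path) -> SimulatedTruth:
    outdir = Path(outdir)
    return SimulatedTruth(
        categories=pd.read_csv(outdir / "truth_categories.tsv", sep="\t"),
        de_table=pd.read_csv(outdir / "truth_de.tsv", sep="\t"),
        antisense_table=pd.read_csv(outdir / "truth_antisense.tsv", sep="\t"),
    )
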