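"""Anchored mismatch-tolerant mapping and partition assignment."""

import pytest

from solidsage import (
    RawTagLibrary,
    ReferenceSet,
    Transcript,
    candidate_sites,
    map_library,
    map_tags,
    mapping_rates,
    match_tag,
)
from solidsage._util import revcomp
from solidsage.qc import filter_library
from solidsage.reference import ANCHOR, TAG_LENGTH

from conftest import random_seq


def oracle_map(tag, refset, budget=2):
    """Exhaustive both-strand window scan: the independent mapping oracle."""
    best = budget + 1
    hits = []
    for t in refset:
        for strand, seq in (("sense", t.seq), ("antisense", revcomp(t.seq))):
            for pos in range(len(seq) - TAG_LENGTH + 1):
                window = seq[pos : pos + TAG_LENGTH]
                if not window.startswith(ANCHOR):
                    continue
                d = sum(a != b for a, b in zip(tag[4:], window[4:]))
                if d < best:
                    best = d
                    hits = [(t.id, pos, strand, t.origin)]
                elif d == best:
                    hits.append((t.id, pos, strand, t.origin))
    if best > budget:
        return "unmapped", None, set()
    origins = {h[3] for h in hits}
    if origins == {"plant", "fungal"}:
        partition = "ambiguous"
    else:
        partition = origins.pop()
    return partition, best, set(hits)


class TestCandidateSites:
    def test_single_sense_site(self):
        t = Transcript("t", "CATG" + "C" * 23, "plant")
        assert candidate_sites(t) == [(0, "sense")]

    def test_two_sense_sites(self):
        t = Transcript("t", "CATG" + "C" * 23 + "CATG" + "G" * 23, "plant")
        assert [s for s in candidate_sites(t) if s[1] == "sense"] == [
            (0, "sense"),
            (27, "sense"),
        ]

    def test_antisense_site_found(self):
        # reverse complement of the sequence contains an eligible CATG
        t = Transcript("t", "G" * 23 + revcomp("CATG" + "C" * 23), "plant")
        assert (0, "antisense") in candidate_sites(t)

    def test_matches_regex_scan_on_random_sequence(self, rng):
        seq = random_seq(rng, 1000)
        t = Transcript("t", seq, "plant")
        sites = set(candidate_sites(t))
        expected = set()
        for strand, s in (("sense", seq), ("antisense", revcomp(seq))):
            for pos in range(len(s) - TAG_LENGTH + 1):
                if s[pos : pos + 4] == ANCHOR:
                    expected.add((pos, strand))
        assert sites == expected


class TestMatchTag:
    def test_identical(self):
        tag = "CATG" + "A" * 23
        assert match_tag(tag, tag) == 0

    def test_two_mismatches_hit(self):
        tag = "CATG" + "A" * 23
        window = "CATG" + "C" + "A" * 21 + "C"
        assert match_tag(tag, window) == 2

    def test_three_mismatches_no_hit(self):
        tag = "CATG" + "A" * 23
        window = "CATG" + "CCC" + "A" * 20
        assert match_tag(tag, window) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_tag("CATG", "CATG" + "A" * 23)

    def test_unanchored_window_rejected(self):
        with pytest.raises(ValueError):
            match_tag("CATG" + "A" * 23, "AATG" + "A" * 23)


class TestMapLibrary:
    def test_exact_plant_hit(self, two_part_refset):
        tag = "CATG" + "C" * 23
        lib = RawTagLibrary("s", 1, {tag: 4})
        table = map_library(lib, two_part_refset)
        a = table.assignments[tag]
        assert a.partition == "plant"
        assert a.best_mismatches == 0
        assert all(h.strand == "sense" for h in a.hits)
        assert table.tallies["plant_mapped"] == 4

    def test_antisense_fungal_hit(self):
        fungal = Transcript("f", "G" * 10 + revcomp("CATG" + "T" * 23), "fungal")
        refset = ReferenceSet([fungal])
        tag = "CATG" + "T" * 23
        table = map_library(RawTagLibrary("s", 1, {tag: 1}), refset)
        a = table.assignments[tag]
        assert a.partition == "fungal"
        assert a.hits[0].strand == "antisense"

    def test_best_distance_wins_across_partitions(self):
        plant = Transcript("p", "CATG" + "C" * 22 + "G", "plant")  # distance 1
        fungal = Transcript("f", "CATG" + "C" * 23, "fungal")  # distance 0
        tag = "CATG" + "C" * 23
        table = map_library(RawTagLibrary("s", 1, {tag: 1}), ReferenceSet([plant, fungal]))
        assert table.assignments[tag].partition == "fungal"

    def test_equal_distance_both_partitions_is_ambiguous(self):
        plant = Transcript("p", "CATG" + "C" * 23, "plant")
        fungal = Transcript("f", "CATG" + "C" * 23, "fungal")
        tag = "CATG" + "C" * 23
        table = map_library(RawTagLibrary("s", 1, {tag: 2}), ReferenceSet([plant, fungal]))
        assert table.assignments[tag].partition == "ambiguous"
        assert table.tallies == {
            "plant_mapped": 0,
            "fungal_mapped": 0,
            "ambiguous": 2,
            "unmapped": 0,
        }

    def test_over_budget_unmapped(self, two_part_refset):
        tag = "CATG" + "T" * 23
        table = map_library(RawTagLibrary("s", 1, {tag: 1}), two_part_refset)
        assert table.assignments[tag].partition == "unmapped"

    def test_non_oriented_reference_gives_unknown_strand(self):
        t = Transcript("t", "CATG" + "C" * 23, "plant", oriented=False)
        tag = "CATG" + "C" * 23
        assignments = map_tags([tag], ReferenceSet([t]))
        assert assignments[tag].hits[0].strand == "unknown"

    def test_order_invariance(self, rng):
        transcripts = [
            Transcript(f"t{i}", random_seq(rng, 150) + "A" * 30, "plant")
            for i in range(5)
        ]
        refset = ReferenceSet(transcripts)
        tags = ["CATG" + random_seq(rng, 23) for _ in range(40)]
        forward = map_tags(tags, refset)
        backward = map_tags(tags[::-1], refset)
        for tag in tags:
            assert forward[tag].partition == backward[tag].partition
            assert forward[tag].best_mismatches == backward[tag].best_mismatches

    def test_tallies_conserve_library_total(self, rng, two_part_refset):
        tags = {"CATG" + random_seq(rng, 23): int(c) for c in rng.integers(1, 9, 30)}
        lib = RawTagLibrary("s", 1, tags)
        table = map_library(lib, two_part_refset)
        assert sum(table.tallies.values()) == lib.total


def test_agrees_with_exhaustive_oracle(rng):
    """Anchored mapper vs exhaustive both-strand window scan, randomized."""
    for _ in range(30):
        n_t = int(rng.integers(2, 8))
        transcripts = []
        for i in range(n_t):
            origin = "plant" if rng.random() < 0.5 else "fungal"
            transcripts.append(
                Transcript(f"t{i}", random_seq(rng, int(rng.integers(60, 200))), origin)
            )
        refset = ReferenceSet(transcripts)
        tags = []
        for _ in range(25):
            if rng.random() < 0.5 or not transcripts:
                tags.append("CATG" + random_seq(rng, 23))
            else:
                # perturb a real window so near-hits are well represented
                t = transcripts[rng.integers(n_t)]
                sites = candidate_sites(t)
                if not sites:
                    tags.append("CATG" + random_seq(rng, 23))
                    continue
                pos, strand = sites[rng.integers(len(sites))]
                seq = t.seq if strand == "sense" else revcomp(t.seq)
                tag = list(seq[pos : pos + 27])
                for p in rng.choice(23, size=rng.integers(0, 4), replace=False):
                    tag[4 + p] = "ACGT"[rng.integers(4)]
                tags.append("".join(tag))
        assignments = map_tags(list(dict.fromkeys(tags)), refset)
        for tag, a in assignments.items():
            partition, best, hits = oracle_map(tag, refset)
            assert a.partition == partition, tag
            assert a.best_mismatches == best
            got = {(h.transcript_id, h.position, h.strand, h.origin) for h in a.hits}
            assert got == hits


def test_mapping_rates_reproduce_report_convention(two_part_refset):
    raw = RawTagLibrary(
        "s",
        1,
        {
            "CATG" + "C" * 23: 6,  # plant
            "CATG" + "T" * 11 + "G" * 12: 4,  # fungal
            "AATG" + "G" * 23: 5,  # fails QC
            "CATG" + "A" * 23: 10,  # poly-A runoff, fails QC
        },
    )
    passed, report = filter_library(raw)
    table = map_library(passed, two_part_refset)
    row = mapping_rates(table, report)
    assert row["plant_pct"] == 60  # 6 of 10 potential mappable
    assert row["fungal_pct"] == 40.0
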