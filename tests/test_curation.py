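"""CDS curation steps against hand-built cases and a DP oracle."""

import numpy as np
import pytest

from jdint.curation import (
    CdsRecord,
    CurationReport,
    annotate_headers,
    collapse_shared_region,
    curate,
    dedupe_identical,
    parse_header,
    read_cds_fasta,
    remove_inframe_stops,
    shared_block_length,
    size_filter,
    strip_terminal_stops,
    write_cds_fasta,
)
from jdint.simulate import CdsSimParams, _random_cds, generate_cds_set


def rec(accession, sequence):
    return CdsRecord(accession, sequence)


def lcs_dp(a: str, b: str) -> int:
    """Quadratic dynamic-programming longest-common-substring oracle."""
    an = np.frombuffer(a.encode(), dtype=np.uint8)
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    best = 0
    prev = np.zeros(bn.size + 1, dtype=np.int32)
    for i in range(an.size):
        cur = np.zeros(bn.size + 1, dtype=np.int32)
        match = an[i] == bn
        cur[1:][match] = prev[:-1][match] + 1
        best = max(best, int(cur.max()))
        prev = cur
    return best


class TestDedupe:
    def test_first_of_identical_pair_survives(self):
        report = CurationReport()
        out = dedupe_identical([rec("A", "ATGAAA"), rec("B", "ATGAAA")], report)
        assert [r.accession for r in out] == ["A"]
        assert report.removals == {"B": "duplicate"}

    def test_empty_input(self):
        assert dedupe_identical([]) == []

    def test_two_duplicate_pairs_leave_three(self):
        records = [rec("A", "ATGAAA"), rec("B", "ATGCCC"), rec("C", "ATGAAA"),
                   rec("D", "ATGCCC"), rec("E", "ATGGGG")]
        assert len(dedupe_identical(records)) == 3


class TestSizeFilter:
    @pytest.mark.parametrize("length,kept", [
        (900, True),    # equals the query
        (990, True),    # exactly 1.10x: boundary inclusive
        (810, True),    # exactly 0.90x
        (1125, False),  # 1.25x of the only query
        (808, False),
    ])
    def test_single_query_boundaries(self, length, kept):
        out = size_filter([rec("A", "A" * length)], [900])
        assert bool(out) is kept

    def test_any_query_suffices(self):
        out = size_filter([rec("A", "A" * 660)], [1086, 660])
        assert len(out) == 1

    def test_no_queries_rejected(self):
        with pytest.raises(ValueError):
            size_filter([rec("A", "AAA")], [])


class TestCollapseSharedRegion:
    def test_sequence_closest_to_reference_survives(self):
        rng = np.random.default_rng(0)
        block = _random_cds(rng, 252, False)[:251]
        short = "C" * 300 + block + "G" * 349   # 900 nt
        long = "T" * 400 + block + "A" * 429    # 1080 nt
        out = collapse_shared_region([rec("short", short), rec("long", long)],
                                     reference_length=1080)
        assert [r.accession for r in out] == ["long"]

    def test_exactly_250_shared_keeps_both(self):
        rng = np.random.default_rng(1)
        block = _random_cds(rng, 252, False)[:250]
        a = "C" * 300 + block + "G" * 350
        b = "T" * 400 + block + "A" * 430
        assert shared_block_length(a, b) == 250
        out = collapse_shared_region([rec("a", a), rec("b", b)],
                                     reference_length=1080)
        assert len(out) == 2

    def test_no_shared_blocks_keeps_all(self):
        rng = np.random.default_rng(2)
        records = [rec(f"r{i}", _random_cds(rng, 600, False)) for i in range(5)]
        out = collapse_shared_region(records, reference_length=600)
        assert out == records

    def test_transitive_grouping_keeps_single_survivor(self):
        rng = np.random.default_rng(3)
        block1 = _random_cds(rng, 252, False)[:251]
        block2 = _random_cds(rng, 252, False)[:251]
        a = "C" * 100 + block1 + "G" * 100          # 451 nt
        b = "T" * 60 + block1 + "A" * 60 + block2   # shares with both a and c
        c = block2 + "C" * 400                      # 651 nt
        out = collapse_shared_region([rec("a", a), rec("b", b), rec("c", c)],
                                     reference_length=650)
        assert [r.accession for r in out] == ["c"]

    def test_distance_tie_prefers_longer_then_accession(self):
        rng = np.random.default_rng(4)
        block = _random_cds(rng, 252, False)[:251]
        shorter = block + "A" * 49    # 300 nt, distance 50
        longer = block + "C" * 149    # 400 nt, distance 50
        out = collapse_shared_region([rec("s", shorter), rec("l", longer)],
                                     reference_length=350)
        assert [r.accession for r in out] == ["l"]
        same_len_a = block + "A" * 49
        same_len_b = block + "C" * 49
        out = collapse_shared_region([rec("zzz", same_len_a), rec("aaa", same_len_b)],
                                     reference_length=350)
        assert [r.accession for r in out] == ["aaa"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dp_oracle_grouping(self, seed):
        """Survivors agree with a brute-force all-pairs DP oracle."""
        rng = np.random.default_rng(seed)
        records = []
        for i in range(12):
            seq = _random_cds(rng, int(rng.integers(100, 220)) * 3, False)
            records.append(rec(f"r{i:02d}", seq))
        # plant shared blocks among random pairs
        for j, (x, y) in enumerate([(0, 1), (1, 2), (5, 6), (8, 9)]):
            block = records[x].sequence[30:30 + 260]
            host = records[y].sequence
            records[y] = rec(records[y].accession,
                             host[:50] + block + host[50 + 260:])
        reference_length = 500

        # oracle: union-find over all pairs using the DP matcher
        parent = list(range(len(records)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                if lcs_dp(records[i].sequence, records[j].sequence) > 250:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(len(records)):
            groups.setdefault(find(i), []).append(i)
        expected = set()
        for members in groups.values():
            best = min(members, key=lambda i: (
                abs(len(records[i].sequence) - reference_length),
                -len(records[i].sequence),
                records[i].accession))
            expected.add(records[best].accession)

        out = collapse_shared_region(records, reference_length)
        assert {r.accession for r in out} == expected


class TestStops:
    def test_terminal_stop_only_is_kept(self):
        assert len(remove_inframe_stops([rec("A", "ATGAAATAA")])) == 1

    def test_internal_stop_removed(self):
        report = CurationReport()
        out = remove_inframe_stops([rec("A", "ATGTAAAAA")], report)
        assert out == []
        assert report.removals == {"A": "internal-stop"}

    def test_out_of_frame_removed_with_frame_reason(self):
        report = CurationReport()
        remove_inframe_stops([rec("A", "ATGAAAA")], report)
        assert report.removals == {"A": "frame"}

    def test_strip_terminal_stop_and_idempotence(self):
        once = strip_terminal_stops([rec("A", "ATGAAATAA"), rec("B", "ATGAAA")])
        assert [r.sequence for r in once] == ["ATGAAA", "ATGAAA"]
        assert strip_terminal_stops(once) == once


class TestHeaders:
    def test_annotation_and_round_trip(self):
        taxonomy = {"ACC1": {"species": "Homo sapiens", "family": "Hominidae",
                             "class": "Mammalia"}}
        (annotated,) = annotate_headers([rec("ACC1", "ATG")], taxonomy)
        assert annotated.header == "ACC1|Homo sapiens|Hominidae|Mammalia"
        parsed = parse_header(annotated.header)
        assert (parsed.accession, parsed.species, parsed.family, parsed.class_) \
            == ("ACC1", "Homo sapiens", "Hominidae", "Mammalia")

    def test_missing_taxonomy_keeps_accession_and_warns(self):
        report = CurationReport()
        (out,) = annotate_headers([rec("X", "ATG")], {}, report)
        assert out.header == "X"
        assert report.warnings


class TestFastaIO:
    def test_round_trip_wrapped_at_60(self, tmp_path):
        rng = np.random.default_rng(6)
        records = [rec("A1", _random_cds(rng, 300, True)),
                   CdsRecord("B2", _random_cds(rng, 150, False),
                             species="Mus_musculus", family="Muridae",
                             class_="Mammalia")]
        path = tmp_path / "out.fasta"
        write_cds_fasta(records, path)
        lines = path.read_text().splitlines()
        assert max(len(line) for line in lines if not line.startswith(">")) == 60
        assert read_cds_fasta(path) == records


class TestCuratePipeline:
    def test_counts_telescope_and_reasons_unique(self):
        records, truth = generate_cds_set(CdsSimParams(seed=11))
        survivors, report = curate([records], truth.query_lengths,
                                   truth.reference_length)
        for prev, nxt in zip(report.steps, report.steps[1:]):
            assert prev.n_out == nxt.n_in
        n_removed = report.steps[0].n_in - report.steps[-1].n_out
        assert len(report.removals) == n_removed
        assert {r.accession for r in survivors} == set(truth.survivors)

    def test_survivors_match_truth_exactly(self):
        records, truth = generate_cds_set(CdsSimParams(seed=21))
        survivors, report = curate([records], truth.query_lengths,
                                   truth.reference_length)
        assert {r.accession for r in survivors} == set(truth.survivors)
        assert report.removals == truth.removal_reasons

    def test_step_toggle_skips_collapse(self):
        records, truth = generate_cds_set(CdsSimParams(seed=31))
        enabled = ("dedupe", "size", "merge-dedupe", "annotate",
                   "internal-stops", "strip-stops")
        survivors, report = curate([records], truth.query_lengths,
                                   truth.reference_length, steps=enabled)
        accessions = {r.accession for r in survivors}
        isoforms = {acc for acc, why in truth.removal_reasons.items()
                    if why == "isoform"}
        assert isoforms <= accessions  # collapse disabled: isoforms survive

    def test_benign_input_is_identity_minus_terminal_stops(self):
        params = CdsSimParams(n_duplicates=0, n_isoform_pairs=0,
                              n_internal_stop=0, n_off_size=0,
                              include_boundary_cases=False, seed=41)
        records, truth = generate_cds_set(params)
        survivors, _ = curate([records], truth.query_lengths,
                              truth.reference_length)
        assert {r.accession for r in survivors} == {r.accession for r in records}
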