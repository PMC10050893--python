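"""Docking readers and best-cluster/structure selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jdint import (
    AnalysisConfig,
    ClusterSummary,
    InterfaceSet,
    NoAdmissibleCluster,
    StructureInterface,
    filter_by_length,
    read_interface_tsv,
    read_pisa_interface_xml,
    select_best_cluster,
    write_interface_tsv,
)
from jdint.docking import build_clusters, read_cluster_table


def pisa_xml(entries) -> str:
    """Build a PISA-style XML document from {structure: {chain: positions}}."""
    parts = ["<pisa_interfaces>"]
    for code, chains in entries.items():
        parts.append(f"<pdb_entry><pdb_code>{code}</pdb_code><interface>")
        parts.append("<int_area>500.0</int_area>")
        for chain, positions in chains.items():
            parts.append(f"<molecule><chain_id>{chain}</chain_id><residues>")
            for pos, bsa in positions:
                parts.append(f"<residue><seq_num>{pos}</seq_num>"
                             f"<bsa>{bsa}</bsa></residue>")
            parts.append("</residues></molecule>")
        parts.append("</interface></pdb_entry>")
    parts.append("</pisa_interfaces>")
    return "".join(parts)


class TestPisaReader:
    def test_flagged_residues_collected(self, tmp_path):
        path = tmp_path / "pisa.xml"
        path.write_text(pisa_xml({"s1": {"A": [(10, 12.5), (11, 3.0)],
                                         "B": [(4, 9.9)]}}))
        (structure,) = read_pisa_interface_xml(path, "A")
        assert structure.ref_positions == frozenset({10, 11})
        assert structure.ref_interfacing_count == 2
        assert structure.total_contacts == 3  # both chains
        assert structure.interface_area == pytest.approx(500.0)

    def test_zero_bsa_residues_not_interfacing(self, tmp_path):
        path = tmp_path / "pisa.xml"
        path.write_text(pisa_xml({"s1": {"A": [(10, 0.0), (11, 0.0)],
                                         "B": [(1, 0.0)]}}))
        (structure,) = read_pisa_interface_xml(path, "A")
        assert structure.ref_positions == frozenset()
        assert structure.total_contacts == 0

    def test_only_reference_chain_contributes_positions(self, tmp_path):
        path = tmp_path / "pisa.xml"
        path.write_text(pisa_xml({"s1": {"A": [(5, 1.0), (6, 1.0), (7, 1.0)],
                                         "B": [(50, 1.0), (51, 1.0)]}}))
        (structure,) = read_pisa_interface_xml(path, "A")
        # hand count of the fixture: three chain-A residues, five in total
        assert structure.ref_positions == frozenset({5, 6, 7})
        assert structure.total_contacts == 5

    def test_missing_reference_chain_is_configuration_error(self, tmp_path):
        path = tmp_path / "pisa.xml"
        path.write_text(pisa_xml({"s1": {"B": [(4, 1.0)]}}))
        with pytest.raises(ValueError, match="reference chain"):
            read_pisa_interface_xml(path, "A")

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<pisa_interfaces><pdb_entry>")
        with pytest.raises(ValueError, match="malformed"):
            read_pisa_interface_xml(path, "A")


class TestInterfaceTsv:
    def test_duplicate_positions_deduplicated(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text("interactor_id\treference_id\tpositions\n"
                        "P1\tref\t3,5,5,9\n")
        (iset,) = read_interface_tsv(path)
        assert iset.positions == frozenset({3, 5, 9})

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_interface_tsv(path) == []

    def test_non_integer_position_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("interactor_id\treference_id\tpositions\n"
                        "P1\tref\t3,x,9\n")
        with pytest.raises(ValueError, match=":2"):
            read_interface_tsv(path)

    @settings(derandomize=True, max_examples=50)
    @given(datasets=st.lists(
        st.sets(st.integers(min_value=1, max_value=400), min_size=1),
        min_size=1, max_size=6))
    def test_round_trip(self, tmp_path_factory, datasets):
        interfaces = [
            InterfaceSet(f"P{i}", "ref", frozenset(positions))
            for i, positions in enumerate(datasets)
        ]
        path = tmp_path_factory.mktemp("rt") / "i.tsv"
        write_interface_tsv(interfaces, path)
        assert read_interface_tsv(path) == interfaces


def structure(sid, n_ref, contacts, area):
    return StructureInterface(
        structure_id=sid,
        ref_positions=frozenset(range(1, n_ref + 1)),
        total_contacts=contacts,
        interface_area=area,
    )


def selection_oracle(clusters, zmax=0.0):
    """Brute-force lexicographic sort over all admissible (cluster, structure)."""
    pairs = [
        (c, s) for c in clusters if c.z_score <= zmax for s in c.structures
    ]
    if not pairs:
        return None
    return min(pairs, key=lambda cs: (-cs[1].ref_interfacing_count,
                                      -cs[1].total_contacts,
                                      -cs[1].interface_area,
                                      cs[1].structure_id))


def random_clusters(rng, allow_positive_only=False):
    clusters = []
    sid = itertools.count()
    for ci in range(rng.integers(1, 5)):
        structures = tuple(
            structure(f"s{next(sid):03d}",
                      int(rng.integers(5, 9)),       # narrow ranges force ties
                      int(rng.integers(10, 14)),
                      float(rng.integers(300, 304)))
            for _ in range(rng.integers(1, 4))
        )
        z = float(rng.normal(loc=0.5 if allow_positive_only else -0.2, scale=1.0))
        clusters.append(ClusterSummary(f"c{ci}", round(z, 2), structures))
    return clusters


class TestSelectBestCluster:
    def test_zero_zscore_cluster_retained(self):
        """The z <= 0 filter is boundary-inclusive: z = 0 stays in play."""
        good = ClusterSummary("boundary", 0.0, (structure("a", 10, 20, 100.0),))
        better_but_positive = ClusterSummary(
            "pos", 0.5, (structure("b", 99, 99, 999.0),))
        worse = ClusterSummary("neg", -1.2, (structure("c", 5, 10, 50.0),))
        cluster, chosen = select_best_cluster([worse, good, better_but_positive])
        assert cluster.cluster_id == "boundary"
        assert chosen.structure_id == "a"

    def test_single_cluster_single_structure(self):
        only = ClusterSummary("c", -1.0, (structure("s", 3, 3, 1.0),))
        assert select_best_cluster([only])[1].structure_id == "s"

    def test_tie_broken_by_contacts_then_area(self):
        cluster = ClusterSummary("c", -1.0, (
            structure("first", 30, 40, 500.0),
            structure("second", 30, 55, 100.0),
        ))
        assert select_best_cluster([cluster])[1].structure_id == "second"
        full_tie = ClusterSummary("c", -1.0, (
            structure("small", 30, 40, 100.0),
            structure("big", 30, 40, 900.0),
        ))
        assert select_best_cluster([full_tie])[1].structure_id == "big"

    def test_no_admissible_cluster_signalled(self):
        bad = ClusterSummary("c", 0.01, (structure("s", 3, 3, 1.0),))
        with pytest.raises(NoAdmissibleCluster):
            select_best_cluster([bad])

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            clusters = random_clusters(rng)
            if all(c.z_score > 0 for c in clusters):
                continue
            baseline = select_best_cluster(clusters)
            for perm_seed in range(3):
                perm_rng = np.random.default_rng(perm_seed)
                shuffled = [
                    ClusterSummary(c.cluster_id, c.z_score, tuple(
                        c.structures[i]
                        for i in perm_rng.permutation(len(c.structures))
                    ))
                    for c in perm_rng.permutation(clusters)
                ]
                cluster, chosen = select_best_cluster(shuffled)
                assert cluster.cluster_id == baseline[0].cluster_id
                assert chosen.structure_id == baseline[1].structure_id

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 200:
            clusters = random_clusters(rng)
            expected = selection_oracle(clusters)
            if expected is None:
                with pytest.raises(NoAdmissibleCluster):
                    select_best_cluster(clusters)
                continue
            cluster, chosen = select_best_cluster(clusters)
            assert chosen.structure_id == expected[1].structure_id
            checked += 1


class TestClusterTable:
    def test_build_clusters_from_table(self, tmp_path):
        table = tmp_path / "clusters.tsv"
        table.write_text("cluster_id\tz_score\tstructure_id\n"
                         "c1\t-1.5\ts1\nc1\t-1.5\ts2\nc2\t0.3\ts3\n")
        structures = {sid: structure(sid, 5, 5, 10.0) for sid in ("s1", "s2", "s3")}
        clusters = build_clusters(read_cluster_table(table), structures)
        by_id = {c.cluster_id: c for c in clusters}
        assert len(by_id["c1"].structures) == 2
        assert by_id["c2"].z_score == pytest.approx(0.3)

    def test_unknown_structure_raises(self, tmp_path):
        table = tmp_path / "clusters.tsv"
        table.write_text("cluster_id\tz_score\tstructure_id\nc1\t-1\tmissing\n")
        with pytest.raises(KeyError):
            build_clusters(read_cluster_table(table), {})


class TestLengthFilter:
    def test_boundary_is_strictly_longer_than(self):
        retained, excluded = filter_by_length(
            {"at_limit": 1500, "over": 1501, "short": 12})
        assert retained == ["at_limit", "short"]
        assert [e.interactor_id for e in excluded] == ["over"]

    def test_empty_input(self):
        assert filter_by_length({}) == ([], [])
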