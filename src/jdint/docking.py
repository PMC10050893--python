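"""Docking-output readers and best cluster/structure selection.

Consumes HADDOCK-style cluster tables (cluster id, z-score, member
structures) together with PISA-style per-structure interface reports, and
applies the selection protocol: keep clusters with z-score <= 0, then pick
the structure with the most interfacing residues on the reference protein,
breaking ties by total interface contacts, then by interface area, and
finally (for reproducibility) by structure id.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from lxml import etree

from .core import AnalysisConfig

__all__ = [
    "StructureInterface",
    "ClusterSummary",
    "InterfaceSet",
    "NoAdmissibleCluster",
    "read_pisa_interface_xml",
    "read_interface_tsv",
    "write_interface_tsv",
    "read_cluster_table",
    "build_clusters",
    "select_best_cluster",
    "filter_by_length",
]


@dataclass(frozen=True)
class StructureInterface:
    """Interface metrics of a single docked structure.

    ``ref_positions`` are the interfacing residue positions on the
    reference (bait) chain; ``total_contacts`` counts interfacing residues
    over all chains of the complex; ``interface_area`` is in Å².
    """

    structure_id: str
    ref_positions: frozenset[int]
    total_contacts: int
    interface_area: float

    def __post_init__(self) -> None:
        if self.interface_area < 0:
            raise ValueError("interface_area must be non-negative")

    @property
    def ref_interfacing_count(self) -> int:
        return len(self.ref_positions)


@dataclass(frozen=True)
class ClusterSummary:
    """A docking cluster: z-score and member structures."""

    cluster_id: str
    z_score: float
    structures: tuple[StructureInterface, ...]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError(f"cluster {self.cluster_id} has no structures")


@dataclass(frozen=True)
class InterfaceSet:
    """One interactor's interfacing residue positions on a reference protein."""

    interactor_id: str
    reference_id: str
    positions: frozenset[int]
    source: str = "direct-tsv"  # selected-structure | direct-tsv | synthetic

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.positions):
            raise ValueError("positions must be 1-based (>= 1)")


class NoAdmissibleCluster(Exception):
    """No docking cluster passed the z-score filter for this interactor."""


# ---------------------------------------------------------------------------
# readers

def read_pisa_interface_xml(path: str | Path, reference_chain_id: str) -> list[StructureInterface]:
    """Parse a PISA-style interface XML report into per-structure interfaces.

    Expected layout: ``<pisa_interfaces>`` containing one ``<pdb_entry>``
    per analyzed structure, each with a ``<pdb_code>`` and one or more
    ``<interface>`` elements carrying ``<int_area>`` and per-chain
    ``<molecule>`` blocks whose ``<residue>`` entries list ``<seq_num>``
    and buried surface area ``<bsa>``. A residue with ``bsa > 0`` is
    interfacing. Positions on the reference chain populate
    ``ref_positions``; interfacing residues on every chain are summed into
    ``total_contacts``; ``interface_area`` sums the per-interface areas.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed PISA XML in {path}: {exc}") from exc
    root = tree.getroot()
    results: list[StructureInterface] = []
    for entry in root.iter("pdb_entry"):
        code = entry.findtext("pdb_code")
        if code is None:
            raise ValueError(f"{path}: <pdb_entry> missing <pdb_code>")
        ref_positions: set[int] = set()
        total_contacts = 0
        area = 0.0
        chains_seen: set[str] = set()
        for interface in entry.iter("interface"):
            int_area = interface.findtext("int_area")
            if int_area is not None:
                area += float(int_area)
            for molecule in interface.iter("molecule"):
                chain = molecule.findtext("chain_id")
                if chain is None:
                    raise ValueError(f"{path}: <molecule> missing <chain_id>")
                chains_seen.add(chain)
                for residue in molecule.iter("residue"):
                    seq_num = residue.findtext("seq_num")
                    if seq_num is None:
                        raise ValueError(f"{path}: <residue> missing <seq_num>")
                    bsa = float(residue.findtext("bsa", default="0"))
                    if bsa > 0:
                        total_contacts += 1
                        if chain == reference_chain_id:
                            ref_positions.add(int(seq_num))
        if chains_seen and reference_chain_id not in chains_seen:
            raise ValueError(
                f"{path}: reference chain {reference_chain_id!r} absent from "
                f"structure {code} (chains: {sorted(chains_seen)})"
            )
        results.append(StructureInterface(
            structure_id=code,
            ref_positions=frozenset(ref_positions),
            total_contacts=total_contacts,
            interface_area=area,
        ))
    return results


def read_interface_tsv(path: str | Path) -> list[InterfaceSet]:
    """Read the simplified interface TSV.

    Tab-separated with a header row; required columns ``interactor_id``,
    ``reference_id`` and ``positions`` (comma-separated 1-based residue
    positions, duplicates ignored). Extra columns are tolerated.
    """
    out: list[InterfaceSet] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        for col in ("interactor_id", "reference_id", "positions"):
            if col not in reader.fieldnames:
                raise ValueError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            raw = (row["positions"] or "").strip()
            positions: set[int] = set()
            if raw:
                for tok in raw.split(","):
                    tok = tok.strip()
                    try:
                        positions.add(int(tok))
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-integer position {tok!r}"
                        ) from None
            out.append(InterfaceSet(
                interactor_id=row["interactor_id"],
                reference_id=row["reference_id"],
                positions=frozenset(positions),
                source=row.get("source") or "direct-tsv",
            ))
    return out


def write_interface_tsv(interfaces: Iterable[InterfaceSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["interactor_id", "reference_id", "positions", "source"])
        for iset in interfaces:
            writer.writerow([
                iset.interactor_id,
                iset.reference_id,
                ",".join(str(p) for p in sorted(iset.positions)),
                iset.source,
            ])


def read_cluster_table(path: str | Path) -> list[dict]:
    """Read a HADDOCK-style cluster table (TSV: cluster_id, z_score, structure_id)."""
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return rows
        for col in ("cluster_id", "z_score", "structure_id"):
            if col not in reader.fieldnames:
                raise ValueError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                z = float(row["z_score"])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric z_score {row['z_score']!r}"
                ) from None
            rows.append({"cluster_id": row["cluster_id"], "z_score": z,
                         "structure_id": row["structure_id"]})
    return rows


def build_clusters(table_rows: Sequence[Mapping],
                   structures: Mapping[str, StructureInterface]) -> list[ClusterSummary]:
    """Assemble ClusterSummary objects from a cluster table and structure interfaces."""
    by_cluster: dict[str, list[StructureInterface]] = {}
    z_scores: dict[str, float] = {}
    for row in table_rows:
        cid = row["cluster_id"]
        sid = row["structure_id"]
        if sid not in structures:
            raise KeyError(f"no interface report for structure {sid!r}")
        by_cluster.setdefault(cid, []).append(structures[sid])
        z_scores[cid] = float(row["z_score"])
    return [
        ClusterSummary(cluster_id=cid, z_score=z_scores[cid],
                       structures=tuple(members))
        for cid, members in by_cluster.items()
    ]


# ---------------------------------------------------------------------------
# selection

def _structure_key(s: StructureInterface) -> tuple:
    # lexicographic: most reference-interfacing residues, then most total
    # contacts, then largest interface area; structure_id settles full ties
    return (-s.ref_interfacing_count, -s.total_contacts, -s.interface_area,
            s.structure_id)


def select_best_cluster(clusters: Sequence[ClusterSummary],
                        cfg: AnalysisConfig | None = None,
                        ) -> tuple[ClusterSummary, StructureInterface]:
    """Select the representative structure among z-admissible clusters.

    Clusters with z-score above the cutoff (default 0; the boundary value
    is retained) are discarded; among all remaining structures, the one
    with the highest reference-interfacing residue count wins, with ties
    broken by total contact count, then interface area, then structure id.

    Raises
    ------
    NoAdmissibleCluster
        If every cluster fails the z-score filter.
    """
    if not clusters:
        raise ValueError("no clusters given")
    cfg = cfg or AnalysisConfig()
    admissible = [c for c in clusters if c.z_score <= cfg.zscore_cutoff]
    if not admissible:
        raise NoAdmissibleCluster(
            f"all {len(clusters)} clusters have z-score > {cfg.zscore_cutoff}"
        )
    best: tuple[ClusterSummary, StructureInterface] | None = None
    for cluster in admissible:
        for structure in cluster.structures:
            if best is None or _structure_key(structure) < _structure_key(best[1]):
                best = (cluster, structure)
    assert best is not None
    return best


@dataclass(frozen=True)
class LengthExclusion:
    interactor_id: str
    length: int
    reason: str = "length"


def filter_by_length(lengths: Mapping[str, int],
                     cfg: AnalysisConfig | None = None,
                     ) -> tuple[list[str], list[LengthExclusion]]:
    """Drop interactors strictly longer than the size cutoff (default 1,500).

    Returns the retained interactor ids (input order preserved) and an
    exclusion report.
    """
    cfg = cfg or AnalysisConfig()
    retained: list[str] = []
    excluded: list[LengthExclusion] = []
    for interactor_id, length in lengths.items():
        if length > cfg.max_interactor_length:
            excluded.append(LengthExclusion(interactor_id, length))
        else:
            retained.append(interactor_id)
    return retained, excluded
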