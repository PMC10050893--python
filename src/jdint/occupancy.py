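"""Per-residue interface occupancy profiles and recognition-region calling.

Occupancy at a residue is the percentage of interactors whose selected
interface contains that residue (the y-axis of the interface-usage plots).
Molecular recognition regions are runs of positions each bound by more
than half of the interactors, chained while successive qualifying
positions are at most ``max_gap`` apart and kept only when the resulting
span exceeds ``min_region_span``. Interactors are classified as
JD-dominant or C-terminal-dominant by where the majority of their
interface residues fall relative to the Josephin-domain boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .core import AnalysisConfig, DomainSpan, ReferenceProtein, residues_in_span
from .docking import InterfaceSet
from .stats import CorrelationResult, pearson_with_fit

__all__ = [
    "OccupancyProfile",
    "RecognitionRegion",
    "BindingClassification",
    "DomainFractionSummary",
    "compute_occupancy",
    "call_regions",
    "classify_binding",
    "mean_fraction_in_domain",
    "compare_profiles",
    "region_overlap",
    "counts_in_regions",
    "write_occupancy_tsv",
    "write_regions_bed",
    "write_classification_tsv",
]


@dataclass(frozen=True)
class OccupancyProfile:
    """Percent of interactors binding each residue of the reference protein.

    ``occupancy[i]`` is the percentage for residue position ``i + 1``.
    """

    reference_id: str
    n_interactors: int
    occupancy: np.ndarray

    def value(self, pos: int) -> float:
        """Occupancy percentage at 1-based residue position ``pos``."""
        if not (1 <= pos <= len(self.occupancy)):
            raise ValueError(f"position {pos} outside profile")
        return float(self.occupancy[pos - 1])

    @property
    def length(self) -> int:
        return len(self.occupancy)


@dataclass(frozen=True)
class RecognitionRegion:
    """A called molecular recognition region (1-based inclusive interval)."""

    start: int
    end: int
    qualifying_positions: frozenset[int]
    mean_occupancy: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BindingClassification:
    interactor_id: str
    jd_count: int
    cterm_count: int
    label: str  # JD-dominant | Cterm-dominant | tie

    @property
    def fraction_jd(self) -> float:
        """Percentage of interface residues inside the JD."""
        return 100.0 * self.jd_count / (self.jd_count + self.cterm_count)


@dataclass(frozen=True)
class DomainFractionSummary:
    mean: float
    min: float
    max: float
    n: int


def compute_occupancy(interfaces: Sequence[InterfaceSet],
                      reference: ReferenceProtein) -> OccupancyProfile:
    """Per-position coverage percentages over a set of interactor interfaces."""
    if not interfaces:
        raise ValueError("need at least one interface set")
    counts = np.zeros(reference.length, dtype=float)
    for iset in interfaces:
        if iset.reference_id != reference.id:
            raise ValueError(
                f"interface {iset.interactor_id} is on {iset.reference_id!r}, "
                f"not {reference.id!r}"
            )
        for p in iset.positions:
            if p > reference.length:
                raise ValueError(
                    f"position {p} of {iset.interactor_id} outside "
                    f"[1, {reference.length}]"
                )
            counts[p - 1] += 1
    return OccupancyProfile(
        reference_id=reference.id,
        n_interactors=len(interfaces),
        occupancy=100.0 * counts / len(interfaces),
    )


def call_regions(profile: OccupancyProfile,
                 cfg: AnalysisConfig | None = None) -> list[RecognitionRegion]:
    """Call molecular recognition regions from an occupancy profile.

    Qualifying positions have occupancy strictly above ``occupancy_cutoff``;
    successive qualifying positions at most ``max_gap`` apart are chained
    into one region; regions whose span (end - start + 1) does not exceed
    ``min_region_span`` are discarded. Returned sorted by start.
    """
    cfg = cfg or AnalysisConfig()
    qualifying = np.flatnonzero(profile.occupancy > cfg.occupancy_cutoff) + 1
    regions: list[RecognitionRegion] = []
    if qualifying.size == 0:
        return regions
    breaks = np.flatnonzero(np.diff(qualifying) > cfg.max_gap)
    for chain in np.split(qualifying, breaks + 1):
        start, end = int(chain[0]), int(chain[-1])
        if end - start + 1 <= cfg.min_region_span:
            continue
        regions.append(RecognitionRegion(
            start=start,
            end=end,
            qualifying_positions=frozenset(int(p) for p in chain),
            mean_occupancy=float(np.mean([profile.value(int(p)) for p in chain])),
        ))
    return regions


def classify_binding(interface: InterfaceSet,
                     reference: ReferenceProtein) -> BindingClassification:
    """Split an interactor's interface at the JD boundary and label the majority."""
    if not interface.positions:
        raise ValueError(f"interface {interface.interactor_id} is empty")
    jd = reference.jd_span
    jd_count = residues_in_span(interface.positions, jd)
    cterm_count = len(interface.positions) - jd_count
    if jd_count > cterm_count:
        label = "JD-dominant"
    elif jd_count < cterm_count:
        label = "Cterm-dominant"
    else:
        label = "tie"
    return BindingClassification(
        interactor_id=interface.interactor_id,
        jd_count=jd_count,
        cterm_count=cterm_count,
        label=label,
    )


def mean_fraction_in_domain(interfaces: Sequence[InterfaceSet],
                            reference: ReferenceProtein,
                            span: DomainSpan) -> DomainFractionSummary:
    """Mean (and range of) per-interactor percentage of interface residues in a span."""
    if not interfaces:
        raise ValueError("need at least one interface set")
    fractions = []
    for iset in interfaces:
        if not iset.positions:
            raise ValueError(f"interface {iset.interactor_id} is empty")
        inside = residues_in_span(iset.positions, span)
        fractions.append(100.0 * inside / len(iset.positions))
    return DomainFractionSummary(
        mean=float(np.mean(fractions)),
        min=float(np.min(fractions)),
        max=float(np.max(fractions)),
        n=len(fractions),
    )


PositionMap = Union[Mapping[int, int], Callable[[int], Optional[int]]]


def compare_profiles(a: OccupancyProfile, b: OccupancyProfile,
                     position_map: PositionMap | None = None) -> CorrelationResult:
    """Pearson correlation and OLS line between two occupancy profiles.

    Without a position map the profiles must have equal length and are
    paired position-by-position. With a map (e.g. the wt -> exp coordinate
    map, where polyQ positions are undefined) only mapped positions are
    paired; the regression is of ``b`` on ``a``.
    """
    if position_map is None:
        if a.length != b.length:
            raise ValueError("profiles differ in length; supply a position map")
        xs = a.occupancy
        ys = b.occupancy
    else:
        mapper = position_map if callable(position_map) else position_map.get
        xs_list, ys_list = [], []
        for pos in range(1, a.length + 1):
            mapped = mapper(pos)
            if mapped is None or not (1 <= mapped <= b.length):
                continue
            xs_list.append(a.value(pos))
            ys_list.append(b.value(mapped))
        xs, ys = np.asarray(xs_list), np.asarray(ys_list)
    if len(xs) < 3:
        raise ValueError("fewer than 3 paired positions")
    return pearson_with_fit(xs, ys)


def _as_positions(obj: Union[Iterable[int], Sequence[RecognitionRegion]]) -> set[int]:
    items = list(obj)
    if items and isinstance(items[0], RecognitionRegion):
        out: set[int] = set()
        for region in items:
            out.update(range(region.start, region.end + 1))
        return out
    return set(items)  # type: ignore[arg-type]


def region_overlap(a, b) -> int:
    """Number of positions shared by two region lists (or position sets)."""
    return len(_as_positions(a) & _as_positions(b))


def counts_in_regions(interfaces: Sequence[InterfaceSet],
                      regions: Sequence[RecognitionRegion]) -> dict[str, int]:
    """Per-interactor count of interface residues inside any called region.

    Positions covered by several (overlapping) regions are counted once.
    """
    covered: set[int] = set()
    for region in regions:
        covered.update(range(region.start, region.end + 1))
    return {
        iset.interactor_id: len(iset.positions & covered)
        for iset in interfaces
    }


# ---------------------------------------------------------------------------
# writers

def write_occupancy_tsv(profile: OccupancyProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["position", "occupancy_pct"])
        for i, value in enumerate(profile.occupancy, start=1):
            writer.writerow([i, f"{value:.4f}"])


def write_regions_bed(regions: Sequence[RecognitionRegion], reference_id: str,
                      path: str | Path) -> None:
    """Write regions as BED intervals (0-based half-open: start-1, end)."""
    with open(path, "w", newline="") as fh:
        for i, region in enumerate(regions, start=1):
            fh.write(f"{reference_id}\t{region.start - 1}\t{region.end}\t"
                     f"region_{i}\t{region.mean_occupancy:.1f}\n")


def write_classification_tsv(classifications: Sequence[BindingClassification],
                             path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["interactor_id", "jd_count", "cterm_count",
                        "fraction_jd_pct", "label"])
        for c in classifications:
            writer.writerow([c.interactor_id, c.jd_count, c.cterm_count,
                             f"{c.fraction_jd:.1f}", c.label])
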