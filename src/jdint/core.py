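"""Core domain model: reference proteins, domain spans, analysis thresholds.

The reference (bait) proteins are the Josephin-domain deubiquitinases:
human ataxin-3 in its wild-type (14Q) and polyQ-expanded (50Q) forms,
the single-domain paralogs JOSD1/JOSD2, and the fly Josephin-like protein.
Residue numbering is 1-based and all intervals are inclusive on both ends,
matching the conventional "residues 1-180" style of structural annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "DomainSpan",
    "ReferenceProtein",
    "AnalysisConfig",
    "map_position",
    "wt_exp_position_map",
    "residues_in_span",
    "load_references",
    "builtin_references",
]


@dataclass(frozen=True)
class DomainSpan:
    """A named 1-based inclusive residue interval on a reference protein."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid span {self.name}: [{self.start}, {self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: object) -> bool:
        return isinstance(pos, int) and self.start <= pos <= self.end


@dataclass(frozen=True)
class ReferenceProtein:
    """A docked bait protein with its domain architecture.

    Parameters
    ----------
    id:
        Short identifier, e.g. ``"wt_atxn3"``.
    form:
        ``"wt"``, ``"exp"`` (polyQ-expanded) or ``"single-domain"`` for
        proteins that are essentially a bare Josephin domain.
    length:
        Residue count (361 for wild-type ataxin-3, 397 for the 50Q form).
    polyq_span:
        1-based inclusive interval of the polyQ tract, or ``None``.
    polyq_length:
        Number of consecutive glutamines (14 wild-type, 50 expanded).
    domains:
        Annotated :class:`DomainSpan` intervals (JD, UIMs, NES, polyQ).
    """

    id: str
    form: str
    length: int
    polyq_span: Optional[tuple[int, int]] = None
    polyq_length: Optional[int] = None
    domains: tuple[DomainSpan, ...] = ()

    def __post_init__(self) -> None:
        if self.form not in ("wt", "exp", "single-domain"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.length < 1:
            raise ValueError("length must be positive")
        if self.polyq_span is not None:
            q0, q1 = self.polyq_span
            if not (1 <= q0 <= q1 <= self.length):
                raise ValueError(f"polyQ span {self.polyq_span} outside protein")
            if self.polyq_length is not None and q1 - q0 + 1 != self.polyq_length:
                raise ValueError(
                    f"polyQ span {self.polyq_span} inconsistent with "
                    f"{self.polyq_length}Q"
                )
        for d in self.domains:
            if d.end > self.length:
                raise ValueError(f"domain {d.name} extends past length {self.length}")

    def domain(self, name: str) -> DomainSpan:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(f"{self.id} has no domain named {name!r}")

    @property
    def jd_span(self) -> DomainSpan:
        """The Josephin-domain interval (present on every reference)."""
        return self.domain("JD")

    @property
    def cterm_span(self) -> DomainSpan:
        """Everything C-terminal of the JD, i.e. [jd.end+1, length]."""
        jd = self.jd_span
        if jd.end >= self.length:
            raise ValueError(f"{self.id} has no residues beyond the JD")
        return DomainSpan("C-term", jd.end + 1, self.length)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the docking-interface analysis protocol.

    Defaults follow the published protocol: docking clusters kept at
    z-score <= 0; interactors longer than 1,500 residues excluded;
    interactors with six or more polyQ-tract contacts excluded as likely
    artifacts; recognition regions require per-position occupancy strictly
    above 50%, qualifying positions at most 3 apart, and a span strictly
    greater than 3; interaction-strength changes are called at a strict
    10% relative difference.
    """

    occupancy_cutoff: float = 50.0      # percent, strict >
    max_gap: int = 3                    # qualifying positions merge if <= 3 apart
    min_region_span: int = 3            # region kept only if span > this
    polyq_contact_cutoff: int = 6       # excluded at >= this many polyQ contacts
    strength_change_cutoff: float = 0.10  # fraction, strict >
    max_interactor_length: int = 1500   # excluded if strictly longer
    zscore_cutoff: float = 0.0          # clusters retained at z <= this

    def __post_init__(self) -> None:
        if not (0.0 < self.occupancy_cutoff < 100.0):
            raise ValueError("occupancy_cutoff must be in (0, 100)")
        for name in ("max_gap", "polyq_contact_cutoff",
                     "strength_change_cutoff", "max_interactor_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_region_span < 0:
            raise ValueError("min_region_span must be non-negative")


def map_position(pos: int, src: ReferenceProtein, dst: ReferenceProtein) -> Optional[int]:
    """Map a residue position between two forms differing only in polyQ length.

    Positions upstream of the polyQ tract map to themselves; positions
    downstream shift by the difference in polyQ length; positions inside
    the source polyQ tract have no 1:1 counterpart and map to ``None``.

    Raises
    ------
    ValueError
        If ``pos`` is outside ``[1, src.length]`` or either form lacks a
        polyQ annotation.
    """
    if src.polyq_span is None or dst.polyq_span is None:
        raise ValueError("both forms need a polyQ annotation to be mapped")
    if src.polyq_length is None or dst.polyq_length is None:
        raise ValueError("both forms need a polyQ length")
    if not (1 <= pos <= src.length):
        raise ValueError(f"position {pos} outside [1, {src.length}]")
    q0, q1 = src.polyq_span
    if pos < q0:
        return pos
    if pos <= q1:
        return None
    return pos + (dst.polyq_length - src.polyq_length)


def wt_exp_position_map(src: ReferenceProtein, dst: ReferenceProtein) -> dict[int, int]:
    """Dense position map ``src -> dst`` over all mappable (non-polyQ) positions."""
    out: dict[int, int] = {}
    for pos in range(1, src.length + 1):
        mapped = map_position(pos, src, dst)
        if mapped is not None:
            out[pos] = mapped
    return out


def residues_in_span(positions: Iterable[int], span: DomainSpan) -> int:
    """Count positions falling inside a span (boundaries inclusive)."""
    return sum(1 for p in positions if span.start <= p <= span.end)


# ---------------------------------------------------------------------------
# reference annotation I/O

def _parse_reference(entry: Mapping) -> ReferenceProtein:
    domains = tuple(
        DomainSpan(d["name"], int(d["start"]), int(d["end"]))
        for d in entry.get("domains", ())
    )
    polyq = entry.get("polyq")
    span = None
    qlen = None
    if polyq:
        span = (int(polyq["start"]), int(polyq["end"]))
        qlen = int(polyq.get("length", span[1] - span[0] + 1))
    return ReferenceProtein(
        id=str(entry["id"]),
        form=str(entry["form"]),
        length=int(entry["length"]),
        polyq_span=span,
        polyq_length=qlen,
        domains=domains,
    )


def load_references(path: str | Path) -> dict[str, ReferenceProtein]:
    """Load reference-protein annotations from a YAML (or JSON) file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    refs = {}
    for entry in doc["references"]:
        ref = _parse_reference(entry)
        refs[ref.id] = ref
    return refs


def builtin_references() -> dict[str, ReferenceProtein]:
    """Shipped default annotations for the five Josephin-domain baits."""
    text = resources.files("jdint.data").joinpath("references.yaml").read_text()
    doc = yaml.safe_load(text)
    refs = {}
    for entry in doc["references"]:
        ref = _parse_reference(entry)
        refs[ref.id] = ref
    return refs
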