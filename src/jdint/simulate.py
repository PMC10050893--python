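"""Synthetic datasets with known ground truth for every pipeline stage.

Interface sets are sampled per residue: positions inside planted
recognition regions are covered with probability ``p_in`` and everything
else with background probability ``p_out``, emulating the region-structured
occupancy seen in docking interface profiles. Paired wild-type/expanded
datasets derive the expanded interface from the wild-type one through the
polyQ coordinate map and add extra C-terminal coverage (the directional
shift observed for the expanded form), plus optional planted polyQ-contact
artifact interactors. CDS sets contain planted duplicates, isoform pairs
sharing long identical blocks, in-frame-stop and off-size sequences with a
known survivor list.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import AnalysisConfig, DomainSpan, ReferenceProtein, map_position
from .curation import CdsRecord
from .docking import InterfaceSet

__all__ = [
    "InterfaceSimParams",
    "PairSimParams",
    "CdsSimParams",
    "InterfaceTruth",
    "PairTruth",
    "CdsTruth",
    "default_planted_regions",
    "generate_interfaces",
    "generate_wt_exp_pair",
    "generate_cds_set",
]


def default_planted_regions(reference: ReferenceProtein) -> tuple[DomainSpan, ...]:
    """Planted recognition regions echoing the observed binding architecture:

    five regions inside the Josephin domain and, where the protein extends
    beyond it, two in the C-terminal tail (placed clear of the polyQ tract).
    """
    jd = reference.jd_span
    regions = [
        DomainSpan("R1", 10, 22),
        DomainSpan("R2", 45, 57),
        DomainSpan("R3", 80, 92),
        DomainSpan("R4", 120, 132),
        DomainSpan("R5", 160, 172),
    ]
    limit = reference.length
    if reference.polyq_span is not None:
        limit = min(limit, reference.polyq_span[0] - 1)
    for name, start in (("R6", jd.end + 30), ("R7", jd.end + 70)):
        if start + 12 <= limit:
            regions.append(DomainSpan(name, start, start + 12))
    return tuple(regions)


@dataclass(frozen=True)
class InterfaceSimParams:
    """Parameters of the planted-region interface generator.

    ``class_mix`` (fraction of JD-dominant interactors) switches on class
    structure: a JD-class interactor samples ``p_in`` only inside planted
    regions lying in the JD, a C-terminal-class one only in regions beyond
    it. With ``class_mix=None`` every interactor samples every region.
    """

    reference: ReferenceProtein
    regions: tuple[DomainSpan, ...] = ()
    n_interactors: int = 40
    p_in: float = 0.9
    p_out: float = 0.02
    class_mix: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0) and not (self.p_in == self.p_out == 0.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_interactors < 1:
            raise ValueError("n_interactors must be >= 1")
        if self.class_mix is not None and not (0.0 <= self.class_mix <= 1.0):
            raise ValueError("class_mix must be in [0, 1]")

    def planted_regions(self) -> tuple[DomainSpan, ...]:
        return self.regions or default_planted_regions(self.reference)


@dataclass(frozen=True)
class InterfaceTruth:
    regions: tuple[DomainSpan, ...]
    classes: dict[str, Optional[str]]  # interactor -> "JD" | "Cterm" | None


def _coverage_probabilities(params: InterfaceSimParams,
                            interactor_class: Optional[str]) -> np.ndarray:
    ref = params.reference
    jd_end = ref.jd_span.end
    p = np.full(ref.length, params.p_out)
    for region in params.planted_regions():
        mid = (region.start + region.end) // 2
        region_side = "JD" if mid <= jd_end else "Cterm"
        if interactor_class is None or interactor_class == region_side:
            p[region.start - 1:region.end] = params.p_in
    return p


def _sample_positions(rng: np.random.Generator, p: np.ndarray) -> frozenset[int]:
    covered = np.flatnonzero(rng.random(p.size) < p) + 1
    if covered.size == 0 and p.max() > 0:
        # degenerate draw: force one position at the best-covered residue
        covered = np.array([int(np.argmax(p)) + 1])
    return frozenset(int(x) for x in covered)


def generate_interfaces(params: InterfaceSimParams,
                        ) -> tuple[list[InterfaceSet], InterfaceTruth]:
    """Sample interactor interface sets with planted region structure."""
    rng = np.random.default_rng(params.seed)
    interfaces: list[InterfaceSet] = []
    classes: dict[str, Optional[str]] = {}
    for i in range(params.n_interactors):
        interactor_id = f"synth_{i:03d}"
        if params.class_mix is None:
            cls: Optional[str] = None
        else:
            cls = "JD" if rng.random() < params.class_mix else "Cterm"
        p = _coverage_probabilities(params, cls)
        positions = _sample_positions(rng, p)
        interfaces.append(InterfaceSet(
            interactor_id=interactor_id,
            reference_id=params.reference.id,
            positions=positions,
            source="synthetic",
        ))
        classes[interactor_id] = cls
    return interfaces, InterfaceTruth(regions=params.planted_regions(),
                                      classes=classes)


# ---------------------------------------------------------------------------
# paired wild-type / expanded datasets

@dataclass(frozen=True)
class PairSimParams:
    """Parameters of the paired wt/exp interface generator.

    The base coverage levels default to values that reproduce realistic
    interface sizes for ataxin-3 (on the order of 65-70 interfacing
    residues in total, two thirds of them in the JD). ``cterm_inflation``
    is the multiplicative increase of C-terminal coverage in the expanded
    form; ``jd_attrition`` is the fraction of JD coverage retained there
    (1.0 = unchanged). ``polyq_artifact_fraction`` of the interactors get
    planted polyQ-tract contacts at or above the exclusion cutoff in both
    forms.
    """

    wt_reference: ReferenceProtein
    exp_reference: ReferenceProtein
    n_interactors: int = 100
    p_in: float = 0.55
    p_out: float = 0.08
    class_mix: Optional[float] = None
    cterm_inflation: float = 1.3
    jd_attrition: float = 1.0
    polyq_artifact_fraction: float = 0.0
    polyq_contact_cutoff: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cterm_inflation < 1.0:
            raise ValueError("cterm_inflation must be >= 1")
        if not (0.0 < self.jd_attrition <= 1.0):
            raise ValueError("jd_attrition must be in (0, 1]")
        if not (0.0 <= self.polyq_artifact_fraction <= 1.0):
            raise ValueError("polyq_artifact_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PairTruth:
    regions: tuple[DomainSpan, ...]
    classes: dict[str, Optional[str]]
    artifact_ids: frozenset[str]


def generate_wt_exp_pair(params: PairSimParams,
                         ) -> tuple[list[InterfaceSet], list[InterfaceSet], PairTruth]:
    """Sample matched wt/exp interface sets with C-terminal inflation.

    The wild-type interface is sampled as in :func:`generate_interfaces`
    but with zero coverage inside the polyQ tract (polyQ contacts are the
    artifact signal, planted only for designated artifact interactors).
    The expanded interface is the coordinate-mapped wild-type interface
    with extra C-terminal gains: an uncovered C-terminal position is added
    with probability ``(cterm_inflation - 1)`` times its base coverage
    probability, so expected C-terminal coverage scales by roughly the
    inflation factor. JD positions are optionally thinned by
    ``jd_attrition``.
    """
    wt, exp = params.wt_reference, params.exp_reference
    base = InterfaceSimParams(
        reference=wt, n_interactors=params.n_interactors,
        p_in=params.p_in, p_out=params.p_out,
        class_mix=params.class_mix, seed=params.seed,
    )
    rng = np.random.default_rng(params.seed)
    jd_end = wt.jd_span.end
    q0, q1 = wt.polyq_span  # type: ignore[misc]
    eq0, eq1 = exp.polyq_span  # type: ignore[misc]

    n_artifacts = int(round(params.polyq_artifact_fraction * params.n_interactors))
    artifact_idx = set(
        rng.choice(params.n_interactors, size=n_artifacts, replace=False).tolist()
    ) if n_artifacts else set()

    wt_sets: list[InterfaceSet] = []
    exp_sets: list[InterfaceSet] = []
    classes: dict[str, Optional[str]] = {}
    artifact_ids: set[str] = set()
    for i in range(params.n_interactors):
        interactor_id = f"pair_{i:03d}"
        if params.class_mix is None:
            cls: Optional[str] = None
        else:
            cls = "JD" if rng.random() < params.class_mix else "Cterm"
        classes[interactor_id] = cls
        p = _coverage_probabilities(base, cls)
        p[q0 - 1:q1] = 0.0  # polyQ tract carries no genuine signal
        wt_positions = set(_sample_positions(rng, p))

        exp_positions = {map_position(pos, wt, exp) for pos in wt_positions}
        exp_positions.discard(None)
        exp_positions = {int(x) for x in exp_positions}  # type: ignore[arg-type]

        if params.jd_attrition < 1.0:
            for pos in [x for x in exp_positions if x <= jd_end]:
                if rng.random() > params.jd_attrition:
                    exp_positions.discard(pos)

        gain_p = (params.cterm_inflation - 1.0) * p
        for pos in range(jd_end + 1, wt.length + 1):
            if pos in wt_positions or q0 <= pos <= q1:
                continue
            if rng.random() < gain_p[pos - 1]:
                mapped = map_position(pos, wt, exp)
                assert mapped is not None
                exp_positions.add(mapped)

        if i in artifact_idx:
            artifact_ids.add(interactor_id)
            k_wt = int(rng.integers(params.polyq_contact_cutoff, q1 - q0 + 2))
            k_exp = int(rng.integers(params.polyq_contact_cutoff, eq1 - eq0 + 2))
            wt_positions.update(
                int(x) + q0 for x in rng.choice(q1 - q0 + 1, size=k_wt, replace=False)
            )
            exp_positions.update(
                int(x) + eq0 for x in rng.choice(eq1 - eq0 + 1, size=k_exp, replace=False)
            )

        wt_sets.append(InterfaceSet(interactor_id, wt.id,
                                    frozenset(wt_positions), "synthetic"))
        exp_sets.append(InterfaceSet(interactor_id, exp.id,
                                     frozenset(exp_positions), "synthetic"))
    truth = PairTruth(regions=base.planted_regions(), classes=classes,
                      artifact_ids=frozenset(artifact_ids))
    return wt_sets, exp_sets, truth


# ---------------------------------------------------------------------------
# synthetic CDS sets

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


@dataclass(frozen=True)
class CdsSimParams:
    """Composition of a synthetic candidate-CDS set.

    ``query_lengths`` play the role of the homology-search query sizes the
    ±10% size filter compares against; ``reference_length`` is the CDS
    size the isoform collapse prefers (an ataxin-3-like 1,086 nt default).
    """

    n_clean: int = 12
    n_duplicates: int = 3
    n_isoform_pairs: int = 3
    n_internal_stop: int = 2
    n_off_size: int = 2
    query_lengths: tuple[int, ...] = (1086, 900, 660)
    reference_length: int = 1086
    isoform_block: int = 300
    include_boundary_cases: bool = True
    seed: int = 0


@dataclass(frozen=True)
class CdsTruth:
    survivors: frozenset[str]          # accessions expected after curation
    removal_reasons: dict[str, str]    # accession -> duplicate|size|isoform|internal-stop
    query_lengths: tuple[int, ...]
    reference_length: int


def _random_cds(rng: np.random.Generator, n_nt: int,
                terminal_stop: bool) -> str:
    """Random in-frame CDS of ``n_nt`` nucleotides with no internal stops."""
    assert n_nt % 3 == 0
    n_codons = n_nt // 3
    body = "".join(
        _NON_STOP_CODONS[int(i)]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    )
    if terminal_stop:
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        body = body[:-3] + stop
    return body


def _clean_length(rng: np.random.Generator, query_lengths: Sequence[int]) -> int:
    q = int(query_lengths[int(rng.integers(0, len(query_lengths)))])
    n = int(round(q * rng.uniform(0.92, 1.08)))
    return n - n % 3


def generate_cds_set(params: CdsSimParams,
                     ) -> tuple[list[CdsRecord], CdsTruth]:
    """Candidate CDS set with planted curation events and known survivors."""
    rng = np.random.default_rng(params.seed)
    records: list[CdsRecord] = []
    survivors: set[str] = set()
    reasons: dict[str, str] = {}
    counter = 0

    def acc(tag: str) -> str:
        nonlocal counter
        counter += 1
        return f"SYN_{tag}_{counter:04d}"

    clean: list[CdsRecord] = []
    for _ in range(params.n_clean):
        n = _clean_length(rng, params.query_lengths)
        rec = CdsRecord(acc("CLEAN"), _random_cds(rng, n, rng.random() < 0.7))
        clean.append(rec)
        records.append(rec)
        survivors.add(rec.accession)

    for _ in range(params.n_duplicates):
        original = clean[int(rng.integers(0, len(clean)))]
        dup = CdsRecord(acc("DUP"), original.sequence)
        records.append(dup)  # appears after the original, so original is kept
        reasons[dup.accession] = "duplicate"

    block = params.isoform_block
    for _ in range(params.n_isoform_pairs):
        host = clean[int(rng.integers(0, len(clean)))]
        # partner strictly farther from the reference size than the host
        host_dist = abs(len(host.sequence) - params.reference_length)
        partner_len = None
        for q in params.query_lengths:
            for factor in (0.905, 1.095):
                cand = int(round(q * factor))
                cand -= cand % 3
                if cand >= block + 6 and abs(cand - params.reference_length) > host_dist:
                    partner_len = cand
                    break
            if partner_len:
                break
        assert partner_len is not None, "no admissible isoform partner length"
        start = 3 * int(rng.integers(1, (len(host.sequence) - block) // 3))
        shared = host.sequence[start:start + block]
        flank = partner_len - block
        pre = flank // 2 - (flank // 2) % 3
        post = flank - pre
        partner_seq = (_random_cds(rng, pre, False) + shared +
                       _random_cds(rng, post - post % 3 + (3 if post % 3 else 0), False))
        partner_seq = partner_seq[:partner_len - partner_len % 3]
        partner = CdsRecord(acc("ISO"), partner_seq)
        records.append(partner)
        reasons[partner.accession] = "isoform"

    for _ in range(params.n_internal_stop):
        n = _clean_length(rng, params.query_lengths)
        seq = _random_cds(rng, n, True)
        stop_at = 3 * int(rng.integers(1, n // 3 - 1))
        seq = seq[:stop_at] + "TAA" + seq[stop_at + 3:]
        rec = CdsRecord(acc("STOP"), seq)
        records.append(rec)
        reasons[rec.accession] = "internal-stop"

    for _ in range(params.n_off_size):
        n = 2 * max(params.query_lengths)
        n -= n % 3
        rec = CdsRecord(acc("SIZE"), _random_cds(rng, n, False))
        records.append(rec)
        reasons[rec.accession] = "size"

    if params.include_boundary_cases:
        records.extend(_boundary_pair_250(rng, acc, params, survivors))
        # length exactly 1.10 x query: inclusive boundary, must be kept
        q = max(q for q in params.query_lengths if int(round(1.10 * q)) % 3 == 0)
        rec = CdsRecord(acc("B110"), _random_cds(rng, int(round(1.10 * q)), False))
        records.append(rec)
        survivors.add(rec.accession)

    order = rng.permutation(len(records))
    # duplicates must stay after their originals so the first occurrence wins
    shuffled = [records[int(i)] for i in order]
    originals = {r.accession for r in clean}
    dup_seqs = {r.sequence for r in records if reasons.get(r.accession) == "duplicate"}
    front = [r for r in shuffled
             if not (r.accession in originals and r.sequence in dup_seqs)]
    keep_first = [r for r in shuffled
                  if r.accession in originals and r.sequence in dup_seqs]
    ordered = keep_first + front

    truth = CdsTruth(
        survivors=frozenset(survivors),
        removal_reasons=reasons,
        query_lengths=params.query_lengths,
        reference_length=params.reference_length,
    )
    return ordered, truth


def _boundary_pair_250(rng: np.random.Generator, acc, params: CdsSimParams,
                       survivors: set[str]) -> list[CdsRecord]:
    """Two sequences sharing an identical block of exactly 250 nt.

    The collapse rule is strict (> 250), so both must survive. Flanking
    bases on each side of the block are forced to differ between the two
    hosts, capping the shared substring at exactly 250.
    """
    block_len = 250
    host_len = params.query_lengths[0] - params.query_lengths[0] % 3
    seq_a = _random_cds(rng, host_len, False)
    a_start = 3 * int(rng.integers(2, (host_len - block_len - 6) // 3))
    block = seq_a[a_start:a_start + block_len]

    pre_len = a_start  # same in-frame offset keeps the block stop-free
    pre = _random_cds(rng, pre_len, False)
    # last base of the prefix must differ from seq_a's base before the block
    if pre[-1] == seq_a[a_start - 1]:
        alt = "GCA" if seq_a[a_start - 1] != "A" else "GCC"
        pre = pre[:-3] + alt
    # complete the straddled codon with a stop-free doublet differing from
    # seq_a's base right after the block
    after = seq_a[a_start + block_len]
    completion = "CC" if after != "C" else "GG"
    tail_len = host_len - pre_len - block_len - 2
    tail_len -= tail_len % 3
    seq_b = pre + block + completion + _random_cds(rng, tail_len, False)

    rec_a = CdsRecord(acc("B250"), seq_a)
    rec_b = CdsRecord(acc("B250"), seq_b)
    survivors.add(rec_a.accession)
    survivors.add(rec_b.accession)
    return [rec_a, rec_b]
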