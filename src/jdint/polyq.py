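"""Paired wild-type vs polyQ-expanded ataxin-3 interface comparison.

Interactors with six or more interface residues inside the polyQ tract are
excluded as likely docking artifacts. For the remaining interactors that
were docked against both ataxin-3 forms, interface residue counts are
tallied in total and split at the JD boundary, feeding paired sign tests,
and relative interaction-strength changes are categorized as increase /
decrease / similar at a strict 10% cutoff.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .core import AnalysisConfig, DomainSpan, ReferenceProtein, residues_in_span
from .docking import InterfaceSet

__all__ = [
    "PairedCounts",
    "StrengthChange",
    "PolyqExclusion",
    "polyq_filter",
    "paired_counts",
    "strength_change",
    "sign_counts",
    "write_paired_counts_tsv",
    "write_strength_change_tsv",
]


@dataclass(frozen=True)
class PairedCounts:
    """Interface residue counts for one interactor against both ataxin-3 forms."""

    interactor_id: str
    wt_total: int
    exp_total: int
    wt_jd: int
    exp_jd: int
    wt_cterm: int
    exp_cterm: int

    def __post_init__(self) -> None:
        if self.wt_jd + self.wt_cterm != self.wt_total:
            raise ValueError("wt counts do not sum to total")
        if self.exp_jd + self.exp_cterm != self.exp_total:
            raise ValueError("exp counts do not sum to total")


@dataclass(frozen=True)
class StrengthChange:
    """Relative change in interface size, (exp - wt) / wt, and its category."""

    interactor_id: str
    relative_change: float
    category: str  # increase | decrease | similar


@dataclass(frozen=True)
class PolyqExclusion:
    interactor_id: str
    form: str
    polyq_contacts: int
    reason: str = "polyQ"


def polyq_filter(interfaces: Sequence[InterfaceSet],
                 reference: ReferenceProtein,
                 cfg: AnalysisConfig | None = None,
                 ) -> tuple[list[InterfaceSet], list[PolyqExclusion]]:
    """Exclude interactors with >= 6 interface residues in the polyQ tract."""
    cfg = cfg or AnalysisConfig()
    if reference.polyq_span is None:
        raise ValueError(f"{reference.id} has no polyQ tract annotated")
    q0, q1 = reference.polyq_span
    span = DomainSpan("polyQ", q0, q1)
    retained: list[InterfaceSet] = []
    excluded: list[PolyqExclusion] = []
    for iset in interfaces:
        contacts = residues_in_span(iset.positions, span)
        if contacts >= cfg.polyq_contact_cutoff:
            excluded.append(PolyqExclusion(iset.interactor_id, reference.form,
                                           contacts))
        else:
            retained.append(iset)
    return retained, excluded


def _split_counts(iset: InterfaceSet, reference: ReferenceProtein) -> tuple[int, int]:
    jd = residues_in_span(iset.positions, reference.jd_span)
    return jd, len(iset.positions) - jd


def paired_counts(wt_interfaces: Sequence[InterfaceSet],
                  exp_interfaces: Sequence[InterfaceSet],
                  wt_ref: ReferenceProtein,
                  exp_ref: ReferenceProtein,
                  cfg: AnalysisConfig | None = None,
                  ) -> tuple[list[PairedCounts], dict[str, list]]:
    """Match interactors docked against both forms and tally interface counts.

    The polyQ artifact filter is applied to each form independently; an
    interactor failing in either form is excluded from the paired analysis.
    Interactors present in only one form are reported as unmatched. The JD
    split uses each form's own coordinates (the JD is N-terminal of the
    polyQ tract, so it is identical in both).
    """
    cfg = cfg or AnalysisConfig()
    wt_kept, wt_excl = polyq_filter(wt_interfaces, wt_ref, cfg)
    exp_kept, exp_excl = polyq_filter(exp_interfaces, exp_ref, cfg)
    polyq_failed = {e.interactor_id for e in wt_excl} | {e.interactor_id for e in exp_excl}
    wt_by_id = {i.interactor_id: i for i in wt_kept
                if i.interactor_id not in polyq_failed}
    exp_by_id = {i.interactor_id: i for i in exp_kept
                 if i.interactor_id not in polyq_failed}
    shared = [i for i in wt_by_id if i in exp_by_id]
    unmatched = sorted((set(wt_by_id) | set(exp_by_id)) - set(shared))
    if not shared:
        raise ValueError("no interactor is present in both forms after filtering")
    pairs: list[PairedCounts] = []
    for interactor_id in shared:
        wt_jd, wt_ct = _split_counts(wt_by_id[interactor_id], wt_ref)
        exp_jd, exp_ct = _split_counts(exp_by_id[interactor_id], exp_ref)
        pairs.append(PairedCounts(
            interactor_id=interactor_id,
            wt_total=wt_jd + wt_ct, exp_total=exp_jd + exp_ct,
            wt_jd=wt_jd, exp_jd=exp_jd,
            wt_cterm=wt_ct, exp_cterm=exp_ct,
        ))
    report = {
        "polyq_excluded": wt_excl + exp_excl,
        "unmatched": unmatched,
    }
    return pairs, report


def sign_counts(pairs: Sequence[PairedCounts], region: str = "total",
                ) -> tuple[int, int, int]:
    """Tally (positive, negative, tie) signs of exp - wt differences.

    ``region`` selects which counts are compared: ``"total"``, ``"jd"`` or
    ``"cterm"``.
    """
    attr = {"total": ("exp_total", "wt_total"),
            "jd": ("exp_jd", "wt_jd"),
            "cterm": ("exp_cterm", "wt_cterm")}[region]
    n_pos = n_neg = n_tie = 0
    for pair in pairs:
        diff = getattr(pair, attr[0]) - getattr(pair, attr[1])
        if diff > 0:
            n_pos += 1
        elif diff < 0:
            n_neg += 1
        else:
            n_tie += 1
    return n_pos, n_neg, n_tie


def strength_change(pairs: Sequence[PairedCounts],
                    cfg: AnalysisConfig | None = None,
                    ) -> tuple[list[StrengthChange], dict[str, float]]:
    """Relative interaction-strength change per interactor and category shares.

    The change is (exp_total - wt_total) normalized by the wt count;
    ``increase`` / ``decrease`` require the magnitude to strictly exceed
    the cutoff (default 10%), everything else is ``similar``. Pairs with
    wt_total == 0 are excluded from the shares (no defined denominator).
    Shares are percentages over the analyzed pairs and sum to 100.
    """
    cfg = cfg or AnalysisConfig()
    changes: list[StrengthChange] = []
    for pair in pairs:
        if pair.wt_total == 0:
            continue
        rel = (pair.exp_total - pair.wt_total) / pair.wt_total
        if rel > cfg.strength_change_cutoff:
            category = "increase"
        elif rel < -cfg.strength_change_cutoff:
            category = "decrease"
        else:
            category = "similar"
        changes.append(StrengthChange(pair.interactor_id, rel, category))
    shares: dict[str, float] = {"increase": 0.0, "decrease": 0.0, "similar": 0.0}
    if changes:
        for c in changes:
            shares[c.category] += 1
        for key in shares:
            shares[key] = 100.0 * shares[key] / len(changes)
    return changes, shares


def write_paired_counts_tsv(pairs: Sequence[PairedCounts], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["interactor_id", "wt_total", "exp_total",
                         "wt_jd", "exp_jd", "wt_cterm", "exp_cterm"])
        for p in pairs:
            writer.writerow([p.interactor_id, p.wt_total, p.exp_total,
                             p.wt_jd, p.exp_jd, p.wt_cterm, p.exp_cterm])


def write_strength_change_tsv(changes: Sequence[StrengthChange],
                              path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["interactor_id", "relative_change", "category"])
        for c in changes:
            writer.writerow([c.interactor_id, f"{c.relative_change:.4f}",
                             c.category])
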