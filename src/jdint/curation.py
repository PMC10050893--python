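"""CDS curation for the Josephin gene-family phylogeny input.

Starting from candidate coding sequences pulled from annotated genomes,
the protocol removes identical CDS encoded by different transcripts,
discards sequences whose length is more than 10% away from every query
sequence, collapses isoform transcripts that share an identical nucleotide
block longer than 250 bp (keeping the one closest in length to the
reference CDS), rewrites headers to accession plus taxonomy, drops
sequences with in-frame stop codons, and strips terminal stop codons.
Every removal is attributed to exactly one reason and the per-step counts
telescope through the report.

Alignment, translation-aware alignment and tree inference are downstream
external steps and are out of scope here, as is the initial homology
search that produces the candidate CDS.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CdsRecord",
    "StepReport",
    "CurationReport",
    "read_cds_fasta",
    "write_cds_fasta",
    "parse_header",
    "dedupe_identical",
    "size_filter",
    "collapse_shared_region",
    "remove_inframe_stops",
    "strip_terminal_stops",
    "annotate_headers",
    "shared_block_length",
    "curate",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CdsRecord:
    """A candidate coding sequence with optional taxonomy metadata."""

    accession: str
    sequence: str
    species: Optional[str] = None
    family: Optional[str] = None
    class_: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    @property
    def header(self) -> str:
        fields = [self.accession]
        if self.species or self.family or self.class_:
            fields += [self.species or "", self.family or "", self.class_ or ""]
        return "|".join(fields)


@dataclass(frozen=True)
class StepReport:
    step: str
    n_in: int
    n_out: int


@dataclass
class CurationReport:
    steps: list[StepReport] = field(default_factory=list)
    removals: dict[str, str] = field(default_factory=dict)  # accession -> reason
    warnings: list[str] = field(default_factory=list)

    def record_step(self, step: str, n_in: int, n_out: int) -> None:
        if self.steps and self.steps[-1].n_out != n_in:
            raise ValueError(
                f"step counts do not telescope: {self.steps[-1].step} emitted "
                f"{self.steps[-1].n_out} but {step} received {n_in}"
            )
        self.steps.append(StepReport(step, n_in, n_out))

    def record_removal(self, accession: str, reason: str) -> None:
        if accession in self.removals:
            raise ValueError(f"{accession} removed twice ({self.removals[accession]}, {reason})")
        self.removals[accession] = reason


# ---------------------------------------------------------------------------
# FASTA I/O

def parse_header(header: str) -> CdsRecord:
    """Parse an ``accession|species|family|class`` header (partial fields ok)."""
    fields = header.split("|")
    return CdsRecord(
        accession=fields[0],
        sequence="N",  # placeholder; caller replaces
        species=fields[1] if len(fields) > 1 and fields[1] else None,
        family=fields[2] if len(fields) > 2 and fields[2] else None,
        class_=fields[3] if len(fields) > 3 and fields[3] else None,
    )


def read_cds_fasta(path: str | Path) -> list[CdsRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = parse_header(rec.description.split()[0])
        records.append(replace(meta, sequence=str(rec.seq).upper()))
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.header, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# curation steps

def dedupe_identical(records: Sequence[CdsRecord],
                     report: CurationReport | None = None) -> list[CdsRecord]:
    """Keep one representative per exact nucleotide sequence (first wins)."""
    seen: set[str] = set()
    out: list[CdsRecord] = []
    for rec in records:
        if rec.sequence in seen:
            if report is not None:
                report.record_removal(rec.accession, "duplicate")
            continue
        seen.add(rec.sequence)
        out.append(rec)
    return out


def size_filter(records: Sequence[CdsRecord], query_lengths: Sequence[int],
                tol: float = 0.10,
                report: CurationReport | None = None) -> list[CdsRecord]:
    """Keep sequences within ±tol of at least one query length (inclusive).

    Lengths are compared in a single unit (nucleotides here); a record is
    kept iff some query length ``q`` satisfies ``|len - q| <= tol * q``.
    """
    if not query_lengths:
        raise ValueError("need at least one query length")
    out: list[CdsRecord] = []
    for rec in records:
        n = len(rec.sequence)
        if any(abs(n - q) <= tol * q for q in query_lengths):
            out.append(rec)
        elif report is not None:
            report.record_removal(rec.accession, "size")
    return out


def shared_block_length(a: str, b: str) -> int:
    """Length of the longest identical substring shared by two sequences."""
    matcher = difflib.SequenceMatcher(None, a, b, autojunk=False)
    return matcher.find_longest_match(0, len(a), 0, len(b)).size


def _candidate_pairs(records: Sequence[CdsRecord], k: int) -> set[tuple[int, int]]:
    # k-mer seeding: any shared identical block of length >= k contains a
    # shared k-mer, so seeding is complete for blocks longer than min_shared
    index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        seq = rec.sequence
        for j in range(len(seq) - k + 1):
            index.setdefault(seq[j:j + k], []).append(i)
    pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        uniq = sorted(set(hits))
        for ai in range(len(uniq)):
            for bi in range(ai + 1, len(uniq)):
                pairs.add((uniq[ai], uniq[bi]))
    return pairs


def collapse_shared_region(records: Sequence[CdsRecord],
                           reference_length: int,
                           min_shared: int = 250,
                           report: CurationReport | None = None) -> list[CdsRecord]:
    """Collapse transcripts sharing an identical block strictly longer than 250 nt.

    Pairs sharing such a block are grouped transitively; within a group,
    only the sequence whose length is closest to ``reference_length``
    survives, ties broken by keeping the longer sequence, then by
    lexicographic accession.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    n = len(records)
    if n < 2:
        return list(records)
    k = min(32, min_shared + 1)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in _candidate_pairs(records, k):
        if find(i) != find(j):
            if shared_block_length(records[i].sequence, records[j].sequence) > min_shared:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    out: list[CdsRecord] = []
    survivors: set[int] = set()
    for members in groups.values():
        best = min(members, key=lambda i: (
            abs(len(records[i].sequence) - reference_length),
            -len(records[i].sequence),
            records[i].accession,
        ))
        survivors.add(best)
        if report is not None:
            for i in members:
                if i != best:
                    report.record_removal(records[i].accession, "isoform")
    for i in range(n):
        if i in survivors:
            out.append(records[i])
    return out


def remove_inframe_stops(records: Sequence[CdsRecord],
                         report: CurationReport | None = None) -> list[CdsRecord]:
    """Drop sequences with a stop codon before the final codon (frame 1).

    Sequences whose length is not a multiple of 3 cannot be scanned in
    frame and are removed with reason ``frame``.
    """
    out: list[CdsRecord] = []
    for rec in records:
        seq = rec.sequence
        if len(seq) % 3 != 0:
            if report is not None:
                report.record_removal(rec.accession, "frame")
            continue
        codons = [seq[i:i + 3] for i in range(0, len(seq) - 3, 3)]
        if any(c in STOP_CODONS for c in codons):
            if report is not None:
                report.record_removal(rec.accession, "internal-stop")
            continue
        out.append(rec)
    return out


def strip_terminal_stops(records: Sequence[CdsRecord]) -> list[CdsRecord]:
    """Remove a trailing stop codon where present (idempotent)."""
    out = []
    for rec in records:
        seq = rec.sequence
        if len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS:
            out.append(replace(rec, sequence=seq[:-3]))
        else:
            out.append(rec)
    return out


def annotate_headers(records: Sequence[CdsRecord],
                     taxonomy: Mapping[str, Mapping[str, str]],
                     report: CurationReport | None = None) -> list[CdsRecord]:
    """Attach species/family/class to each record from a taxonomy table."""
    out = []
    for rec in records:
        entry = taxonomy.get(rec.accession)
        if entry is None:
            if report is not None:
                report.warnings.append(f"no taxonomy for {rec.accession}")
            out.append(rec)
        else:
            out.append(replace(rec,
                               species=entry.get("species"),
                               family=entry.get("family"),
                               class_=entry.get("class")))
    return out


# ---------------------------------------------------------------------------
# pipeline

_ALL_STEPS = ("dedupe", "size", "merge-dedupe", "collapse", "annotate",
              "internal-stops", "strip-stops")


def curate(record_sets: Sequence[Sequence[CdsRecord]],
           query_lengths: Sequence[int],
           reference_length: int,
           taxonomy: Mapping[str, Mapping[str, str]] | None = None,
           min_shared: int = 250,
           size_tol: float = 0.10,
           steps: Sequence[str] = _ALL_STEPS,
           ) -> tuple[list[CdsRecord], CurationReport]:
    """Run the full curation protocol over one or more candidate CDS sets.

    Per-set steps (duplicate removal, size filter) run first; the sets are
    then merged and deduplicated again before isoform collapse, header
    annotation and stop-codon handling. ``steps`` allows disabling
    individual stages.
    """
    report = CurationReport()
    enabled = set(steps)
    per_file: list[list[CdsRecord]] = [list(s) for s in record_sets]

    n_in = sum(len(s) for s in per_file)
    if "dedupe" in enabled:
        per_file = [dedupe_identical(s, report) for s in per_file]
    report.record_step("dedupe", n_in, sum(len(s) for s in per_file))

    n_in = sum(len(s) for s in per_file)
    if "size" in enabled:
        per_file = [size_filter(s, query_lengths, size_tol, report)
                    for s in per_file]
    report.record_step("size", n_in, sum(len(s) for s in per_file))

    merged: list[CdsRecord] = [rec for s in per_file for rec in s]
    n_in = len(merged)
    if "merge-dedupe" in enabled:
        merged = dedupe_identical(merged, report)
    report.record_step("merge-dedupe", n_in, len(merged))

    n_in = len(merged)
    if "collapse" in enabled:
        merged = collapse_shared_region(merged, reference_length, min_shared,
                                        report)
    report.record_step("collapse", n_in, len(merged))

    n_in = len(merged)
    if "annotate" in enabled and taxonomy is not None:
        merged = annotate_headers(merged, taxonomy, report)
    report.record_step("annotate", n_in, len(merged))

    n_in = len(merged)
    if "internal-stops" in enabled:
        merged = remove_inframe_stops(merged, report)
    report.record_step("internal-stops", n_in, len(merged))

    n_in = len(merged)
    if "strip-stops" in enabled:
        merged = strip_terminal_stops(merged)
    report.record_step("strip-stops", n_in, len(merged))

    return merged, report
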