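"""End-to-end pipeline runs driven by a single YAML config.

The occupancy pipeline goes read -> length filter -> polyQ artifact filter
-> occupancy profile -> recognition regions -> JD/C-terminal classification
-> statistics, and, when a matched expanded-form dataset is configured,
additionally produces paired counts, sign tests and strength-change
categories. Every run writes a manifest (config snapshot, input digests,
per-stage counts, package version) so outputs are reproducible
byte-for-byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .core import AnalysisConfig, ReferenceProtein, builtin_references, load_references, wt_exp_position_map
from .curation import CurationReport, curate, read_cds_fasta, write_cds_fasta
from .docking import filter_by_length, read_interface_tsv
from .occupancy import (
    classify_binding,
    compute_occupancy,
    call_regions,
    compare_profiles,
    mean_fraction_in_domain,
    write_classification_tsv,
    write_occupancy_tsv,
    write_regions_bed,
)
from .polyq import (
    paired_counts,
    polyq_filter,
    sign_counts,
    strength_change,
    write_paired_counts_tsv,
    write_strength_change_tsv,
)
from .stats import sign_test

__all__ = ["InputError", "run_occupancy_pipeline", "run_curation_pipeline"]


class InputError(Exception):
    """A missing or malformed pipeline input."""


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def _resolve_reference(spec: Any) -> ReferenceProtein:
    refs = builtin_references()
    if isinstance(spec, str):
        if spec in refs:
            return refs[spec]
        raise InputError(f"unknown builtin reference {spec!r} "
                         f"(have: {sorted(refs)})")
    if isinstance(spec, Mapping):
        path = Path(spec["file"])
        if not path.exists():
            raise InputError(f"reference file not found: {path}")
        custom = load_references(path)
        return custom[spec["id"]]
    raise InputError(f"cannot interpret reference spec {spec!r}")


def _analysis_config(cfg_section: Mapping | None) -> AnalysisConfig:
    return AnalysisConfig(**(cfg_section or {}))


def _read_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            lengths[row["interactor_id"]] = int(row["length"])
    return lengths


def _one_form(interfaces, reference, cfg, out_dir: Path, suffix: str,
              exclusions: list[dict], counts: dict) -> tuple:
    """Length/polyQ filtering, occupancy, regions and classification for one form."""
    if reference.polyq_span is not None:
        interfaces, polyq_excluded = polyq_filter(interfaces, reference, cfg)
        for exc in polyq_excluded:
            exclusions.append({"interactor_id": exc.interactor_id,
                               "reason": "polyQ", "form": reference.form,
                               "detail": str(exc.polyq_contacts)})
    counts[f"after_polyq_filter{suffix}"] = len(interfaces)
    if not interfaces:
        raise InputError(f"no interactors remain for {reference.id}")
    profile = compute_occupancy(interfaces, reference)
    regions = call_regions(profile, cfg)
    classifications = [classify_binding(i, reference) for i in interfaces]
    write_occupancy_tsv(profile, out_dir / f"occupancy{suffix}.tsv")
    write_regions_bed(regions, reference.id, out_dir / f"regions{suffix}.bed")
    write_classification_tsv(classifications,
                             out_dir / f"classification{suffix}.tsv")
    return interfaces, profile, regions, classifications


def run_occupancy_pipeline(config: str | Path | Mapping,
                           out_dir: str | Path | None = None) -> Path:
    """Run the interface-occupancy pipeline; returns the output directory."""
    cfg_doc = _load_config(config)
    out = Path(out_dir or cfg_doc.get("out_dir", "jdint_out"))
    out.mkdir(parents=True, exist_ok=True)
    cfg = _analysis_config(cfg_doc.get("analysis"))
    reference = _resolve_reference(cfg_doc["reference"])

    interface_path = Path(cfg_doc["interfaces"])
    if not interface_path.exists():
        raise InputError(f"interface file not found: {interface_path}")
    interfaces = read_interface_tsv(interface_path)
    input_digests = {str(interface_path): _sha256(interface_path)}

    counts: dict[str, int] = {"input": len(interfaces)}
    exclusions: list[dict] = []

    if cfg_doc.get("lengths"):
        lengths_path = Path(cfg_doc["lengths"])
        if not lengths_path.exists():
            raise InputError(f"lengths file not found: {lengths_path}")
        input_digests[str(lengths_path)] = _sha256(lengths_path)
        lengths = _read_lengths(lengths_path)
        retained_ids, length_excluded = filter_by_length(lengths, cfg)
        retained = set(retained_ids)
        for exc in length_excluded:
            exclusions.append({"interactor_id": exc.interactor_id,
                               "reason": "length", "form": reference.form,
                               "detail": str(exc.length)})
        interfaces = [i for i in interfaces
                      if lengths.get(i.interactor_id) is None
                      or i.interactor_id in retained]
    counts["after_length_filter"] = len(interfaces)

    interfaces, profile, regions, classifications = _one_form(
        interfaces, reference, cfg, out, "", exclusions, counts)

    n_jd = sum(1 for c in classifications if c.label == "JD-dominant")
    n_ct = sum(1 for c in classifications if c.label == "Cterm-dominant")
    n_tie = len(classifications) - n_jd - n_ct
    stats_doc: dict[str, Any] = {
        "n_interactors": len(interfaces),
        "n_regions": len(regions),
        "jd_dominant": n_jd,
        "cterm_dominant": n_ct,
        "classification_ties": n_tie,
    }
    if n_jd + n_ct > 0:
        stats_doc["jd_vs_cterm_sign_test_p"] = sign_test(n_jd, n_ct, n_tie).p_value
    jd_fraction = mean_fraction_in_domain(interfaces, reference, reference.jd_span)
    stats_doc["mean_jd_fraction_pct"] = jd_fraction.mean
    stats_doc["jd_fraction_range_pct"] = [jd_fraction.min, jd_fraction.max]

    # optional paired wt/exp comparison
    if cfg_doc.get("exp_interfaces"):
        exp_reference = _resolve_reference(cfg_doc.get("exp_reference", "exp_atxn3"))
        exp_path = Path(cfg_doc["exp_interfaces"])
        if not exp_path.exists():
            raise InputError(f"interface file not found: {exp_path}")
        input_digests[str(exp_path)] = _sha256(exp_path)
        exp_raw = read_interface_tsv(exp_path)
        exp_interfaces, exp_profile, exp_regions, _ = _one_form(
            exp_raw, exp_reference, cfg, out, "_exp", exclusions, counts)

        pairs, pair_report = paired_counts(interfaces, exp_interfaces,
                                           reference, exp_reference, cfg)
        for interactor_id in pair_report["unmatched"]:
            exclusions.append({"interactor_id": interactor_id,
                               "reason": "unmatched", "form": "both",
                               "detail": ""})
        write_paired_counts_tsv(pairs, out / "paired_counts.tsv")
        changes, shares = strength_change(pairs, cfg)
        write_strength_change_tsv(changes, out / "strength_change.tsv")
        counts["paired"] = len(pairs)

        for region_name in ("total", "jd", "cterm"):
            n_pos, n_neg, n_ties = sign_counts(pairs, region_name)
            entry: dict[str, Any] = {"positive": n_pos, "negative": n_neg,
                                     "ties": n_ties}
            if n_pos + n_neg > 0:
                entry["p_value"] = sign_test(n_pos, n_neg, n_ties).p_value
            stats_doc[f"paired_sign_test_{region_name}"] = entry
        stats_doc["strength_change_shares_pct"] = shares
        corr = compare_profiles(profile, exp_profile,
                                wt_exp_position_map(reference, exp_reference))
        stats_doc["wt_exp_profile_correlation"] = asdict(corr)

    with open(out / "stats.json", "w") as fh:
        json.dump(stats_doc, fh, indent=2, sort_keys=True)
    with open(out / "exclusions.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["interactor_id", "reason",
                                                "form", "detail"],
                                delimiter="\t", lineterminator="\n")
        writer.writeheader()
        writer.writerows(exclusions)

    manifest = {
        "tool": "jdint",
        "version": __version__,
        "pipeline": "occupancy",
        "config": cfg_doc,
        "inputs": input_digests,
        "counts": counts,
        "analysis_config": asdict(cfg),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def run_curation_pipeline(config: str | Path | Mapping,
                          out_dir: str | Path | None = None) -> Path:
    """Run the CDS curation pipeline; returns the output directory."""
    cfg_doc = _load_config(config)
    out = Path(out_dir or cfg_doc.get("out_dir", "jdint_curation"))
    out.mkdir(parents=True, exist_ok=True)

    fasta_paths = [Path(p) for p in cfg_doc["fastas"]]
    for path in fasta_paths:
        if not path.exists():
            raise InputError(f"FASTA not found: {path}")
    record_sets = [read_cds_fasta(p) for p in fasta_paths]

    taxonomy = None
    input_digests = {str(p): _sha256(p) for p in fasta_paths}
    if cfg_doc.get("taxonomy"):
        tax_path = Path(cfg_doc["taxonomy"])
        if not tax_path.exists():
            raise InputError(f"taxonomy file not found: {tax_path}")
        input_digests[str(tax_path)] = _sha256(tax_path)
        taxonomy = {}
        with open(tax_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                taxonomy[row["accession"]] = row

    kwargs: dict[str, Any] = {}
    if cfg_doc.get("steps"):
        kwargs["steps"] = cfg_doc["steps"]
    survivors, report = curate(
        record_sets,
        query_lengths=[int(q) for q in cfg_doc["query_lengths"]],
        reference_length=int(cfg_doc["reference_length"]),
        taxonomy=taxonomy,
        min_shared=int(cfg_doc.get("min_shared", 250)),
        size_tol=float(cfg_doc.get("size_tol", 0.10)),
        **kwargs,
    )
    write_cds_fasta(survivors, out / "curated.fasta")
    _write_curation_report(report, out / "curation_report.tsv")

    manifest = {
        "tool": "jdint",
        "version": __version__,
        "pipeline": "curation",
        "config": cfg_doc,
        "inputs": input_digests,
        "counts": {s.step: {"in": s.n_in, "out": s.n_out} for s in report.steps},
        "disabled_steps": [
            s for s in ("dedupe", "size", "merge-dedupe", "collapse",
                        "annotate", "internal-stops", "strip-stops")
            if cfg_doc.get("steps") and s not in cfg_doc["steps"]
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


def _write_curation_report(report: CurationReport, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record", "field", "value"])
        for step in report.steps:
            writer.writerow(["step", step.step, f"{step.n_in}->{step.n_out}"])
        for accession, reason in sorted(report.removals.items()):
            writer.writerow(["removal", accession, reason])
        for warning in report.warnings:
            writer.writerow(["warning", "", warning])
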