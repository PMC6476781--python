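"""End-to-end orchestration of the OLSP workflow.

Per sequencing run: demultiplex -> dereplicate -> calibrate LFN
thresholds on the run's controls (per marker) -> filter -> Renkonen
replicate screen -> >=2-replicate consensus. After a first taxonomic
assignment, habitat-incompatible detections drive a second calibration
pass from the original dereplicated table. Validated variants from all
runs are pooled, merged into cross-marker contigs, clustered into MOTUs
and assigned; metrics are computed on the Macrometazoan items of the
eDNA samples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import contigs as contigs_mod
from . import lfn, metrics as metrics_mod, motus as motus_mod, taxonomy
from .counts import ReadCountTable
from .demux import DemuxStats, demultiplex, dereplicate, read_seqs
from .design import (
    EDNA,
    MOCK,
    RunDesign,
    Variant,
    attach_mock_expectations,
    load_mock_expectations,
    parse_design_all,
)
from .seqs import in_silico_pcr
from .simulate import PRIMERS


@dataclass
class PipelineParams:
    primer_mismatches: int = 2
    thresholds: lfn.LFNThresholds | None = None  # None = calibrate on controls
    renkonen_cutoff: float = 0.5
    min_replicates: int = 2
    min_overlap: int = 100
    cluster_threshold: float = 0.03
    ltg_ladder: tuple = taxonomy.DEFAULT_LADDER
    ltg_inclusion: float = 0.9
    min_identity: float = 80.0
    exclusions: tuple = taxonomy.DEFAULT_EXCLUSIONS
    anneal_mismatches: int = 2  # for expected mock amplicon prediction
    second_pass: bool = True

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["thresholds"] = self.thresholds.as_dict() if self.thresholds else None
        d["ltg_ladder"] = [list(x) for x in self.ltg_ladder]
        d["exclusions"] = list(self.exclusions)
        return d


@dataclass
class RunReport:
    run_id: str
    demux_stats: DemuxStats
    discarded_non_acgt: int = 0
    calibration: dict = field(default_factory=dict)  # marker -> CalibrationReport
    calibration_pass2: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)  # marker -> FilterTrace
    missing_mock_taxa: list = field(default_factory=list)


@dataclass
class PipelineResult:
    params: PipelineParams
    run_reports: dict[str, RunReport]
    validated: pd.DataFrame  # item-level: variant, marker, sample, count
    variants: dict[str, Variant]
    contigs: list
    unmerged: list
    ambiguous: list
    items: pd.DataFrame  # (item, sample) rows with markers/motu/taxonomy
    assignments: list
    motus: list
    mock_retention: dict[str, dict]
    metrics: dict[str, pd.DataFrame]


def expected_mock_variants(
    design: RunDesign,
    reference: taxonomy.ReferenceDB,
    anneal_mismatches: int = 2,
) -> dict[str, dict[str, list[tuple[str, str, str]]]]:
    """Per mock sample: expected (marker, sequence, role) trimmed amplicons.

    Expected sequences are predicted by in-silico PCR of each expected
    taxon's reference template with each primer set.
    """
    species_to_ref = {
        path.at("species"): ref_id for ref_id, path in reference.taxonomy.items()
    }
    out: dict[str, dict[str, list[tuple[str, str, str]]]] = {}
    for sample_id, rec in design.samples.items():
        if rec.category != MOCK:
            continue
        per_taxon: dict[str, list[tuple[str, str, str]]] = {}
        for taxon, role in rec.expected_taxa:
            ref_id = species_to_ref.get(taxon)
            amps = []
            if ref_id is not None:
                template = reference.seqs[ref_id]
                for name, marker in design.markers.items():
                    amp = in_silico_pcr(template, marker.fwd, marker.rev, anneal_mismatches)
                    if amp:
                        amps.append((name, amp, role))
            per_taxon[taxon] = amps
        out[sample_id] = per_taxon
    return out


def build_control_sets(
    table: ReadCountTable,
    design: RunDesign,
    expected: dict[str, dict[str, list[tuple[str, str, str]]]],
) -> tuple[set, set, list]:
    """(must_keep, must_drop, missing mock taxa) for calibration.

    must_keep: every replicate occurrence of an expected variant in its
    mock sample. must_drop: every occurrence in a negative control, plus
    occurrences in mocks of variants that are not expected there.
    """
    by_seq = {(v.marker, v.seq): vid for vid, v in table.variants.items()}
    must_keep: set = set()
    must_drop: set = set()
    missing: list = []
    expected_vids_per_mock: dict[str, set[str]] = {}
    for sample_id, per_taxon in expected.items():
        vids = set()
        for taxon, amps in per_taxon.items():
            found = False
            for marker, seq, _role in amps:
                vid = by_seq.get((marker, seq))
                if vid is None:
                    continue
                found = True
                vids.add(vid)
                for rep in design.replicates(sample_id, marker):
                    must_keep.add((vid, sample_id, rep))
            if not found:
                missing.append((sample_id, taxon))
        expected_vids_per_mock[sample_id] = vids

    negatives = {s for s, rec in design.samples.items() if rec.is_negative}
    for row in table.df.itertuples():
        if row.sample in negatives:
            must_drop.add((row.variant, row.sample, row.replicate))
        elif row.sample in expected_vids_per_mock and row.variant not in expected_vids_per_mock[row.sample]:
            must_drop.add((row.variant, row.sample, row.replicate))
    # keep occurrences with zero reads are reported by calibrate as dropouts
    must_keep = {o for o in must_keep}
    return must_keep, must_drop, missing


def _process_run(
    run_id: str,
    reads,
    design: RunDesign,
    reference: taxonomy.ReferenceDB,
    params: PipelineParams,
) -> tuple[ReadCountTable, pd.DataFrame, RunReport, set, set]:
    """First pass for one run. Returns (dereplicated table, validated,

    report, must_keep, must_drop)."""
    per_pcr, stats, _ = demultiplex(reads, design, params.primer_mismatches)
    table, discarded = dereplicate(per_pcr)
    report = RunReport(run_id=run_id, demux_stats=stats, discarded_non_acgt=discarded)

    expected = expected_mock_variants(design, reference, params.anneal_mismatches)
    must_keep, must_drop, missing = build_control_sets(table, design, expected)
    report.missing_mock_taxa = missing

    validated_parts = []
    for marker in sorted(design.markers):
        sub = table.subset_marker(marker)
        if sub.n_occurrences() == 0:
            continue
        if params.thresholds is None:
            cal = lfn.calibrate(
                sub,
                _marker_occurrences(must_keep, table, marker),
                _marker_occurrences(must_drop, table, marker),
            )
            report.calibration[marker] = cal
            thresholds = cal.thresholds
        else:
            thresholds = params.thresholds
        validated, _, trace = lfn.filter_chain(
            sub, thresholds, params.renkonen_cutoff, params.min_replicates
        )
        report.traces[marker] = trace
        validated_parts.append(validated)
    validated = (
        pd.concat(validated_parts, ignore_index=True)
        if validated_parts
        else pd.DataFrame(columns=["variant", "marker", "sample", "count", "n_replicates"])
    )
    return table, validated, report, must_keep, must_drop


def _marker_occurrences(occs: set, table: ReadCountTable, marker: str) -> set:
    """Subset an occurrence set to variants of one marker."""
    return {o for o in occs if table.variants[o[0]].marker == marker}


def _assign_variant_taxa(
    validated: pd.DataFrame,
    variants: dict[str, Variant],
    reference: taxonomy.ReferenceDB,
    params: PipelineParams,
) -> dict[str, str | None]:
    """Deepest assigned taxon name per validated variant id."""
    out: dict[str, str | None] = {}
    cache: dict[str, str | None] = {}
    for vid in sorted(set(validated["variant"])):
        seq = variants[vid].seq
        if seq in cache:
            out[vid] = cache[seq]
            continue
        hits = taxonomy.search_reference(seq, reference, params.min_identity)
        assignment = taxonomy.ltg_assign(vid, hits, params.ltg_ladder, params.ltg_inclusion)
        name = assignment.ltg.deepest_name if assignment.ltg else None
        cache[seq] = name
        out[vid] = name
    return out


def run_pipeline(
    designs: dict[str, RunDesign],
    reads_by_run: dict,
    reference: taxonomy.ReferenceDB,
    habitat_map: dict[str, set[str]] | None = None,
    params: PipelineParams | None = None,
    overrides: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the whole workflow in memory.

    ``reads_by_run`` maps run id to an iterable of (read_id, sequence).
    ``habitat_map`` maps taxon names to their compatible habitats; when
    provided (and non-empty) it drives the second filtering pass.
    """
    params = params or PipelineParams()
    run_reports: dict[str, RunReport] = {}
    run_tables: dict[str, ReadCountTable] = {}
    run_validated: dict[str, pd.DataFrame] = {}
    controls: dict[str, tuple[set, set]] = {}

    for run_id in sorted(designs):
        design = designs[run_id]
        table, validated, report, must_keep, must_drop = _process_run(
            run_id, reads_by_run[run_id], design, reference, params
        )
        run_reports[run_id] = report
        run_tables[run_id] = table
        run_validated[run_id] = validated
        controls[run_id] = (must_keep, must_drop)

    # Second pass: habitat-unexpected eDNA detections join the drop set.
    if params.second_pass and habitat_map:
        for run_id in sorted(designs):
            design = designs[run_id]
            table = run_tables[run_id]
            validated = run_validated[run_id]
            if validated.empty:
                continue
            variant_taxa = _assign_variant_taxa(validated, table.variants, reference, params)
            sample_habitats = {
                s: rec.habitat
                for s, rec in design.samples.items()
                if rec.category == EDNA and rec.habitat
            }
            unexpected, _unknown = lfn.habitat_unexpected_occurrences(
                table, validated, sample_habitats, variant_taxa, habitat_map
            )
            if not unexpected:
                continue  # fixed point: pass-2 result equals pass 1
            must_keep, must_drop = controls[run_id]
            parts = []
            for marker in sorted(design.markers):
                sub = table.subset_marker(marker)
                if sub.n_occurrences() == 0:
                    continue
                cal2, validated2, trace2 = lfn.second_pass(
                    sub,
                    _marker_occurrences(must_keep, table, marker),
                    _marker_occurrences(must_drop, table, marker),
                    _marker_occurrences(unexpected, table, marker),
                    params.renkonen_cutoff,
                    params.min_replicates,
                )
                run_reports[run_id].calibration_pass2[marker] = cal2
                run_reports[run_id].traces[marker + "_pass2"] = trace2
                parts.append(validated2)
            run_validated[run_id] = (
                pd.concat(parts, ignore_index=True) if parts else validated.iloc[0:0]
            )

    # Pool runs: global variant ids keyed by (marker, sequence).
    pooled_rows = []
    for run_id in sorted(designs):
        table = run_tables[run_id]
        for row in run_validated[run_id].itertuples():
            pooled_rows.append(
                {
                    "run": run_id,
                    "marker": row.marker,
                    "seq": table.variants[row.variant].seq,
                    "sample": row.sample,
                    "count": row.count,
                }
            )
    pooled = pd.DataFrame(pooled_rows, columns=["run", "marker", "seq", "sample", "count"])
    variants: dict[str, Variant] = {}
    seq_to_vid: dict[tuple[str, str], str] = {}
    counter: dict[str, int] = {}
    for marker, seq in sorted(set(zip(pooled["marker"], pooled["seq"]))):
        counter[marker] = counter.get(marker, 0) + 1
        vid = f"{marker}_{counter[marker]:06d}"
        seq_to_vid[(marker, seq)] = vid
        variants[vid] = Variant(vid, marker, seq)
    if len(pooled):
        pooled["variant"] = [seq_to_vid[(m, s)] for m, s in zip(pooled["marker"], pooled["seq"])]
    else:
        pooled["variant"] = pd.Series(dtype=str)
    validated_all = (
        pooled.groupby(["variant", "marker", "sample"], as_index=False)["count"].sum()
        if len(pooled)
        else pd.DataFrame(columns=["variant", "marker", "sample", "count"])
    )

    # Cross-marker contig merging (run-global).
    contig_list, unmerged, ambiguous = contigs_mod.build_contigs(
        sorted(variants.values(), key=lambda v: v.variant_id), params.min_overlap
    )
    variant_to_item: dict[str, str] = {}
    item_seqs: dict[str, str] = {}
    item_members: dict[str, list[str]] = {}
    for c in contig_list:
        for vid in c.members.values():
            variant_to_item[vid] = c.contig_id
        item_seqs[c.contig_id] = c.seq
        item_members[c.contig_id] = sorted(c.members.values())
    for v in unmerged:
        variant_to_item[v.variant_id] = v.variant_id
        item_seqs[v.variant_id] = v.seq
        item_members[v.variant_id] = [v.variant_id]

    # Taxonomic assignment of items (LTG), then MOTU clustering.
    assignments = []
    for item_id in sorted(item_seqs):
        hits = taxonomy.search_reference(item_seqs[item_id], reference, params.min_identity)
        assignments.append(
            taxonomy.ltg_assign(item_id, hits, params.ltg_ladder, params.ltg_inclusion)
        )
    if overrides is not None and len(overrides):
        assignments = taxonomy.apply_overrides(assignments, overrides)
    motu_list = motus_mod.complete_linkage(item_seqs, params.cluster_threshold)
    item_motu = {m: motu.motu_id for motu in motu_list for m in motu.members}

    kept, excluded = taxonomy.macrometazoan_filter(list(assignments), params.exclusions)
    macro_items = {a.item_id for a in kept}
    assign_by_item = {a.item_id: a for a in assignments}

    # Item table: one row per (item, sample).
    item_rows = []
    if len(validated_all):
        per_sample = validated_all.groupby("sample")
        for sample, grp in per_sample:
            by_item: dict[str, set] = {}
            for row in grp.itertuples():
                by_item.setdefault(variant_to_item[row.variant], set()).add(row.marker)
            for item_id, markers in sorted(by_item.items()):
                a = assign_by_item[item_id]
                names = a.ltg.names if a.ltg else (None,) * len(taxonomy.RANKS)
                item_rows.append(
                    {
                        "item": item_id,
                        "sample": sample,
                        "markers": frozenset(markers),
                        "motu": item_motu[item_id],
                        **dict(zip(taxonomy.RANKS, names)),
                        "ir_score": taxonomy.ir_score(a),
                        "macro": item_id in macro_items,
                    }
                )
    items = pd.DataFrame(
        item_rows,
        columns=["item", "sample", "markers", "motu", *taxonomy.RANKS, "ir_score", "macro"],
    )

    mock_retention = _mock_retention(designs, reference, validated_all, variants, params)

    # Metrics on Macrometazoan items of eDNA samples.
    edna_ids = {
        s for rd in designs.values() for s, rec in rd.samples.items() if rec.category == EDNA
    }
    macro_edna = items[(items["macro"]) & (items["sample"].isin(edna_ids))]
    marker_names = sorted({m for rd in designs.values() for m in rd.markers})
    groups = {
        s: rec.predator
        for rd in designs.values()
        for s, rec in rd.samples.items()
        if rec.category == EDNA and rec.predator
    }
    metric_tables = {
        "bc": metrics_mod.bc_table(macro_edna, marker_names),
        "com": metrics_mod.com_table(macro_edna, marker_names),
        "wsd": metrics_mod.wsd_table(macro_edna, marker_names),
        "bsd": metrics_mod.bsd_table(macro_edna),
        "mni": metrics_mod.mni_summary(macro_edna, groups) if len(macro_edna) else pd.DataFrame(),
        "ir": metrics_mod.ir_table(macro_edna, groups) if len(macro_edna) else pd.DataFrame(),
    }

    return PipelineResult(
        params=params,
        run_reports=run_reports,
        validated=validated_all,
        variants=variants,
        contigs=contig_list,
        unmerged=unmerged,
        ambiguous=ambiguous,
        items=items,
        assignments=assignments,
        motus=motu_list,
        mock_retention=mock_retention,
        metrics=metric_tables,
    )


def _mock_retention(designs, reference, validated_all, variants, params):
    """Per mock sample: how many expected prey/predator taxa survived.

    A taxon counts as retained when any of its predicted amplicons is a
    validated variant sequence in that mock sample.
    """
    out: dict[str, dict] = {}
    if not len(validated_all):
        validated_seqs_by_sample = {}
    else:
        validated_seqs_by_sample = {
            sample: {(variants[v].marker, variants[v].seq) for v in grp["variant"]}
            for sample, grp in validated_all.groupby("sample")
        }
    for run_id in sorted(designs):
        design = designs[run_id]
        expected = expected_mock_variants(design, reference, params.anneal_mismatches)
        for sample_id, per_taxon in expected.items():
            present = validated_seqs_by_sample.get(sample_id, set())
            report = {"prey_expected": 0, "prey_retained": 0, "predator_retained": False,
                      "missing": []}
            for taxon, amps in per_taxon.items():
                role = amps[0][2] if amps else "prey"
                retained = any((marker, seq) in present for marker, seq, _ in amps)
                if role == "predator":
                    report["predator_retained"] = bool(retained)
                else:
                    report["prey_expected"] += 1
                    if retained:
                        report["prey_retained"] += 1
                    else:
                        report["missing"].append(taxon)
            out[sample_id] = report
    return out


# ---------------------------------------------------------------------------
# file-based front end


def run_all(config: dict, outdir) -> PipelineResult:
    """Run the pipeline from a configuration mapping (see CLI docs).

    Required keys: design, reads (mapping run id -> FASTQ/FASTA path, or
    a single path for one-run designs), reference_fasta, reference_taxonomy.
    Optional: mocks (expectations TSV: sample, taxon, role — required for
    control-driven calibration), habitat, overrides, and any
    PipelineParams field under "params". Writes all artifact tables plus
    a manifest into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    designs = parse_design_all(config["design"], dict(PRIMERS))
    if config.get("mocks"):
        attach_mock_expectations(designs, load_mock_expectations(config["mocks"]))
    reads_cfg = config["reads"]
    if isinstance(reads_cfg, (str, Path)):
        if len(designs) != 1:
            raise ValueError("a single reads file requires a single-run design")
        reads_cfg = {next(iter(designs)): reads_cfg}
    reads_by_run = {run: read_seqs(path) for run, path in reads_cfg.items()}
    reference = taxonomy.ReferenceDB.load(config["reference_fasta"], config["reference_taxonomy"])
    habitat_map = None
    if config.get("habitat"):
        hdf = pd.read_csv(config["habitat"], sep="\t", dtype=str)
        habitat_map = {
            row.taxon: set(str(row.habitats).split(",")) for row in hdf.itertuples()
        }
    overrides = None
    if config.get("overrides"):
        overrides = pd.read_csv(config["overrides"], sep="\t", dtype=str).fillna("")
    params = PipelineParams(**config.get("params", {}))

    result = run_pipeline(designs, reads_by_run, reference, habitat_map, params, overrides)
    write_artifacts(result, config, outdir)
    return result


def write_artifacts(result: PipelineResult, config: dict, outdir: Path) -> None:
    outdir = Path(outdir)
    result.validated.to_csv(outdir / "validated.tsv", sep="\t", index=False)
    items = result.items.copy()
    if len(items):
        items["markers"] = items["markers"].map(lambda s: ",".join(sorted(s)))
    items.to_csv(outdir / "items.tsv", sep="\t", index=False)
    with open(outdir / "contigs.fasta", "w") as fh:
        for c in result.contigs:
            fh.write(f">{c.contig_id}\n{c.seq}\n")
    with open(outdir / "membership.tsv", "w") as fh:
        fh.write("contig_id\tmarker\tvariant_id\n")
        for c in result.contigs:
            for marker, vid in sorted(c.members.items()):
                fh.write(f"{c.contig_id}\t{marker}\t{vid}\n")
    with open(outdir / "motus.tsv", "w") as fh:
        fh.write("item_id\tmotu_id\trepresentative\n")
        for m in result.motus:
            for member in m.members:
                fh.write(f"{member}\t{m.motu_id}\t{int(member == m.representative)}\n")
    taxonomy.assignments_to_frame(result.assignments).to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )
    for name, table in result.metrics.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    calibration = {
        run_id: {
            "pass1": {m: c.as_dict() for m, c in rep.calibration.items()},
            "pass2": {m: c.as_dict() for m, c in rep.calibration_pass2.items()},
            "missing_mock_taxa": [list(x) for x in rep.missing_mock_taxa],
        }
        for run_id, rep in result.run_reports.items()
    }
    (outdir / "calibration.yaml").write_text(yaml.safe_dump(calibration, sort_keys=True))
    trace = {
        run_id: {
            "demux": rep.demux_stats.as_dict(),
            "discarded_non_acgt": rep.discarded_non_acgt,
            "filters": {m: t.steps for m, t in rep.traces.items()},
        }
        for run_id, rep in result.run_reports.items()
    }
    (outdir / "trace.json").write_text(json.dumps(trace, indent=1, sort_keys=True))
    (outdir / "mock_retention.json").write_text(
        json.dumps(result.mock_retention, indent=1, sort_keys=True)
    )
    manifest = {
        "config": _jsonable(config),
        "config_sha256": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True).encode()
        ).hexdigest(),
        "input_sha256": {
            key: _file_sha256(config[key])
            for key in ("design", "reference_fasta", "reference_taxonomy")
            if config.get(key)
        },
        "params": result.params.as_dict(),
        "n_validated_variants": len(result.variants),
        "n_contigs": len(result.contigs),
        "n_unmerged_variants": len(result.unmerged),
        "n_motus": len(result.motus),
        "n_items": int(result.items["item"].nunique()) if len(result.items) else 0,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
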