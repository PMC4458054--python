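"""End-to-end workflows wiring the modules together.

Two classification workflows are supported -- the stepwise cascade and
the conventional reference-based subtraction -- plus assessment-only
runs over precomputed tables and the simulation workflow that writes a
complete synthetic input set. Every run writes its artifacts plus a run
log recording the package version, seed and thresholds, so that a run
can be reproduced byte-for-byte from its config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from . import __version__
from . import seqio
from .align import MappingParams, PRESETS
from .assess import assessment_report, label_tally
from .classify import (
    CascadeConfig,
    SPECIES_A,
    SPECIES_B,
    TaxonomyMap,
    reference_based_classify,
    run_cascade,
    stage_counts,
)
from .prefilter import contaminant_filter
from .simulate import SimConfig, simulate_reads, simulate_transcriptomes

WORKFLOWS = ("stepwise", "reference_based", "assess_only", "simulate")


class PipelineError(RuntimeError):
    """A pipeline failure carrying the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(config: dict, keys: list[str], workflow: str) -> None:
    missing = [k for k in keys if not config.get(k)]
    if missing:
        raise PipelineError("config", f"workflow {workflow!r} requires: {', '.join(missing)}")


def _preset(config: dict) -> MappingParams:
    name = config.get("preset", "ci_lenient")
    if name not in PRESETS:
        raise PipelineError("config", f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[name]


def _log(out_dir: Path, payload: dict) -> None:
    payload = {"version": __version__, **payload}
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _metrics_from_truth(truth: dict, predicted: dict) -> dict:
    report = assessment_report(truth, predicted)
    metrics = report.as_dict()
    tally = label_tally(predicted)
    for label, n in sorted(tally.items()):
        metrics[f"n_{label}"] = n
    return metrics


def run_pipeline(config: dict) -> dict[str, Path]:
    """Execute one workflow from a validated key/value config.

    Returns the artifact paths written. Raises :class:`PipelineError`
    (with the failing stage) before writing any partial outputs when the
    configuration is invalid.
    """
    workflow = config.get("workflow")
    if workflow not in WORKFLOWS:
        raise PipelineError("config", f"workflow must be one of {WORKFLOWS}, got {workflow!r}")
    _require(config, ["out_dir"], workflow)
    artifacts: dict[str, Path] = {}

    if workflow == "simulate":
        _require(config, ["seed"], workflow)
        out_dir = Path(config["out_dir"])
        sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
        sim_config = SimConfig(**{k: v for k, v in config.items() if k in sim_keys})
        refs = simulate_transcriptomes(sim_config)
        reads, truth = simulate_reads(refs, sim_config, n_reads=int(config.get("n_reads", 10_000)))
        out_dir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(refs.contigs_a, out_dir / "contigs_a.fasta")
        seqio.write_fasta(refs.contigs_b, out_dir / "contigs_b.fasta")
        seqio.write_fasta(refs.genus_refs, out_dir / "genus_refs.fasta")
        seqio.write_fasta(refs.family_db, out_dir / "family_db.fasta")
        seqio.write_taxonomy_tsv(refs.subject_to_family, out_dir / "taxonomy.tsv")
        if sim_config.paired:
            seqio.write_fastq([r for p in reads for r in (p.r1, p.r2)], out_dir / "reads.fastq")
        else:
            seqio.write_fastq(reads, out_dir / "reads.fastq")
        seqio.write_truth_tsv(truth.labels(), out_dir / "truth.tsv")
        _log(out_dir, {"workflow": workflow, "config": config})
        artifacts = {name: out_dir / name for name in (
            "contigs_a.fasta", "contigs_b.fasta", "genus_refs.fasta", "family_db.fasta",
            "taxonomy.tsv", "reads.fastq", "truth.tsv")}
        return artifacts

    if workflow == "assess_only":
        _require(config, ["truth", "predicted"], workflow)
        out_dir = Path(config["out_dir"])
        truth = seqio.read_truth_tsv(config["truth"])
        predicted = {rec.read_id: rec.label for rec in seqio.read_classification(config["predicted"])}
        metrics = _metrics_from_truth(truth, predicted)
        out_dir.mkdir(parents=True, exist_ok=True)
        seqio.write_metrics(metrics, out_dir / "metrics.json")
        _log(out_dir, {"workflow": workflow, "config": config})
        return {"metrics.json": out_dir / "metrics.json"}

    # classification workflows
    if workflow == "stepwise":
        _require(config, ["reads", "ref_a", "ref_b"], workflow)
    else:
        _require(config, ["reads", "ref_b"], workflow)
    out_dir = Path(config["out_dir"])
    reads = seqio.read_reads(config["reads"], format=config.get("reads_format", "fastq"))

    report = None
    if config.get("contaminants"):
        db = seqio.read_sequences(config["contaminants"], "fasta")
        reads, report = contaminant_filter(reads, db)

    if workflow == "stepwise":
        refs_a = seqio.read_sequences(config["ref_a"], "fasta")
        refs_b = seqio.read_sequences(config["ref_b"], "fasta")
        genus_refs = (
            seqio.read_sequences(config["genus_refs"], "fasta") if config.get("genus_refs") else []
        )
        taxonomy = None
        family_db = []
        if config.get("family_db") and config.get("taxonomy"):
            family_db = seqio.read_sequences(config["family_db"], "fasta")
            taxonomy = TaxonomyMap(
                seqio.read_taxonomy_tsv(config["taxonomy"]),
                config.get("family_to_species", {"FamilyA": SPECIES_A, "FamilyB": SPECIES_B}),
            )
        cascade = CascadeConfig(
            params_stage1=_preset(config),
            top_k=int(config.get("top_k", 5)),
        )
        table = run_cascade(reads, refs_a, refs_b, genus_refs, family_db, taxonomy, cascade)
    else:
        host_ref = seqio.read_sequences(config["ref_b"], "fasta")
        table = reference_based_classify(reads, host_ref, _preset(config))

    out_dir.mkdir(parents=True, exist_ok=True)
    seqio.write_classification(table, out_dir / "classification.tsv")
    counts = stage_counts(table)
    if report is not None:
        counts.update({f"prefilter_{k}": v for k, v in report.as_dict().items()})
    seqio.write_metrics(counts, out_dir / "stage_counts.json")
    artifacts["classification.tsv"] = out_dir / "classification.tsv"
    artifacts["stage_counts.json"] = out_dir / "stage_counts.json"

    if config.get("truth"):
        truth = seqio.read_truth_tsv(config["truth"])
        predicted = {rec.read_id: rec.label for rec in table}
        metrics = _metrics_from_truth(truth, predicted)
        seqio.write_metrics(metrics, out_dir / "metrics.json")
        artifacts["metrics.json"] = out_dir / "metrics.json"

    _log(out_dir, {"workflow": workflow, "config": config,
                   "preset": dataclasses.asdict(_preset(config))})
    return artifacts
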