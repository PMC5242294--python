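"""End-to-end pipeline orchestration with a single validated config.

Two composite runs are provided. The amplicon run either simulates or loads
a multiplexed BBA-Seq experiment, then demultiplexes, assigns reads to
amplicons, calls per-read methylation, fits/applies the senescence clock and
computes co-methylation profiles. The array run simulates beta matrices,
calls differentially methylated CpGs and tests annotation enrichment. Every
output is a TSV/JSON re-derivable from config plus seed; reruns of the same
config are byte-identical (the run log records parameters and versions but
no wall-clock time).
"""

from __future__ import annotations

import fnmatch
import json
import sys
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__, amplicon_io, array_dml, calling, clock, comethylation, simulate

__all__ = ["RunConfig", "BbaseqParams", "ArrayParams", "run_bbaseq_pipeline", "run_array_pipeline"]


class BbaseqParams(BaseModel):
    """Amplicon-pipeline stage parameters."""

    model_config = ConfigDict(extra="forbid")

    # either simulate (paths None) or load an existing experiment
    fastq: Optional[str] = None
    panel_fasta: Optional[str] = None
    panel_bed: Optional[str] = None
    sample_sheet: Optional[str] = None

    n_cells_bulk: int = 2000
    passages: list[int] = Field(default_factory=lambda: list(range(2, 17, 2)))
    reads_per_sample: int = 3000
    clones_per_passage: int = 0
    clone_cells: int = 200
    post_switch_rate: float = 0.0
    conversion_failure_rate: float = 0.005
    inappropriate_conversion_rate: float = 0.002
    seq_error_rate: float = 0.001

    barcode_location: Literal["header", "inline"] = "header"
    max_barcode_mismatch: int = 1
    max_mismatch_frac: float = 0.10
    min_multiplicity: int = calling.DEFAULT_MIN_MULTIPLICITY
    anchor_amplicon: str = "CASR"
    train_sample_pattern: str = "bulk_*"

    @model_validator(mode="after")
    def _check_paths(self) -> "BbaseqParams":
        given = [self.fastq, self.panel_fasta, self.panel_bed, self.sample_sheet]
        if any(given) and not all(given):
            raise ValueError(
                "fastq, panel_fasta, panel_bed and sample_sheet must be given together"
            )
        for p in given:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        return self


class ArrayParams(BaseModel):
    """Array-pipeline stage parameters."""

    model_config = ConfigDict(extra="forbid")

    beta_matrix: Optional[str] = None  # TSV to load instead of simulating
    annotation: Optional[str] = None
    groups: Optional[str] = None

    n_cpgs: int = 2000
    n_samples_per_group: int = 4
    fraction_drifting: float = 0.05
    effect_size: float = 0.3
    noise_sd: float = 0.02
    delta_threshold: float = array_dml.DELTA_THRESHOLD
    alpha: float = array_dml.ALPHA

    @model_validator(mode="after")
    def _check_paths(self) -> "ArrayParams":
        given = [self.beta_matrix, self.annotation, self.groups]
        if any(given) and not all(given):
            raise ValueError("beta_matrix, annotation and groups must be given together")
        for p in given:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        return self


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    target: Literal["passage", "cpd"] = "passage"
    bbaseq: BbaseqParams = Field(default_factory=BbaseqParams)
    array: ArrayParams = Field(default_factory=ArrayParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _log(out_dir: Path, lines: list[str]) -> None:
    (out_dir / "run.log").write_text("\n".join(lines) + "\n")


def _manifest(out_dir: Path, stages: list[dict]) -> None:
    with open(out_dir / "MANIFEST.json", "w") as fh:
        json.dump({"version": __version__, "stages": stages}, fh, indent=1, sort_keys=True)


def run_bbaseq_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate/load -> demux -> assign -> call -> clock -> co-methylation.

    Writes per-sample methylation-call and epiallele-pattern TSVs, the
    trained clock model JSON, a predictions TSV (per-CpG estimates, combined,
    truth, deviation), conditional co-methylation profiles for the anchor
    amplicon, and demultiplex/assignment statistics. On a stage failure the
    partial outputs are kept and MANIFEST.json records the failed stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = config.bbaseq
    stages: list[dict] = []
    log = [f"senmeth {__version__}", f"seed {config.seed}", f"target {config.target}",
           "config " + json.dumps(config.model_dump(), sort_keys=True)]
    stage = "simulate"
    try:
        if p.fastq is None:
            sim_cfg = simulate.default_config(
                seed=config.seed,
                n_cells_bulk=p.n_cells_bulk,
                passages=list(p.passages),
                reads_per_sample=p.reads_per_sample,
                conversion_failure_rate=p.conversion_failure_rate,
                inappropriate_conversion_rate=p.inappropriate_conversion_rate,
                seq_error_rate=p.seq_error_rate,
                barcode_location=p.barcode_location,
            )
            sim = simulate.simulate_bbaseq_run(
                sim_cfg, out_dir / "simulated",
                clones_per_passage=p.clones_per_passage,
                clone_cells=p.clone_cells,
                post_switch_rate=p.post_switch_rate,
            )
            fastq = sim["paths"]["fastq"]
            panel = simulate.default_panel()
            sheet = sim["sheet"]
        else:
            fastq = p.fastq
            panel = amplicon_io.read_panel(p.panel_fasta, p.panel_bed)
            sheet = amplicon_io.SampleSheet.from_tsv(p.sample_sheet)
        stages.append({"stage": stage, "status": "ok"})

        stage = "demultiplex"
        bins = amplicon_io.demultiplex(
            fastq, sheet, p.max_barcode_mismatch, p.barcode_location
        )
        demux_stats = pd.DataFrame(
            {"sample_id": list(bins), "n_reads": [len(v) for v in bins.values()]}
        )
        demux_stats.to_csv(out_dir / "demux_stats.tsv", sep="\t", index=False)
        stages.append({"stage": stage, "status": "ok"})

        stage = "assign_and_call"
        sig_ids = {spec.name: f"{spec.name}_cpg{spec.signature_index}" for spec in panel}
        call_rows, pattern_rows, sample_betas = [], [], {}
        reads_by_amplicon: dict[tuple[str, str], list[str]] = {}
        assign_counts = []
        for sample_id, reads in sorted(bins.items()):
            if sample_id == "undetermined":
                continue
            results = []
            for read in reads:
                res = amplicon_io.assign_to_amplicon(
                    read.sequence, panel, p.max_mismatch_frac
                )
                results.append(res)
                if res.assigned:
                    reads_by_amplicon.setdefault(
                        (sample_id, res.amplicon.name), []
                    ).append(read.sequence)
            counts = amplicon_io.assignment_stats(results)
            counts.name = sample_id
            assign_counts.append(counts)
            betas: dict[str, float] = {}
            for spec in panel:
                seqs = reads_by_amplicon.get((sample_id, spec.name), [])
                collapsed = calling.collapse_and_filter(seqs, spec, p.min_multiplicity)
                profile = calling.compute_beta(collapsed, spec)
                profile.insert(0, "amplicon", spec.name)
                profile.insert(0, "sample_id", sample_id)
                call_rows.append(profile)
                pat = calling.patterns_to_frame(collapsed)
                pat.insert(0, "sample_id", sample_id)
                pattern_rows.append(pat)
                sig_beta = profile["beta"].iloc[spec.signature_index] if len(profile) else np.nan
                betas[sig_ids[spec.name]] = sig_beta
            sample_betas[sample_id] = betas
        pd.concat(call_rows, ignore_index=True).to_csv(
            out_dir / "methylation_calls.tsv", sep="\t", index=False
        )
        pd.concat(pattern_rows, ignore_index=True).to_csv(
            out_dir / "read_patterns.tsv", sep="\t", index=False
        )
        pd.DataFrame(assign_counts).fillna(0).astype(int).rename_axis("sample_id").to_csv(
            out_dir / "assignment_stats.tsv", sep="\t"
        )
        stages.append({"stage": stage, "status": "ok"})

        stage = "clock"
        meta = sheet.table.set_index("sample_id")
        target_col = {"passage": "passage", "cpd": "cpd"}[config.target]
        table = pd.DataFrame.from_dict(sample_betas, orient="index")
        table[config.target] = meta[target_col].reindex(table.index)
        train_mask = [
            fnmatch.fnmatch(s, p.train_sample_pattern) for s in table.index
        ]
        model = clock.fit_clock(table[train_mask], target=config.target)
        model.to_json(out_dir / "clock_model.json")
        pred_rows = []
        predictions, truths = [], []
        for sample_id, row in table.iterrows():
            pred = clock.predict(model, row.drop(config.target).to_dict(), sample=sample_id)
            predictions.append(pred)
            truths.append(float(row[config.target]))
            pred_rows.append(
                {"sample_id": sample_id, "true": row[config.target],
                 "combined": pred.combined, "n_cpgs_used": pred.n_cpgs_used,
                 "deviation": pred.combined - row[config.target], **pred.estimates}
            )
        pd.DataFrame(pred_rows).to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
        metrics = clock.evaluate(predictions, truths)
        with open(out_dir / "clock_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1, sort_keys=True)
        log.append(f"clock r2={metrics['r2']:.4f} rmse={metrics['rmse']:.4f} n={metrics['n']}")
        stages.append({"stage": stage, "status": "ok"})

        stage = "comethylation"
        anchor_spec = next(s for s in panel if s.name == p.anchor_amplicon)
        cond_rows = []
        for sample_id in sorted(sample_betas):
            seqs = reads_by_amplicon.get((sample_id, anchor_spec.name), [])
            collapsed = calling.collapse_and_filter(seqs, anchor_spec, p.min_multiplicity)
            if not collapsed:
                continue
            for state in ("M", "U"):
                prof = comethylation.conditional_profile(
                    collapsed, anchor_spec.signature_index, state
                )
                frame = prof.to_frame()
                frame.insert(0, "sample_id", sample_id)
                cond_rows.append(frame)
        if cond_rows:
            pd.concat(cond_rows, ignore_index=True).to_csv(
                out_dir / "conditional_profiles.tsv", sep="\t", index=False
            )
        stages.append({"stage": stage, "status": "ok"})
    except Exception as exc:
        stages.append({"stage": stage, "status": "failed", "error": str(exc)})
        _manifest(out_dir, stages)
        _log(out_dir, log + [f"FAILED at {stage}: {exc}"])
        raise
    _manifest(out_dir, stages)
    _log(out_dir, log)
    return out_dir


def run_array_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate/load beta matrices -> DML -> enrichment -> overlap.

    Two matrices ("series A/B", independently seeded drifting sets) are
    simulated so the cross-series overlap of differentially methylated CpGs
    can be reported alongside per-series DML tables and region/CGI
    enrichment.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a = config.array
    stages: list[dict] = []
    log = [f"senmeth {__version__}", f"seed {config.seed}",
           "config " + json.dumps(config.model_dump(), sort_keys=True)]
    stage = "simulate"
    results = {}
    try:
        datasets = {}
        if a.beta_matrix is not None:
            betas = pd.read_csv(a.beta_matrix, sep="\t", index_col=0)
            annotation = pd.read_csv(a.annotation, sep="\t", index_col=0)
            groups = pd.read_csv(a.groups, sep="\t", index_col=0).iloc[:, 0]
            datasets["A"] = (betas, annotation, groups)
        else:
            for label, offset in (("A", 0), ("B", 1)):
                rng = np.random.default_rng([config.seed + offset, 20162])
                betas, annotation, truth = simulate.generate_beta_matrix(
                    a.n_cpgs, a.n_samples_per_group, a.fraction_drifting, rng,
                    effect_size=a.effect_size, noise_sd=a.noise_sd,
                )
                groups = pd.Series(
                    {c: c.split("_")[0] for c in betas.columns}, name="group"
                )
                betas.to_csv(out_dir / f"betas_{label}.tsv", sep="\t")
                annotation.to_csv(out_dir / f"annotation_{label}.tsv", sep="\t")
                truth.to_csv(out_dir / f"truth_{label}.tsv", sep="\t")
                datasets[label] = (betas, annotation, groups)
        stages.append({"stage": stage, "status": "ok"})

        stage = "dml"
        for label, (betas, annotation, groups) in datasets.items():
            res = array_dml.test_differential(
                betas, groups, a.delta_threshold, a.alpha
            )
            res.to_csv(out_dir / f"dml_{label}.tsv", sep="\t")
            results[label] = (res, annotation)
            counts = array_dml.classify_and_count(res)
            log.append(
                f"series {label}: {counts['n_hyper']} hyper, {counts['n_hypo']} hypo"
            )
        stages.append({"stage": stage, "status": "ok"})

        stage = "enrichment"
        enrich_rows = []
        for label, (res, annotation) in results.items():
            dml_ids = list(res.index[res["call"] != "none"])
            if not dml_ids:
                continue
            for axis in ("refgene_group", "cgi_relation"):
                enr = array_dml.hypergeometric_enrichment(dml_ids, annotation[axis])
                enr = enr.reset_index()
                enr.insert(0, "axis", axis)
                enr.insert(0, "series", label)
                enrich_rows.append(enr)
        if enrich_rows:
            pd.concat(enrich_rows, ignore_index=True).to_csv(
                out_dir / "enrichment.tsv", sep="\t", index=False
            )
        stages.append({"stage": stage, "status": "ok"})

        stage = "overlap"
        if len(results) == 2:
            overlap = array_dml.overlap_sets(results["A"][0], results["B"][0])
            overlap.to_csv(out_dir / "overlap.tsv", sep="\t")
        stages.append({"stage": stage, "status": "ok"})
    except Exception as exc:
        stages.append({"stage": stage, "status": "failed", "error": str(exc)})
        _manifest(out_dir, stages)
        _log(out_dir, log + [f"FAILED at {stage}: {exc}"])
        raise
    _manifest(out_dir, stages)
    _log(out_dir, log)
    return out_dir
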