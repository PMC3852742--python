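"""End-to-end orchestration: quantify -> collate -> classify -> predict ->
enrich -> report, with a provenance manifest sufficient to replay the run."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

from . import diffphos, enrich, quantio, sitepred, synthdata
from .config import ConfigurationError, PipelineConfig


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    manifest: dict
    site_table: quantio.SiteQuantTable
    differential: diffphos.DifferentialTable
    predicted_flags: dict
    overrepresentation: enrich.EnrichmentResult
    fc_shift: enrich.EnrichmentResult | None
    output_dir: Path


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "circaphos",
        "version": _pkg_version("circaphos"),
        "seed": cfg.effective_seed,
        "settings": {
            "criteria": asdict(cfg.criteria),
            "enrichment": asdict(cfg.enrichment),
            "groups": [cfg.group_parent, cfg.group_ox],
        },
        "stages": [],
        "inputs": {
            "quant_table": cfg.quant_table,
            "proteome_fasta": cfg.proteome_fasta,
            "predictions_tsv": cfg.predictions_tsv,
            "synthetic": asdict(cfg.synthetic) if cfg.synthetic else None,
        },
    }

    def stage(name):
        manifest["stages"].append(name)

    try:
        if cfg.synthetic is not None:
            stage("simulate")
            sim = cfg.synthetic
            table, truth = synthdata.generate_phospho_dataset(sim)
            proteome = truth.proteome
            measurements = quantio.measurements_from_frame(table)
            table.to_csv(out / "peptides_synthetic.csv", index=False)
            truth.to_json(out / "truth_synthetic.json")
            group_parent, group_ox = sim.group_parent, sim.group_ox
        else:
            stage("read")
            measurements = quantio.read_quant_table(cfg.quant_table)
            proteome = quantio.read_fasta(cfg.proteome_fasta)
            group_parent, group_ox = cfg.group_parent, cfg.group_ox
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise StageError("input", exc) from exc

    try:
        stage("collate")
        sqt = quantio.collate_sites(measurements, proteome)
        sqt.to_tsv(out / "site_quant.tsv")
    except Exception as exc:
        raise StageError("collate", exc) from exc

    try:
        stage("classify")
        dt = diffphos.classify_partition(
            sqt, cfg.criteria, group_parent=group_parent, group_ox=group_ox
        )
        dt.to_tsv(out / "differential.tsv")
        diffphos.volcano_frame(dt).to_csv(out / "volcano.csv", index=False)
    except Exception as exc:
        raise StageError("classify", exc) from exc

    try:
        stage("predict")
        if cfg.predictions_tsv is not None:
            report = sitepred.import_predictions(cfg.predictions_tsv, proteome)
            predictions = report.accepted
        else:
            predictions = sitepred.predict_proteome(proteome)
        sitepred.export_predictions(predictions, out / "predicted_sites.tsv")
        flags = sitepred.flag_sites(sqt.sites, sitepred.predicted_position_set(predictions))
    except Exception as exc:
        raise StageError("predict", exc) from exc

    try:
        stage("enrich")
        tested = {r.site for r in dt.results if r.site_class != "untested"}
        over = enrich.overrepresentation_test(
            dt.up_sites | dt.down_sites,
            flags,
            tested,
            n_perm=cfg.enrichment.n_perm,
            seed=cfg.effective_seed,
            tail=cfg.enrichment.tail,
        )
        fcs = {k: v for k, v in dt.fold_changes().items() if k in tested}
        n_flagged = sum(1 for k in fcs if flags.get(k, False))
        fc_shift = None
        if 0 < n_flagged < len(fcs):
            fc_shift = enrich.foldchange_shift_test(
                fcs, flags, n_perm=cfg.enrichment.n_perm, seed=cfg.effective_seed + 1
            )
        doc = {"overrepresentation": enrich.result_to_dict(over)}
        if fc_shift is not None:
            doc["fold_change_shift"] = enrich.result_to_dict(fc_shift)
        (out / "enrichment.json").write_text(json.dumps(doc, indent=1))
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    stage("report")
    manifest["counts"] = {
        "n_sites": sqt.n_sites,
        "n_skipped_peptides": len(sqt.skipped),
        "n_up": dt.n_up,
        "n_down": dt.n_down,
        "n_ns": dt.n_ns,
        "n_untested": dt.n_untested,
        "n_predicted_flagged": int(sum(bool(v) for v in flags.values())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return RunReport(manifest, sqt, dt, flags, over, fc_shift, out)
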