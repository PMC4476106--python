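"""End-to-end orchestration: normalize -> detect -> classify -> integrate -> summarize.

Each run logs machine-parsable ``key=value`` count lines per stage and, when
an output directory is given, writes every intermediate table (TSV) plus the
summary report (JSON). When a truth sidecar is available (synthetic runs),
the selected pairs are scored against the planted network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, expression, integration, summary, tables_io
from .config import PipelineConfig
from .simulate import RegulatoryTruth, simulate_dataset, write_truth_sidecar

logger = logging.getLogger("mirlink")

__all__ = ["PipelineResult", "run_pipeline", "evaluate_against_truth"]


@dataclass
class PipelineResult:
    ct: pd.DataFrame
    ndct: pd.DataFrame
    expr: pd.DataFrame
    sheet: pd.DataFrame
    predictions: pd.DataFrame
    expressed: list[str]
    de: pd.DataFrame
    pairs: pd.DataFrame
    panel: pd.DataFrame
    report: dict
    truth: RegulatoryTruth | None = None
    evaluation: dict | None = None
    stage_counts: dict = field(default_factory=dict)


def _log_stage(counts: dict, stage: str, **kv) -> None:
    counts[stage] = kv
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kv.items()))


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        truth, ct, expr, sheet, predictions = simulate_dataset(config.simulation)
        return truth, ct, expr, sheet, predictions, config.simulation.reference_assay
    for name in ("ct_path", "expr_path", "sheet_path", "predictions_path"):
        if getattr(config, name) is None:
            raise ValueError(f"no simulation configured and {name} is not set")
    ct = tables_io.read_expression_matrix(config.ct_path)
    expr = tables_io.read_expression_matrix(config.expr_path)
    sheet = tables_io.read_sample_sheet(config.sheet_path)
    predictions = tables_io.read_prediction_table(config.predictions_path)
    truth = None
    if config.truth_path:
        from .simulate import read_truth_sidecar

        truth = read_truth_sidecar(config.truth_path)
    return truth, ct, expr, sheet, predictions, config.reference_assay


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the full analysis described by ``config``."""
    config.validate()
    counts: dict = {}
    truth, ct, expr, sheet, predictions, reference = _load_inputs(config)
    tables_io.validate_sample_sheet(sheet)
    _log_stage(
        counts, "input", n_assays=ct.shape[0], n_genes=expr.shape[0],
        n_samples=len(sheet), n_predictions=len(predictions),
    )

    # normalize
    ct_resolved = expression.handle_undetermined(
        ct, policy=config.undetermined_policy, undetermined_ct=config.undetermined_ct
    )
    ndct = expression.neg_delta_ct(ct_resolved, reference)
    _log_stage(counts, "normalize", n_assays=ndct.shape[0], reference=reference)

    # detect
    q, a = diffexpr.hsc_sample_groups(sheet)
    expressed = expression.detect_expressed(
        ct_resolved,
        {"quiescent": q, "activated": a},
        max_detect_ct=config.max_detect_ct,
        min_samples_per_group=config.min_detect_samples,
    )
    expressed = [m for m in expressed if m != reference]
    _log_stage(
        counts, "detect", input=ct.shape[0] - 1, kept=len(expressed),
        dropped=ct.shape[0] - 1 - len(expressed),
    )

    # classify
    de_mirna = diffexpr.classify_mirnas(
        ndct.loc[expressed], sheet,
        q_fc=config.mirna_q_fc, a_fc=config.mirna_a_fc,
        p_cut=config.p_cut, paired=config.paired,
    )
    de_gene = diffexpr.classify_genes(
        expr, sheet,
        enrichment_fc=config.gene_enrichment_fc, q_down_fc=config.gene_q_down_fc,
        p_cut=config.p_cut, paired=config.paired,
    )
    de = pd.concat([de_mirna, de_gene], ignore_index=True)
    _log_stage(
        counts, "classify",
        mirna_q=int((de_mirna["class_label"] == "q_associated").sum()),
        mirna_a=int((de_mirna["class_label"] == "a_associated").sum()),
        mirna_unchanged=int((de_mirna["class_label"] == "unchanged").sum()),
        gene_q=int((de_gene["class_label"] == "q_associated").sum()),
        gene_a=int((de_gene["class_label"] == "a_associated").sum()),
        gene_unchanged=int((de_gene["class_label"] == "unchanged").sum()),
    )

    # integrate
    pairs = integration.integrate(
        ndct, expr, de, sheet, predictions,
        fdr_cut=config.fdr_cut, pdb_cut=config.pdb_cut,
    )
    _log_stage(
        counts, "integrate", n_pairs=len(pairs),
        n_selected=int(pairs["selected"].sum()),
    )

    # summarize
    dereg_mirnas = de_mirna.loc[de_mirna["class_label"] != "unchanged", "feature_id"]
    tcounts = summary.targets_per_mirna(pairs, mirna_ids=dereg_mirnas)
    panel = summary.build_panel(
        de, tcounts, panel_min=config.panel_min, strict=config.panel_strict
    )
    cstats = summary.class_target_stats(
        de, tcounts, panel_min=config.panel_min, strict=config.panel_strict
    )
    mirna_classes = summary.class_count_summary(de_mirna)
    gene_classes = summary.class_count_summary(de_gene)
    try:
        coverage = summary.coverage_stats(pairs, de, panel)
    except ValueError:
        coverage = None
    report = {
        "mirna_class_counts": mirna_classes.to_dict(orient="records"),
        "gene_class_counts": gene_classes.to_dict(orient="records"),
        "class_target_stats": cstats.replace({np.nan: None}).to_dict(orient="records"),
        "panel": panel.to_dict(orient="records"),
        "panel_min": config.panel_min,
        "coverage": coverage,
        "targets_histogram": summary.targets_histogram(tcounts).to_dict(orient="records"),
        "n_selected_pairs": int(pairs["selected"].sum()),
        "stage_counts": counts,
    }
    _log_stage(counts, "summarize", panel_size=len(panel))

    evaluation = None
    if truth is not None:
        evaluation = evaluate_against_truth(pairs, truth)
        report["evaluation"] = evaluation

    result = PipelineResult(
        ct=ct, ndct=ndct, expr=expr, sheet=sheet, predictions=predictions,
        expressed=expressed, de=de, pairs=pairs, panel=panel, report=report,
        truth=truth, evaluation=evaluation, stage_counts=counts,
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tables_io.write_expression_matrix(result.ct, out / "mirna_ct.tsv")
    tables_io.write_expression_matrix(result.ndct, out / "mirna_ndct.tsv")
    tables_io.write_expression_matrix(result.expr, out / "gene_expression.tsv")
    tables_io.write_sample_sheet(result.sheet, out / "sample_sheet.tsv")
    tables_io.write_prediction_table(result.predictions, out / "predictions.tsv")
    result.de.to_csv(out / "differential.tsv", sep="\t", index=False, na_rep="NA")
    tables_io.write_pair_table(result.pairs, out / "pairs.tsv")
    tables_io.write_pair_table(
        result.pairs[result.pairs["selected"]], out / "pairs_selected.tsv"
    )
    result.panel.to_csv(out / "panel.tsv", sep="\t", index=False)
    (out / "summary_report.json").write_text(json.dumps(result.report, indent=1))
    if result.truth is not None:
        write_truth_sidecar(result.truth, out / "truth.json")
    config.save(out / "config.yaml")


def evaluate_against_truth(pairs: pd.DataFrame, truth: RegulatoryTruth) -> dict:
    """Precision/recall/empirical FDR of the selected pairs vs the planted set.

    With zero selected pairs precision is undefined (missing) and recall 0.
    """
    if "selected" in pairs.columns:
        flagged = pairs[pairs["selected"]]
    else:
        flagged = pairs
    selected = set(zip(flagged["mirna_id"], flagged["gene_id"]))
    tp = len(selected & truth.true_pairs)
    n_sel = len(selected)
    n_true = len(truth.true_pairs)
    precision = tp / n_sel if n_sel else float("nan")
    recall = tp / n_true if n_true else float("nan")
    return {
        "n_selected": n_sel,
        "n_true": n_true,
        "n_true_positive": tp,
        "precision": precision,
        "recall": recall,
        "empirical_fdr": 1.0 - precision if n_sel else float("nan"),
    }
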