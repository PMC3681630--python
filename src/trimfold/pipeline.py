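"""Stage orchestration: simulate -> preprocess -> DE -> enrichment -> qPCR.

Every stage reads its inputs from, and writes its outputs to, a single run
directory, so any later stage can be re-run from the files on disk.  All
randomness flows from the one seed in the configuration; with a fixed
config the whole output tree is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__, array_io, diffexpr, enrichment, preprocess, qpcr
from .config import SimulationConfig
from .simulate import CONTROL, TREATMENT, array_id, simulate_experiment, \
    write_simulation

logger = logging.getLogger("trimfold")

PathLike = Union[str, Path]


def _load_config(outdir: Path) -> SimulationConfig:
    return SimulationConfig.from_json(outdir / "config.json")


def stage_simulate(config: SimulationConfig, outdir: PathLike):
    """Generate the synthetic experiment and write every table."""
    outdir = Path(outdir)
    result = simulate_experiment(config)
    write_simulation(result, outdir)
    return result


def stage_preprocess(outdir: PathLike) -> dict:
    """Scale-factor normalization and trimmed-mean summarization per phase."""
    outdir = Path(outdir)
    config = _load_config(outdir)
    scale_factors = {}
    for phase in config.phases:
        table = array_io.read_probe_table(outdir / f"probes_{phase}.tsv")
        ctrl, treat = array_id(phase, CONTROL), array_id(phase, TREATMENT)
        summary, sf = preprocess.normalize_and_summarize(table, ctrl, treat)
        array_io.write_gene_signal_table(summary,
                                         outdir / f"gene_signals_{phase}.tsv")
        scale_factors[phase] = {
            "value": sf.value,
            "control_mean": sf.control_mean,
            "treatment_mean": sf.treatment_mean,
        }
    _write_json(scale_factors, outdir / "scale_factors.json")
    return scale_factors


def stage_de(outdir: PathLike, threshold: float = 3.0,
             strict: bool = True) -> dict:
    """Expression ratios, signed fold changes and threshold DE calls."""
    outdir = Path(outdir)
    config = _load_config(outdir)
    counts = {}
    for phase in config.phases:
        signals = array_io.read_gene_signal_table(
            outdir / f"gene_signals_{phase}.tsv")
        ctrl = signals[signals["array_id"] == array_id(phase, CONTROL)]
        treat = signals[signals["array_id"] == array_id(phase, TREATMENT)]
        records = diffexpr.fold_change_table(
            treat, ctrl, phase=phase, floor=config.signal_floor,
            threshold=threshold, strict=strict)
        array_io.write_results(records, outdir / f"fold_changes_{phase}.tsv",
                               columns=array_io.FOLD_COLUMNS)
        up, down = diffexpr.call_differential(records, threshold, strict)
        array_io.write_gene_list(up["gene_id"], outdir / f"de_up_{phase}.txt")
        array_io.write_gene_list(down["gene_id"],
                                 outdir / f"de_down_{phase}.txt")
        counts[phase] = {"up": len(up), "down": len(down),
                         "genes_with_ratio": len(records)}
    return counts


def stage_enrich(outdir: PathLike, method: str = "fisher",
                 alpha: float = 0.05) -> dict:
    """Over-representation of annotation terms in each phase's DE list.

    The background universe is the set of genes with a defined expression
    ratio in that phase (genes lost to QC cannot be called DE).
    """
    outdir = Path(outdir)
    config = _load_config(outdir)
    annotation = array_io.read_annotation(outdir / "annotation.tsv")
    counts = {}
    for phase in config.phases:
        records = array_io.read_fold_changes(outdir / f"fold_changes_{phase}.tsv")
        background = records["gene_id"].tolist()
        de_genes = (array_io.read_gene_list(outdir / f"de_up_{phase}.txt")
                    + array_io.read_gene_list(outdir / f"de_down_{phase}.txt"))
        results = enrichment.term_enrichment(de_genes, background, annotation,
                                             method=method)
        array_io.write_results(results, outdir / f"enrichment_{phase}.tsv",
                               columns=enrichment.RESULT_COLUMNS)
        counts[phase] = int((results["adjusted_p"] <= alpha).sum())
    return counts


def stage_qpcr(outdir: PathLike, scale: str = "fold") -> dict:
    """Comparative-CT quantification and microarray concordance per phase."""
    outdir = Path(outdir)
    config = _load_config(outdir)
    out = {}
    for phase in config.phases:
        ct = array_io.read_ct_table(outdir / f"qpcr_{phase}.tsv")
        stability = qpcr.reference_stability(ct, config.reference_gene)
        if not stability.passed:
            logger.warning("phase %s: reference gene drifts %.3f cycles "
                           "between conditions", phase,
                           stability.max_abs_difference)
        relative = qpcr.delta_delta_ct(ct, config.reference_gene,
                                       CONTROL, TREATMENT)
        array_io.write_results(
            relative, outdir / f"qpcr_relative_{phase}.tsv",
            columns=["gene_id", "delta_ct_treatment", "delta_ct_control",
                     "delta_delta_ct", "relative_expression",
                     "qpcr_fold_change"])
        records = array_io.read_fold_changes(outdir / f"fold_changes_{phase}.tsv")
        try:
            corr = qpcr.concordance(records, relative, scale=scale)
        except ValueError as err:
            # degenerate contrast (e.g. nothing differentially expressed):
            # report the run rather than abort it
            logger.warning("phase %s: concordance undefined (%s)", phase, err)
            corr = {"r": None, "n": int(len(relative)), "slope": None,
                    "intercept": None, "scale": scale,
                    "undefined": str(err)}
        out[phase] = {
            "reference_stability": {
                "max_abs_difference": stability.max_abs_difference,
                "passed": stability.passed,
            },
            "concordance": corr,
        }
    _write_json(out, outdir / "concordance.json")
    return out


def run_all(config: SimulationConfig, outdir: PathLike,
            threshold: float = 3.0, strict: bool = True,
            method: str = "fisher", scale: str = "fold",
            alpha: float = 0.05) -> dict:
    """Execute every stage in order and write the machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, outdir)
    scale_factors = stage_preprocess(outdir)
    de_counts = stage_de(outdir, threshold=threshold, strict=strict)
    enrich_counts = stage_enrich(outdir, method=method, alpha=alpha)
    qpcr_out = stage_qpcr(outdir, scale=scale)

    n_summarized = {}
    for phase in config.phases:
        signals = array_io.read_gene_signal_table(
            outdir / f"gene_signals_{phase}.tsv")
        n_summarized[phase] = int(signals["gene_id"].nunique())

    summary = {
        "tool": "trimfold",
        "version": __version__,
        "seed": config.seed,
        "threshold": threshold,
        "strict": strict,
        "method": method,
        "scale": scale,
        "alpha": alpha,
        "config": config.to_dict(),
        "phases": {
            phase: {
                "scale_factor": scale_factors[phase]["value"],
                "genes_summarized": n_summarized[phase],
                "genes_with_ratio": de_counts[phase]["genes_with_ratio"],
                "n_up": de_counts[phase]["up"],
                "n_down": de_counts[phase]["down"],
                "n_enriched_terms": enrich_counts[phase],
                "concordance_r": qpcr_out[phase]["concordance"]["r"],
                "concordance_n": qpcr_out[phase]["concordance"]["n"],
                "reference_stability_passed":
                    qpcr_out[phase]["reference_stability"]["passed"],
            }
            for phase in config.phases
        },
    }
    _write_json(summary, outdir / "summary.json")
    report(outdir)
    return summary


def report(outdir: PathLike, alpha: float = 0.05,
           top_terms: int = 5) -> str:
    """Human-readable run report plus a gene x contrast log2-ratio matrix.

    The matrix (one log2 column per phase) is suitable for any heatmap
    viewer.  Repeated calls on the same run directory produce byte-identical
    files.
    """
    outdir = Path(outdir)
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"run summary missing: {summary_path}")
    summary = json.loads(summary_path.read_text())
    phases = list(summary["config"]["phases"])

    folds = {p: array_io.read_fold_changes(outdir / f"fold_changes_{p}.tsv")
             for p in phases}
    matrix = None
    for p in phases:
        col = folds[p][["gene_id", "log2_ratio"]].rename(
            columns={"log2_ratio": f"log2_{p}"})
        matrix = col if matrix is None else matrix.merge(
            col, on="gene_id", how="outer")
    matrix = matrix.sort_values("gene_id", kind="mergesort")
    array_io.write_results(matrix, outdir / "log2_matrix.tsv")

    lines = [f"trimfold {summary['version']} run report",
             f"seed: {summary['seed']}", ""]
    for p in phases:
        ph = summary["phases"][p]
        lines.append(f"[{p}]")
        lines.append(f"  scale factor: {ph['scale_factor']:.6f}")
        lines.append(f"  genes summarized: {ph['genes_summarized']}")
        lines.append(f"  genes with defined ratio: {ph['genes_with_ratio']}")
        lines.append(f"  up-regulated (> {summary['threshold']:g}-fold): "
                     f"{ph['n_up']}")
        lines.append(f"  down-regulated: {ph['n_down']}")
        if ph["n_up"] + ph["n_down"] == 0:
            lines.append("  zero DE genes; enrichment not reported")
        else:
            enr = pd.read_csv(outdir / f"enrichment_{p}.tsv", sep="\t")
            hits = enr[enr["adjusted_p"] <= alpha]
            lines.append(f"  enriched terms (BH <= {alpha:g}): {len(hits)}")
            for _, row in hits.head(top_terms).iterrows():
                lines.append(
                    f"    {row['term_id']}  k={row['k']}/K={row['K']}  "
                    f"p={row['p_value']:.3e}  adj={row['adjusted_p']:.3e}")
        if ph["concordance_r"] is None:
            lines.append("  microarray-qPCR concordance undefined "
                         f"(n = {ph['concordance_n']})")
        else:
            lines.append(f"  microarray-qPCR concordance R = "
                         f"{ph['concordance_r']:.4f} (n = {ph['concordance_n']})")
        lines.append("")
    text = "\n".join(lines)
    (outdir / "report.txt").write_text(text)
    return text


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
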