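"""Synthetic spotted-array experiment with known ground truth.

The generator emulates a single-channel oligonucleotide array design with
five identical replicate spots per gene and one pooled control plus one
pooled treatment hybridization per growth phase.  The spot model is
log-normal multiplicative:

    signal(g, r, a) = scale(a) * 2 ** ( baseline(g)
                                        + true_log2_fc(g) * [a is treatment]
                                        + affinity(g, r)
                                        + outlier_shift(g, r, a)
                                        + eps(g, r, a) )

with ``eps ~ Normal(0, noise_sd^2)`` per spot, probe affinity fixed per
physical probe (g, r) across all arrays, and rare symmetric log2 outlier
shifts to exercise the trimmed mean.  Signals are clamped to a positive
floor; floor hits are logged.

Term annotations are drawn so that a configurable number of terms per phase
over-sample that phase's differentially expressed genes, and qPCR plates are
drawn from the same expression truth so that the microarray and qPCR
branches of the pipeline agree exactly in the zero-noise limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import array_io
from .config import SimulationConfig

logger = logging.getLogger("trimfold")

CONTROL = "control"
TREATMENT = "treatment"


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded during generation, for recovery tests.

    ``genes``: one row per (gene, phase) with the spiked log2 fold change,
    the DE label implied by its sign, and the gene's baseline log2
    expression (shared across phases).
    ``terms``: one row per (term, phase) with the enrichment flag.
    ``outliers``: one row per contaminated spot (gene, probe, array).
    """

    genes: pd.DataFrame
    terms: pd.DataFrame
    outliers: pd.DataFrame


@dataclass(frozen=True)
class SimulationResult:
    config: SimulationConfig
    probe_tables: dict[str, pd.DataFrame]   # phase -> spot-level table
    truth: SimulationTruth
    annotation: pd.DataFrame                # long format term/gene pairs
    ct_tables: dict[str, pd.DataFrame]      # phase -> qPCR plate


def gene_ids(n_genes: int) -> np.ndarray:
    width = max(4, len(str(n_genes)))
    return np.array([f"g{i + 1:0{width}d}" for i in range(n_genes)])


def array_id(phase: str, condition: str) -> str:
    return f"{phase}_{condition}"


def _streams(config: SimulationConfig) -> dict:
    """Deterministic per-purpose RNG substreams derived from the one seed."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(4 + 3 * config.n_phases)
    streams = {
        "baseline": np.random.default_rng(children[0]),
        "affinity": np.random.default_rng(children[1]),
        "terms": np.random.default_rng(children[2]),
        "qpcr": np.random.default_rng(children[3]),
    }
    for i, phase in enumerate(config.phases):
        streams[f"de:{phase}"] = np.random.default_rng(children[4 + 3 * i])
        streams[f"noise:{phase}"] = np.random.default_rng(children[5 + 3 * i])
        streams[f"outlier:{phase}"] = np.random.default_rng(children[6 + 3 * i])
    return streams


def _spike_fold_changes(config: SimulationConfig, phase_idx: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-gene true log2 fold changes for one phase (0 for non-DE genes)."""
    n = config.n_genes
    frac_up = config.per_phase("de_fraction_up")[phase_idx]
    frac_down = config.per_phase("de_fraction_down")[phase_idx]
    lo = config.per_phase("fc_log2_min")[phase_idx]
    hi = config.per_phase("fc_log2_max")[phase_idx]
    n_up = round(frac_up * n)
    n_down = round(frac_down * n)
    fc = np.zeros(n)
    chosen = rng.choice(n, size=n_up + n_down, replace=False)
    if hi > lo:
        magnitudes = rng.uniform(lo, hi, size=n_up + n_down)
    else:
        magnitudes = np.full(n_up + n_down, lo)
    fc[chosen[:n_up]] = magnitudes[:n_up]
    fc[chosen[n_up:]] = -magnitudes[n_up:]
    return fc


def _de_labels(fc: np.ndarray) -> np.ndarray:
    return np.where(fc > 0, "up", np.where(fc < 0, "down", "none"))


def simulate_experiment(
    config: SimulationConfig,
    forced_log2_fc: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> SimulationResult:
    """Generate probe tables, truth, annotation and qPCR plates.

    ``forced_log2_fc`` optionally pins the true log2 fold change of specific
    genes, as ``{phase: {gene_id: value}}``; useful for closed-form checks.

    Identical config (including seed) produces bit-identical tables.
    """
    config.validate()
    ids = gene_ids(config.n_genes)
    id_index = {g: i for i, g in enumerate(ids)}
    streams = _streams(config)

    baseline = streams["baseline"].normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes)
    affinity = streams["affinity"].normal(
        0.0, config.probe_affinity_sd,
        size=(config.n_genes, config.n_probe_reps))

    probe_tables: dict[str, pd.DataFrame] = {}
    gene_rows = []
    outlier_rows = []
    scales = config.per_phase("array_scales")

    for p, phase in enumerate(config.phases):
        fc = _spike_fold_changes(config, p, streams[f"de:{phase}"])
        if forced_log2_fc and phase in forced_log2_fc:
            for gid, value in forced_log2_fc[phase].items():
                fc[id_index[gid]] = float(value)

        G, R = config.n_genes, config.n_probe_reps
        eps = streams[f"noise:{phase}"].normal(0.0, config.noise_sd, size=(G, R, 2)) \
            if config.noise_sd > 0 else np.zeros((G, R, 2))
        log2sig = (baseline[:, None, None]
                   + affinity[:, :, None]
                   + fc[:, None, None] * np.array([0.0, 1.0])[None, None, :]
                   + eps)

        rng_out = streams[f"outlier:{phase}"]
        if config.outlier_prob > 0:
            mask = rng_out.random((G, R, 2)) < config.outlier_prob
            signs = rng_out.choice([-1.0, 1.0], size=(G, R, 2))
            log2sig = log2sig + mask * signs * config.outlier_log2_shift
        else:
            mask = np.zeros((G, R, 2), dtype=bool)

        conditions = (CONTROL, TREATMENT)
        arrays = [array_id(phase, c) for c in conditions]
        signal = np.empty((G, R, 2))
        for a, (scale, aid) in enumerate(zip(scales[p], arrays)):
            signal[:, :, a] = scale * np.exp2(log2sig[:, :, a])
        if not np.isfinite(signal).all():
            raise FloatingPointError(
                f"non-finite signal generated for phase {phase}; "
                "check baseline/fold-change magnitudes")
        floored = signal < config.signal_floor
        if floored.any():
            logger.warning("phase %s: %d spot(s) clamped to the signal floor %g",
                           phase, int(floored.sum()), config.signal_floor)
            signal = np.maximum(signal, config.signal_floor)

        frames = []
        for a, (cond, aid) in enumerate(zip(conditions, arrays)):
            frames.append(pd.DataFrame({
                "gene_id": np.repeat(ids, R),
                "probe_index": np.tile(np.arange(1, R + 1), G),
                "array_id": aid,
                "condition": cond,
                "phase": phase,
                "signal": signal[:, :, a].reshape(-1),
            }))
        table = pd.concat(frames, ignore_index=True)
        array_io.validate_probe_table(table, config.n_probe_reps)
        probe_tables[phase] = table

        gene_rows.append(pd.DataFrame({
            "gene_id": ids,
            "phase": phase,
            "true_log2_fc": fc,
            "de_label": _de_labels(fc),
            "baseline_log2": baseline,
        }))
        g_idx, r_idx, a_idx = np.nonzero(mask)
        if len(g_idx):
            outlier_rows.append(pd.DataFrame({
                "gene_id": ids[g_idx],
                "probe_index": r_idx + 1,
                "array_id": [arrays[a] for a in a_idx],
                "phase": phase,
            }))

    truth_genes = pd.concat(gene_rows, ignore_index=True)
    outliers = (pd.concat(outlier_rows, ignore_index=True) if outlier_rows
                else pd.DataFrame(columns=["gene_id", "probe_index",
                                           "array_id", "phase"]))

    annotation, truth_terms = _simulate_annotation(config, ids, truth_genes,
                                                   streams["terms"])
    truth = SimulationTruth(genes=truth_genes, terms=truth_terms,
                            outliers=outliers)
    ct_tables = simulate_qpcr(truth, config, rng=streams["qpcr"])
    return SimulationResult(config=config, probe_tables=probe_tables,
                            truth=truth, annotation=annotation,
                            ct_tables=ct_tables)


def _simulate_annotation(config: SimulationConfig, ids: np.ndarray,
                         truth_genes: pd.DataFrame,
                         rng: np.random.Generator):
    """Draw term memberships; some terms over-sample one phase's DE genes.

    Enriched terms for phase p draw members with weight ``enrichment_boost``
    on that phase's DE genes and weight 1 elsewhere, without replacement.
    """
    n_terms = config.n_terms
    term_ids = [f"T{i + 1:03d}" for i in range(n_terms)]
    sizes = rng.integers(config.term_size_min, config.term_size_max + 1,
                         size=n_terms)
    # first n_enriched_terms per phase are the spiked (enriched) terms
    assigned_phase = {}
    t = 0
    for phase in config.phases:
        for _ in range(config.n_enriched_terms):
            assigned_phase[term_ids[t]] = phase
            t += 1

    de_mask = {
        phase: (truth_genes.loc[truth_genes["phase"] == phase, "de_label"]
                .to_numpy() != "none")
        for phase in config.phases
    }

    members_rows = []
    term_rows = []
    for tid, size in zip(term_ids, sizes):
        phase = assigned_phase.get(tid)
        if phase is not None and de_mask[phase].any():
            weights = np.where(de_mask[phase], config.enrichment_boost, 1.0)
            weights = weights / weights.sum()
            members = rng.choice(ids, size=size, replace=False, p=weights)
        else:
            members = rng.choice(ids, size=size, replace=False)
        members = np.sort(members)
        members_rows.append(pd.DataFrame({
            "term_id": tid,
            "term_label": f"synthetic term {tid}",
            "gene_id": members,
        }))
        for ph in config.phases:
            term_rows.append((tid, ph, phase == ph))
    annotation = pd.concat(members_rows, ignore_index=True)
    truth_terms = pd.DataFrame(term_rows,
                               columns=["term_id", "phase", "enriched"])
    return annotation, truth_terms


def _stratified_panel(fc: np.ndarray, count: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Pick qPCR panel gene indices across up / down / unchanged strata.

    Mirrors a validation panel chosen "within each range of fold change":
    roughly 40% up-regulated, 40% down-regulated, the rest unchanged,
    rebalanced when a stratum is too small.
    """
    up = np.flatnonzero(fc > 0)
    down = np.flatnonzero(fc < 0)
    none = np.flatnonzero(fc == 0)
    want_up = min(len(up), max(0, round(0.4 * count)))
    want_down = min(len(down), max(0, round(0.4 * count)))
    want_none = min(len(none), count - want_up - want_down)
    # top up remaining slots from whichever strata still have genes
    chosen = []
    for pool, want in ((up, want_up), (down, want_down), (none, want_none)):
        if want > 0:
            chosen.append(rng.choice(pool, size=want, replace=False))
    picked = np.concatenate(chosen) if chosen else np.array([], dtype=int)
    short = count - len(picked)
    if short > 0:
        remaining = np.setdiff1d(np.arange(len(fc)), picked)
        picked = np.concatenate([picked, rng.choice(remaining, size=short,
                                                    replace=False)])
    return np.sort(picked)


def simulate_qpcr(truth: SimulationTruth, config: SimulationConfig,
                  rng: Optional[np.random.Generator] = None,
                  ) -> dict[str, pd.DataFrame]:
    """Generate comparative-CT plates from the expression ground truth.

    CT(target, condition) = ct_offset - log2_expression(gene, condition)
    + Normal(0, qpcr_ct_sd); the reference gene sits at a constant CT in
    every condition.  Wells are run in triplicate per (gene, condition) by
    default.
    """
    config.validate()
    if rng is None:
        rng = _streams(config)["qpcr"]
    counts = config.per_phase("qpcr_gene_count")
    plates: dict[str, pd.DataFrame] = {}
    for p, phase in enumerate(config.phases):
        sub = truth.genes[truth.genes["phase"] == phase].reset_index(drop=True)
        fc = sub["true_log2_fc"].to_numpy()
        baseline = sub["baseline_log2"].to_numpy()
        panel = _stratified_panel(fc, counts[p], rng)
        rows = []
        W = config.qpcr_wells
        for cond, is_treat in ((CONTROL, 0.0), (TREATMENT, 1.0)):
            for i in panel:
                expr = baseline[i] + fc[i] * is_treat
                true_ct = config.qpcr_target_ct_offset - expr
                cts = true_ct + (rng.normal(0.0, config.qpcr_ct_sd, size=W)
                                 if config.qpcr_ct_sd > 0 else np.zeros(W))
                for w in range(W):
                    rows.append((cond, sub["gene_id"].iloc[i], w + 1, cts[w]))
            ref = config.qpcr_ref_ct + (
                rng.normal(0.0, config.qpcr_ct_sd, size=W)
                if config.qpcr_ct_sd > 0 else np.zeros(W))
            for w in range(W):
                rows.append((cond, config.reference_gene, w + 1, ref[w]))
        plate = pd.DataFrame(rows, columns=array_io.CT_COLUMNS)
        if (plate["ct"] <= 0).any():
            raise FloatingPointError(
                f"phase {phase}: generated non-positive CT; raise "
                "qpcr_target_ct_offset")
        plates[phase] = plate
    return plates


def write_simulation(result: SimulationResult,
                     outdir: Union[str, Path]) -> None:
    """Write every generated table under ``outdir`` (TSV + config JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_json(outdir / "config.json")
    for phase, table in result.probe_tables.items():
        array_io.write_probe_table(table, outdir / f"probes_{phase}.tsv")
    for phase, plate in result.ct_tables.items():
        array_io.write_ct_table(plate, outdir / f"qpcr_{phase}.tsv")
    array_io.write_annotation(result.annotation, outdir / "annotation.tsv")
    array_io._write_tsv(result.truth.genes, outdir / "truth_genes.tsv",
                        ["gene_id", "phase", "true_log2_fc", "de_label",
                         "baseline_log2"])
    array_io._write_tsv(result.truth.terms, outdir / "truth_terms.tsv",
                        ["term_id", "phase", "enriched"])
    array_io._write_tsv(result.truth.outliers, outdir / "truth_outliers.tsv",
                        ["gene_id", "probe_index", "array_id", "phase"])
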