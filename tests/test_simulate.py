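"""Generator contracts: determinism, structure, closed forms, calibration."""

import numpy as np
import pandas as pd
import pytest

from trimfold import array_io
from trimfold.config import SimulationConfig
from trimfold.simulate import (array_id, simulate_experiment, simulate_qpcr,
                               write_simulation)


def test_identical_config_and_seed_give_bit_identical_tables(
        small_config, tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    write_simulation(simulate_experiment(small_config), a)
    write_simulation(simulate_experiment(small_config), b)
    files_a = sorted(p.name for p in a.iterdir())
    assert files_a == sorted(p.name for p in b.iterdir())
    for name in files_a:
        assert (a / name).read_bytes() == (b / name).read_bytes(), name


def test_different_seeds_differ(small_config):
    a = simulate_experiment(small_config)
    b = simulate_experiment(small_config.replace(seed=small_config.seed + 1))
    phase = small_config.phases[0]
    assert not a.probe_tables[phase]["signal"].equals(
        b.probe_tables[phase]["signal"])


def test_probe_tables_satisfy_structural_invariants(small_result):
    cfg = small_result.config
    for phase, table in small_result.probe_tables.items():
        array_io.validate_probe_table(table, cfg.n_probe_reps)
        assert set(table["array_id"]) == {array_id(phase, "control"),
                                          array_id(phase, "treatment")}
        assert (table["signal"] >= cfg.signal_floor).all()


def test_truth_labels_consistent_with_spiked_folds(small_result):
    genes = small_result.truth.genes
    assert ((genes["true_log2_fc"] > 0) == (genes["de_label"] == "up")).all()
    assert ((genes["true_log2_fc"] < 0) == (genes["de_label"] == "down")).all()
    cfg = small_result.config
    for p, phase in enumerate(cfg.phases):
        sub = genes[genes["phase"] == phase]
        n_up = round(cfg.per_phase("de_fraction_up")[p] * cfg.n_genes)
        n_down = round(cfg.per_phase("de_fraction_down")[p] * cfg.n_genes)
        assert (sub["de_label"] == "up").sum() == n_up
        assert (sub["de_label"] == "down").sum() == n_down
        spiked = sub.loc[sub["de_label"] != "none", "true_log2_fc"].abs()
        assert (spiked >= cfg.per_phase("fc_log2_min")[p] - 1e-12).all()
        assert (spiked <= cfg.per_phase("fc_log2_max")[p] + 1e-12).all()


def test_zero_noise_ratio_is_scale_ratio_without_de(zero_noise_config):
    """With no gene effect every treatment/control spot ratio is the
    array-scale ratio, exactly."""
    cfg = zero_noise_config.replace(de_fraction_up=0.0, de_fraction_down=0.0)
    result = simulate_experiment(cfg)
    for p, phase in enumerate(cfg.phases):
        scale_c, scale_t = cfg.per_phase("array_scales")[p]
        table = result.probe_tables[phase]
        wide = table.pivot_table(index=["gene_id", "probe_index"],
                                 columns="condition", values="signal")
        ratio = wide["treatment"] / wide["control"]
        assert np.allclose(ratio, scale_t / scale_c, rtol=0, atol=0)


def test_forced_fold_change_appears_in_spot_ratios(zero_noise_config):
    cfg = zero_noise_config.replace(de_fraction_up=0.0, de_fraction_down=0.0)
    phase = cfg.phases[0]
    result = simulate_experiment(cfg, forced_log2_fc={phase: {"g0001": 2.0}})
    scale_c, scale_t = cfg.per_phase("array_scales")[0]
    table = result.probe_tables[phase]
    sub = table[table["gene_id"] == "g0001"].pivot_table(
        index="probe_index", columns="condition", values="signal")
    ratio = sub["treatment"] / sub["control"]
    assert np.allclose(ratio, 4.0 * scale_t / scale_c, rtol=1e-15)


def test_outlier_fraction_within_three_binomial_sd():
    cfg = SimulationConfig(n_genes=2000, n_probe_reps=5, outlier_prob=0.02,
                           de_fraction_up=0.0, de_fraction_down=0.0,
                           qpcr_gene_count=5, seed=11)
    result = simulate_experiment(cfg)
    n_spots = sum(len(t) for t in result.probe_tables.values())
    observed = len(result.truth.outliers) / n_spots
    sd = np.sqrt(cfg.outlier_prob * (1 - cfg.outlier_prob) / n_spots)
    assert abs(observed - cfg.outlier_prob) <= 3 * sd


def test_annotation_members_subset_of_universe_and_nonempty(small_result):
    annotation = small_result.annotation
    universe = set(small_result.truth.genes["gene_id"])
    assert set(annotation["gene_id"]) <= universe
    sizes = annotation.groupby("term_id").size()
    assert (sizes > 0).all()
    assert sizes.between(small_result.config.term_size_min,
                         small_result.config.term_size_max).all()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_probe_reps=2).validate()
    with pytest.raises(ValueError):
        SimulationConfig(de_fraction_up=0.6, de_fraction_down=0.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(fc_log2_min=-0.1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(outlier_prob=1.5).validate()


def test_config_json_round_trip(small_config, tmp_path):
    """Scalars canonicalize to per-phase lists; a second trip is exact."""
    path = tmp_path / "config.json"
    small_config.to_json(path)
    once = SimulationConfig.from_json(path)
    assert once.to_dict() == small_config.to_dict()
    once.to_json(path)
    assert SimulationConfig.from_json(path) == once


class TestQpcrPlates:
    def test_zero_noise_ct_differences_follow_spiked_folds(
            self, zero_noise_config):
        result = simulate_experiment(zero_noise_config)
        for phase in zero_noise_config.phases:
            plate = result.ct_tables[phase]
            truth = result.truth.genes.set_index("gene_id")
            truth = truth[truth["phase"] == phase]
            wide = plate.groupby(["gene_id", "condition"])["ct"].mean().unstack()
            for gene, row in wide.iterrows():
                if gene == zero_noise_config.reference_gene:
                    continue
                fc = truth.loc[gene, "true_log2_fc"]
                # treatment CT sits exactly -fc cycles from control CT
                assert row["treatment"] - row["control"] == pytest.approx(
                    -fc, abs=1e-12)

    def test_zero_noise_reference_wells_all_equal_configured_ct(
            self, zero_noise_config):
        result = simulate_experiment(zero_noise_config)
        for plate in result.ct_tables.values():
            ref = plate.loc[plate["gene_id"] ==
                            zero_noise_config.reference_gene, "ct"]
            assert (ref == zero_noise_config.qpcr_ref_ct).all()

    def test_triplicate_wells_per_gene_and_condition(self, small_result):
        for plate in small_result.ct_tables.values():
            wells = plate.groupby(["gene_id", "condition"])["well"].agg(list)
            assert all(sorted(w) == [1, 2, 3] for w in wells)

    def test_panel_spans_de_and_unchanged_strata(self, small_result):
        truth = small_result.truth.genes
        for phase, plate in small_result.ct_tables.items():
            labels = truth[truth["phase"] == phase].set_index("gene_id")
            panel = set(plate["gene_id"]) - {small_result.config.reference_gene}
            panel_labels = set(labels.loc[sorted(panel), "de_label"])
            assert {"up", "down", "none"} <= panel_labels

    def test_standalone_call_reproduces_experiment_plates(self, small_config):
        result = simulate_experiment(small_config)
        again = simulate_qpcr(result.truth, small_config)
        for phase in small_config.phases:
            pd.testing.assert_frame_equal(result.ct_tables[phase], again[phase])
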