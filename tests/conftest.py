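import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trimfold.config import SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from trimfold.simulate import simulate_experiment


@pytest.fixture
def small_config() -> SimulationConfig:
    """A quick 60-gene experiment with every noise source active."""
    return SimulationConfig(
        n_genes=60, n_probe_reps=5,
        de_fraction_up=0.1, de_fraction_down=0.1,
        n_terms=8, term_size_min=5, term_size_max=15, n_enriched_terms=2,
        qpcr_gene_count=8, seed=7,
    ).validate()


@pytest.fixture
def zero_noise_config(small_config) -> SimulationConfig:
    """Same design with every stochastic nuisance switched off."""
    return small_config.replace(
        noise_sd=0.0, probe_affinity_sd=0.0, outlier_prob=0.0,
        baseline_log2_sd=0.0, qpcr_ct_sd=0.0,
    )


@pytest.fixture
def small_result(small_config):
    return simulate_experiment(small_config)


def probe_frame(signals_by_array, gene_id="gA", phase="acidogenic"):
    """Build a one-gene probe table from {array_id: (condition, values)}."""
    frames = []
    for array_id, (condition, values) in signals_by_array.items():
        frames.append(pd.DataFrame({
            "gene_id": gene_id,
            "probe_index": np.arange(1, len(values) + 1),
            "array_id": array_id,
            "condition": condition,
            "phase": phase,
            "signal": np.asarray(values, dtype=float),
        }))
    return pd.concat(frames, ignore_index=True)
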