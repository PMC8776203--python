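import numpy as np
import pandas as pd
import pytest

from chronode import CountExperiment, SimulationConfig, generate_counts


def make_experiment(counts: np.ndarray, time_points=(4, 8, 24, 48), n_rep=3) -> CountExperiment:
    """Wrap a raw array as a CountExperiment with the standard 24-sample design."""
    rows = []
    for t in time_points:
        for arm in ("control", "treated"):
            for r in range(1, n_rep + 1):
                rows.append((f"t{t}_{arm}_r{r}", t, arm, r))
    design = pd.DataFrame(rows, columns=["sample", "time_h", "arm", "replicate"]).set_index(
        "sample"
    )
    genes = [f"G{i:05d}" for i in range(counts.shape[0])]
    return CountExperiment(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=design.index),
        design,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene simulated experiment with the default archetype mixture."""
    cfg = SimulationConfig(n_genes=300, seed=5)
    experiment, truth = generate_counts(cfg)
    return cfg, experiment, truth


@pytest.fixture(scope="session")
def strong_dataset():
    """Strong-effect recovery dataset: |log2FC| = 3, baseline CPM >= ~52, phi = 0.1."""
    fractions = {
        "null": 0.90,
        "direct_up": 0.02,
        "direct_down": 0.02,
        "indirect_up": 0.03,
        "indirect_down": 0.03,
    }
    cfg = SimulationConfig(
        n_genes=2000,
        archetype_fractions=fractions,
        effect_log2_range=(3.0, 3.0),
        baseline_log2cpm_range=(5.7, 9.0),
        dispersion=0.1,
        seed=17,
    )
    experiment, truth = generate_counts(cfg)
    return cfg, experiment, truth
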