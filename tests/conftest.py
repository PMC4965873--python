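import numpy as np
import pandas as pd
import pytest

import corecnet as cn


def small_config(**overrides):
    """Reduced-size simulation for fast unit tests."""
    defaults = dict(
        n_background_proteins=30,
        n_specific=8,
        modules=(("M1", 4, "early-peak"), ("M2", 4, "late-peak")),
        seed=11,
    )
    defaults.update(overrides)
    return cn.SimulationConfig(**defaults)


def make_normalized(values, runs=None, proteins=None):
    """NormalizedTable straight from a log10 array (no imputed cells)."""
    arr = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(arr.shape[0])]
    runs = runs or [f"run{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=proteins, columns=runs)
    mask = pd.DataFrame(False, index=proteins, columns=runs)
    return cn.NormalizedTable(df, mask)


def make_design(rows):
    """SampleDesign from (run, background, time_s, bio, tech) tuples."""
    df = pd.DataFrame(
        [{"run": r, "background": bg, "bait_name": "BAIT1", "time_s": t,
          "bio_rep": b, "tech_rep": k} for r, bg, t, b, k in rows]
    ).set_index("run")
    return cn.SampleDesign(df)


@pytest.fixture(scope="session")
def small_experiment():
    """One small simulated experiment shared across read-only tests."""
    config = small_config()
    table, design, truth = cn.simulate_experiment(config)
    return config, table, design, truth


@pytest.fixture(scope="session")
def small_normalized(small_experiment):
    _, table, design, _ = small_experiment
    return cn.preprocess_table(table, design, seed=5), design
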