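"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import mtgblup as mg


@pytest.fixture(scope="session")
def small_panel():
    """100 DH lines in two families with one simulated trait and its kinship."""
    cfg = mg.SimConfig(
        n_families=2, lines_per_family=(50, 50), n_parents=3,
        chrom_lengths_cM=(100.0,) * 3, n_markers=600, n_traits=1,
        Sigma_g=np.array([[1.0]]), Sigma_e=np.array([[1.0]]),
        n_envs=1, n_blocks=1, var_env=0.0, var_block=0.0, var_gei=0.0,
        replicate_fraction=0.0, seed=11,
    )
    markers, truth, plots = mg.simulate_dataset(cfg)
    K = mg.additive_relationship(mg.qc_filter(markers, 0.0, 0.0))
    return cfg, markers, truth, plots, K


@pytest.fixture(scope="session")
def pair_panel():
    """300 lines in many small families, two traits with genetic correlation 0.8."""
    Sg = np.array([[1.0, 0.8], [0.8, 1.0]])
    Se = np.diag([2.3333, 0.6667])  # target h2 = 0.3, helper h2 = 0.6
    cfg = mg.SimConfig(
        n_families=150, lines_per_family=(2,) * 150, n_parents=151,
        chrom_lengths_cM=(150.0,) * 7, n_markers=2000, n_traits=2,
        Sigma_g=Sg, Sigma_e=Se, n_envs=1, n_blocks=1,
        var_env=0.0, var_block=0.0, var_gei=0.0,
        replicate_fraction=0.0, seed=42,
    )
    markers, truth, plots = mg.simulate_dataset(cfg)
    K = mg.additive_relationship(mg.qc_filter(markers, 0.0, 0.0))
    blues = plots.rename(columns={"value": "blue"})[["line_id", "trait", "blue"]]
    blues = blues.assign(scope="ALL", se=0.0)
    return cfg, truth, blues, K


def blues_from_single_plot(plots: pd.DataFrame) -> pd.DataFrame:
    """Treat single-plot-per-line phenotypes directly as BLUEs."""
    b = plots.rename(columns={"value": "blue"})[["line_id", "trait", "blue"]]
    return b.assign(scope="ALL", se=0.0)
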