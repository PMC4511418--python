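import dataclasses

import pytest

from seedfx.io import AnalysisConfig, DesignConfig, LayoutConfig, RunConfig
from seedfx.pipeline import run_chain, run_simulation
from seedfx.simulate import EffectParams


def small_run_config(master_seed: int = 7, **effect_overrides) -> RunConfig:
    """A miniature experiment (2 plates, 40 features) for fast tests."""
    effects = EffectParams(
        n_features=40,
        latent_dim=6,
        noise_rank=3,
        cells_per_well=15,
        loading_seed=11,
        sampling_seed=master_seed,
    )
    if effect_overrides:
        effects = dataclasses.replace(effects, **effect_overrides)
    return RunConfig(
        design=DesignConfig(n_genes=6, shrnas_per_gene=3, n_seed_pairs=3,
                            n_controls=2, design_seed=master_seed),
        layout=LayoutConfig(n_layout_replicates=1, plate_size=48,
                            n_untreated_per_plate=6, layout_seed=master_seed),
        effects=effects,
        analysis=AnalysisConfig(),
    )


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return small_run_config()


@pytest.fixture(scope="session")
def small_experiment(small_config):
    cells, metadata, truth = run_simulation(small_config)
    return {"cells": cells, "metadata": metadata, "truth": truth,
            "config": small_config}


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """Full simulate -> profile -> analyze bundle on the miniature design."""
    return run_chain(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """One full chain at the default (study-condition) scale."""
    return run_chain(RunConfig.from_master_seed(2026))
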