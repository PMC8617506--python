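import numpy as np
import pandas as pd
import pytest

import midparent as mp


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition panel simulation shared across tests (read-only)."""
    return mp.simulate_panel(mp.SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_norm(default_sim):
    cfg = default_sim.truth.config
    return mp.normalize_to_anchor(default_sim.matrix, default_sim.design, cfg.anchor_genotype)


@pytest.fixture(scope="session")
def default_panel_analysis(default_sim, default_norm):
    """Classified records, expression-heterosis matrix, trait heterosis, correlations."""
    sim = default_sim
    records = mp.panel_records(default_norm, sim.design, sim.panel)
    eh = mp.expression_heterosis_matrix(records, order=sim.panel.hybrids)
    th = mp.trait_heterosis(sim.traits, sim.panel)
    corr = mp.protein_trait_correlation(eh, th)
    return {"records": records, "eh": eh, "trait_h": th, "corr": corr}


@pytest.fixture()
def tiny_matrix():
    return mp.AbundanceMatrix(
        pd.DataFrame(
            [[8.0, 12.0, 15.0], [2.0, 4.0, np.nan]],
            index=["f1", "f2"],
            columns=["a1", "a2", "h1"],
        )
    )


@pytest.fixture()
def tiny_design():
    return mp.SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "h1"],
                "genotype": ["B73", "B73", "B73xMo17"],
                "replicate": [1, 2, 1],
                "run": ["run1", "run1", "run1"],
                "tissue": ["seedling_leaf"] * 3,
                "role": ["inbred", "inbred", "hybrid"],
            }
        )
    )
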