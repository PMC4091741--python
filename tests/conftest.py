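import numpy as np
import pandas as pd
import pytest

from txdist import simulate


@pytest.fixture
def small_study():
    """Two-group study with spiked effects and a known truth record."""
    config = simulate.StudyConfig(
        n_genes=300,
        groups=[("WT", 3), ("GM", 3)],
        de_spikes=[("GM", 20, 2.0)],
        seed=11,
    )
    return simulate.generate_expression_study(config)


@pytest.fixture
def batch_study():
    """Two-batch study with injected per-gene batch offsets."""
    config = simulate.StudyConfig(
        n_genes=200,
        groups=[("WT", 4), ("GM", 4)],
        batch_assignments={
            "WT_1": "b1", "WT_2": "b1", "GM_1": "b1", "GM_2": "b1",
            "WT_3": "b2", "WT_4": "b2", "GM_3": "b2", "GM_4": "b2",
        },
        seed=7,
    )
    return simulate.generate_expression_study(config)


@pytest.fixture
def three_group_study():
    """Wild type plus two independently modified lines, three replicates
    each — the comparison design of the assessment."""
    config = simulate.StudyConfig(
        n_genes=250,
        groups=[("WT", 3), ("GMa", 3), ("GMb", 3)],
        de_spikes=[("GMa", 15, 1.5), ("GMb", 10, -1.5)],
        seed=5,
    )
    return simulate.generate_expression_study(config)
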