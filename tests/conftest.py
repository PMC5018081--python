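import numpy as np
import pytest

from capmotion import (
    Dataset,
    SyntheticScenario,
    compute_tip_context,
    correct_dataset,
    resolve_dataset,
    simulate,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with divisions (40 cells, 30 steps)."""
    scenario = SyntheticScenario(n_cells=40, n_steps=30, division_prob=0.01, seed=7)
    dataset, ledger = simulate(scenario)
    return scenario, dataset, ledger


@pytest.fixture(scope="session")
def default_sim():
    """Default-sized scenario (200 cells, 70 steps, 3 drifting tips)."""
    scenario = SyntheticScenario(seed=3)
    dataset, ledger = simulate(scenario)
    return scenario, dataset, ledger


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Resolved/context/corrected tables for the default scenario."""
    _, dataset, _ = default_sim
    resolved, links = resolve_dataset(dataset.cells)
    resolved_ds = Dataset(
        resolved, dataset.tip_clouds, dataset.tip_ends,
        dataset.attachments, dataset.annotated_tracks, dataset.metadata,
    )
    context = compute_tip_context(resolved_ds)
    corrected = correct_dataset(resolved, dataset.tip_ends)
    return {
        "dataset": dataset,
        "resolved": resolved,
        "links": links,
        "context": context,
        "corrected": corrected,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
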