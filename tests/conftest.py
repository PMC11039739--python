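import numpy as np
import pandas as pd
import pytest

from crisprmod import hit_calling, screen_qc, synthetic


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated screen with planted resistance genes."""
    cfg = synthetic.ScreenSimConfig(n_genes=200, n_resistance_genes=10, seed=11)
    gcm, design, truth = synthetic.simulate_screen(cfg)
    return cfg, gcm, design, truth


@pytest.fixture(scope="session")
def small_screen_enrichment(small_screen):
    _, gcm, design, _ = small_screen
    norm = screen_qc.normalize_counts(gcm)
    return hit_calling.guide_fold_differences(norm, design)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_counts():
    """Tiny guide count matrix with a guide -> gene map."""
    counts = pd.DataFrame(
        {"s1": [10, 30, 50, 7], "s2": [20, 60, 100, 14], "s3": [12, 28, 55, 9]},
        index=["gA_sg0", "gA_sg1", "gB_sg0", "gB_sg1"],
    )
    gene_map = pd.Series(["gA", "gA", "gB", "gB"], index=counts.index)
    return screen_qc.GuideCountMatrix(counts=counts, gene_map=gene_map)
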