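import numpy as np
import pandas as pd
import pytest

from cgsig import MarkerProfile, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A reduced paired cohort shared by unit tests (fast to analyze)."""
    cfg = SimulationConfig(
        seed=7,
        n_samples=30,
        n_paired=10,
        n_chromosomes=1,
        markers_per_chromosome=200,
        n_genes=150,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def two_level_profile():
    """100 markers ~N(0, 0.1) then 100 ~N(1, 0.1) on one chromosome."""
    rng = np.random.default_rng(42)
    x = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(1, 0.1, 100)])
    return MarkerProfile(
        sample_id="S0",
        chromosomes=np.array(["1"] * 200, dtype=object),
        positions=np.arange(200) * 1000 + 1000,
        log_ratios=x,
    )


def make_profile(values, chrom="1", sample_id="S0", spacing=1000):
    values = np.asarray(values, dtype=float)
    return MarkerProfile(
        sample_id=sample_id,
        chromosomes=np.array([chrom] * len(values), dtype=object),
        positions=np.arange(len(values)) * spacing + spacing,
        log_ratios=values,
    )
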